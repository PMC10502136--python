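"""Physical locus definition on FDR-valued variants, FUMA-protocol style.

Independent significant variants are greedily selected in ascending conjFDR at
mutual r^2 < 0.6; lead variants are the subset mutually at r^2 < 0.1.  A locus
is the min-max base-pair span of all candidate variants (conjFDR < 0.1 and
r^2 >= 0.6 with an independent significant variant); loci closer than 250 kb on
the same chromosome are merged.  Effect-direction concordance compares the lead
variant's z-score signs in the two source GWAS.  All coordinates are 1-based
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .sumstats import LDPanel

CANDIDATE_FDR = 0.1
SIGNIFICANT_FDR = 0.05
INDEP_R2 = 0.6
LEAD_R2 = 0.1
MERGE_DIST = 250_000


@dataclass
class Locus:
    chrom: int
    start_bp: int
    end_bp: int
    lead_snp: str
    lead_conjfdr: float
    z1: float
    z2: float
    p1: float = float("nan")
    p2: float = float("nan")
    concordant: bool | None = None
    novel: bool | None = None

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("locus start after end")

    def overlaps(self, other: "Locus") -> bool:
        return (self.chrom == other.chrom
                and self.start_bp <= other.end_bp
                and other.start_bp <= self.end_bp)


@dataclass
class LocusSet:
    loci: list[Locus]
    label: str = ""

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "Chr": l.chrom,
                "MinBP": l.start_bp,
                "MaxBP": l.end_bp,
                "LeadSNP": l.lead_snp,
                "conjFDR": l.lead_conjfdr,
                "Z1": l.z1,
                "P1": l.p1,
                "Z2": l.z2,
                "P2": l.p2,
                "Concordant": l.concordant,
                "Novel": l.novel,
            }
            for l in self.loci
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        # report-layer rounding only; internal values keep full precision
        for col in ("Z1", "Z2"):
            if col in df:
                df[col] = df[col].round(2)
        df.to_csv(path, sep="\t", index=False)


def _pairwise_r2(panel: LDPanel, idx: np.ndarray) -> np.ndarray:
    """Dense r^2 among the given panel row indices (0 across blocks)."""
    block_id = np.empty(len(panel), int)
    for b, sl in enumerate(panel.block_slices()):
        block_id[sl] = b
    r2 = np.zeros((len(idx), len(idx)))
    bid = block_id[idx]
    starts = np.array([sl.start for sl in panel.block_slices()])
    for b in np.unique(bid):
        sel = np.where(bid == b)[0]
        local = idx[sel] - starts[b]
        R = panel.blocks[b]
        r2[np.ix_(sel, sel)] = np.square(R[np.ix_(local, local)])
    return r2


def independent_significant(conjfdr: np.ndarray, panel: LDPanel,
                            threshold: float = SIGNIFICANT_FDR,
                            r2: float = INDEP_R2) -> np.ndarray:
    """Indices of independent significant variants (greedy by ascending conjFDR).

    A variant qualifies if conjFDR < ``threshold`` and its r^2 with every
    already-selected variant is below ``r2``.
    """
    conjfdr = np.asarray(conjfdr, float)
    sig = np.where(conjfdr < threshold)[0]
    if len(sig) == 0:
        return np.array([], dtype=int)
    sig = sig[np.argsort(conjfdr[sig], kind="stable")]
    r2m = _pairwise_r2(panel, sig)
    chosen: list[int] = []
    for i in range(len(sig)):
        if all(r2m[i, j] < r2 for j in chosen):
            chosen.append(i)
    return np.sort(sig[chosen])


def define_loci(conjfdr: np.ndarray, panel: LDPanel,
                z1: np.ndarray, z2: np.ndarray,
                p1: np.ndarray | None = None, p2: np.ndarray | None = None,
                threshold: float = SIGNIFICANT_FDR,
                candidate_fdr: float = CANDIDATE_FDR,
                merge_dist: int = MERGE_DIST,
                label: str = "") -> LocusSet:
    """Build the locus set from per-variant conjFDR values and the LD panel.

    Lead variants are independent significant variants mutually at
    r^2 < 0.1; each locus spans the min-max positions of its candidate
    variants (conjFDR < ``candidate_fdr`` with r^2 >= 0.6 to an independent
    significant variant); loci within ``merge_dist`` bp merge, keeping the
    lowest-conjFDR lead.
    """
    conjfdr = np.asarray(conjfdr, float)
    chrom = panel.index["CHR"].to_numpy()
    bp = panel.index["BP"].to_numpy()
    snp = panel.index["SNP"].to_numpy()
    indep = independent_significant(conjfdr, panel, threshold=threshold)
    if len(indep) == 0:
        return LocusSet(loci=[], label=label)
    # leads: subset of independent significant variants mutually at r^2 < 0.1
    r2m = _pairwise_r2(panel, indep)
    order = np.argsort(conjfdr[indep], kind="stable")
    lead_pos: list[int] = []
    for i in order:
        if all(r2m[i, j] < LEAD_R2 for j in lead_pos):
            lead_pos.append(i)
    leads = np.sort(indep[np.array(lead_pos)])
    # candidates: conjFDR < candidate_fdr and r^2 >= 0.6 with an indep.-sig. variant
    cand_mask = conjfdr < candidate_fdr
    cand = np.where(cand_mask)[0]
    both = np.unique(np.concatenate([cand, indep]))
    r2_all = _pairwise_r2(panel, both)
    pos_of = {v: i for i, v in enumerate(both)}
    indep_cols = np.array([pos_of[v] for v in indep])
    linked = r2_all[:, indep_cols] >= INDEP_R2
    # assign each candidate to the indep variant it tags (highest r^2)
    assign = {}
    for row, v in enumerate(both):
        if not cand_mask[v] and v not in indep:
            continue
        hits = np.where(linked[row])[0]
        if len(hits) == 0:
            continue
        best = hits[np.argmax(r2_all[row, indep_cols[hits]])]
        assign.setdefault(indep[best], []).append(v)
    # group independent variants under their lead (r^2 >= 0.1 chain to a lead)
    lead_cols = np.array([pos_of[v] for v in leads])
    loci: list[Locus] = []
    for lead in leads:
        members = [v for v in indep
                   if r2_all[pos_of[v], pos_of[lead]] >= LEAD_R2 or v == lead]
        span = []
        for m in members:
            span.extend(assign.get(m, [m]))
        span = np.array(sorted(set(span)))
        span = span[chrom[span] == chrom[lead]]
        in_locus = span[conjfdr[span] < candidate_fdr]
        if len(in_locus) == 0:
            in_locus = np.array([lead])
        best = in_locus[np.argmin(conjfdr[in_locus])]
        loci.append(Locus(
            chrom=int(chrom[lead]),
            start_bp=int(bp[in_locus].min()),
            end_bp=int(bp[in_locus].max()),
            lead_snp=str(snp[best]),
            lead_conjfdr=float(conjfdr[in_locus].min()),
            z1=float(z1[best]), z2=float(z2[best]),
            p1=float(p1[best]) if p1 is not None else float("nan"),
            p2=float(p2[best]) if p2 is not None else float("nan"),
        ))
    # merge loci closer than merge_dist on the same chromosome
    loci.sort(key=lambda l: (l.chrom, l.start_bp))
    merged: list[Locus] = []
    for l in loci:
        if merged and l.chrom == merged[-1].chrom \
                and l.start_bp - merged[-1].end_bp < merge_dist:
            prev = merged[-1]
            keep = prev if prev.lead_conjfdr <= l.lead_conjfdr else l
            merged[-1] = replace(keep,
                                 start_bp=min(prev.start_bp, l.start_bp),
                                 end_bp=max(prev.end_bp, l.end_bp))
        else:
            merged.append(l)
    return LocusSet(loci=merged, label=label)


def concordance(locus: Locus) -> bool:
    """True iff the lead variant's z-scores agree in sign across the two GWAS."""
    if locus.z1 == 0 or locus.z2 == 0:
        raise ValueError(f"zero z-score at lead {locus.lead_snp}: direction undefined")
    return (locus.z1 > 0) == (locus.z2 > 0)


def annotate_concordance(locus_set: LocusSet) -> LocusSet:
    for l in locus_set.loci:
        l.concordant = concordance(l)
    return locus_set


def concordant_share(locus_set: LocusSet) -> tuple[int, int, int]:
    """(n_concordant, n_total, integer percent) over a locus set."""
    if len(locus_set) == 0:
        raise ValueError("empty locus set")
    flags = [concordance(l) if l.concordant is None else l.concordant
             for l in locus_set]
    n_conc = int(sum(flags))
    n_tot = len(flags)
    return n_conc, n_tot, round(100.0 * n_conc / n_tot)


def union_count(set_a: LocusSet, set_b: LocusSet) -> int:
    """Distinct loci across two analyses; >= 1 bp physical overlap counts once."""
    overlapping = 0
    used_b: set[int] = set()
    for la in set_a:
        for j, lb in enumerate(set_b):
            if j in used_b:
                continue
            if la.overlaps(lb):
                overlapping += 1
                used_b.add(j)
                break
    return len(set_a) + len(set_b) - overlapping


def annotate_novelty(locus_set: LocusSet,
                     known_intervals: list[tuple[int, int, int]]) -> LocusSet:
    """Flag loci with no physical overlap with any known (chrom, start, end) interval."""
    for l in locus_set.loci:
        l.novel = not any(
            l.chrom == c and l.start_bp <= e and s <= l.end_bp
            for c, s, e in known_intervals
        )
    return locus_set
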