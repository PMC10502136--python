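"""GWAS summary-statistics I/O, validation, harmonization and LD reference handling.

Summary statistics for one trait are held in a :class:`SumStats` wrapper around a
pandas DataFrame with the canonical columns ``SNP CHR BP A1 A2 Z P N`` sorted by
(CHR, BP).  The LD reference is a :class:`LDPanel`: a variant index plus a list of
block-diagonal correlation matrices that partition the index and never span a
chromosome boundary.

Coordinates are 1-based inclusive throughout (hg19-style printed intervals); the
genome build is a label only and never checked against the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger("pleiomix")

#: canonical column order for summary-statistics tables
SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "Z", "P", "N"]

#: tolerance for the |p - 2*Phi(-|z|)| consistency check; loose enough for
#: rounded published inputs, tight enough to catch column mix-ups
PZ_TOLERANCE = 1e-4

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: long-range LD regions excluded from FDR-model fitting (hg19, 1-based
#: inclusive): extended MHC, 8p23.1 inversion, MAPT region
DEFAULT_EXCLUSION_REGIONS = (
    (6, 25_119_106, 33_854_733),
    (8, 7_242_715, 12_483_982),
    (17, 40_000_000, 47_000_000),
)


class SumStatsError(ValueError):
    """Raised for unrecoverable summary-statistics problems."""


@dataclass
class SumStats:
    """One trait's per-variant GWAS results, validated and position-sorted."""

    df: pd.DataFrame
    trait: str = "trait"

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.df.columns]
        if missing:
            raise SumStatsError(f"missing mandatory column(s): {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def z(self) -> np.ndarray:
        return self.df["Z"].to_numpy(float)

    @property
    def p(self) -> np.ndarray:
        return self.df["P"].to_numpy(float)

    @property
    def n_eff(self) -> float:
        """Median per-variant sample size (scalar N used by the model fits)."""
        return float(np.median(self.df["N"].to_numpy(float)))


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows violating the per-variant invariants; return (kept, n_dropped)."""
    z = pd.to_numeric(df["Z"], errors="coerce")
    p = pd.to_numeric(df["P"], errors="coerce")
    a1 = df["A1"].astype(str).str.upper()
    a2 = df["A2"].astype(str).str.upper()
    ok = (
        np.isfinite(z)
        & np.isfinite(p)
        & (p > 0)
        & (p <= 1)
        & a1.isin(VALID_BASES)
        & a2.isin(VALID_BASES)
        & (a1 != a2)
    )
    # p/z consistency where both are present and finite
    with np.errstate(invalid="ignore"):
        p_implied = 2.0 * norm.sf(np.abs(z))
    ok &= np.abs(p - p_implied) <= PZ_TOLERANCE
    out = df.loc[ok.to_numpy(bool)].copy()
    out["A1"] = a1[ok]
    out["A2"] = a2[ok]
    out["Z"] = z[ok]
    out["P"] = p[ok]
    return out, int((~ok).sum())


def read_sumstats(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    trait: str | None = None,
    default_n: float | None = None,
) -> SumStats:
    """Read a whitespace/tab-delimited summary-statistics file with a header row.

    ``column_map`` maps canonical names (``SNP``, ``CHR``, ...) to the file's
    column names.  Rows failing validation (p outside (0,1], non-ACGT or equal
    alleles, p/z inconsistency) are dropped with a logged count.  A missing ``N``
    column falls back to the scalar ``default_n``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    if df.empty:
        raise SumStatsError(f"empty summary-statistics file: {path}")
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    if "N" not in df.columns:
        if default_n is None:
            raise SumStatsError("missing mandatory column: N (and no default_n given)")
        df["N"] = default_n
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise SumStatsError(f"missing mandatory column(s): {missing}")
    df = df[SUMSTATS_COLUMNS].copy()
    for col in ("CHR", "BP"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    df = df.dropna(subset=["CHR", "BP"])
    df["CHR"] = df["CHR"].astype(int)
    df["BP"] = df["BP"].astype(int)
    df["N"] = pd.to_numeric(df["N"], errors="coerce")
    df, n_dropped = _validate_rows(df)
    if n_dropped:
        logger.info("read_sumstats(%s): dropped %d invalid row(s)", path.name, n_dropped)
    dup = df.duplicated(subset="SNP", keep="first")
    if dup.any():
        logger.info("read_sumstats(%s): dropped %d duplicate variant id(s)", path.name, int(dup.sum()))
        df = df.loc[~dup]
    df = df.sort_values(["CHR", "BP"], kind="mergesort").reset_index(drop=True)
    if df.empty:
        raise SumStatsError(f"no valid rows in {path}")
    return SumStats(df, trait=trait or path.stem)


# ---------------------------------------------------------------------------
# LD panel
# ---------------------------------------------------------------------------


@dataclass
class LDPanel:
    """Block-diagonal LD correlation structure over a fixed variant index.

    ``index`` holds columns ``SNP CHR BP A1 A2`` in (CHR, BP) order; ``blocks``
    are symmetric correlation matrices (diagonal 1) whose sizes partition the
    index; no block crosses a chromosome boundary.
    """

    index: pd.DataFrame
    blocks: list[np.ndarray]
    build: str = "hg19"
    _ld_score: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        sizes = [b.shape[0] for b in self.blocks]
        if sum(sizes) != len(self.index):
            raise ValueError("block sizes do not partition the variant index")
        self.index = self.index.reset_index(drop=True)
        chroms = self.index["CHR"].to_numpy()
        start = 0
        for size in sizes:
            if len(set(chroms[start : start + size])) > 1:
                raise ValueError("an LD block crosses a chromosome boundary")
            start += size

    def __len__(self) -> int:
        return len(self.index)

    @property
    def n_variants(self) -> int:
        return len(self.index)

    def block_slices(self) -> list[slice]:
        out, start = [], 0
        for b in self.blocks:
            out.append(slice(start, start + b.shape[0]))
            start += b.shape[0]
        return out

    @property
    def ld_score(self) -> np.ndarray:
        if self._ld_score is None:
            self._ld_score = compute_ld_scores(self)
        return self._ld_score


def compute_ld_scores(panel: LDPanel) -> np.ndarray:
    """Per-variant LD score: ell_j = sum_k r^2_jk over the variant's block.

    The self term r^2_jj = 1 is included, so ell >= 1 everywhere.
    """
    return np.concatenate([np.square(b).sum(axis=1) for b in panel.blocks])


def make_ar1_panel(
    n_variants: int,
    block_size: int = 50,
    r: float = 0.9,
    n_chrom: int = 22,
    bp_spacing: int = 10_000,
    rng: np.random.Generator | None = None,
) -> LDPanel:
    """Construct an AR(1)-block LD panel with an evenly spaced variant index.

    Each block of ``block_size`` variants has correlations r^{|i-j|}; blocks are
    spread round-robin-free across ``n_chrom`` chromosomes in contiguous runs so
    no block crosses a chromosome.  The closed-form LD score of an interior AR(1)
    variant makes this panel convenient for oracle tests.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n_blocks = int(np.ceil(n_variants / block_size))
    sizes = [block_size] * (n_blocks - 1) + [n_variants - block_size * (n_blocks - 1)]
    blocks_per_chrom = int(np.ceil(n_blocks / n_chrom))
    chrom_of_block = [min(1 + i // blocks_per_chrom, n_chrom) for i in range(n_blocks)]
    rows = []
    pos_by_chrom = {c: 0 for c in range(1, n_chrom + 1)}
    idx = 0
    blocks = []
    for b, size in enumerate(sizes):
        d = np.abs(np.subtract.outer(np.arange(size), np.arange(size)))
        blocks.append(r ** d.astype(float))
        chrom = chrom_of_block[b]
        for _ in range(size):
            pos_by_chrom[chrom] += bp_spacing
            rows.append((f"rs{idx + 1}", chrom, pos_by_chrom[chrom]))
            idx += 1
    index = pd.DataFrame(rows, columns=["SNP", "CHR", "BP"])
    alleles = rng.choice(len(_ALLELE_PAIRS), size=n_variants)
    index["A1"] = [_ALLELE_PAIRS[a][0] for a in alleles]
    index["A2"] = [_ALLELE_PAIRS[a][1] for a in alleles]
    return LDPanel(index=index, blocks=blocks)


#: unambiguous allele pairs only (no A/T, C/G) — the generator never emits
#: strand-ambiguous variants
_ALLELE_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]


def write_panel(panel: LDPanel, directory: str | Path) -> None:
    """Serialize a panel: one whitespace text matrix per block plus an index TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    panel.index.to_csv(directory / "variants.tsv", sep="\t", index=False)
    for i, b in enumerate(panel.blocks):
        np.savetxt(directory / f"block_{i:05d}.txt", b, fmt="%.6g")


def read_panel(directory: str | Path, build: str = "hg19") -> LDPanel:
    directory = Path(directory)
    index = pd.read_csv(directory / "variants.tsv", sep="\t")
    blocks = [
        np.atleast_2d(np.loadtxt(f))
        for f in sorted(directory.glob("block_*.txt"))
    ]
    return LDPanel(index=index, blocks=blocks, build=build)


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------


def _is_ambiguous(a1: pd.Series, a2: pd.Series) -> pd.Series:
    comp = a1.map(COMPLEMENT)
    return comp == a2


def harmonize_pair(
    s1: SumStats, s2: SumStats, panel: LDPanel
) -> tuple[SumStats, SumStats]:
    """Restrict both traits to the panel's variant set with alleles reconciled.

    For each trait, variants are matched to the panel by id; alleles are
    reconciled to the panel's effect allele, flipping the z sign on an allele
    swap and accepting strand-complement encodings.  Strand-ambiguous (A/T,
    C/G) variants are always dropped.  Returns two tables over the identical,
    panel-ordered variant subset.
    """
    aligned = []
    for s in (s1, s2):
        df = s.df.merge(
            panel.index[["SNP", "A1", "A2"]].rename(columns={"A1": "PA1", "A2": "PA2"}),
            on="SNP",
            how="inner",
        )
        a1, a2 = df["A1"], df["A2"]
        ambiguous = _is_ambiguous(a1, a2) | _is_ambiguous(df["PA1"], df["PA2"])
        same = (a1 == df["PA1"]) & (a2 == df["PA2"])
        swap = (a1 == df["PA2"]) & (a2 == df["PA1"])
        c1, c2 = a1.map(COMPLEMENT), a2.map(COMPLEMENT)
        comp_same = (c1 == df["PA1"]) & (c2 == df["PA2"])
        comp_swap = (c1 == df["PA2"]) & (c2 == df["PA1"])
        keep = ~ambiguous & (same | swap | comp_same | comp_swap)
        flip = ~ambiguous & ~same & ~comp_same & (swap | comp_swap)
        n_flip = int(flip.sum())
        if n_flip:
            logger.info("harmonize_pair(%s): flipped z sign for %d variant(s)", s.trait, n_flip)
        df = df.loc[keep].copy()
        df.loc[flip[keep], "Z"] = -df.loc[flip[keep], "Z"]
        df["A1"] = df.loc[:, "PA1"]
        df["A2"] = df.loc[:, "PA2"]
        df = df.drop(columns=["PA1", "PA2"])
        aligned.append(df)
    common = pd.Index(aligned[0]["SNP"]).intersection(aligned[1]["SNP"])
    order = panel.index.loc[panel.index["SNP"].isin(common), "SNP"]
    if len(order) < 2:
        raise SumStatsError("fewer than 2 variants survive harmonization")
    out = []
    for s, df in zip((s1, s2), aligned):
        df = df.set_index("SNP").loc[order].reset_index()
        out.append(SumStats(df[SUMSTATS_COLUMNS], trait=s.trait))
    return out[0], out[1]


def subset_panel(panel: LDPanel, snp_ids: Iterable[str]) -> LDPanel:
    """Restrict a panel (index and blocks) to the given variant ids, in panel order."""
    wanted = set(snp_ids)
    mask = panel.index["SNP"].isin(wanted).to_numpy()
    new_blocks = []
    for sl, b in zip(panel.block_slices(), panel.blocks):
        m = mask[sl]
        if m.any():
            new_blocks.append(b[np.ix_(m, m)])
    return LDPanel(index=panel.index.loc[mask], blocks=new_blocks, build=panel.build)


# ---------------------------------------------------------------------------
# Exclusion regions
# ---------------------------------------------------------------------------


@dataclass
class ExclusionRegions:
    """Genomic intervals removed from FDR-model fitting (never from discovery)."""

    intervals: Sequence[tuple[int, int, int]] = DEFAULT_EXCLUSION_REGIONS

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start > end:
                raise ValueError(f"interval start > end on chr{chrom}")

    @classmethod
    def from_file(cls, path: str | Path) -> "ExclusionRegions":
        """Read a BED-like text file (chrom, start, end), 1-based inclusive."""
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                         names=["chrom", "start", "end"])
        df["chrom"] = df["chrom"].astype(str).str.removeprefix("chr").astype(int)
        return cls(intervals=[tuple(r) for r in df.itertuples(index=False)])


def apply_exclusions(table: SumStats, regions: ExclusionRegions | None = None) -> np.ndarray:
    """Boolean mask, True = retained for FDR-table fitting.

    Variants inside any exclusion interval are masked out of the fitting set
    only; discovery always uses every variant.
    """
    if regions is None:
        regions = ExclusionRegions()
    chrom = table.df["CHR"].to_numpy()
    bp = table.df["BP"].to_numpy()
    mask = np.ones(len(table), dtype=bool)
    for c, start, end in regions.intervals:
        mask &= ~((chrom == c) & (bp >= start) & (bp <= end))
    return mask
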