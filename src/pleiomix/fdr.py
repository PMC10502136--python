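"""Conditional and conjunctional FDR from paired GWAS p-values.

condFDR(p1 | p2 <= s) estimates the probability that a variant is null for the
primary trait given that both observed p-values are at least as extreme as
(p1, s).  With the null fraction conservatively fixed at 1 it reduces to the
stratified empirical-Bayes ratio

    condFDR = p1 / Fhat(p1 | p2 <= s),

where Fhat is the empirical CDF of primary p-values within the secondary
stratum.  The lookup table is averaged over random LD prunings (one variant
kept per r^2 > 0.1 clique) so LD-redundant strata do not distort the CDF, and
is made monotone by cumulative sweeps.  conjFDR is the elementwise maximum of
the two reciprocal condFDR values.

The three long-range LD exclusion regions are removed from table fitting only;
every variant still receives a condFDR value for discovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .sumstats import LDPanel

logger = logging.getLogger("pleiomix")

#: condFDR / conjFDR significance thresholds (strict inequalities)
COND_FDR_THRESHOLD = 0.01
CONJ_FDR_THRESHOLD = 0.05

#: secondary-trait p-value strata of the conditional QQ display
QQ_THRESHOLDS = (1.0, 0.1, 0.01, 0.001)

#: lookup-table secondary thresholds: the QQ strata plus interpolation headroom
TABLE_THRESHOLDS = (1.0, 0.1, 0.01, 0.001, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8)


# ---------------------------------------------------------------------------
# Conditional QQ curves
# ---------------------------------------------------------------------------


@dataclass
class QQCurves:
    """Observed vs expected -log10 p of the primary trait per secondary stratum."""

    thresholds: tuple[float, ...]
    expected: dict[float, np.ndarray]
    observed: dict[float, np.ndarray]

    def curve(self, threshold: float) -> tuple[np.ndarray, np.ndarray]:
        return self.expected[threshold], self.observed[threshold]


def conditional_qq(p_primary: np.ndarray, p_secondary: np.ndarray,
                   thresholds: tuple[float, ...] = QQ_THRESHOLDS,
                   min_stratum: int = 100) -> QQCurves:
    """Empirical QQ quantiles of primary p among variants passing each secondary cut.

    The threshold-1 stratum is the unconditional QQ curve.  Strata with fewer
    than ``min_stratum`` variants are omitted with a warning.
    """
    p1 = np.asarray(p_primary, float)
    p2 = np.asarray(p_secondary, float)
    expected, observed = {}, {}
    for thr in thresholds:
        sel = p2 <= thr
        n = int(sel.sum())
        if n < min_stratum:
            logger.warning("conditional_qq: stratum p2<=%g has %d < %d variants; omitted",
                           thr, n, min_stratum)
            continue
        ps = np.sort(p1[sel])
        ranks = (np.arange(n) + 0.5) / n
        expected[thr] = -np.log10(ranks)
        observed[thr] = -np.log10(ps)
    return QQCurves(thresholds=tuple(expected), expected=expected, observed=observed)


# ---------------------------------------------------------------------------
# condFDR lookup table
# ---------------------------------------------------------------------------


@dataclass
class FDRLookup:
    """Grid of condFDR values over (-log10 p1 breakpoints) x (secondary thresholds)."""

    log10p1_grid: np.ndarray            # ascending, length G
    thresholds: np.ndarray              # secondary p cuts, descending (1 .. 1e-8)
    table: np.ndarray                   # (G, T) condFDR values in (0, 1]
    n_prune: int

    def lookup(self, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
        return assign_condfdr(p1, p2, self)


def _prune_mask(panel: LDPanel, r2: float, rng: np.random.Generator) -> np.ndarray:
    """Random LD pruning: keep one variant per r^2 > ``r2`` clique.

    Within each block, variants are visited in random order; a visited variant
    is kept unless it is in LD above the cut with an already-kept variant.
    """
    keep = np.zeros(len(panel), dtype=bool)
    for sl, R in zip(panel.block_slices(), panel.blocks):
        n = R.shape[0]
        high = np.square(R) > r2
        alive = np.ones(n, dtype=bool)
        for i in rng.permutation(n):
            if alive[i]:
                keep[sl.start + i] = True
                alive &= ~high[i]
    return keep


def condfdr_table(p_primary: np.ndarray, p_secondary: np.ndarray,
                  mask: np.ndarray | None, panel: LDPanel | None,
                  n_prune: int = 100, seed: int = 0,
                  prune_r2: float = 0.1,
                  log10p_max: float = 10.0, n_breaks: int = 201,
                  thresholds: tuple[float, ...] = TABLE_THRESHOLDS,
                  min_stratum: int = 100) -> FDRLookup:
    """Estimate the stratified condFDR lookup table.

    ``mask`` (True = usable) removes exclusion-region variants from fitting.
    Each of ``n_prune`` random prunings recomputes the stratified empirical CDF
    on an approximately LD-independent variant subset; cell values are averaged
    across prunings, clipped to (0, 1], and made monotone non-increasing in
    both significance directions by cumulative-minimum sweeps.

    Strata with fewer than ``min_stratum`` pruned variants are unusable: the
    empirical CDF of a handful of points overestimates F(p) at small p (its
    floor is 0.5/n), which would underestimate condFDR.  Such strata inherit
    the nearest wider stratum instead.
    """
    p1 = np.asarray(p_primary, float)
    p2 = np.asarray(p_secondary, float)
    if mask is None:
        mask = np.ones(len(p1), bool)
    grid = np.linspace(0.0, log10p_max, n_breaks)
    p1_break = 10.0 ** (-grid)
    thr = np.asarray(sorted(thresholds, reverse=True), float)
    acc = np.zeros((n_breaks, len(thr)))
    col_counts = np.zeros(len(thr))
    rng = np.random.default_rng(seed)
    n_iter = n_prune if panel is not None else 1
    for _ in range(n_iter):
        sub = mask & (_prune_mask(panel, prune_r2, rng) if panel is not None
                      else np.ones(len(p1), bool))
        q1, q2 = p1[sub], p2[sub]
        tab = np.empty((n_breaks, len(thr)))
        for j, s in enumerate(thr):
            in_str = q2 <= s
            n = int(in_str.sum())
            if n < max(min_stratum, 1):
                tab[:, j] = np.nan
                continue
            ps = np.sort(q1[in_str])
            # empirical CDF with a half-count continuity offset, floored at 1/n
            cdf = np.maximum(np.searchsorted(ps, p1_break, side="right") - 0.5, 0.5) / n
            tab[:, j] = np.clip(p1_break / cdf, None, 1.0)
        ok = ~np.isnan(tab[0])
        col_counts += ok
        acc += np.where(np.isnan(tab), 0.0, tab)
    if col_counts[0] == 0:
        raise ValueError(
            f"fewer than {min_stratum} pruned variants overall; "
            "cannot estimate a condFDR table")
    table = acc / np.maximum(col_counts, 1)[None, :]
    # unusable (too-small) strata inherit the nearest less-extreme stratum
    for j in range(1, len(thr)):
        if col_counts[j] == 0:
            table[:, j] = table[:, j - 1]
            logger.warning("condfdr_table: stratum p2<=%g below %d pruned variants"
                           " in every pruning; inherits p2<=%g",
                           thr[j], min_stratum, thr[j - 1])
    table = np.clip(table, 1e-12, 1.0)
    # monotone non-increasing with increasing significance on both axes
    table = np.minimum.accumulate(table, axis=0)   # down the p1 grid
    table = np.minimum.accumulate(table, axis=1)   # across tightening strata
    return FDRLookup(log10p1_grid=grid, thresholds=thr, table=table, n_prune=n_iter)


def assign_condfdr(p1: np.ndarray, p2: np.ndarray, table: FDRLookup) -> np.ndarray:
    """Per-variant condFDR by bilinear interpolation in -log10 p space.

    Queries beyond the grid clamp to the edge cells.
    """
    p1 = np.atleast_1d(np.asarray(p1, float))
    p2 = np.atleast_1d(np.asarray(p2, float))
    x = np.clip(-np.log10(np.clip(p1, 1e-300, 1.0)), 0, table.log10p1_grid[-1])
    y = np.clip(-np.log10(np.clip(p2, 1e-300, 1.0)), 0, -np.log10(table.thresholds[-1]))
    gx = table.log10p1_grid
    gy = -np.log10(table.thresholds)  # ascending significance
    ix = np.clip(np.searchsorted(gx, x) - 1, 0, len(gx) - 2)
    iy = np.clip(np.searchsorted(gy, y) - 1, 0, len(gy) - 2)
    fx = (x - gx[ix]) / (gx[ix + 1] - gx[ix])
    fy = (y - gy[iy]) / (gy[iy + 1] - gy[iy])
    t = table.table
    v = (t[ix, iy] * (1 - fx) * (1 - fy)
         + t[ix + 1, iy] * fx * (1 - fy)
         + t[ix, iy + 1] * (1 - fx) * fy
         + t[ix + 1, iy + 1] * fx * fy)
    return v


def conjfdr(cond_1given2: np.ndarray, cond_2given1: np.ndarray) -> np.ndarray:
    """Conjunctional FDR: elementwise maximum of the two reciprocal condFDRs."""
    a = np.asarray(cond_1given2, float)
    b = np.asarray(cond_2given1, float)
    if a.shape != b.shape:
        raise ValueError("condFDR vectors must be aligned")
    return np.maximum(a, b)


def call_significant(values: np.ndarray, mode: str = "conj") -> np.ndarray:
    """Boolean significance mask with strict thresholds: cond < 0.01, conj < 0.05."""
    values = np.asarray(values, float)
    if mode == "cond":
        return values < COND_FDR_THRESHOLD
    if mode == "conj":
        return values < CONJ_FDR_THRESHOLD
    raise ValueError(f"unknown mode {mode!r}")
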