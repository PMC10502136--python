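"""LD-score regression: SNP heritability and cross-trait genetic correlation.

Univariate model: E[z_j^2] = intercept + N * h2 * ell_j / M, fitted by weighted
least squares with weights from a two-pass fit (first pass unweighted to get a
provisional (intercept, h2), second pass with 1 / (2 * mu_j^2) variance
weights).  Cross-trait model: E[z1_j z2_j] = intercept + sqrt(N1 N2) * rho_g *
ell_j / M, whose intercept absorbs the sample-overlap term.  Standard errors
come from a delete-one block jackknife over contiguous variant blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm


@dataclass
class UnivariateLdsc:
    h2: float
    intercept: float
    se_h2: float
    se_intercept: float
    n_blocks: int


@dataclass
class LdscResult:
    """Cross-trait LD-score regression summary."""

    h2_1: float
    h2_2: float
    intercept_1: float
    intercept_2: float
    cross_intercept: float
    rho_g: float
    rg: float
    se_rg: float
    p_rg: float
    flags: list[str] = field(default_factory=list)


def _wls(y: np.ndarray, x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted least squares of y on [1, x]; returns (intercept, slope)."""
    X = np.column_stack([np.ones_like(x), x])
    Xw = X * w[:, None]
    beta, *_ = np.linalg.lstsq(Xw.T @ X, Xw.T @ y, rcond=None)
    return beta


def _jackknife(values: np.ndarray) -> float:
    """Standard error of a statistic from delete-one pseudo-estimates."""
    n = len(values)
    return float(np.sqrt((n - 1) / n * np.sum((values - values.mean()) ** 2)))


def _two_pass_fit(y: np.ndarray, ell: np.ndarray, scale: float, M: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Two-pass WLS of y on ell; returns (coef, weights). slope_units: per ell."""
    b0 = _wls(y, ell, np.ones_like(ell))
    mu = np.clip(b0[0] + b0[1] * ell, 0.1, None)
    w = 1.0 / (2.0 * mu**2)
    return _wls(y, ell, w), w


def univariate_ldsc(z: np.ndarray, ell: np.ndarray, N: float, M: int,
                    n_blocks: int = 200) -> UnivariateLdsc:
    """Estimate SNP heritability and inflation intercept from z^2 vs LD score."""
    z = np.asarray(z, float)
    ell = np.asarray(ell, float)
    if len(z) < 200:
        raise ValueError("need at least 200 variants for LD-score regression")
    if np.ptp(ell) < 1e-12:
        raise ValueError("LD scores are constant; regression is degenerate")
    y = z**2
    coef, w = _two_pass_fit(y, ell, N, M)
    h2 = coef[1] * M / N
    n_blocks = min(n_blocks, len(z) // 10)
    splits = np.array_split(np.arange(len(z)), n_blocks)
    pseudo = np.empty((n_blocks, 2))
    for i, sl in enumerate(splits):
        keep = np.ones(len(z), bool)
        keep[sl] = False
        c = _wls(y[keep], ell[keep], w[keep])
        pseudo[i] = (c[0], c[1] * M / N)
    return UnivariateLdsc(
        h2=float(h2),
        intercept=float(coef[0]),
        se_h2=_jackknife(pseudo[:, 1]),
        se_intercept=_jackknife(pseudo[:, 0]),
        n_blocks=n_blocks,
    )


def cross_ldsc(z1: np.ndarray, z2: np.ndarray, ell: np.ndarray,
               N1: float, N2: float, M: int,
               h2_1: float | None = None, h2_2: float | None = None,
               n_blocks: int = 200) -> LdscResult:
    """Cross-trait LD-score regression; rg = rho_g / sqrt(h2_1 * h2_2).

    If the univariate heritabilities are not supplied they are fitted here.
    The product-regression intercept absorbs sample-overlap correlation, so rg
    is unbiased under overlapping cohorts.
    """
    z1, z2, ell = (np.asarray(a, float) for a in (z1, z2, ell))
    u1 = univariate_ldsc(z1, ell, N1, M, n_blocks)
    u2 = univariate_ldsc(z2, ell, N2, M, n_blocks)
    if h2_1 is None:
        h2_1 = u1.h2
    if h2_2 is None:
        h2_2 = u2.h2
    flags = []
    y = z1 * z2
    scale = np.sqrt(N1 * N2)
    # weights from the product-moment variance ~ mu1 * mu2 + cross-term; the
    # univariate two-pass means serve as the variance proxy
    mu1 = np.clip(u1.intercept + N1 * u1.h2 * ell / M, 0.1, None)
    mu2 = np.clip(u2.intercept + N2 * u2.h2 * ell / M, 0.1, None)
    w = 1.0 / (mu1 * mu2)
    coef = _wls(y, ell, w)
    rho_g = coef[1] * M / scale

    def _rg(rho: float) -> float:
        if h2_1 <= 0 or h2_2 <= 0:
            return float("nan")
        return float(np.clip(rho / np.sqrt(h2_1 * h2_2), -1.0, 1.0))

    if h2_1 <= 0 or h2_2 <= 0:
        flags.append("nonpositive heritability; rg undefined")
    n_blocks = min(n_blocks, len(z1) // 10)
    splits = np.array_split(np.arange(len(z1)), n_blocks)
    pseudo = np.empty(n_blocks)
    for i, sl in enumerate(splits):
        keep = np.ones(len(z1), bool)
        keep[sl] = False
        c = _wls(y[keep], ell[keep], w[keep])
        pseudo[i] = _rg(c[1] * M / scale)
    se_rg = _jackknife(pseudo[~np.isnan(pseudo)]) if not np.all(np.isnan(pseudo)) else float("nan")
    rg = _rg(rho_g)
    p = 2 * norm.sf(abs(rg) / se_rg) if se_rg and np.isfinite(se_rg) and se_rg > 0 else float("nan")
    return LdscResult(
        h2_1=float(h2_1), h2_2=float(h2_2),
        intercept_1=u1.intercept, intercept_2=u2.intercept,
        cross_intercept=float(coef[0]),
        rho_g=float(rho_g), rg=rg, se_rg=se_rg, p_rg=float(p), flags=flags,
    )
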