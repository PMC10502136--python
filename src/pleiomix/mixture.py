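"""Bivariate causal mixture model for GWAS z-scores.

The model assumes each variant's true (standardized) effect pair comes from a
four-component mixture: null, trait-1-only, trait-2-only, and shared, with the
shared pair bivariate Gaussian at correlation ``rho_beta``.  Observed z-scores
convolve these effects over LD, so the marginal density of z_j is not Gaussian;
it is evaluated through its characteristic function,

    phi_j(t) = exp(-sigma0^2 t^2 / 2)
               * prod_{k : r^2_jk > r2_min} [ 1 - pi + pi * exp(-N sigma_b^2 r^2_jk t^2 / 2) ],

inverted numerically on a Fourier grid (and its 2-D analogue for the bivariate
four-component mixture with residual cross-correlation rho0 from sample
overlap).  Per-variant LD profiles are compressed into an r^2 histogram so the
product over neighbours becomes a matrix multiply.

Headline summaries derived from a fit follow the field's reporting
conventions: Venn counts of trait-specific/shared causal variants on the
90%-heritability scale, the Dice similarity of the two architectures, the
orthant probability of effect-sign concordance, the mixture-implied genetic
correlation, and AIC comparisons against minimum- and maximum-overlap
constrained models.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize
from scipy.stats import chi2

from .sumstats import LDPanel, SumStats
from . import ldsc as _ldsc

logger = logging.getLogger("pleiomix")


# ---------------------------------------------------------------------------
# Closed-form summaries
# ---------------------------------------------------------------------------


def dice(n1_unique: float, n2_unique: float, n_shared: float) -> float:
    """Dice similarity of two causal-variant sets: 2*shared / (total_1 + total_2)."""
    if min(n1_unique, n2_unique, n_shared) < 0:
        raise ValueError("counts must be nonnegative")
    denom = n1_unique + n2_unique + 2.0 * n_shared
    if denom == 0:
        raise ValueError("all counts are zero; Dice undefined")
    return 2.0 * n_shared / denom


def concordant_fraction(rho_beta: float) -> float:
    """Probability that a shared effect pair agrees in sign.

    For a centred bivariate Gaussian with correlation rho this is the orthant
    probability 1/2 + arcsin(rho)/pi.
    """
    if abs(rho_beta) > 1:
        raise ValueError("|rho_beta| must be <= 1")
    return 0.5 + np.arcsin(rho_beta) / np.pi


def _n90_threshold() -> float:
    """Chi-square(1) threshold t with E[X 1(X>t)] / E[X] = 0.9.

    Uses the partial-expectation identity E[X 1(X>t)] = P(chi2_3 > t) for
    X ~ chi2_1 (E[X] = 1) and solves by root-finding.
    """
    return optimize.brentq(lambda t: chi2.sf(t, 3) - 0.9, 1e-12, 10.0, xtol=1e-12)


#: fraction of iid Gaussian causal effects needed to reach 90% of heritability
N90_FRACTION = chi2.sf(_n90_threshold(), 1)


def n90(pi_total: float, M: float) -> float:
    """Number of causal variants explaining 90% of SNP heritability.

    Guards polygenicity estimates against extrapolation into variants of
    infinitesimally small effect: only the fraction of causal effects whose
    squared values reach 90% of the total is counted.  Linear in both
    arguments: n90 = q * pi_total * M with q ~ 0.4473.
    """
    if not 0 <= pi_total <= 1:
        raise ValueError("pi_total must be in [0, 1]")
    return N90_FRACTION * pi_total * M


# ---------------------------------------------------------------------------
# Fit containers
# ---------------------------------------------------------------------------


@dataclass
class UnivariateFit:
    """One trait's causal-mixture fit: (pi, sigma_b^2, sigma0^2) plus logL."""

    pi_total: float
    sigma_b_sq: float
    sigma0_sq: float
    logL: float
    M: int
    N: float
    n_used: int
    warnings: list[str] = field(default_factory=list)
    se: dict[str, float] = field(default_factory=dict)

    @property
    def h2_snp(self) -> float:
        return self.M * self.pi_total * self.sigma_b_sq


@dataclass
class BivariateFit:
    """Joint mixture fit on top of two fixed univariate fits."""

    pi1_spec: float
    pi2_spec: float
    pi12: float
    rho_beta: float
    rho0: float
    logL: float
    uni1: UnivariateFit
    uni2: UnivariateFit
    warnings: list[str] = field(default_factory=list)
    se: dict[str, float] = field(default_factory=dict)

    @property
    def M(self) -> int:
        return self.uni1.M


@dataclass
class VennSummary:
    """Fig.-style overlap summary: counts in thousands on the 90%-h2 scale."""

    n1_unique: float
    n2_unique: float
    n_shared: float
    n1_unique_raw: float
    n2_unique_raw: float
    n_shared_raw: float
    dice: float
    concordant_fraction: float
    rg_model: float

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("n1_unique\tn_shared\tn2_unique\tdice\trg_model\n")
            fh.write(
                f"{self.n1_unique:.4g}\t{self.n_shared:.4g}\t{self.n2_unique:.4g}"
                f"\t{self.dice:.4g}\t{self.rg_model:.4g}\n"
            )


def rg_from_params(pi1_spec: float, pi2_spec: float, pi12: float,
                   rho_beta: float, sigma1_sq: float = 1.0, sigma2_sq: float = 1.0) -> float:
    """Mixture-implied genome-wide genetic correlation.

    Covariance across the whole mixture is pi12 * rho_beta * sigma1 * sigma2;
    marginal variances are (pi_spec + pi12) * sigma^2.
    """
    v1 = (pi1_spec + pi12) * sigma1_sq
    v2 = (pi2_spec + pi12) * sigma2_sq
    if v1 <= 0 or v2 <= 0:
        return 0.0
    return pi12 * rho_beta * np.sqrt(sigma1_sq * sigma2_sq) / np.sqrt(v1 * v2)


def venn_summary(biv: BivariateFit, M: int | None = None) -> VennSummary:
    """Derive the overlap summary (counts in thousands) from a bivariate fit."""
    M = M or biv.M
    counts90 = [n90(p, M) / 1e3 for p in (biv.pi1_spec, biv.pi2_spec, biv.pi12)]
    counts_raw = [p * M / 1e3 for p in (biv.pi1_spec, biv.pi2_spec, biv.pi12)]
    return VennSummary(
        n1_unique=counts90[0],
        n2_unique=counts90[1],
        n_shared=counts90[2],
        n1_unique_raw=counts_raw[0],
        n2_unique_raw=counts_raw[1],
        n_shared_raw=counts_raw[2],
        dice=dice(counts90[0], counts90[1], counts90[2]) if sum(counts90) > 0 else float("nan"),
        concordant_fraction=concordant_fraction(biv.rho_beta),
        rg_model=rg_from_params(biv.pi1_spec, biv.pi2_spec, biv.pi12, biv.rho_beta,
                                biv.uni1.sigma_b_sq, biv.uni2.sigma_b_sq),
    )


# ---------------------------------------------------------------------------
# Characteristic-function workspace
# ---------------------------------------------------------------------------


@dataclass
class GridConfig:
    """Numerical settings of the Fourier inversion.

    ``grid_size`` Fourier points span |z| <= ``z_max``; frequency spacing is
    dt = 2*pi / (grid_size * dz) = pi / z_max, and nodes are truncated where the
    residual-Gaussian envelope is numerically zero (``t_cut``).  Variants with
    |z| >= ``censor_z`` contribute a censored (tail-mass) likelihood term
    instead of a density; censoring inside the grid edge keeps the periodized
    inversion accurate in the extreme tail without an excessively wide grid.
    LD r^2 terms below ``r2_min`` are ignored and the rest histogrammed into
    ``n_r2_bins`` bins.
    """

    z_max: float = 12.0
    grid_size: int = 2048
    t_cut: float = 10.0
    censor_z: float = 9.0
    r2_min: float = 0.05
    n_r2_bins: int = 24
    subsample_cap: int = 100_000
    biv_subsample_cap: int = 10_000
    double_precision: bool = False   # float64 bivariate caches (small problems)

    @property
    def dt(self) -> float:
        return np.pi / self.z_max

    def t_nodes(self) -> np.ndarray:
        k_max = min(self.grid_size // 2, int(np.ceil(self.t_cut / self.dt)))
        return self.dt * np.arange(k_max + 1)


class MixtureWorkspace:
    """Precomputed LD histograms, Fourier nodes and data caches for one pair.

    Binning: each variant's within-block r^2 values above ``r2_min`` (self term
    r^2 = 1 included) are counted into a shared histogram; the per-bin
    representative r^2 is the global count-weighted mean, so the neighbour
    product in the characteristic function becomes counts @ log(mixture terms).
    """

    def __init__(self, z1: np.ndarray, z2: np.ndarray | None, panel: LDPanel,
                 N1: float, N2: float | None = None, config: GridConfig | None = None):
        self.config = config or GridConfig()
        self.panel = panel
        self.M = len(panel)
        if np.max(np.abs(z1)) > 10 * self.config.z_max:
            raise ValueError(
                "observed |z| vastly exceeds the Fourier grid span; widen z_max")
        self.z1 = np.asarray(z1, float)
        self.z2 = None if z2 is None else np.asarray(z2, float)
        self.N1, self.N2 = float(N1), None if N2 is None else float(N2)
        self.C, self.r2_repr = self._bin_ld(panel)
        self.t = self.config.t_nodes()
        self._uni_cache: dict = {}
        self._biv_cache: dict = {}

    # -- LD histogram ------------------------------------------------------
    def _bin_ld(self, panel: LDPanel) -> tuple[np.ndarray, np.ndarray]:
        cfg = self.config
        B = cfg.n_r2_bins
        edges = np.linspace(cfg.r2_min, 1.0, B + 1)
        counts = np.zeros((self.M, B), dtype=np.float32)
        sums = np.zeros(B)
        totals = np.zeros(B)
        for sl, R in zip(panel.block_slices(), panel.blocks):
            r2 = np.square(R)
            mask = r2 > cfg.r2_min
            idx = np.clip(np.searchsorted(edges, r2, side="right") - 1, 0, B - 1)
            n = R.shape[0]
            rows = np.repeat(np.arange(n), n).reshape(n, n)
            flat = (rows * B + idx)[mask]
            counts[sl] += np.bincount(flat, minlength=n * B).reshape(n, B)
            binflat = idx[mask]
            sums += np.bincount(binflat, weights=r2[mask], minlength=B)
            totals += np.bincount(binflat, minlength=B)
        centers = 0.5 * (edges[:-1] + edges[1:])
        repr_r2 = np.where(totals > 0, sums / np.maximum(totals, 1), centers)
        return counts, repr_r2

    def _subsample(self, cap: int) -> np.ndarray:
        if self.M <= cap:
            return np.arange(self.M)
        step = int(np.ceil(self.M / cap))
        return np.arange(0, self.M, step)

    # -- univariate --------------------------------------------------------
    def _uni_data(self, trait: int) -> dict:
        key = ("uni", trait)
        if key not in self._uni_cache:
            z = self.z1 if trait == 1 else self.z2
            idx = self._subsample(self.config.subsample_cap)
            zs = z[idx]
            cens = np.abs(zs) >= self.config.censor_z
            t = self.t
            self._uni_cache[key] = {
                "idx": idx,
                "z": zs,
                "cens": cens,
                "C": self.C[idx].astype(np.float64),
                "cos": np.cos(np.outer(zs[~cens], t[1:])),
                "n_cens": int(cens.sum()),
            }
        return self._uni_cache[key]

    def uni_loglik(self, trait: int, pi: float, sigma_b_sq: float, sigma0_sq: float) -> float:
        """Summed log marginal density of one trait's z-scores.

        Variants with |z| beyond the censoring point contribute the tail mass
        P(|Z| >= censor_z) under the same model.
        """
        if not (0 <= pi <= 1) or sigma_b_sq <= 0 or sigma0_sq <= 0:
            return -np.inf
        d = self._uni_data(trait)
        N = self.N1 if trait == 1 else self.N2
        t = self.t
        c = N * sigma_b_sq
        # B x K mixture term, exactly 0 at t=0
        expo = -0.5 * c * np.outer(self.r2_repr, t**2)
        logm = np.log1p(pi * np.expm1(expo))
        logphi = d["C"] @ logm
        phi = np.exp(logphi - (0.5 * sigma0_sq * t**2)[None, :])
        dtpi = self.config.dt / np.pi
        pdf = dtpi * (0.5 + (phi[~d["cens"], 1:] * d["cos"]).sum(axis=1))
        ll = float(np.log(np.clip(pdf, 1e-120, None)).sum())
        if d["n_cens"]:
            zc = self.config.censor_z
            g = np.empty_like(t)
            g[0] = 2 * zc
            g[1:] = 2 * np.sin(t[1:] * zc) / t[1:]
            p_in = (self.config.dt / (2 * np.pi)) * (
                phi[d["cens"]] @ g + phi[d["cens"], 1:] @ g[1:]
            )
            ll += float(np.log(np.clip(1.0 - p_in, 1e-12, None)).sum())
        return ll

    # -- bivariate ---------------------------------------------------------
    def _biv_nodes(self) -> dict:
        """Half-plane disc of 2-D Fourier nodes with symmetry weights."""
        if "nodes" in self._biv_cache:
            return self._biv_cache["nodes"]
        cfg = self.config
        k_max = len(self.t) - 1
        a, b = np.meshgrid(np.arange(0, k_max + 1), np.arange(-k_max, k_max + 1),
                           indexing="ij")
        a, b = a.ravel(), b.ravel()
        keep = (a**2 + b**2 <= k_max**2) & ~((a == 0) & (b < 0))
        a, b = a[keep], b[keep]
        w = np.where((a == 0) & (b == 0), 1.0, 2.0)
        nodes = {"a": a, "b": b, "w": w,
                 "t1": a * cfg.dt, "t2": b * cfg.dt}
        self._biv_cache["nodes"] = nodes
        return nodes

    def _biv_data(self) -> dict:
        if "data" in self._biv_cache:
            return self._biv_cache["data"]
        if self.z2 is None:
            raise ValueError("workspace was built without a second trait")
        nd = self._biv_nodes()
        idx = self._subsample(self.config.biv_subsample_cap)
        z1, z2 = self.z1[idx], self.z2[idx]
        cens = (np.abs(z1) >= self.config.censor_z) | (np.abs(z2) >= self.config.censor_z)
        t = self.t
        a, b = nd["a"], nd["b"]
        babs, bsgn = np.abs(b), np.sign(b)
        zin1, zin2 = z1[~cens], z2[~cens]
        ftype = np.float64 if self.config.double_precision else np.float32
        cA = np.cos(np.outer(zin1, t)).astype(ftype)
        sA = np.sin(np.outer(zin1, t)).astype(ftype)
        cB = np.cos(np.outer(zin2, t)).astype(ftype)
        sB = np.sin(np.outer(zin2, t)).astype(ftype)
        # weighted phase cache: w * cos(t1 z1 + t2 z2) per in-grid variant/node
        phase = (cA[:, a] * cB[:, babs] - sA[:, a] * (bsgn.astype(ftype) * sB[:, babs]))
        phase *= nd["w"].astype(ftype)
        zc = self.config.censor_z
        g = np.empty_like(t)
        g[0] = 2 * zc
        g[1:] = 2 * np.sin(t[1:] * zc) / t[1:]
        data = {
            "idx": idx,
            "cens": cens,
            "C_in": self.C[idx][~cens].astype(ftype),
            "C_cens": self.C[idx][cens].astype(ftype),
            "phase": phase,
            "box": (nd["w"] * g[a] * g[babs]).astype(ftype),
            "n_cens": int(cens.sum()),
        }
        self._biv_cache["data"] = data
        return data

    def biv_loglik(self, pi1_spec: float, pi2_spec: float, pi12: float,
                   rho_beta: float, rho0: float,
                   sigma1_sq: float, sigma2_sq: float,
                   sigma0_1_sq: float, sigma0_2_sq: float) -> float:
        """Summed log joint density of the two z-scores under the 4-component model."""
        pi0 = 1.0 - pi1_spec - pi2_spec - pi12
        if min(pi0, pi1_spec, pi2_spec, pi12) < -1e-12 or abs(rho_beta) > 1 or abs(rho0) >= 1:
            return -np.inf
        nd = self._biv_nodes()
        d = self._biv_data()
        t1, t2 = nd["t1"], nd["t2"]
        c1 = self.N1 * sigma1_sq
        c2 = self.N2 * sigma2_sq
        cx = np.sqrt(c1 * c2) * rho_beta
        q1 = 0.5 * c1 * t1**2
        q2 = 0.5 * c2 * t2**2
        qx = cx * t1 * t2
        r2 = self.r2_repr[:, None]
        g1 = np.exp(-r2 * q1[None, :])
        g2 = np.exp(-r2 * q2[None, :])
        g12 = np.exp(-r2 * (q1 + q2 + 0.5 * qx)[None, :] - 0.5 * r2 * qx[None, :])
        m = pi0 + pi1_spec * g1 + pi2_spec * g2 + pi12 * g12
        ftype = np.float64 if self.config.double_precision else np.float32
        # clip at the quadrature noise floor to keep the surface smooth
        floor = 1e-30 if self.config.double_precision else 1e-9
        logm = np.log(np.clip(m, 1e-300, None)).astype(ftype)
        s01, s02 = np.sqrt(sigma0_1_sq), np.sqrt(sigma0_2_sq)
        gauss = -0.5 * (sigma0_1_sq * t1**2 + sigma0_2_sq * t2**2
                        + 2 * rho0 * s01 * s02 * t1 * t2)
        gaussf = gauss.astype(ftype)
        norm = (self.config.dt / (2 * np.pi)) ** 2
        ll = 0.0
        phi_in = np.exp(d["C_in"] @ logm + gaussf)
        pdf = norm * np.einsum("jm,jm->j", phi_in, d["phase"]).astype(np.float64)
        ll += float(np.log(np.clip(pdf, floor, None)).sum())
        if d["n_cens"]:
            phi_c = np.exp(d["C_cens"] @ logm + gaussf)
            p_in = norm * (phi_c @ d["box"]).astype(np.float64)
            ll += float(np.log(np.clip(1.0 - p_in, floor, None)).sum())
        return ll


# ---------------------------------------------------------------------------
# Reference densities (exact r^2 profile, dense quadrature; no binning)
# ---------------------------------------------------------------------------


def uni_density(z: np.ndarray, r2_profile: np.ndarray, pi: float,
                sigma_b_sq: float, sigma0_sq: float, N: float,
                t_max: float = 16.0, dt: float = 0.02) -> np.ndarray:
    """Marginal z density at one variant given its exact LD r^2 profile.

    Direct cosine-transform inversion of the characteristic function on a
    dense frequency grid; serves as the reference for the binned/histogrammed
    fitting path and for Monte-Carlo cross-checks.
    """
    z = np.atleast_1d(np.asarray(z, float))
    t = np.arange(0.0, t_max, dt)
    r2 = np.asarray(r2_profile, float)[:, None]
    mix = np.clip(1.0 + pi * np.expm1(-0.5 * N * sigma_b_sq * r2 * t[None, :] ** 2),
                  1e-300, None)
    logphi = np.log(mix).sum(axis=0)
    phi = np.exp(logphi - 0.5 * sigma0_sq * t**2)
    return (dt / np.pi) * (np.cos(np.outer(z, t)) @ phi - 0.5 * phi[0])


def biv_density(z1: np.ndarray, z2: np.ndarray, r2_profile: np.ndarray,
                pi1_spec: float, pi2_spec: float, pi12: float,
                rho_beta: float, rho0: float,
                sigma1_sq: float, sigma2_sq: float,
                sigma0_1_sq: float, sigma0_2_sq: float,
                N1: float, N2: float,
                t_max: float = 14.0, dt: float = 0.05) -> np.ndarray:
    """Joint (z1, z2) density at one variant from the 2-D characteristic function.

    ``z1``/``z2`` are paired coordinates; returns one density per pair.  Dense
    full-plane quadrature — reference quality, cost quadratic in t_max/dt.
    """
    z1 = np.atleast_1d(np.asarray(z1, float))
    z2 = np.atleast_1d(np.asarray(z2, float))
    tv = np.arange(-t_max, t_max, dt)
    T1, T2 = np.meshgrid(tv, tv, indexing="ij")
    t1, t2 = T1.ravel(), T2.ravel()
    c1, c2 = N1 * sigma1_sq, N2 * sigma2_sq
    cx = np.sqrt(c1 * c2) * rho_beta
    pi0 = 1.0 - pi1_spec - pi2_spec - pi12
    logm = np.zeros_like(t1)
    for r2 in np.asarray(r2_profile, float):
        g1 = np.exp(-0.5 * c1 * r2 * t1**2)
        g2 = np.exp(-0.5 * c2 * r2 * t2**2)
        g12 = np.exp(-0.5 * r2 * (c1 * t1**2 + c2 * t2**2 + 2 * cx * t1 * t2))
        logm += np.log(pi0 + pi1_spec * g1 + pi2_spec * g2 + pi12 * g12)
    s01, s02 = np.sqrt(sigma0_1_sq), np.sqrt(sigma0_2_sq)
    phi = np.exp(logm - 0.5 * (sigma0_1_sq * t1**2 + sigma0_2_sq * t2**2
                               + 2 * rho0 * s01 * s02 * t1 * t2))
    out = np.empty(len(z1))
    w = (dt / (2 * np.pi)) ** 2
    for i, (a, b) in enumerate(zip(z1, z2)):
        out[i] = w * float(phi @ np.cos(t1 * a + t2 * b))
    return out


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def univariate_loglik(z: np.ndarray, panel: LDPanel,
                      params: tuple[float, float, float], N: float,
                      config: GridConfig | None = None) -> float:
    """Convenience wrapper: log-likelihood of (pi, sigma_b_sq, sigma0_sq)."""
    ws = MixtureWorkspace(z, None, panel, N, config=config)
    return ws.uni_loglik(1, *params)


def bivariate_loglik(z1: np.ndarray, z2: np.ndarray, panel: LDPanel,
                     params: dict, N1: float, N2: float,
                     config: GridConfig | None = None) -> float:
    """Convenience wrapper over :meth:`MixtureWorkspace.biv_loglik`; ``params``
    carries pi1_spec/pi2_spec/pi12/rho_beta/rho0/sigma1_sq/sigma2_sq/
    sigma0_1_sq/sigma0_2_sq."""
    ws = MixtureWorkspace(z1, z2, panel, N1, N2, config=config)
    return ws.biv_loglik(**params)


def _hess_diag_se(fun, x0: np.ndarray, names: list[str], rel_h: float = 0.03) -> dict:
    """Standard errors from the diagonal of a finite-difference observed information."""
    se = {}
    f0 = fun(x0)
    for i, name in enumerate(names):
        h = max(abs(x0[i]) * rel_h, 1e-6)
        xp, xm = x0.copy(), x0.copy()
        xp[i] += h
        xm[i] -= h
        d2 = (fun(xp) - 2 * f0 + fun(xm)) / h**2
        se[name] = float(1.0 / np.sqrt(-d2)) if d2 < 0 else float("nan")
    return se


def fit_univariate(table: SumStats, panel: LDPanel,
                   config: GridConfig | None = None,
                   workspace: MixtureWorkspace | None = None,
                   trait: int = 1,
                   compute_se: bool = False) -> UnivariateFit:
    """Maximize the univariate mixture likelihood over (pi, sigma_b^2, sigma0^2).

    Deterministic multi-start: an LD-score-regression moment fit seeds the
    heritability product, a log-spaced pi grid crossed with three sigma_b^2
    scalings is screened, and the best point is refined by Nelder-Mead in log
    space.
    """
    if len(table) < 1000:
        raise ValueError("need at least 1,000 variants for a mixture fit")
    cfg = config or GridConfig()
    if workspace is None:
        workspace = MixtureWorkspace(table.z, None, panel, table.n_eff, config=cfg)
        trait = 1
    N = workspace.N1 if trait == 1 else workspace.N2
    M = workspace.M
    ell = panel.ld_score
    try:
        res0 = _ldsc.univariate_ldsc(table.z, ell, N, M)
        h2_mom, s0_mom = max(res0.h2, 1e-4), max(res0.intercept, 0.7)
    except Exception:  # degenerate ell; keep defaults
        h2_mom, s0_mom = 0.1, 1.0

    def nll(u):
        pi = 10.0 ** u[0]
        sb2 = 10.0 ** u[1]
        s02 = np.exp(u[2])
        if pi > 0.5:
            return 1e12
        return -workspace.uni_loglik(trait, pi, sb2, s02)

    best = None
    for lp in np.linspace(-4.5, -1.5, 6):
        pi = 10.0 ** lp
        for scale in (0.3, 1.0, 3.0):
            sb2 = scale * h2_mom / (M * pi)
            u = np.array([lp, np.log10(sb2), np.log(s0_mom)])
            v = nll(u)
            if best is None or v < best[1]:
                best = (u, v)
    res = optimize.minimize(nll, best[0], method="Nelder-Mead",
                            options={"xatol": 1e-3, "fatol": 1e-3, "maxiter": 400})
    pi = float(10.0 ** res.x[0])
    sb2 = float(10.0 ** res.x[1])
    s02 = float(np.exp(res.x[2]))
    warnings = []
    if pi > 0.45 or res.x[0] < -4.4:
        warnings.append("pi at a search-box bound")
    fit = UnivariateFit(pi_total=pi, sigma_b_sq=sb2, sigma0_sq=s02,
                        logL=-float(res.fun), M=M, N=N,
                        n_used=len(workspace._subsample(cfg.subsample_cap)),
                        warnings=warnings)
    if compute_se:
        fit.se = _hess_diag_se(lambda u: -nll(u), res.x,
                               ["log10_pi", "log10_sigma_b_sq", "log_sigma0_sq"])
    return fit


def _biv_nll_factory(ws: MixtureWorkspace, uni1: UnivariateFit, uni2: UnivariateFit):
    min_tot = min(uni1.pi_total, uni2.pi_total)

    def unpack(u):
        frac = 1.0 / (1.0 + np.exp(-u[0]))  # pi12 as a fraction of min_tot
        pi12 = frac * min_tot
        rho_beta = np.tanh(u[1])
        rho0 = 0.95 * np.tanh(u[2])
        return pi12, rho_beta, rho0

    def nll(u):
        pi12, rho_beta, rho0 = unpack(u)
        return -ws.biv_loglik(
            pi1_spec=max(uni1.pi_total - pi12, 0.0),
            pi2_spec=max(uni2.pi_total - pi12, 0.0),
            pi12=pi12, rho_beta=rho_beta, rho0=rho0,
            sigma1_sq=uni1.sigma_b_sq, sigma2_sq=uni2.sigma_b_sq,
            sigma0_1_sq=uni1.sigma0_sq, sigma0_2_sq=uni2.sigma0_sq,
        )

    return nll, unpack, min_tot


def fit_bivariate(t1: SumStats, t2: SumStats, panel: LDPanel,
                  uni1: UnivariateFit, uni2: UnivariateFit,
                  config: GridConfig | None = None,
                  workspace: MixtureWorkspace | None = None,
                  compute_se: bool = False) -> BivariateFit:
    """Maximize the bivariate likelihood over (pi12, rho_beta, rho0).

    Univariate parameters are held fixed; the trait-specific fractions are the
    univariate totals minus pi12, constrained nonnegative.  A cross-trait
    LD-score moment fit seeds rho_beta at each of three pi12 starting fractions.
    """
    cfg = config or GridConfig()
    if workspace is None:
        workspace = MixtureWorkspace(t1.z, t2.z, panel, t1.n_eff, t2.n_eff, config=cfg)
    nll, unpack, min_tot = _biv_nll_factory(workspace, uni1, uni2)

    # moment seed: E[z1 z2] slope ~ sqrt(N1 N2) * ell / M * pi12 rho sigma1 sigma2
    ell = panel.ld_score
    slope = np.polyfit(ell, t1.z * t2.z, 1)[0]
    cov_b = slope * workspace.M / np.sqrt(workspace.N1 * workspace.N2)
    s1s2 = np.sqrt(uni1.sigma_b_sq * uni2.sigma_b_sq)
    best = None
    for frac in (0.2, 0.5, 0.9):
        pi12 = frac * min_tot
        rho_seed = np.clip(cov_b / max(pi12 * s1s2, 1e-300), -0.95, 0.95)
        u = np.array([np.log(frac / (1 - frac)), np.arctanh(rho_seed), 0.0])
        v = nll(u)
        if best is None or v < best[1]:
            best = (u, v)
    res = optimize.minimize(nll, best[0], method="Nelder-Mead",
                            options={"xatol": 5e-3, "fatol": 0.05, "maxiter": 150})
    pi12, rho_beta, rho0 = unpack(res.x)
    warnings = []
    if pi12 > 0.99 * min_tot or pi12 < 0.01 * min_tot:
        warnings.append("pi12 at a feasibility bound")
    fit = BivariateFit(
        pi1_spec=max(uni1.pi_total - pi12, 0.0),
        pi2_spec=max(uni2.pi_total - pi12, 0.0),
        pi12=float(pi12), rho_beta=float(rho_beta), rho0=float(rho0),
        logL=-float(res.fun), uni1=uni1, uni2=uni2, warnings=warnings,
    )
    if compute_se:
        fit.se = _hess_diag_se(lambda u: -nll(u), res.x,
                               ["logit_pi12_frac", "atanh_rho_beta", "atanh_rho0"])
    return fit


def _fit_constrained(ws: MixtureWorkspace, uni1: UnivariateFit, uni2: UnivariateFit,
                     pi12: float, fit_rho_beta: bool) -> tuple[float, int]:
    """Refit free parameters with pi12 pinned; returns (logL, n_free_params)."""

    def nll(v):
        rho_beta = np.tanh(v[0]) if fit_rho_beta else 0.0
        rho0 = 0.95 * np.tanh(v[-1])
        return -ws.biv_loglik(
            pi1_spec=max(uni1.pi_total - pi12, 0.0),
            pi2_spec=max(uni2.pi_total - pi12, 0.0),
            pi12=pi12, rho_beta=rho_beta, rho0=rho0,
            sigma1_sq=uni1.sigma_b_sq, sigma2_sq=uni2.sigma_b_sq,
            sigma0_1_sq=uni1.sigma0_sq, sigma0_2_sq=uni2.sigma0_sq,
        )

    x0 = np.array([0.2, 0.0]) if fit_rho_beta else np.array([0.0])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 5e-3, "fatol": 0.05, "maxiter": 100})
    return -float(res.fun), len(x0)


def aic_comparison(biv: BivariateFit, t1: SumStats, t2: SumStats, panel: LDPanel,
                   config: GridConfig | None = None,
                   workspace: MixtureWorkspace | None = None) -> tuple[float, float]:
    """AIC discrimination against minimum- and maximum-overlap models.

    Refits with pi12 pinned at 0 (rho_beta drops out) and at
    min(pi1_total, pi2_total), re-optimizing the remaining free parameters.
    Returns (aic_vs_min, aic_vs_max) = AIC(constrained) - AIC(best); positive
    values mean the data discriminate the fitted overlap from that extreme.
    """
    cfg = config or GridConfig()
    if workspace is None:
        workspace = MixtureWorkspace(t1.z, t2.z, panel, t1.n_eff, t2.n_eff, config=cfg)
    uni1, uni2 = biv.uni1, biv.uni2
    min_tot = min(uni1.pi_total, uni2.pi_total)
    aic_best = 2 * 3 - 2 * biv.logL
    ll_min, k_min = _fit_constrained(workspace, uni1, uni2, 0.0, fit_rho_beta=False)
    ll_max, k_max = _fit_constrained(workspace, uni1, uni2, min_tot, fit_rho_beta=True)
    aic_vs_min = (2 * k_min - 2 * ll_min) - aic_best
    aic_vs_max = (2 * k_max - 2 * ll_max) - aic_best
    return float(aic_vs_min), float(aic_vs_max)


def likelihood_profile(biv: BivariateFit, t1: SumStats, t2: SumStats, panel: LDPanel,
                       grid: np.ndarray | None = None, n_grid: int = 9,
                       config: GridConfig | None = None,
                       workspace: MixtureWorkspace | None = None) -> np.ndarray:
    """Profile log-likelihood over pi12, re-optimizing (rho_beta, rho0) per point.

    Returns an (n, 2) array of (pi12, logL); the profile peaks at the fitted
    pi12 within grid resolution and its endpoints are the constrained models of
    :func:`aic_comparison`.
    """
    cfg = config or GridConfig()
    if workspace is None:
        workspace = MixtureWorkspace(t1.z, t2.z, panel, t1.n_eff, t2.n_eff, config=cfg)
    uni1, uni2 = biv.uni1, biv.uni2
    min_tot = min(uni1.pi_total, uni2.pi_total)
    if grid is None:
        grid = np.linspace(0.0, min_tot, n_grid)
    out = []
    for pi12 in grid:
        ll, _ = _fit_constrained(workspace, uni1, uni2, float(pi12),
                                 fit_rho_beta=pi12 > 0)
        out.append((float(pi12), ll))
    return np.array(out)


def fit_report(biv: BivariateFit, venn: VennSummary,
               aic: tuple[float, float] | None = None,
               profile: np.ndarray | None = None) -> dict:
    """Structured report of a completed bivariate analysis (JSON-serializable)."""
    report = {
        "univariate": {
            "trait1": {k: v for k, v in asdict(biv.uni1).items()},
            "trait2": {k: v for k, v in asdict(biv.uni2).items()},
        },
        "bivariate": {
            "pi1_spec": biv.pi1_spec, "pi2_spec": biv.pi2_spec, "pi12": biv.pi12,
            "rho_beta": biv.rho_beta, "rho0": biv.rho0, "logL": biv.logL,
            "se": biv.se, "warnings": biv.warnings,
        },
        "venn": asdict(venn),
    }
    if aic is not None:
        report["aic"] = {"vs_min_overlap": aic[0], "vs_max_overlap": aic[1]}
    if profile is not None:
        report["likelihood_profile"] = [list(row) for row in profile]
    return report
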