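"""Synthetic two-trait GWAS summary statistics with known mixture ground truth.

True per-variant effects follow a four-component mixture: null, trait-1-only,
trait-2-only, and a shared component whose effect pair is bivariate Gaussian
with correlation ``rho_beta``.  Effects are on the standardized-genotype scale
(unit variance per variant) so allele frequency drops out and the marginal
z-score model is a function of (N, LD score, sigma_beta^2) only.

Observed z-scores are LD-convolved within each block:

    z_t = sqrt(N_t) * R beta_t + eps_t,   eps_t ~ Normal(0, sigma0_t^2 * R)

with the two traits' residual vectors coupled through the same Cholesky factor
at cross-correlation ``rho0`` (the sample-overlap term), so that at null
variants E[z1 z2] = rho0 * sigma0_1 * sigma0_2 * R.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .sumstats import LDPanel, SumStats, SUMSTATS_COLUMNS, make_ar1_panel, logger

COMPONENTS = ("null", "t1_only", "t2_only", "shared")


@dataclass
class MixtureTruth:
    """Ground-truth parameters of the bivariate causal mixture generator.

    pi* are fractions of the M variants in each causal component; sigma*_sq are
    per-causal-variant effect variances; sigma0_*_sq are residual inflation
    variances; rho0 is the cross-trait residual correlation induced by sample
    overlap.  Defaults emulate a strongly overlapping polygenic trait pair.
    """

    M: int = 100_000
    pi1_spec: float = 0.0005
    pi2_spec: float = 0.0005
    pi12: float = 0.003
    sigma1_sq: float = 1e-4
    sigma2_sq: float = 1e-4
    rho_beta: float = 0.25
    sigma0_1_sq: float = 1.0
    sigma0_2_sq: float = 1.0
    rho0: float = 0.0
    N1: float = 50_000
    N2: float = 250_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pi1_spec + self.pi12 > 1 or self.pi2_spec + self.pi12 > 1:
            raise ValueError("component fractions exceed 1")
        if min(self.pi1_spec, self.pi2_spec, self.pi12) < 0:
            raise ValueError("negative mixture fraction")
        if self.sigma1_sq <= 0 or self.sigma2_sq <= 0:
            raise ValueError("effect variances must be positive")
        if self.sigma0_1_sq <= 0 or self.sigma0_2_sq <= 0:
            raise ValueError("residual variances must be positive")
        if abs(self.rho_beta) > 1 or abs(self.rho0) > 1:
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def pi_null(self) -> float:
        return 1.0 - self.pi1_spec - self.pi2_spec - self.pi12

    @property
    def h2_1(self) -> float:
        """Expected trait-1 SNP heritability M*(pi1_spec+pi12)*sigma1_sq."""
        return self.M * (self.pi1_spec + self.pi12) * self.sigma1_sq

    @property
    def h2_2(self) -> float:
        return self.M * (self.pi2_spec + self.pi12) * self.sigma2_sq


@dataclass
class EffectDraw:
    """Per-variant true effects (standardized scale) with component labels."""

    beta1: np.ndarray
    beta2: np.ndarray
    component: np.ndarray  # integer index into COMPONENTS


def draw_effects(truth: MixtureTruth, rng: np.random.Generator | None = None) -> EffectDraw:
    """Sample component labels and true effect pairs for all M variants."""
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    probs = np.array([truth.pi_null, truth.pi1_spec, truth.pi2_spec, truth.pi12])
    if probs.min() < -1e-12 or abs(probs.sum() - 1) > 1e-9:
        raise ValueError(f"invalid component probability vector {probs}")
    component = rng.choice(4, size=truth.M, p=probs / probs.sum())
    beta1 = np.zeros(truth.M)
    beta2 = np.zeros(truth.M)
    s1, s2 = np.sqrt(truth.sigma1_sq), np.sqrt(truth.sigma2_sq)
    m1 = component == 1
    beta1[m1] = rng.normal(0.0, s1, m1.sum())
    m2 = component == 2
    beta2[m2] = rng.normal(0.0, s2, m2.sum())
    ms = component == 3
    n_shared = int(ms.sum())
    if n_shared:
        # correlated pair via shared + independent standard-normal parts
        u = rng.standard_normal(n_shared)
        v = rng.standard_normal(n_shared)
        rho = truth.rho_beta
        beta1[ms] = s1 * u
        beta2[ms] = s2 * (rho * u + np.sqrt(max(0.0, 1 - rho**2)) * v)
    return EffectDraw(beta1=beta1, beta2=beta2, component=component)


def _block_cholesky(R: np.ndarray) -> np.ndarray:
    """Cholesky factor of a correlation block, eigenvalue-clipped if needed."""
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(R)
        w_clipped = np.clip(w, 1e-8, None)
        logger.info("repaired non-PD LD block by eigenvalue clipping (min eig %.3g)", w.min())
        return V @ np.diag(np.sqrt(w_clipped))


def simulate_z(
    effects: EffectDraw,
    panel: LDPanel,
    truth: MixtureTruth,
    rng: np.random.Generator | None = None,
) -> tuple[SumStats, SumStats]:
    """LD-convolve true effects into observed z-scores for both traits."""
    if len(panel) != truth.M:
        raise ValueError("panel and truth disagree on variant count")
    if rng is None:
        rng = np.random.default_rng(truth.seed + 1)
    z1 = np.empty(truth.M)
    z2 = np.empty(truth.M)
    s01 = np.sqrt(truth.sigma0_1_sq)
    s02 = np.sqrt(truth.sigma0_2_sq)
    rho0 = truth.rho0
    for sl, R in zip(panel.block_slices(), panel.blocks):
        L = _block_cholesky(R)
        k = R.shape[0]
        a = rng.standard_normal(k)
        b = rng.standard_normal(k)
        e1 = L @ a
        e2 = L @ (rho0 * a + np.sqrt(max(0.0, 1 - rho0**2)) * b)
        z1[sl] = np.sqrt(truth.N1) * (R @ effects.beta1[sl]) + s01 * e1
        z2[sl] = np.sqrt(truth.N2) * (R @ effects.beta2[sl]) + s02 * e2
    tables = []
    for trait, z, n in (("trait1", z1, truth.N1), ("trait2", z2, truth.N2)):
        df = panel.index[["SNP", "CHR", "BP", "A1", "A2"]].copy()
        df["Z"] = z
        df["P"] = np.clip(2.0 * norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
        df["N"] = float(n)
        tables.append(SumStats(df[SUMSTATS_COLUMNS], trait=trait))
    return tables[0], tables[1]


def simulate_pair(
    truth: MixtureTruth,
    panel: LDPanel | None = None,
    block_size: int = 50,
    ar1_r: float = 0.9,
) -> tuple[SumStats, SumStats, EffectDraw, LDPanel]:
    """One-call generator: panel (AR(1) blocks by default), effects and z-scores."""
    rng = np.random.default_rng(truth.seed)
    if panel is None:
        panel = make_ar1_panel(truth.M, block_size=block_size, r=ar1_r,
                               rng=np.random.default_rng(truth.seed + 2))
    effects = draw_effects(truth, rng)
    t1, t2 = simulate_z(effects, panel, truth, rng)
    return t1, t2, effects, panel


def write_fixture(
    tables: tuple[SumStats, SumStats],
    truth: MixtureTruth,
    directory: str | Path,
) -> None:
    """Write both trait tables (6 significant digits) plus the truth as JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for s in tables:
        s.df.to_csv(directory / f"{s.trait}.sumstats.tsv", sep="\t",
                    index=False, float_format="%.6g")
    (directory / "truth.json").write_text(json.dumps(asdict(truth), indent=1))


def read_truth(directory: str | Path) -> MixtureTruth:
    data = json.loads((Path(directory) / "truth.json").read_text())
    return MixtureTruth(**data)
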