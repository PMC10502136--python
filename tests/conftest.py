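"""Shared fixtures: synthetic GWAS pairs at desk scale, generated at test time."""

import numpy as np
import pytest

import pleiomix as px


@pytest.fixture(scope="session")
def small_panel():
    """600-variant AR(1) panel (blocks of 30, r = 0.8)."""
    return px.make_ar1_panel(600, block_size=30, r=0.8, rng=np.random.default_rng(42))


@pytest.fixture(scope="session")
def null_pair():
    """Two completely null traits with sample-overlap correlation 0.2, M = 4000."""
    truth = px.MixtureTruth(M=4000, pi1_spec=0.0, pi2_spec=0.0, pi12=0.0,
                            rho0=0.2, seed=101)
    t1, t2, eff, panel = px.simulate_pair(truth)
    return truth, t1, t2, eff, panel


@pytest.fixture(scope="session")
def shared_pair():
    """Strongly overlapping polygenic pair, M = 20,000, used by enrichment tests."""
    truth = px.MixtureTruth(
        M=20_000, pi1_spec=0.0005, pi2_spec=0.0005, pi12=0.002,
        sigma1_sq=40 / 50_000, sigma2_sq=40 / 250_000,
        rho_beta=0.6, rho0=0.0, N1=50_000, N2=250_000, seed=202,
    )
    t1, t2, eff, panel = px.simulate_pair(truth)
    return truth, t1, t2, eff, panel
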