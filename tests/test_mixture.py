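"""Mixture-model summaries, characteristic-function densities and fits."""

import numpy as np
import pytest
from scipy.stats import norm

import pleiomix as px
from pleiomix.mixture import N90_FRACTION, biv_density, uni_density


class TestDice:
    def test_symmetric_example(self):
        assert px.dice(1.0, 1.0, 1.0) == pytest.approx(0.5)

    def test_no_overlap(self):
        assert px.dice(5.0, 3.0, 0.0) == 0.0

    def test_full_overlap(self):
        assert px.dice(0.0, 0.0, 7.0) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            px.dice(-1.0, 1.0, 1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            px.dice(0.0, 0.0, 0.0)


class TestConcordantFraction:
    def test_independent_effects_give_half(self):
        assert px.concordant_fraction(0.0) == pytest.approx(0.5)

    def test_perfect_correlation(self):
        assert px.concordant_fraction(1.0) == pytest.approx(1.0)
        assert px.concordant_fraction(-1.0) == pytest.approx(0.0)

    def test_matches_monte_carlo(self):
        rho = 0.37
        rng = np.random.default_rng(8)
        u = rng.standard_normal(400_000)
        v = rho * u + np.sqrt(1 - rho**2) * rng.standard_normal(400_000)
        mc = np.mean(np.sign(u) == np.sign(v))
        assert px.concordant_fraction(rho) == pytest.approx(mc, abs=0.003)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            px.concordant_fraction(1.01)


class TestN90:
    def test_fraction_matches_monte_carlo(self):
        """Smallest top fraction of chi2_1 effects reaching 90% of their sum."""
        rng = np.random.default_rng(12)
        x = np.sort(rng.standard_normal(400_000) ** 2)[::-1]
        cum = np.cumsum(x) / x.sum()
        frac = (np.searchsorted(cum, 0.9) + 1) / len(x)
        assert N90_FRACTION == pytest.approx(frac, abs=0.005)

    def test_linear_in_arguments(self):
        assert px.n90(0.01, 100_000) == pytest.approx(N90_FRACTION * 1000)
        assert px.n90(0.02, 100_000) == pytest.approx(2 * px.n90(0.01, 100_000))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            px.n90(1.5, 100)


class TestRgFromParams:
    def test_matches_effect_draw_correlation(self):
        truth = px.MixtureTruth(M=400_000, pi1_spec=0.01, pi2_spec=0.02,
                                pi12=0.03, sigma1_sq=1.0, sigma2_sq=4.0,
                                rho_beta=0.6, seed=5)
        eff = px.draw_effects(truth)
        mc = np.corrcoef(eff.beta1, eff.beta2)[0, 1]
        model = px.rg_from_params(0.01, 0.02, 0.03, 0.6, 1.0, 4.0)
        assert model == pytest.approx(mc, abs=0.01)

    def test_zero_without_shared_component(self):
        assert px.rg_from_params(0.01, 0.01, 0.0, 0.9) == 0.0

    def test_independent_of_effect_scales_when_symmetric(self):
        a = px.rg_from_params(0.01, 0.01, 0.02, 0.5, 1.0, 1.0)
        b = px.rg_from_params(0.01, 0.01, 0.02, 0.5, 9.0, 0.25)
        assert a == pytest.approx(b)


class TestVennSummary:
    def _fit(self, pi1s, pi2s, pi12, rho, M=100_000):
        uni = px.UnivariateFit(pi_total=pi1s + pi12, sigma_b_sq=1e-4,
                               sigma0_sq=1.0, logL=0.0, M=M, N=1e5, n_used=M)
        uni2 = px.UnivariateFit(pi_total=pi2s + pi12, sigma_b_sq=1e-4,
                                sigma0_sq=1.0, logL=0.0, M=M, N=1e5, n_used=M)
        return px.BivariateFit(pi1_spec=pi1s, pi2_spec=pi2s, pi12=pi12,
                               rho_beta=rho, rho0=0.0, logL=0.0,
                               uni1=uni, uni2=uni2)

    def test_counts_and_dice(self):
        venn = px.venn_summary(self._fit(0.001, 0.002, 0.004, 0.3))
        assert venn.n_shared == pytest.approx(N90_FRACTION * 0.004 * 100_000 / 1e3)
        assert venn.n_shared_raw == pytest.approx(0.4)
        # n90 scaling is linear, so Dice is unchanged by it
        assert venn.dice == pytest.approx(px.dice(0.1, 0.2, 0.4))
        assert venn.concordant_fraction == pytest.approx(px.concordant_fraction(0.3))

    def test_tsv_written(self, tmp_path):
        venn = px.venn_summary(self._fit(0.001, 0.002, 0.004, 0.3))
        path = tmp_path / "venn.tsv"
        venn.to_tsv(path)
        assert "n_shared" in path.read_text()


# ---------------------------------------------------------------------------
# Densities against closed forms and Monte Carlo
# ---------------------------------------------------------------------------


class TestReferenceDensities:
    def test_uni_density_null_is_standard_normal(self):
        z = np.linspace(-4, 4, 17)
        got = uni_density(z, np.array([1.0]), pi=0.0, sigma_b_sq=1e-4,
                          sigma0_sq=1.0, N=1e5)
        assert np.allclose(got, norm.pdf(z), atol=1e-6)

    def test_uni_density_all_causal_is_gaussian_convolution(self):
        """pi = 1 makes every neighbour causal: Gaussian with known variance."""
        r2 = np.array([1.0, 0.64, 0.36])
        N, sb2, s02 = 5e4, 2e-4, 1.2
        var = s02 + N * sb2 * r2.sum()
        z = np.linspace(-8, 8, 33)
        got = uni_density(z, r2, pi=1.0, sigma_b_sq=sb2, sigma0_sq=s02, N=N)
        assert np.allclose(got, norm.pdf(z, scale=np.sqrt(var)), atol=1e-6)

    def test_uni_density_matches_monte_carlo_mixture(self):
        """2-variant block, moderate pi: histogram of simulated z vs density."""
        rng = np.random.default_rng(3)
        n = 2_000_000
        N, sb2, pi = 1e5, 1e-4, 0.3
        r = 0.8
        b1 = rng.standard_normal(n) * np.sqrt(sb2) * (rng.random(n) < pi)
        b2 = rng.standard_normal(n) * np.sqrt(sb2) * (rng.random(n) < pi)
        z = np.sqrt(N) * (b1 + r * b2) + rng.standard_normal(n)
        edges = np.linspace(-6, 6, 41)
        hist, _ = np.histogram(z, bins=edges, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        got = uni_density(centers, np.array([1.0, r**2]), pi=pi,
                          sigma_b_sq=sb2, sigma0_sq=1.0, N=N)
        assert np.allclose(hist, got, rtol=0.05, atol=2e-4)

    def test_biv_density_null_factorizes(self):
        z = np.array([0.0, 1.0, -2.0])
        got = biv_density(z, z, np.array([1.0]), 0.0, 0.0, 0.0, 0.0, 0.0,
                          1e-4, 1e-4, 1.0, 1.0, 1e5, 1e5)
        assert np.allclose(got, norm.pdf(z) ** 2, atol=1e-5)

    def test_biv_density_gaussian_with_rho0(self):
        rho0 = 0.5
        pts = np.array([[0.0, 0.0], [1.0, -1.0], [2.0, 1.5]])
        got = biv_density(pts[:, 0], pts[:, 1], np.array([1.0]),
                          0.0, 0.0, 0.0, 0.0, rho0,
                          1e-4, 1e-4, 1.0, 1.0, 1e5, 1e5)
        det = 1 - rho0**2
        quad = (pts[:, 0] ** 2 - 2 * rho0 * pts[:, 0] * pts[:, 1] + pts[:, 1] ** 2) / det
        exact = np.exp(-0.5 * quad) / (2 * np.pi * np.sqrt(det))
        assert np.allclose(got, exact, atol=1e-5)

    def test_biv_density_integrates_to_one(self):
        """Coarse lattice integral of the joint density over the bulk."""
        grid = np.linspace(-8, 8, 65)
        Z1, Z2 = np.meshgrid(grid, grid, indexing="ij")
        dens = biv_density(Z1.ravel(), Z2.ravel(), np.array([1.0, 0.5]),
                           0.002, 0.002, 0.004, 0.5, 0.1,
                           2e-4, 1e-4, 1.0, 1.0, 5e4, 1e5)
        total = dens.sum() * (grid[1] - grid[0]) ** 2
        assert total == pytest.approx(1.0, abs=0.01)


class TestWorkspaceLikelihoods:
    def test_uni_loglik_null_matches_gaussian(self, small_panel):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(len(small_panel))
        ws = px.MixtureWorkspace(z, None, small_panel, N1=1e5)
        got = ws.uni_loglik(1, 1e-9, 1e-4, 1.0)
        exact = norm.logpdf(z).sum()
        assert got == pytest.approx(exact, abs=1e-3 * abs(exact))

    def test_uni_loglik_matches_reference_density(self, small_panel):
        """Binned-histogram path vs exact-profile dense quadrature."""
        truth = px.MixtureTruth(M=600, pi1_spec=0.02, pi2_spec=0.0, pi12=0.0,
                                sigma1_sq=2e-4, sigma2_sq=1e-6, N1=1e5, seed=33)
        t1, _, _, _ = px.simulate_pair(truth, panel=small_panel)
        ws = px.MixtureWorkspace(t1.z, None, small_panel, N1=1e5)
        pi, sb2, s02 = 0.02, 2e-4, 1.0
        got = ws.uni_loglik(1, pi, sb2, s02)
        ll_ref = 0.0
        r2min = ws.config.r2_min
        for sl, R in zip(small_panel.block_slices(), small_panel.blocks):
            for i in range(R.shape[0]):
                prof = np.square(R[i])
                prof = prof[prof > r2min]
                d = uni_density(t1.z[sl.start + i], prof, pi, sb2, s02, 1e5)
                ll_ref += np.log(d[0])
        assert got == pytest.approx(ll_ref, abs=0.01 * abs(ll_ref))

    def test_biv_loglik_factorizes_when_trait2_null(self, small_panel):
        """With pi2_spec = pi12 = rho0 = 0 the joint splits exactly into
        marginal mixture (trait 1) times standard normal (trait 2)."""
        truth = px.MixtureTruth(M=600, pi1_spec=0.02, pi2_spec=1e-12, pi12=0.0,
                                sigma1_sq=2e-4, sigma2_sq=1e-6, N1=1e5, N2=1e5,
                                rho0=0.0, seed=44)
        t1, t2, _, _ = px.simulate_pair(truth, panel=small_panel)
        cfg = px.GridConfig(double_precision=True)
        ws = px.MixtureWorkspace(t1.z, t2.z, small_panel, 1e5, 1e5, config=cfg)
        joint = ws.biv_loglik(0.02, 0.0, 0.0, 0.0, 0.0, 2e-4, 1e-6, 1.0, 1.0)
        marg1 = ws.uni_loglik(1, 0.02, 2e-4, 1.0)
        marg2 = norm.logpdf(t2.z).sum()
        assert joint == pytest.approx(marg1 + marg2, rel=1e-4)

    def test_biv_loglik_matches_reference_density(self, small_panel):
        """Binned 2-D workspace vs exact-profile dense quadrature, shared model."""
        truth = px.MixtureTruth(M=600, pi1_spec=0.005, pi2_spec=0.005,
                                pi12=0.01, sigma1_sq=2e-4, sigma2_sq=1e-4,
                                rho_beta=0.5, rho0=0.2, N1=5e4, N2=1e5, seed=55)
        t1, t2, _, _ = px.simulate_pair(truth, panel=small_panel)
        cfg = px.GridConfig(double_precision=True)
        ws = px.MixtureWorkspace(t1.z, t2.z, small_panel, 5e4, 1e5, config=cfg)
        params = dict(pi1_spec=0.005, pi2_spec=0.005, pi12=0.01, rho_beta=0.5,
                      rho0=0.2, sigma1_sq=2e-4, sigma2_sq=1e-4,
                      sigma0_1_sq=1.0, sigma0_2_sq=1.0)
        got = ws.biv_loglik(**params)
        ll_ref = 0.0
        r2min = ws.config.r2_min
        for sl, R in zip(small_panel.block_slices(), small_panel.blocks):
            for i in range(R.shape[0]):
                prof = np.square(R[i])
                prof = prof[prof > r2min]
                d = biv_density(t1.z[sl.start + i], t2.z[sl.start + i], prof,
                                N1=5e4, N2=1e5, **params)
                ll_ref += np.log(max(d[0], 1e-300))
        assert got == pytest.approx(ll_ref, abs=0.01 * abs(ll_ref))


class TestFitting:
    def test_fit_univariate_requires_variants(self, small_panel):
        truth = px.MixtureTruth(M=600, seed=1)
        t1, _, _, _ = px.simulate_pair(truth, panel=small_panel)
        with pytest.raises(ValueError, match="1,000"):
            px.fit_univariate(t1, small_panel)

    def test_fit_univariate_recovers_h2(self, shared_pair):
        truth, t1, _, _, panel = shared_pair
        fit = px.fit_univariate(t1, panel)
        assert fit.h2_snp == pytest.approx(truth.h2_1, rel=0.35)
        assert fit.sigma0_sq == pytest.approx(1.0, abs=0.1)
        assert 0 < fit.pi_total < 0.5

    def test_workspace_rejects_offscale_z(self, small_panel):
        z = np.zeros(len(small_panel))
        z[0] = 1e4
        with pytest.raises(ValueError, match="z_max"):
            px.MixtureWorkspace(z, None, small_panel, N1=1e5)
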