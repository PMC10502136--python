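# Methods

This note describes the statistical model behind `pleiomix`, the synthetic
data generator used to exercise it, the numerical choices made in the
implementation, and its limitations. Everything here refers to what the code
computes; claims about real traits are out of scope.

## Model

### Bivariate causal mixture

For a pair of traits, each variant's true effect pair `(beta1_j, beta2_j)` on
the standardized-genotype scale is drawn from a four-component mixture:

- null for both traits, with probability `1 - pi1_spec - pi2_spec - pi12`;
- causal for trait 1 only (`pi1_spec`): `beta1 ~ Normal(0, sigma1^2)`;
- causal for trait 2 only (`pi2_spec`): `beta2 ~ Normal(0, sigma2^2)`;
- shared (`pi12`): bivariate Gaussian with per-trait variances
  `sigma1^2, sigma2^2` and correlation `rho_beta`.

Observed z-scores convolve the effects over LD within blocks:

    z_t = sqrt(N_t) * R beta_t + eps_t,   eps_t ~ Normal(0, sigma0_t^2 R),

where `R` is the LD (correlation) matrix and the two traits' residuals are
coupled at correlation `rho0`, the term induced by overlapping samples. The
expected SNP heritability is `h2_t = M * (pi_spec_t + pi12) * sigma_t^2`.

Headline summaries derived from a fit:

- **Venn counts.** Trait-specific and shared causal-variant counts are
  reported on the 90%-heritability scale: only the top fraction
  `q = P(chi2_1 > t*) ~ 0.447` of causal effects, chosen so that they carry
  90% of the heritability, is counted (`n90 = q * pi * M`). This guards the
  polygenicity estimate against extrapolation into infinitesimal effects. The
  threshold `t*` solves `E[X 1(X > t)] = 0.9` for `X ~ chi2_1`, using the
  identity `E[X 1(X > t)] = P(chi2_3 > t)`.
- **Dice coefficient** `2*shared / (total1 + total2)` of the two causal sets
  (invariant to the linear n90 scaling).
- **Concordant shared-effect fraction**: the bivariate-normal orthant
  probability `1/2 + arcsin(rho_beta)/pi`.
- **Model-implied genetic correlation**
  `rg = pi12 rho_beta sigma1 sigma2 / sqrt(v1 v2)` with
  `v_t = (pi_spec_t + pi12) sigma_t^2`.

### Likelihood via characteristic functions

The marginal density of a z-score under the mixture is an LD convolution with
no closed form; it is evaluated through its characteristic function. For one
trait,

    phi_j(t) = exp(-sigma0^2 t^2 / 2) *
               prod_k [ 1 - pi + pi exp(-N sigma_b^2 r2_jk t^2 / 2) ],

with the product over LD neighbours `k` with `r2_jk > r2_min`. The bivariate
analogue multiplies four-component terms per neighbour and includes the
residual cross term `rho0 sigma0_1 sigma0_2 t1 t2`.

Numerical choices:

- **r² histogram compression.** Each variant's neighbour r² profile is
  binned (default 24 bins above `r2_min = 0.05`, bin representative = global
  count-weighted mean), so the log of the neighbour product becomes a matrix
  product `C @ log(mixture terms)` shared across all variants.
- **Cosine-series inversion.** Densities are recovered by quadrature at the
  discrete frequencies `t_k = k * pi / z_max` (default `z_max = 12`),
  truncated where the residual-Gaussian envelope is numerically zero
  (`t_cut = 10`). The 2-D inversion uses the half-plane disc of frequency
  nodes with symmetry weights and a precomputed phase matrix.
- **Tail censoring.** The inversion grid periodizes the density with period
  `2 z_max`, which corrupts the extreme tail. Variants with
  `|z| >= censor_z = 9` therefore contribute a censored (tail-mass)
  likelihood term, computed from the same characteristic function with a box
  kernel, instead of a point density.
- **Precision.** The bivariate node caches default to float32 with the
  per-variant density clipped at the quadrature noise floor (1e-9); a
  `double_precision` switch enables float64 caches for oracle-grade
  comparisons on small problems. The univariate path is always float64.
- **Subsampling.** Likelihoods are evaluated on deterministic every-k-th
  subsets (default caps: 100k variants univariate, 10k bivariate).
- **Optimization.** Univariate fits maximize over
  `(log10 pi, log10 sigma_b^2, log sigma0^2)` by Nelder-Mead from a screened
  multi-start grid seeded by an LD-score-regression moment fit. Bivariate
  fits hold the univariate parameters fixed and optimize
  `(pi12, rho_beta, rho0)` in an unconstrained reparameterization
  (logistic/tanh), seeded by a cross-trait moment fit. Model adequacy is
  reported as AIC differences against minimum-overlap (`pi12 = 0`) and
  maximum-overlap (`pi12 = min(pi1, pi2)`) constrained refits, and as a
  profile likelihood over `pi12`.

Exact-profile dense-quadrature reference densities (`uni_density`,
`biv_density`) are kept alongside the fitting path; the test suite verifies
the binned path against them and both against closed forms and Monte-Carlo
histograms.

### Conditional and conjunctional FDR

The conditional FDR of the primary trait given the secondary is the
empirical-Bayes ratio `condFDR = p1 / Fhat(p1 | p2 <= s)` with the null
fraction conservatively fixed at 1, where `Fhat` is the empirical CDF of
primary p-values in the secondary stratum. Implementation details:

- a lookup table over 201 `-log10 p1` breakpoints x 9 secondary thresholds
  (1 down to 1e-8), queried by bilinear interpolation in `-log10` space;
- the table is averaged over random LD prunings (one variant kept per
  `r^2 > 0.1` clique) so LD-redundant strata do not distort the CDF;
- strata with fewer than 100 pruned variants are unusable — the empirical
  CDF of a handful of points floors at `0.5/n`, overestimating `F(p)` at
  small `p` and hence underestimating condFDR — and inherit the nearest
  wider stratum;
- monotonicity in both significance directions is enforced by
  cumulative-minimum sweeps;
- three long-range LD regions (extended MHC `chr6:25119106-33854733`,
  8p23.1 `chr8:7242715-12483982`, and the MAPT region
  `chr17:40000000-47000000`) are excluded from table fitting but still
  receive values for discovery.

The conjunctional FDR is the elementwise maximum of the two reciprocal
condFDR values. Significance uses strict thresholds: condFDR < 0.01,
conjFDR < 0.05.

### Locus definition

Independent significant variants are selected greedily in ascending conjFDR
at mutual `r^2 < 0.6`; lead variants are the subset mutually at `r^2 < 0.1`.
A locus spans the min-max positions of its candidate variants
(conjFDR < 0.1 and `r^2 >= 0.6` with an independent significant variant);
loci closer than 250 kb merge, keeping the lowest-conjFDR lead. A locus is
concordant when its lead variant's z-scores share a sign in both GWAS; a
zero z-score is an error, not a silent default. Locus sets from different
analyses are combined by counting >= 1 bp physical overlaps once.

### LD-score regression

`E[z^2] = intercept + N h2 ell / M` fitted by two-pass weighted least
squares (second-pass weights `1/(2 mu^2)`); cross-trait
`E[z1 z2] = intercept + sqrt(N1 N2) rho_g ell / M`, whose intercept absorbs
sample overlap. Standard errors come from a delete-one block jackknife
(default 200 contiguous blocks). `rg = rho_g / sqrt(h2_1 h2_2)` is clipped
to [-1, 1] and flagged undefined when either heritability estimate is
nonpositive.

### Local genetic correlation

Within a locus the LD matrix is eigendecomposed and truncated at 99% of the
trace; whitened projections `w = Lambda^{-1/2} U' z` give a
method-of-moments local heritability `(w'w - k)/N` with a chi-square(k)
p-value, and a noise-corrected local correlation
`w1'w2 / sqrt((w1'w1 - k)(w2'w2 - k))` with a sign-permutation p-value.
Loci are highlighted when local heritability is Bonferroni-significant in
both traits and the local correlation is nominally significant (p < 0.05).

## Synthetic data generator

`simulate_pair` draws effects and z-scores exactly under the model above on
a block-diagonal LD panel. The default panel is AR(1) within blocks
(`r = 0.9`, block size 50), which has closed-form LD scores and spans a
realistic r² range; any block-diagonal correlation panel can be supplied
instead. Fixtures (two summary-statistics tables plus the ground-truth
parameters as JSON) are plain text.

The generator's scope is deliberate: block-diagonal LD, standardized
genotypes (allele frequency drops out), Gaussian effect sizes, and constant
per-trait sample size. It exists to give every estimator a known ground
truth, not to emulate any specific cohort.

## Validation summary

The test suite checks, among other things: densities against closed forms
and 10^6-draw Monte-Carlo histograms; the n90 fraction, orthant probability
and model-implied rg against direct simulation; false-discovery control of
conjFDR < 0.05 under `pi12 = 0`; recovery of `(pi12, rho_beta)` over a 3x3
truth grid at M = 50k; LDSC h2/rg recovery over 20 seeds; and uniformity of
null local-correlation permutation p-values.

## Limitations

- LD is block-diagonal; long-range LD exists only through the exclusion-region
  machinery, and the condFDR pruning assumes blocks are exchangeable.
- The mixture likelihood treats neighbour causal states as independent across
  variants and compresses LD into an r² histogram; both are approximations,
  validated empirically rather than bounded analytically.
- The bivariate fit conditions on fixed univariate parameters rather than
  maximizing jointly; uncertainty from the univariate stage is not propagated.
- condFDR with the null fraction fixed at 1 is conservative by construction;
  power comparisons against less conservative variants are not implemented.
- The local-correlation module is a simplified analogue of dedicated local
  genetic-correlation methods (method of moments on an eigen-truncated basis
  with permutation p-values); calibration and recovery on synthetic data are
  its acceptance surface, not parity with any external tool.
- Effect sizes are Gaussian within components; fat-tailed or
  frequency-dependent architectures are out of scope.
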