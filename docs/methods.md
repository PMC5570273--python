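# Methods

## The mutant-count model

A fluctuation test grows `n` parallel cultures from a small inoculum
(`N0 ≈ 1e4` cells) to saturation (`Nt` cells) without selection, then plates
each culture whole on selective medium. Mutational events arise as a Poisson
process with mean `m` per culture; an event founds a resistant clone whose
final size depends on when it arose. With mutants growing at relative fitness
`w` (1 = neutral), the clone-size law is

    f_j = rho * B(j, rho + 1),   rho = 1 / w,

(`B` the beta function), which at `w = 1` reduces to the classical
`f_j = 1/(j(j+1))`. The count probabilities follow the compound-Poisson
(Ma-Sandri-Sarkar) recursion

    p_0 = exp(-m),   p_n = (m/n) * sum_{j=1..n} j f_j p_{n-j}.

The clone-size law has infinite mean (`P(J >= j) = rho * B(j, rho)`, a
power-law tail), which is what produces jackpot cultures.

Numerics: the recursion is run on values rescaled by `exp(m)` with periodic
renormalization (the recursion is linear), so log-probabilities are finite
for any `m` without silent under/overflow; linear-scale probabilities are
`exp()` of those. Sampling inverts the clone-size tail exactly (table lookup
for the bulk, bracketed integer bisection in the deep tail, clone sizes
capped at 1e12 — far beyond any censoring bound — to keep integer arithmetic
safe).

## Estimation of m (and w)

The likelihood of a dataset treats counts above the truncation bound
`r_max` (default 1e4) as right-censored: their contribution is the tail mass
`1 - sum(p)`. This keeps jackpot plates informative without unbounded
recursion; halving or doubling `r_max` moves estimates by well under 1% for
`m <= 30` (tested).

- `estimate_m`: maximizes over `log m` in [-23, 12] (coarse grid then
  bounded Brent). All-zero datasets return the boundary `m_hat = 0` with
  `ci = (0, 1.92/n)`.
- 95% intervals are profile-likelihood: `{m : loglik(m) >= max - 1.92}`
  (chi-square 1 df). Simulated coverage at `m = 5`, `n = 16` is 95.2%
  (500 replicates, seeded).
- `estimate_m_w`: joint Nelder-Mead over `(log m, log w)`, `w` in
  [0.05, 10], three fixed starts. With few cultures the profile in `w` is
  often flat; the fit is then flagged `converged = False` (checked by
  re-profiling `m` at `w/2` and `2w`: an identified `w` must cost > 0.1
  log-likelihood units).
- `p0_method`: `-ln(P0)/Nt` from the fraction of zero-count cultures;
  undefined (distinct error) when no culture is mutant-free.

## From experiment to rate

`mu = m_hat / Nt` exactly; `D = Nt` per post-evaporation millilitre.
`Nt` is the mean of (typically 3) replicate measurements; CFU replicates are
densities scaled by the post-evaporation volume before averaging, ATP and
cell-count replicates are whole-culture sizes. The CV reported with each
summary is population sd / mean. `Ne` is the harmonic mean of the
post-division population sizes `N0*2^i` up to `Nt`, the last term replaced by
`Nt` when the generation count `log2(Nt/N0)` is fractional — a documented
convention; any similar convention changes `Ne` only slightly and
monotonically. Estimates with `m_hat` outside [0.3, 30] are flagged
`excluded` but never dropped; model fits take an include/exclude switch.
Events per space-time is `m_hat / (volume * time)` (per ml per hour).

## The plasticity (DAMP) model

    log2(mu) = intercept[strain x marker] + slope[strain] * log2(D)
               + b[block] + eps

fitted by REML via statsmodels MixedLM (OLS when blocking is absent), ML
refits for likelihood-ratio tests. The covariate is centred at its mean, so
intercepts are rates at the study's central density; slopes are unaffected
and invariant to rescaling all densities. Separate marker intercepts absorb
target-size differences between resistance loci; slopes are per strain by
default (`slope_by="strain_marker"` available).

Inference: Wald `t = estimate/SE` with residual df `n_obs - n_fixed`;
slope confidence intervals use the t quantile at that df (the behaviour of
standard mixed-model software, and necessary for honest coverage at
16-observation studies: measured 96.3% over 300 synthetic studies vs ~91%
with a normal quantile). Likelihood-ratio tests compare ML log-likelihoods
with chi-square df equal to the parameter difference.

Variance covariate (off by default): residual variance proportional to
`|evaporation|^(2*delta)`. Implemented by scaling each row of the model by
`|evap|^-delta` and profiling `delta` on a grid over the REML likelihood
(with the log-Jacobian correction). The row scaling also scales the block
design — exact for the residual term, an approximation for the random
effects — and is the package's documented stand-in for a heteroscedastic
mixed fit, since no installed mixed-model library supports residual variance
functions.

`fitness_sensitivity` re-runs the whole pipeline at each assumed `w`,
reporting slope and SE per grid point; failures at extreme `w` are counted,
not fatal. `doubling_density_reduction(b) = 100*(1 - 2^(1/b))` converts a
negative slope to the percent density reduction at which the rate doubles.

## The meta-analytic model

    log2(rate) = alpha + beta*log2(D) + a_org + b_org*log2(D)
                 + a_study + a_medium + a_marker + eps

Per-organism `(a_org, b_org)` pairs are bivariate normal with an estimated
2x2 covariance Kronecker-multiplied by the Brownian-motion correlation matrix
`C` of the phylogeny (`C_ij` = shared root-to-tip path / geometric mean of
depths; unit diagonal; identity for a star tree). Study, medium and marker
are i.i.d. random intercepts. Variance parameters (7 in the full model:
2 organism sds, their correlation, 3 intercept sds, residual sd) are
estimated by maximizing the REML log-likelihood directly with Nelder-Mead
(two fixed starts, tolerance 1e-8); fixed effects by GLS at the optimum;
per-organism slopes are BLUPs `G Z' V^-1 (y - X beta)`, which shrink toward
the fixed slope as organism-level variance vanishes. This model is authored
in-package because no installed Python library fits random slopes with a
*fixed* cross-group correlation matrix.

Variance explained by density is the proportional reduction in residual
variance between the full fit and a reduced fit with density removed
entirely (fixed and random slope): near 0 for identical fits, near 1 when
density determines the response. The likelihood-ratio test of the density
term instead drops only the fixed slope (df = 1).

Curation applies three exclusion rules — (i) intentionally selective culture
conditions, (ii) genetically manipulated or mutator strains, (iii) partial
plating of the culture — plus removal of rows without a positive rate and
density, each removal logged with its rule id.

## Phylogeny assembly

`graft_subtree` rescales a donor tree into the base tree's branch-length
units using calibration tips present in both the base and a calibration tree
(the donor itself, or the larger source tree the donor was cut from): either
the ratio of mean tip-to-ancestor depths, or the zero-intercept least-squares
gradient `sum(xy)/sum(x^2)` of base depths on donor depths (>= 2 tips). The
scaled donor root becomes a child of a chosen base node (tip label, internal
label, or MRCA of a tip list). Grafting at a tip converts that tip to an
internal node; attach at an internal node to conserve tip counts.

## The synthetic-data generator

`StudyDesign` defaults are the conditions of the batch-culture experiments
the package emulates: 16 parallel cultures per test, `N0` lognormal around
1e4 cells, incubation 24 h, evaporation ~5% (sd 2%, truncated at [0, 0.3]),
`Nt` measured in triplicate with lognormal noise at CV 15.9% (CFU) and
10.9% (ATP; haemocytometer counts treated the same, no published CV), block
effects N(0, 0.25) on log2(mu), and a glucose-to-density map that is linear
with saturation (2e6 cells/ml per mg/l up to 1000 mg/l) so the default
glucose range 25-1000 mg/l spans roughly two orders of magnitude of density
— the paper-scale yield curve is not published, so the map is calibrated to
that span. True rates follow `mu(D) = mu0 (D/1e8)^beta` with `mu0 = 5e-9`
and `beta = -0.68` by default; counts come from the exact sampler at
`m = mu(D) * Nt`.

The literature-corpus generator draws organism slopes/intercepts with
covariance proportional to a pure-birth tree's Brownian correlation. Raw
pure-birth trees conditioned on a tip count carry a dominant shared trunk
(mean tip-tip correlation ~0.75), which confounds the overall slope with the
unidentifiable common phylogenetic deviation; the corpora being emulated
span all domains of life, where most pairs diverge near the root. The
generator therefore applies a Pagel's-lambda depth-preserving transform
(`phylo_signal`, default 0.25: all edges scaled by lambda, the removed
length returned to terminal edges). Between-organism intercept spread
defaults to 4.0 log2 units, matching the several-orders-of-magnitude span of
published rates; densities are log-uniform over >= 4 orders of magnitude.

What the generators do **not** emulate: reporting bias in the literature,
mechanistic growth dynamics or quorum signalling, plate-position effects,
partial plating, or non-lognormal measurement error. Passing recovery and
coverage tests therefore demonstrates calibration of the estimators under
the stated noise model, not robustness to those unmodelled features of real
data.

## Problem sizes and seeds

Simulation-based checks use problem sizes chosen to give informative Monte
Carlo precision at desk scale: 500 replicates for profile-CI coverage, 300
synthetic studies (16 estimates each) for slope-CI coverage, 4000
regression-level null simulations for the Wald size check, 1e4-1e5 draws for
distributional goodness-of-fit. All randomness flows from explicit seeds;
every generator call is deterministic given its seed.

## Known limitations

- Joint `(m, w)` estimation is slow for heavy-tailed datasets at the default
  `r_max` (the recursion is O(r_max^2)); pass a smaller censoring bound when
  jackpot resolution beyond a few hundred colonies is not needed.
- The plating fraction is fixed at 1 (whole cultures plated); partial
  plating, phenotypic delay and post-plating growth are out of scope.
- The meta-model's REML surface can be flat in the organism-slope variance
  when organisms are few or strongly correlated; the fixed-slope SE is then
  conditional on the variance estimate, as in any REML-based mixed model.
- Viral per-strand-copying rate conversion is not implemented; literature
  records must already be on a per-replication scale.
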