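"""Tests for the DAMP mixed-model regression and its tests/summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dampkit import io as dio
from dampkit.fluctuation import estimate_rate
from dampkit.plasticity import (
    DampFit,
    DampModelSpec,
    SingularDesignError,
    doubling_density_reduction,
    fit_damp,
    fitness_sensitivity,
    lr_test,
    wald_slope_test,
)
from dampkit.simulate import DampLaw, StudyDesign, make_damp_study


def exact_table(slope=-0.68, mu0=5e-9, ref=1e8, strains=("A",), markers=("m1", "m2")):
    """Noise-free rate table exactly on the power law."""
    rows = []
    for s in strains:
        for k_i, k in enumerate(markers):
            for d in np.geomspace(1e7, 1e9, 8):
                mu = mu0 * (1 + k_i) * (d / ref) ** slope
                rows.append({"strain": s, "marker": k, "block": "b1",
                             "mu": mu, "D": d, "evaporation": 0.05})
    return pd.DataFrame(rows)


def noisy_table(rng, slope=-0.68, n_blocks=3, block_sd=0.25, resid_sd=0.5,
                n_per_block=8, strains=("A",)):
    rows = []
    for s in strains:
        for b in range(n_blocks):
            beff = rng.normal(0, block_sd)
            d = np.exp(rng.uniform(np.log(1e7), np.log(1e9), n_per_block))
            log2mu = (math.log2(5e-9) + slope * (np.log2(d) - math.log2(1e8))
                      + beff + resid_sd * rng.standard_normal(n_per_block))
            for dd, lm in zip(d, log2mu):
                rows.append({"strain": s, "marker": "m", "block": f"b{b}",
                             "mu": 2.0**lm, "D": dd, "evaporation": 0.05})
    return pd.DataFrame(rows)


def test_noise_free_slope_recovered_exactly():
    fit = fit_damp(exact_table(), DampModelSpec(use_blocks=False))
    assert fit.slopes.loc["A", "estimate"] == pytest.approx(-0.68, abs=1e-6)


def test_matches_ols_closed_form_without_blocks():
    rng = np.random.default_rng(1)
    table = noisy_table(rng)
    fit = fit_damp(table, DampModelSpec(use_blocks=False))
    y = np.log2(table["mu"].to_numpy())
    x = np.log2(table["D"].to_numpy())
    x = x - x.mean()
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    assert fit.slopes.loc["A", "estimate"] == pytest.approx(beta[1], abs=1e-10)


def test_mixed_fit_close_to_ols_when_no_block_effects():
    rng = np.random.default_rng(2)
    table = noisy_table(rng, block_sd=0.0)
    mixed = fit_damp(table, DampModelSpec(use_blocks=True))
    ols = fit_damp(table, DampModelSpec(use_blocks=False))
    assert mixed.slopes.loc["A", "estimate"] == pytest.approx(
        ols.slopes.loc["A", "estimate"], abs=5e-3
    )


def test_slope_invariant_to_density_rescaling():
    rng = np.random.default_rng(3)
    table = noisy_table(rng)
    fit1 = fit_damp(table)
    table2 = table.assign(D=table["D"] * 137.0)
    fit2 = fit_damp(table2)
    assert fit1.slopes.loc["A", "estimate"] == pytest.approx(
        fit2.slopes.loc["A", "estimate"], abs=1e-8
    )


def test_singular_design_named():
    table = exact_table(markers=("m1",))
    # duplicate strain label under two names cannot happen; force collinearity
    # by a single shared density value per marker
    bad = table.copy()
    bad["D"] = 1e8
    with pytest.raises(ValueError, match="densities|collinear"):
        fit_damp(bad, DampModelSpec(use_blocks=False))


def test_wald_test_t_distribution_tail():
    """t = estimate/SE with residual df; p from the t tail (oracle check)."""
    fit = fit_damp(noisy_table(np.random.default_rng(4)))
    res = wald_slope_test(fit, group="A")
    est = fit.slopes.loc["A", "estimate"]
    se = fit.slopes.loc["A", "se"]
    t = est / se
    assert res.statistic == pytest.approx(t)
    assert res.df == fit.n_obs - fit.n_fixed
    assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t), res.df), rel=1e-12)


def test_wald_average_contrast_two_strains():
    rng = np.random.default_rng(8)
    table = pd.concat([
        noisy_table(rng, slope=-0.9, strains=("S1",)),
        noisy_table(rng, slope=-0.4, strains=("S2",)),
    ])
    fit = fit_damp(table)
    res = wald_slope_test(fit)
    avg = fit.slopes["estimate"].mean()
    assert res.statistic * math.copysign(1, avg) > 0
    assert 0 <= res.p_value <= 1


def test_lr_identical_models_zero():
    table = noisy_table(np.random.default_rng(5))
    fit = fit_damp(table)
    res = lr_test(fit, fit)
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_lr_null_distribution_matches_chi2():
    """Without any density effect, LR_1 follows chi-square(1) (KS check)."""
    rng = np.random.default_rng(6)
    lrs = []
    for _ in range(200):
        n = 60
        d = np.exp(rng.uniform(np.log(1e7), np.log(1e9), n))
        mu = 2.0 ** (math.log2(5e-9) + 0.5 * rng.standard_normal(n))
        table = pd.DataFrame({"strain": "A", "marker": "m", "block": "b1",
                              "mu": mu, "D": d})
        full = fit_damp(table, DampModelSpec(use_blocks=False))
        red = fit_damp(table, DampModelSpec(use_blocks=False, include_density=False))
        lrs.append(lr_test(full, red).statistic)
    _, p = stats.kstest(lrs, stats.chi2(1).cdf)
    assert p > 0.01


def test_lr_power_under_strong_slope():
    table = noisy_table(np.random.default_rng(7), slope=-0.68, resid_sd=0.3)
    full = fit_damp(table)
    red = fit_damp(table, DampModelSpec(include_density=False))
    assert lr_test(full, red).p_value < 1e-6


def test_lr_non_nested_rejected():
    a = fit_damp(noisy_table(np.random.default_rng(9)))
    b = fit_damp(noisy_table(np.random.default_rng(9)).iloc[:-2])
    with pytest.raises(ValueError, match="not nested|different"):
        lr_test(a, b)


def test_fitness_sensitivity_identity_at_w1():
    """The w=1 grid point reproduces the baseline pipeline slope exactly."""
    design = StudyDesign(seed=10, n_blocks=2,
                         glucose_mg_l=(25.0, 100.0, 1000.0),
                         volumes_ml=(1.0, 10.0))
    exps, _ = make_damp_study(DampLaw(), design)
    curve = fitness_sensitivity(exps, [1.0], method="CFU")
    rates = [estimate_rate(e, method="CFU", ci=False) for e in exps]
    baseline = fit_damp(dio.rates_to_table(rates))
    c = [n for n in baseline.params.index if n.startswith("slope[")]
    assert curve.loc[0, "slope"] == pytest.approx(
        float(baseline.params[c].mean()), abs=1e-12
    )


def test_variance_covariate_profiling_runs():
    rng = np.random.default_rng(11)
    table = noisy_table(rng)
    table["evaporation"] = rng.uniform(0.01, 0.2, len(table))
    fit = fit_damp(table, DampModelSpec(variance_power="estimate"))
    assert fit.variance_delta is not None
    assert -2.0 <= fit.variance_delta <= 2.0
    # slope should stay near the homoscedastic fit
    base = fit_damp(table)
    assert fit.slopes.loc["A", "estimate"] == pytest.approx(
        base.slopes.loc["A", "estimate"], abs=0.1
    )


class TestDoublingDensityReduction:
    def test_values(self):
        assert doubling_density_reduction(-1.0) == pytest.approx(50.0)
        assert round(doubling_density_reduction(-0.67)) == 64
        assert doubling_density_reduction(-1e6) == pytest.approx(0.0, abs=1e-3)

    def test_nonnegative_slope_rejected(self):
        with pytest.raises(ValueError):
            doubling_density_reduction(0.1)


def test_include_exclude_flagged_estimates_small_effect():
    """Without reporting bias, dropping flagged estimates barely moves the slope."""
    design = StudyDesign(seed=12, n_blocks=3)
    exps, _ = make_damp_study(DampLaw(mu0=2e-9), design)
    rates = [estimate_rate(e, ci=False) for e in exps]
    table = dio.rates_to_table(rates)
    assert table["excluded"].any()
    with_all = fit_damp(table, DampModelSpec(include_excluded=True))
    without = fit_damp(table, DampModelSpec(include_excluded=False))
    diff = abs(with_all.slopes.loc["strainA", "estimate"]
               - without.slopes.loc["strainA", "estimate"])
    assert diff < with_all.slopes.loc["strainA", "se"]
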