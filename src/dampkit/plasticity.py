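"""Hierarchical regression of log2 mutation rate on log2 population density.

Density-associated mutation-rate plasticity (DAMP) is quantified as the slope
of log2(mu) on log2(D) within an organism: a slope of -1 means the mutation
rate halves when final density doubles.  Experiments are structured — several
strains and phenotypic markers, measured in experimental blocks carried out on
different days — so the model is a linear mixed model:

    log2(mu) = intercept[strain x marker] + slope[strain] * log2(D)
               + b[block] + eps,     b ~ N(0, sigma_b^2),  eps ~ N(0, sigma^2)

fitted by REML (ML refits are available for likelihood-ratio tests).  Separate
intercepts per marker absorb the different target sizes of resistance loci
(e.g. many more mutations confer rifampicin than nalidixic-acid resistance);
the slope is shared within a strain unless requested otherwise.

Evaporation can optionally act as a variance covariate: residual variance
proportional to |evap|^(2*delta), with delta profiled.  The weighting is
applied by row-scaling the model (see docs), and is off by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.linear_model import OLS
from statsmodels.regression.mixed_linear_model import MixedLM

from dampkit.fluctuation import FluctuationExperiment, estimate_rate

__all__ = [
    "DampModelSpec",
    "DampFit",
    "TestResult",
    "SingularDesignError",
    "fit_damp",
    "wald_slope_test",
    "lr_test",
    "fitness_sensitivity",
    "doubling_density_reduction",
]


class SingularDesignError(ValueError):
    """Design matrix is rank-deficient; names the collinear columns."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"singular design; collinear terms: {self.columns}")


@dataclass(frozen=True)
class DampModelSpec:
    """What to regress and how.

    response/density name linear-scale columns; logs (base 2) are taken at fit
    time.  ``slope_by`` is the grouping for slopes ("strain" or
    "strain_marker"); intercepts always get one level per strain x marker
    combination unless ``separate_marker_intercepts`` is off.
    ``variance_power`` is None (homoscedastic), a float delta, or "estimate"
    (delta profiled on a grid) for the evaporation variance covariate.
    """

    response: str = "mu"
    density: str = "D"
    strain_col: str = "strain"
    marker_col: str = "marker"
    block_col: str = "block"
    slope_by: str = "strain"
    include_density: bool = True  # False: intercept-only reduced model
    separate_marker_intercepts: bool = True
    include_excluded: bool = True
    use_blocks: bool = True
    variance_power: float | str | None = None
    evap_col: str = "evaporation"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    description: str = ""


@dataclass(frozen=True)
class DampFit:
    """Fitted DAMP model: coefficients, per-strain slopes, variances, logliks."""

    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    slopes: pd.DataFrame  # index: slope group; columns estimate, se, ci_low, ci_high
    re_var: float
    resid_var: float
    loglik_reml: float
    loglik_ml: float
    n_obs: int
    n_fixed: int
    df_resid: int
    converged: bool
    spec: DampModelSpec
    n_dropped: int = 0
    variance_delta: float | None = None

    @property
    def n_params(self) -> int:
        return self.n_fixed

    @property
    def loglik(self) -> float:
        return self.loglik_ml


def _design(table: pd.DataFrame, spec: DampModelSpec):
    df = table.copy()
    if not spec.include_excluded and "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    y_lin = df[spec.response].astype(float)
    d_lin = df[spec.density].astype(float)
    ok = (y_lin > 0) & (d_lin > 0) & np.isfinite(y_lin) & np.isfinite(d_lin)
    n_dropped = int((~ok).sum())
    df = df[ok]
    if len(df) < 3:
        raise ValueError("fewer than 3 usable rows after filtering")
    y = np.log2(df[spec.response].astype(float).to_numpy())
    x = np.log2(df[spec.density].astype(float).to_numpy())
    x = x - x.mean()  # centring: slopes unchanged, design well conditioned

    strain = df[spec.strain_col].astype(str)
    if spec.separate_marker_intercepts and spec.marker_col in df.columns:
        icept_group = strain + "/" + df[spec.marker_col].astype(str)
    else:
        icept_group = strain
    if spec.slope_by == "strain_marker" and spec.marker_col in df.columns:
        slope_group = strain + "/" + df[spec.marker_col].astype(str)
    else:
        slope_group = strain

    cols, names = [], []
    for level in sorted(icept_group.unique()):
        cols.append((icept_group == level).to_numpy(float))
        names.append(f"int[{level}]")
    if spec.include_density:
        for level in sorted(slope_group.unique()):
            cols.append(x * (slope_group == level).to_numpy(float))
            names.append(f"slope[{level}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # report columns whose removal restores full rank
        bad = []
        for j in range(X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == np.linalg.matrix_rank(X):
                bad.append(names[j])
        raise SingularDesignError(bad or names)
    if spec.include_density:
        xs = pd.Series(x, index=df.index)
        for level in slope_group.unique():
            if xs[(slope_group == level).to_numpy()].nunique() < 2:
                raise ValueError(
                    f"need >= 2 distinct densities to estimate slope[{level}]"
                )
    return df, y, X, names, n_dropped


def _fit_once(y, X, names, groups, reml: bool):
    """One (optionally mixed) linear fit; returns a common summary tuple."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if groups is not None:
            model = MixedLM(y, X, groups=groups)
            try:
                res = model.fit(reml=reml)
            except np.linalg.LinAlgError:
                res = model.fit(reml=reml, method="powell")
            params = pd.Series(res.fe_params, index=names)
            bse = pd.Series(np.asarray(res.bse_fe), index=names)
            cov = pd.DataFrame(
                np.asarray(res.cov_params())[: len(names), : len(names)],
                index=names, columns=names,
            )
            re_var = float(np.asarray(res.cov_re).ravel()[0])
            resid_var = float(res.scale)
            llf = float(res.llf)
            converged = bool(res.converged)
        else:
            res = OLS(y, X).fit()
            params = pd.Series(res.params, index=names)
            bse = pd.Series(res.bse, index=names)
            cov = pd.DataFrame(res.cov_params(), index=names, columns=names)
            re_var = 0.0
            resid_var = float(res.mse_resid) if res.df_resid > 0 else 0.0
            llf = float(res.llf)  # ML; equals REML objective shape w/o random terms
            converged = True
    return params, bse, cov, re_var, resid_var, llf, converged


def fit_damp(table: pd.DataFrame, spec: DampModelSpec | None = None) -> DampFit:
    """Fit the DAMP mixed model to a tidy table of rate estimates.

    The table needs linear-scale columns for the response and density plus the
    categorical columns named in the spec.  Returns REML estimates with an ML
    log-likelihood for use in likelihood-ratio tests.
    """
    spec = spec or DampModelSpec()
    df, y, X, names, n_dropped = _design(table, spec)
    groups = None
    if spec.use_blocks and spec.block_col in df.columns:
        g = df[spec.block_col].astype(str)
        if g.nunique() >= 2:
            groups = g.to_numpy()

    delta = None
    if spec.variance_power is not None:
        evap = df[spec.evap_col].astype(float).abs().to_numpy()
        evap = np.maximum(evap, 1e-6)
        if spec.variance_power == "estimate":
            grid = np.arange(-2.0, 2.0001, 0.25)
            best = None
            for d in grid:
                wts = evap ** (-d)
                out = _fit_once(y * wts, X * wts[:, None], names, groups, reml=True)
                penalty = 2.0 * d * float(np.log(evap).sum())  # |evap|^delta Jacobian
                score = out[5] - 0.5 * penalty
                if best is None or score > best[0]:
                    best = (score, d)
            delta = float(best[1])
        else:
            delta = float(spec.variance_power)
        wts = evap ** (-delta)
        y, X = y * wts, X * wts[:, None]

    params, bse, cov, re_var, resid_var, ll_reml, conv = _fit_once(
        y, X, names, groups, reml=True
    )
    if groups is not None:
        _, _, _, _, _, ll_ml, _ = _fit_once(y, X, names, groups, reml=False)
    else:
        ll_ml = ll_reml

    slope_names = [n for n in names if n.startswith("slope[")]
    # t quantile with residual df (not 1.96): matches the interval behaviour
    # of standard mixed-model software and keeps small-study coverage honest
    tcrit = float(stats.t.ppf(0.975, max(len(y) - len(names), 1)))
    rows = []
    for n in slope_names:
        est, se = float(params[n]), float(bse[n])
        rows.append((n[6:-1], est, se, est - tcrit * se, est + tcrit * se))
    slopes = pd.DataFrame(
        rows, columns=["group", "estimate", "se", "ci_low", "ci_high"]
    ).set_index("group")
    n_obs, n_fixed = len(y), len(names)
    return DampFit(
        params=params, bse=bse, cov_params=cov, slopes=slopes,
        re_var=re_var, resid_var=resid_var,
        loglik_reml=ll_reml, loglik_ml=ll_ml,
        n_obs=n_obs, n_fixed=n_fixed, df_resid=n_obs - n_fixed,
        converged=conv, spec=spec, n_dropped=n_dropped, variance_delta=delta,
    )


def wald_slope_test(fit: DampFit, group: str | None = None) -> TestResult:
    """Wald t-test that a slope (or the average slope) is zero.

    ``group=None`` tests the equally weighted average of all slope terms.
    Degrees of freedom are residual: n_obs minus the number of fixed-effect
    parameters.
    """
    slope_names = [n for n in fit.params.index if n.startswith("slope[")]
    if group is not None:
        name = f"slope[{group}]"
        if name not in fit.params.index:
            raise ValueError(f"no slope term for group {group!r}")
        c = pd.Series(0.0, index=fit.params.index)
        c[name] = 1.0
        desc = f"Wald test that slope[{group}] = 0"
    else:
        c = pd.Series(0.0, index=fit.params.index)
        for n in slope_names:
            c[n] = 1.0 / len(slope_names)
        desc = "Wald test that average slope = 0"
    est = float(c @ fit.params)
    se = math.sqrt(float(c @ fit.cov_params @ c))
    if se == 0.0:
        raise ValueError("contrast not estimable (zero variance)")
    t = est / se
    df = fit.df_resid
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(statistic=t, df=df, p_value=p, description=desc)


def lr_test(fit_full, fit_reduced, description: str = "") -> TestResult:
    """Likelihood-ratio test between nested fits (both by maximum likelihood).

    Accepts any pair of fit objects exposing ``loglik_ml``, ``n_params`` and
    ``n_obs``.  df = difference in parameter count.
    """
    if fit_full.n_obs != fit_reduced.n_obs:
        raise ValueError("fits use different numbers of rows; not nested")
    df = fit_full.n_params - fit_reduced.n_params
    if df < 0:
        raise ValueError("full model has fewer parameters than reduced; not nested")
    lr = max(2.0 * (fit_full.loglik_ml - fit_reduced.loglik_ml), 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(lr, df))
    return TestResult(statistic=lr, df=df, p_value=p,
                      description=description or "likelihood ratio test")


def fitness_sensitivity(
    experiments: Iterable[FluctuationExperiment],
    w_grid: Sequence[float],
    spec: DampModelSpec | None = None,
    method: str = "CFU",
    group: str | None = None,
) -> pd.DataFrame:
    """DAMP slope as a function of the assumed mutant relative fitness w.

    For each w, every experiment's m is re-estimated at that fixed fitness,
    rates are rebuilt, and the model refit; the (average or per-group) slope
    and its SE are reported per w.  Estimation failures at extreme w are
    recorded in ``n_failed`` for that grid point rather than aborting the scan.
    """
    experiments = list(experiments)
    spec = spec or DampModelSpec()
    rows = []
    for w in w_grid:
        rates, n_failed = [], 0
        for exp in experiments:
            try:
                rates.append(estimate_rate(exp, method=method, w=w, ci=False))
            except Exception:
                n_failed += 1
        table = pd.DataFrame([r.__dict__ for r in rates])
        fit = fit_damp(table, spec)
        if group is None:
            c = pd.Series(0.0, index=fit.params.index)
            slope_names = [n for n in fit.params.index if n.startswith("slope[")]
            for n in slope_names:
                c[n] = 1.0 / len(slope_names)
            est = float(c @ fit.params)
            se = math.sqrt(float(c @ fit.cov_params @ c))
        else:
            est = float(fit.slopes.loc[group, "estimate"])
            se = float(fit.slopes.loc[group, "se"])
        rows.append((float(w), est, se, n_failed))
    return pd.DataFrame(rows, columns=["w", "slope", "se", "n_failed"])


def doubling_density_reduction(slope: float) -> float:
    """Percent reduction in density at which the mutation rate doubles.

    For log2-log2 slope b < 0, the rate doubles when density is multiplied by
    2^(1/b); the reduction is 100 * (1 - 2^(1/b)) percent.
    """
    if slope >= 0:
        raise ValueError("slope must be negative: rate must fall with density")
    return 100.0 * (1.0 - 2.0 ** (1.0 / slope))
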