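"""Meta-analysis of published fluctuation-test mutation rates.

Published estimates of microbial mutation rate decline steeply with the final
population density D of the cultures they were measured in.  Because the
estimates come from many organisms, studies, media and phenotypic markers —
and the organisms are phylogenetically related — the relationship is modelled
as a linear mixed model on the log2 scale:

    log2(rate) = alpha + beta * log2(D)
                 + a_org + b_org * log2(D)          (organism, correlated
                                                     across organisms by the
                                                     Brownian-motion matrix C)
                 + a_study + a_medium + a_marker    (i.i.d. random intercepts)
                 + eps

The per-organism (intercept, slope) pairs are bivariate with an estimated
2x2 covariance, Kronecker-multiplied by C, so related organisms get similar
plasticity.  Variance parameters are estimated by REML with a direct
marginal-likelihood implementation (the model does not fit the mould of
standard grouped-random-effect software because of the fixed cross-organism
correlation); fixed effects by GLS at the REML variances; per-organism slopes
are reported as BLUPs, which shrink toward the fixed slope as the
organism-level variance vanishes.

Curation of the literature table follows three exclusion rules: estimates
made (i) under intentionally selective conditions, (ii) in genetically
manipulated or mutator strains, or (iii) without plating the whole culture
volume are removed, as are rows with no usable density.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "REQUIRED_LITERATURE_COLUMNS",
    "MetaFit",
    "validate_literature",
    "spearman_assoc",
    "fit_meta",
    "variance_explained",
]

REQUIRED_LITERATURE_COLUMNS = (
    "mutation_rate",
    "D",
    "organism",
    "marker",
    "medium",
    "study",
)
# curation-rule flag columns: truthy value -> row excluded under that rule
RULE_COLUMNS = {
    "selective_conditions": "i",
    "manipulated_or_mutator": "ii",
    "partial_plating": "iii",
}


def validate_literature(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the curation rules; return (curated table, rejection log).

    The rejection log has one row per removed estimate with the rule id
    ("i", "ii", "iii", or "missing") and the original row index.
    """
    missing = [c for c in REQUIRED_LITERATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"literature table missing required columns: {missing}")
    reasons = []
    drop = pd.Series(False, index=table.index)
    for col, rule in RULE_COLUMNS.items():
        if col not in table.columns:
            continue
        flag = table[col].fillna(False).astype(bool)
        for idx in table.index[flag & ~drop]:
            reasons.append((idx, rule, col))
        drop |= flag
    bad = ~(
        pd.to_numeric(table["mutation_rate"], errors="coerce").gt(0)
        & pd.to_numeric(table["D"], errors="coerce").gt(0)
    )
    for idx in table.index[bad & ~drop]:
        reasons.append((idx, "missing", "mutation_rate/D not positive finite"))
    drop |= bad
    log = pd.DataFrame(reasons, columns=["row", "rule", "detail"])
    return table[~drop].copy(), log


def spearman_assoc(table: pd.DataFrame) -> float:
    """Spearman rank correlation between mutation rate and density."""
    if len(table) < 3:
        raise ValueError("need at least 3 rows")
    rate = pd.to_numeric(table["mutation_rate"])
    d = pd.to_numeric(table["D"])
    if rate.nunique() < 2 or d.nunique() < 2:
        raise ValueError("constant column: Spearman correlation undefined")
    rho, _ = stats.spearmanr(rate, d)
    return float(rho)


@dataclass(frozen=True)
class MetaFit:
    """Fitted meta-analytic mixed model."""

    slope: float
    slope_se: float
    slope_ci: tuple[float, float]
    intercept: float
    blup_slopes: pd.Series  # per organism
    blup_intercepts: pd.Series
    variances: dict
    resid_var: float
    loglik_reml: float
    loglik_ml: float
    n_obs: int
    n_params: int  # fixed-effect parameters (for LR tests)
    converged: bool
    used_phylo: bool

    @property
    def loglik(self) -> float:
        return self.loglik_ml


def _build_random_designs(df, x, corr, random_slope, extra_terms):
    organisms = sorted(df["organism"].unique())
    q = len(organisms)
    org_idx = df["organism"].map({o: i for i, o in enumerate(organisms)}).to_numpy()
    n = len(df)
    Zi = np.zeros((n, q))
    Zi[np.arange(n), org_idx] = 1.0
    Zs = Zi * x[:, None] if random_slope else None
    if corr is None:
        C = np.eye(q)
        used_phylo = False
    else:
        missing = [o for o in organisms if o not in corr.index]
        if missing:
            raise ValueError(f"correlation matrix missing organisms: {missing}")
        C = corr.loc[organisms, organisms].to_numpy()
        used_phylo = True
    extras = []
    for col in extra_terms:
        levels = sorted(df[col].astype(str).unique())
        Z = np.zeros((n, len(levels)))
        Z[np.arange(n), df[col].astype(str).map(
            {l: i for i, l in enumerate(levels)}).to_numpy()] = 1.0
        extras.append((col, Z))
    return organisms, C, Zi, Zs, extras, used_phylo


def _marginal_cov(theta, C, Zi, Zs, extras, n):
    """V(theta) and the organism-level covariance block G (2q x 2q or q x q)."""
    k = 0
    s_int = math.exp(theta[k]); k += 1
    if Zs is not None:
        s_slope = math.exp(theta[k]); k += 1
        r = math.tanh(theta[k]); k += 1
    sig_extra = []
    for _ in extras:
        sig_extra.append(math.exp(theta[k])); k += 1
    s_e = math.exp(theta[k])
    if Zs is not None:
        G2 = np.array([
            [s_int**2, r * s_int * s_slope],
            [r * s_int * s_slope, s_slope**2],
        ])
        G = np.kron(G2, C)
        Z = np.hstack([Zi, Zs])
    else:
        G = s_int**2 * C
        Z = Zi
    V = Z @ G @ Z.T
    for (_, Zx), s in zip(extras, sig_extra):
        V += s**2 * (Zx @ Zx.T)
    V[np.diag_indices(n)] += s_e**2
    return V, G, Z, s_e**2, sig_extra, (s_int, (None if Zs is None else s_slope))


def _gls(X, y, V):
    cf = linalg.cho_factor(V, lower=True)
    Vi_X = linalg.cho_solve(cf, X)
    Vi_y = linalg.cho_solve(cf, y)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    resid = y - X @ beta
    Vi_r = linalg.cho_solve(cf, resid)
    logdetV = 2.0 * float(np.log(np.diag(cf[0])).sum())
    return beta, XtViX, resid, Vi_r, logdetV


def _loglik(theta, X, y, C, Zi, Zs, extras, reml):
    n = len(y)
    try:
        V, *_ = _marginal_cov(theta, C, Zi, Zs, extras, n)
        beta, XtViX, resid, Vi_r, logdetV = _gls(X, y, V)
    except np.linalg.LinAlgError:
        return -1e12
    quad = float(resid @ Vi_r)
    ll = -0.5 * (logdetV + quad + n * math.log(2 * math.pi))
    if reml:
        sign, logdetX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return -1e12
        ll -= 0.5 * (logdetX - X.shape[1] * math.log(2 * math.pi))
    return ll if np.isfinite(ll) else -1e12


def fit_meta(
    table: pd.DataFrame,
    corr: pd.DataFrame | None = None,
    include_density: bool = True,
    random_slope: bool | None = None,
    extra_terms: Sequence[str] = ("study", "medium", "marker"),
) -> MetaFit:
    """Fit the meta-analytic mixed model of log2 rate on log2 density.

    ``corr`` is the organism correlation matrix (identity when None).
    ``include_density=False`` drops density entirely (fixed and random slope)
    — the reduced model used for the variance-explained comparison.
    ``extra_terms`` name categorical columns receiving i.i.d. random
    intercepts; terms with fewer than 2 levels are dropped with a warning.
    """
    df = table.copy()
    rate = pd.to_numeric(df["mutation_rate"], errors="coerce")
    dens = pd.to_numeric(df["D"], errors="coerce")
    ok = rate.gt(0) & dens.gt(0)
    df = df[ok]
    y = np.log2(rate[ok].to_numpy())
    x = np.log2(dens[ok].to_numpy())
    x_c = x - x.mean()  # centred covariate stabilizes the intercept/slope corr
    if random_slope is None:
        random_slope = include_density

    kept_terms = []
    for col in extra_terms:
        if col in df.columns and df[col].astype(str).nunique() >= 2:
            kept_terms.append(col)
        else:
            warnings.warn(f"random term {col!r} dropped (absent or single level)")
    organisms, C, Zi, Zs, extras, used_phylo = _build_random_designs(
        df, x_c, corr, random_slope, kept_terms
    )
    X = np.column_stack([np.ones(len(df)), x_c]) if include_density else np.ones((len(df), 1))

    n_theta = 1 + (2 if random_slope else 0) + len(extras) + 1
    sd0 = math.log(max(np.std(y) / 2.0, 1e-3))
    x0 = np.full(n_theta, sd0)
    if random_slope:
        x0[1] = math.log(0.2)
        x0[2] = 0.0

    def neg_reml(theta):
        return -_loglik(theta, X, y, C, Zi, Zs, extras, reml=True)

    best = None
    for start in (x0, x0 - 1.0):
        res = optimize.minimize(
            neg_reml, start, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000, "maxfev": 6000},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    ll_reml = -best.fun
    ll_ml = _loglik(theta, X, y, C, Zi, Zs, extras, reml=False)

    n = len(y)
    V, G, Z, resid_var, sig_extra, (s_int, s_slope) = _marginal_cov(
        theta, C, Zi, Zs, extras, n
    )
    beta, XtViX, resid, Vi_r, _ = _gls(X, y, V)
    cov_beta = np.linalg.inv(XtViX)
    if include_density:
        slope, se = float(beta[1]), float(math.sqrt(cov_beta[1, 1]))
    else:
        slope, se = 0.0, float("nan")
    # BLUPs: u_hat = G Z' V^-1 (y - X beta)
    u = G @ Z.T @ Vi_r
    q = len(organisms)
    if random_slope:
        blup_int = pd.Series(u[:q], index=organisms)
        blup_slope = pd.Series(slope + u[q:], index=organisms)
    else:
        blup_int = pd.Series(u[:q], index=organisms)
        blup_slope = pd.Series(slope, index=organisms, dtype=float)
    variances = {"organism_intercept_sd": s_int, "residual_sd": math.sqrt(resid_var)}
    if s_slope is not None:
        variances["organism_slope_sd"] = s_slope
    for (colname, _), s in zip(extras, sig_extra):
        variances[f"{colname}_sd"] = s
    return MetaFit(
        slope=slope,
        slope_se=se,
        slope_ci=(slope - 1.96 * se, slope + 1.96 * se),
        intercept=float(beta[0]),
        blup_slopes=blup_slope,
        blup_intercepts=blup_int,
        variances=variances,
        resid_var=float(resid_var),
        loglik_reml=float(ll_reml),
        loglik_ml=float(ll_ml),
        n_obs=n,
        n_params=X.shape[1],
        converged=bool(best.success),
        used_phylo=used_phylo,
    )


def variance_explained(fit_full: MetaFit, fit_reduced: MetaFit) -> float:
    """Proportional reduction in residual variance between nested fits.

    1 - resid_var(full) / resid_var(reduced); near 0 for identical fits and
    near 1 when the dropped covariate determines the response.
    """
    if fit_full.n_obs != fit_reduced.n_obs:
        raise ValueError("fits use different rows; not comparable")
    return 1.0 - fit_full.resid_var / fit_reduced.resid_var
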