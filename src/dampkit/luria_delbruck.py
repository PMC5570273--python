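"""Exact Luria-Delbruck mutant-count distribution and maximum-likelihood estimation.

The number of resistant mutants observed on a selective plate after growing a
culture from a small inoculum is not Poisson: a mutation arising early founds a
large resistant clone ("jackpot"), so the count distribution is heavy-tailed.
Under the classical model the number of mutational events per culture is
Poisson(m) and each event founds a clone whose final size j follows the
clone-size law f_j.  With mutants growing at relative fitness w (w = 1 means a
selectively neutral marker) the clone-size law is

    f_j = rho * B(j, rho + 1),   rho = 1 / w,

where B is the beta function; at w = 1 this reduces to the classical
f_j = 1 / (j (j + 1)).  The mutant-count probabilities then satisfy the
compound-Poisson recursion

    p_0 = exp(-m),    p_n = (m / n) * sum_{j=1..n} j f_j p_{n-j},

which is the Ma-Sandri-Sarkar (MSS) formulation used for maximum-likelihood
estimation of m from parallel-culture counts.  Counts above the truncation
bound ``r_max`` are treated as right-censored (their likelihood contribution is
the right-tail mass), which keeps jackpot plates informative without unbounded
recursion.

Confidence intervals are profile-likelihood intervals at a log-likelihood drop
of 1.92 (chi-square, 1 df, 95%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special

__all__ = [
    "LDParams",
    "MutantCounts",
    "MLEResult",
    "ld_pmf",
    "ld_log_pmf",
    "ld_sample",
    "estimate_m",
    "estimate_m_w",
    "p0_method",
]

DEFAULT_R_MAX = 10_000
_LOG_M_LO, _LOG_M_HI = -23.0, 12.0  # search bounds for log m
_PROFILE_DROP = 1.92  # chi2(1) / 2 at 95%
_W_LO, _W_HI = 0.05, 10.0


@dataclass(frozen=True)
class LDParams:
    """Parameters of the mutant-count distribution.

    m      expected mutational events per culture (>= 0)
    w      mutant relative fitness (> 0; 1 = neutral marker)
    r_max  truncation bound of the pmf support (>= 1)
    """

    m: float
    w: float = 1.0
    r_max: int = DEFAULT_R_MAX

    def __post_init__(self) -> None:
        if not (math.isfinite(self.m) and self.m >= 0):
            raise ValueError(f"m must be finite and >= 0, got {self.m}")
        if not (math.isfinite(self.w) and self.w > 0):
            raise ValueError(f"w must be finite and > 0, got {self.w}")
        if int(self.r_max) < 1:
            raise ValueError(f"r_max must be >= 1, got {self.r_max}")


@dataclass(frozen=True)
class MutantCounts:
    """Mutant counts from the parallel cultures of one fluctuation test."""

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) < 1:
            raise ValueError("need at least one culture")
        if any((c < 0 or c != int(c)) for c in self.counts):
            raise ValueError("counts must be non-negative integers")
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))

    @property
    def n_cultures(self) -> int:
        return len(self.counts)

    def __iter__(self):
        return iter(self.counts)


@dataclass(frozen=True)
class MLEResult:
    """Maximum-likelihood estimate of m (optionally jointly with w)."""

    m_hat: float
    ci_low: float
    ci_high: float
    loglik: float
    converged: bool
    w_hat: float | None = None
    boundary: bool = False


def _clone_size_weights(r_max: int, w: float) -> np.ndarray:
    """j * f_j for j = 1..r_max, with f_j = rho * B(j, rho+1), rho = 1/w."""
    rho = 1.0 / w
    j = np.arange(1, r_max + 1, dtype=float)
    logf = math.log(rho) + special.betaln(j, rho + 1.0)
    return np.exp(np.log(j) + logf)


def ld_log_pmf(params: LDParams) -> np.ndarray:
    """Natural-log probabilities log p_0 .. log p_{r_max}.

    The recursion is run on rescaled values (offset tracked in log space) so
    that large m never silently underflows to NaN.
    """
    m, r_max = params.m, int(params.r_max)
    if m == 0.0:
        out = np.full(r_max + 1, -np.inf)
        out[0] = 0.0
        return out
    q = _clone_size_weights(r_max, params.w)
    # work with p~_n = p_n * exp(shift); starting at shift = m makes p~_0 = 1
    # and periodic renormalization (the recursion is linear) guards overflow
    shift = m
    p = np.zeros(r_max + 1)
    p[0] = 1.0
    for n in range(1, r_max + 1):
        # sum_{j=1..n} q_j * p_{n-j}
        p[n] = (m / n) * float(np.dot(q[:n], p[n - 1 :: -1]))
        if p[n] > 1e280:  # renormalize the whole prefix; recursion is linear
            p[: n + 1] *= 1e-280
            shift -= math.log(1e280)
    with np.errstate(divide="ignore"):
        return np.log(p) - shift


def ld_pmf(params: LDParams) -> np.ndarray:
    """Probabilities p_0 .. p_{r_max} of observing n mutants per culture.

    sum(p) <= 1; the remainder is the right-tail mass beyond r_max.
    """
    return np.exp(ld_log_pmf(params))


def _clone_tail(j: np.ndarray | float, rho: float) -> np.ndarray | float:
    """P(clone size >= j) = rho * B(j, rho) (continuous in j)."""
    return np.exp(math.log(rho) + special.betaln(j, rho))


def _sample_clone_sizes(rng: np.random.Generator, k: int, rho: float) -> np.ndarray:
    """Exact inverse-CDF draws from the clone-size law f_j.

    P(J >= j) = rho * B(j, rho) is inverted with a lookup table for the bulk
    and a per-draw bracketed search in the (rare) deep tail.  Sizes are capped
    at 1e12 — the law has a heavy tail (infinite mean), and the cap is far
    beyond any censoring bound used in estimation.
    """
    if k == 0:
        return np.zeros(0, dtype=np.int64)
    u = rng.random(k)
    j_table = np.arange(1, 65537, dtype=float)
    tail = _clone_tail(j_table, rho)  # decreasing
    # J = max{j : tail(j) > u}; tail is sorted descending
    idx = np.searchsorted(-tail, -u, side="right")  # number of j with tail > u
    sizes = np.maximum(idx, 1).astype(np.int64)
    deep = u < tail[-1]
    for i in np.flatnonzero(deep):
        lo, hi = 65536.0, 131072.0
        while _clone_tail(hi, rho) > u[i] and hi < 1e12:
            lo, hi = hi, hi * 2.0
        # integer bisection for max j with tail(j) > u
        while hi - lo > 1.0:
            mid = math.floor((lo + hi) / 2.0)
            if _clone_tail(float(mid), rho) > u[i]:
                lo = float(mid)
            else:
                hi = float(mid)
        sizes[i] = int(min(lo, 1e12))
    return sizes


def ld_sample(
    params: LDParams, n_cultures: int, seed: int | np.random.Generator
) -> MutantCounts:
    """Draw i.i.d. mutant counts for ``n_cultures`` parallel cultures.

    Each culture receives Poisson(m) mutational events whose clone sizes are
    drawn exactly from f_j; the count is their sum (not truncated at r_max —
    truncation is an estimation-side convention).  Identical seed gives
    identical counts.
    """
    if n_cultures < 1:
        raise ValueError("n_cultures must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_clones = rng.poisson(params.m, size=n_cultures)
    total = int(n_clones.sum())
    sizes = _sample_clone_sizes(rng, total, 1.0 / params.w)
    counts = np.zeros(n_cultures, dtype=np.int64)
    culture = np.repeat(np.arange(n_cultures), n_clones)
    np.add.at(counts, culture, sizes)
    return MutantCounts(tuple(int(c) for c in counts))


class _CensoredLoglik:
    """Censored MSS log-likelihood of a dataset as a function of (m, w)."""

    def __init__(self, counts: MutantCounts, r_max: int):
        arr = np.asarray(counts.counts, dtype=np.int64)
        self.n_censored = int((arr > r_max).sum())
        obs = arr[arr <= r_max]
        self.obs_vals, self.obs_mult = np.unique(obs, return_counts=True)
        self.r_needed = int(self.obs_vals.max()) if len(self.obs_vals) else 0
        if self.n_censored:
            self.r_needed = r_max
        self.r_max = r_max

    def __call__(self, m: float, w: float) -> float:
        if m <= 0.0:
            return 0.0 if (self.n_censored == 0 and self.r_needed == 0) else -np.inf
        logp = ld_log_pmf(LDParams(m=m, w=w, r_max=max(self.r_needed, 1)))
        ll = float(np.dot(self.obs_mult, logp[self.obs_vals]))
        if self.n_censored:
            tail = 1.0 - float(np.exp(logp).sum())
            ll += self.n_censored * (math.log(tail) if tail > 0 else -np.inf)
        return ll if np.isfinite(ll) or ll == -np.inf else -np.inf


def _profile_ci(ll, m_hat: float, ll_max: float, lo: float, hi: float) -> tuple[float, float]:
    """95% profile-likelihood interval: {m : ll(m) >= ll_max - 1.92}."""
    target = ll_max - _PROFILE_DROP

    def f(logm: float) -> float:
        return ll(math.exp(logm)) - target

    log_mhat = math.log(m_hat)
    if f(lo) >= 0:
        ci_lo = math.exp(lo)
    else:
        ci_lo = math.exp(optimize.brentq(f, lo, log_mhat, xtol=1e-10))
    if f(hi) >= 0:
        ci_hi = math.exp(hi)
    else:
        ci_hi = math.exp(optimize.brentq(f, log_mhat, hi, xtol=1e-10))
    return ci_lo, ci_hi


def estimate_m(
    counts: MutantCounts | Sequence[int],
    w: float = 1.0,
    r_max: int = DEFAULT_R_MAX,
    ci: bool = True,
) -> MLEResult:
    """MSS maximum-likelihood estimate of m at fixed mutant fitness w.

    Counts above ``r_max`` contribute the right-tail mass (right-censoring).
    All-zero data give the boundary estimate m_hat = 0 with ci_low = 0 and
    ci_high = 1.92 / n (where the profile crosses the 95% drop).
    """
    if not isinstance(counts, MutantCounts):
        counts = MutantCounts(tuple(counts))
    n = counts.n_cultures
    if max(counts.counts) == 0:
        # likelihood exp(-n m) is decreasing in m
        return MLEResult(0.0, 0.0, _PROFILE_DROP / n, 0.0, True, boundary=True)
    ll = _CensoredLoglik(counts, r_max)
    grid = np.arange(_LOG_M_LO, _LOG_M_HI + 1e-9, 0.5)
    vals = np.array([ll(math.exp(g), w) for g in grid])
    k = int(np.nanargmax(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda g: -ll(math.exp(g), w), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-9},
    )
    m_hat = math.exp(res.x)
    ll_max = -res.fun
    if not ci:
        return MLEResult(m_hat, np.nan, np.nan, ll_max, bool(res.success))
    ci_lo, ci_hi = _profile_ci(lambda m: ll(m, w), m_hat, ll_max, _LOG_M_LO, _LOG_M_HI)
    return MLEResult(m_hat, ci_lo, ci_hi, ll_max, bool(res.success))


def estimate_m_w(
    counts: MutantCounts | Sequence[int], r_max: int = DEFAULT_R_MAX
) -> MLEResult:
    """Jointly estimate (m, w) from one fluctuation test.

    Deterministic multi-start Nelder-Mead over (log m, log w), w constrained
    to [0.05, 10].  With few cultures the likelihood profile in w is often
    flat and joint estimation fails; such fits are returned with
    ``converged=False`` rather than raising.
    """
    if not isinstance(counts, MutantCounts):
        counts = MutantCounts(tuple(counts))
    nonzero = {c for c in counts.counts if c > 0}
    base = estimate_m(counts, w=1.0, r_max=r_max, ci=False)
    if len(nonzero) < 2:
        return MLEResult(base.m_hat, np.nan, np.nan, base.loglik, False,
                         w_hat=1.0, boundary=True)
    ll = _CensoredLoglik(counts, r_max)
    log_w_lo, log_w_hi = math.log(_W_LO), math.log(_W_HI)

    def nll(x: np.ndarray) -> float:
        logm, logw = x
        if not (_LOG_M_LO <= logm <= _LOG_M_HI and log_w_lo <= logw <= log_w_hi):
            return 1e12
        v = ll(math.exp(logm), math.exp(logw))
        return -v if np.isfinite(v) else 1e12

    m0 = max(base.m_hat, 1e-6)
    best = None
    for w0 in (0.5, 1.0, 2.0):
        r = optimize.minimize(
            nll, x0=np.array([math.log(m0), math.log(w0)]), method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 2000},
        )
        if best is None or r.fun < best.fun:
            best = r
    m_hat, w_hat = math.exp(best.x[0]), math.exp(best.x[1])
    ll_max = -best.fun
    # flat-profile check: re-optimizing m at w_hat/2 and 2*w_hat should cost
    # a visible amount of likelihood if w is identified
    drop = min(
        ll_max - _profile_m_at_w(ll, max(w_hat / 2, _W_LO)),
        ll_max - _profile_m_at_w(ll, min(w_hat * 2, _W_HI)),
    )
    identified = drop > 0.10
    at_bound = (w_hat < _W_LO * 1.05) or (w_hat > _W_HI * 0.95)
    ci_lo, ci_hi = _profile_ci(
        lambda m: ll(m, w_hat), m_hat, ll_max, _LOG_M_LO, _LOG_M_HI
    )
    return MLEResult(
        m_hat, ci_lo, ci_hi, ll_max,
        converged=bool(best.success) and identified and not at_bound,
        w_hat=w_hat, boundary=at_bound,
    )


def _profile_m_at_w(ll: _CensoredLoglik, w: float) -> float:
    res = optimize.minimize_scalar(
        lambda g: -ll(math.exp(g), w), bounds=(_LOG_M_LO, _LOG_M_HI),
        method="bounded", options={"xatol": 1e-6},
    )
    return -res.fun


class P0Undefined(ValueError):
    """Raised when no culture has zero mutants, so -ln(P0)/Nt is undefined."""


def p0_method(counts: MutantCounts | Sequence[int], Nt: float) -> float:
    """Mutation rate per cell per generation by the P0 method, -ln(P0)/Nt.

    P0 is the proportion of cultures with zero mutants.  Requires at least one
    zero-count culture; otherwise use the MSS MLE.
    """
    if not isinstance(counts, MutantCounts):
        counts = MutantCounts(tuple(counts))
    if Nt <= 0:
        raise ValueError("Nt must be > 0")
    p0 = sum(1 for c in counts.counts if c == 0) / counts.n_cultures
    if p0 == 0.0:
        raise P0Undefined("no zero-count cultures: P0 method undefined")
    return -math.log(p0) / Nt
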