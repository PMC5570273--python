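"""Independent oracles used by the tests.

These deliberately avoid the package's own optimization / sampling code
paths: the grid MLE is an exhaustive search over log m, and the Monte-Carlo
sampler draws clone sizes by inverse-CDF from an explicitly tabulated
clone-size law.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special

from dampkit.luria_delbruck import LDParams, ld_log_pmf


def censored_loglik(counts, m: float, w: float, r_max: int) -> float:
    """Direct censored log-likelihood (no shared state with the estimator)."""
    arr = np.asarray(counts, dtype=int)
    capped = np.minimum(arr, r_max)
    need = int(capped.max())
    logp = ld_log_pmf(LDParams(m=m, w=w, r_max=max(need, 1)))
    ll = 0.0
    for a, c in zip(arr, capped):
        if a > r_max:
            tail = 1.0 - float(np.exp(logp).sum())
            ll += math.log(tail) if tail > 0 else -np.inf
        else:
            ll += float(logp[c])
    return ll


def grid_mle(counts, w: float = 1.0, r_max: int = 10_000) -> float:
    """Exhaustive grid search of the same likelihood, 1e-3 resolution on log m.

    A coarse pass over the full search range locates the optimum; an
    exhaustive 1e-3-step pass over +/- 0.1 around it gives the final value.
    """
    coarse = np.arange(-23.0, 12.0 + 1e-9, 0.05)
    vals = [censored_loglik(counts, math.exp(g), w, r_max) for g in coarse]
    g0 = coarse[int(np.nanargmax(vals))]
    fine = np.arange(g0 - 0.1, g0 + 0.1 + 1e-9, 1e-3)
    vals = [censored_loglik(counts, math.exp(g), w, r_max) for g in fine]
    return math.exp(fine[int(np.nanargmax(vals))])


def mc_mutant_counts(rng: np.random.Generator, m: float, w: float, n: int,
                     j_max: int = 200_000) -> np.ndarray:
    """Monte-Carlo mutant counts: Poisson clones, tabulated clone-size CDF."""
    rho = 1.0 / w
    j = np.arange(1, j_max + 1, dtype=float)
    f = np.exp(math.log(rho) + special.betaln(j, rho + 1.0))
    cdf = np.cumsum(f / f.sum())  # renormalized truncation
    n_clones = rng.poisson(m, n)
    sizes = np.searchsorted(cdf, rng.random(int(n_clones.sum()))) + 1
    counts = np.zeros(n, dtype=np.int64)
    np.add.at(counts, np.repeat(np.arange(n), n_clones), sizes)
    return counts
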