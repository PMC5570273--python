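"""From one fluctuation experiment to a mutation-rate estimate.

A fluctuation experiment consists of parallel cultures grown from a small
inoculum N0 to saturation, plated whole onto selective medium (mutant counts
r), together with replicate measurements of the final population size Nt by
one or more methods (colony-forming units CFU, ATP-based luminescence ATP, or
haemocytometer cell counts CC).  The mutation rate per cell per generation is
mu = m / Nt, where m is the MSS maximum-likelihood number of mutational events
per culture; the final population density is D = Nt per post-evaporation ml.

Estimates with m outside [0.3, 30] are conventionally unreliable (too few
events, or jackpot counts too large to resolve); they are flagged as excluded
but never dropped here — downstream fits choose whether to use them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from dampkit.luria_delbruck import (
    DEFAULT_R_MAX,
    MLEResult,
    MutantCounts,
    estimate_m,
)

__all__ = [
    "NT_METHODS",
    "FluctuationExperiment",
    "RateEstimate",
    "summarize_nt",
    "estimate_rate",
    "effective_population_size",
    "events_per_space_time",
]

NT_METHODS = ("CFU", "ATP", "CC")
M_EXCLUDE_LOW, M_EXCLUDE_HIGH = 0.3, 30.0


@dataclass(frozen=True)
class FluctuationExperiment:
    """One fluctuation test: counts plus culture metadata.

    ``nt_replicates`` maps a method label to replicate measurements.  CFU
    replicates are densities (cells/ml) from plated dilutions and are scaled
    by the post-evaporation culture volume when summarized; ATP and CC
    replicates are already whole-culture population sizes (cells).
    """

    counts: MutantCounts
    N0: float
    nt_replicates: Mapping[str, tuple[float, ...]]
    volume_ml: float
    time_h: float
    evaporation: float = 0.0
    strain: str = ""
    marker: str = ""
    medium: str = ""
    block: str = ""
    experiment_id: str = ""

    def __post_init__(self) -> None:
        if self.N0 <= 0:
            raise ValueError("N0 must be > 0")
        if self.volume_ml <= 0 or self.time_h <= 0:
            raise ValueError("volume and time must be > 0")
        if not (0.0 <= self.evaporation < 1.0):
            raise ValueError("evaporation must be in [0, 1)")
        reps = {}
        for method, values in self.nt_replicates.items():
            if method not in NT_METHODS:
                raise ValueError(f"unknown Nt method {method!r}; expected {NT_METHODS}")
            values = tuple(float(v) for v in values)
            if len(values) == 0 or any(v <= 0 for v in values):
                raise ValueError(f"Nt replicates for {method} must be positive")
            reps[method] = values
        object.__setattr__(self, "nt_replicates", reps)

    @property
    def effective_volume_ml(self) -> float:
        return self.volume_ml * (1.0 - self.evaporation)


@dataclass(frozen=True)
class RateEstimate:
    """Mutation-rate estimate with density, Ne and exclusion flag."""

    m_hat: float
    m_ci_low: float
    m_ci_high: float
    Nt: float
    D: float
    mu: float
    mu_ci_low: float
    mu_ci_high: float
    Ne: float
    events_rate: float
    excluded: bool
    method: str
    nt_cv: float
    converged: bool
    strain: str = ""
    marker: str = ""
    medium: str = ""
    block: str = ""
    experiment_id: str = ""
    evaporation: float = 0.0


def summarize_nt(
    nt_replicates: Mapping[str, Sequence[float]],
    method: str,
    evaporation: float = 0.0,
    volume_ml: float = 1.0,
) -> tuple[float, float]:
    """Mean final population size per culture and its CV for one method.

    CFU replicates (cells/ml) are scaled by the post-evaporation volume before
    averaging; ATP/CC replicates are used as-is.  CV = population sd / mean,
    0 for a single replicate.
    """
    if method not in NT_METHODS:
        raise ValueError(f"unknown Nt method {method!r}; expected {NT_METHODS}")
    if method not in nt_replicates or len(nt_replicates[method]) == 0:
        raise ValueError(f"no Nt replicates for method {method!r}")
    values = np.asarray(nt_replicates[method], dtype=float)
    if method == "CFU":
        values = values * volume_ml * (1.0 - evaporation)
    nt = float(values.mean())
    cv = float(values.std(ddof=0) / nt) if len(values) > 1 else 0.0
    return nt, cv


def effective_population_size(N0: float, Nt: float) -> float:
    """Harmonic-mean effective population size across culture generations.

    The culture doubles from N0 through N0*2^i up to Nt over g = log2(Nt/N0)
    generations; Ne is the harmonic mean of the ceil(g) post-division sizes
    {N0*2^1, ..., N0*2^ceil(g)} with the final term replaced by Nt when g is
    fractional.  Ne lies in [N0, Nt] and is monotone in Nt.
    """
    if N0 <= 0:
        raise ValueError("N0 must be > 0")
    if Nt < N0:
        raise ValueError("Nt must be >= N0")
    if Nt == N0:
        return float(N0)
    g = math.log2(Nt / N0)
    k = math.ceil(g)
    pops = [N0 * 2.0**i for i in range(1, k + 1)]
    pops[-1] = Nt
    return k / sum(1.0 / p for p in pops)


def events_per_space_time(m_hat: float, volume_ml: float, time_h: float) -> float:
    """Mutational events per ml per hour: m / (volume * time)."""
    if volume_ml <= 0 or time_h <= 0:
        raise ValueError("volume and time must be > 0")
    return m_hat / (volume_ml * time_h)


def estimate_rate(
    exp: FluctuationExperiment,
    method: str = "CFU",
    w: float = 1.0,
    r_max: int = DEFAULT_R_MAX,
    ci: bool = True,
) -> RateEstimate:
    """Full per-experiment pipeline: MSS MLE, mu = m/Nt, D, Ne, flags.

    ``method`` selects which Nt measurement divides m (CFU by default, the
    literature convention).  The mu interval is the m profile interval divided
    by Nt.  ``excluded`` is set when m_hat is outside [0.3, 30].
    """
    mle: MLEResult = estimate_m(exp.counts, w=w, r_max=r_max, ci=ci)
    nt, cv = summarize_nt(exp.nt_replicates, method, exp.evaporation, exp.volume_ml)
    d = nt / exp.effective_volume_ml
    mu = mle.m_hat / nt
    ne = effective_population_size(min(exp.N0, nt), nt)
    return RateEstimate(
        m_hat=mle.m_hat,
        m_ci_low=mle.ci_low,
        m_ci_high=mle.ci_high,
        Nt=nt,
        D=d,
        mu=mu,
        mu_ci_low=mle.ci_low / nt,
        mu_ci_high=mle.ci_high / nt,
        Ne=ne,
        events_rate=events_per_space_time(mle.m_hat, exp.volume_ml, exp.time_h),
        excluded=(mle.m_hat < M_EXCLUDE_LOW or mle.m_hat > M_EXCLUDE_HIGH),
        method=method,
        nt_cv=cv,
        converged=mle.converged,
        strain=exp.strain,
        marker=exp.marker,
        medium=exp.medium,
        block=exp.block,
        experiment_id=exp.experiment_id,
        evaporation=exp.evaporation,
    )
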