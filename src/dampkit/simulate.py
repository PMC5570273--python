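"""Synthetic fluctuation experiments, plasticity studies and literature corpora.

The generator mirrors the batch-culture fluctuation-test protocol: parallel
cultures inoculated at N0 ~ 1e4 cells grow to saturation in a defined medium
whose glucose concentration (25-1000 mg/l here) sets the final density D
through a linear-with-saturation yield curve; culture volume (0.5-10 ml)
then sets the final population size Nt = D * volume.  The true mutation rate
follows a power law in density,

    mu(D) = mu0 * (D / reference_D)^beta,

with beta the log2-log2 plasticity slope, plus an additive block effect on
log2(mu) for experiments carried out in the same batch.  Mutant counts are
drawn from the exact Luria-Delbruck distribution at m = mu(D) * Nt with
mutant relative fitness w; the final-size measurements are corrupted with
lognormal noise at the per-method coefficients of variation typical of
colony-forming-unit and ATP-luminescence assays (CV 15.9% and 10.9%).

Every generator returns the visible table (what an experimenter would record)
separately from a hidden truth record, so recovery of known parameters can be
tested at every pipeline stage.  All randomness flows from a single seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from dampkit.fluctuation import FluctuationExperiment
from dampkit.luria_delbruck import LDParams, ld_sample
from dampkit.phylo import phylo_correlation

__all__ = [
    "DampLaw",
    "StudyDesign",
    "make_experiment",
    "make_damp_study",
    "make_literature_corpus",
]


@dataclass(frozen=True)
class DampLaw:
    """Power-law dependence of mutation rate on final density.

    mu0 is the rate (per cell per generation) at ``reference_D`` (cells/ml);
    beta is the log2-log2 slope (dimensionless, negative for plasticity that
    lowers the rate in dense cultures).
    """

    mu0: float = 5e-9
    beta: float = -0.68
    reference_D: float = 1e8

    def __post_init__(self) -> None:
        if self.mu0 <= 0 or self.reference_D <= 0:
            raise ValueError("mu0 and reference_D must be > 0")

    def mu(self, D: float) -> float:
        return self.mu0 * (D / self.reference_D) ** self.beta


@dataclass(frozen=True)
class StudyDesign:
    """Experimental design of a synthetic plasticity study.

    Defaults match the experiments the generator emulates: 16 parallel
    cultures per test, N0 around 1e4 cells, Nt measurement CVs of 15.9% (CFU)
    and 10.9% (ATP; cell counts treated alike), block sd 0.25 on log2(mu),
    evaporation a few percent of volume.  The glucose-to-density map is
    linear with saturation (yield cells/ml per mg/l up to ``glucose_sat``),
    spanning roughly two orders of magnitude of density across the default
    glucose range.
    """

    volumes_ml: tuple[float, ...] = (0.5, 1.0, 2.0, 10.0)
    glucose_mg_l: tuple[float, ...] = (25.0, 50.0, 100.0, 250.0, 500.0, 1000.0)
    yield_per_mg: float = 2e6  # cells/ml per mg/l glucose
    glucose_sat: float = 1000.0
    n_cultures: int = 16
    n_blocks: int = 4
    n0_mean: float = 1e4
    n0_cv: float = 0.3
    nt_cv: Mapping[str, float] = field(
        default_factory=lambda: {"CFU": 0.159, "ATP": 0.109, "CC": 0.109}
    )
    nt_replicates: int = 3
    block_sd: float = 0.25
    biological_cv: float = 0.08  # culture-to-culture variation of true density
    evaporation_mean: float = 0.05
    evaporation_sd: float = 0.02
    time_h: float = 24.0
    w: float = 1.0
    seed: int = 0

    def density(self, glucose: float) -> float:
        return self.yield_per_mg * min(glucose, self.glucose_sat)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-1 multiplicative lognormal noise with coefficient of variation cv."""
    if cv <= 0:
        return np.ones(size) if size else 1.0
    sigma = math.sqrt(math.log1p(cv**2))
    return rng.lognormal(-0.5 * sigma**2, sigma, size)


def make_experiment(
    law: DampLaw,
    design: StudyDesign,
    glucose: float,
    volume_ml: float,
    block: str = "b1",
    block_effect: float = 0.0,
    strain: str = "strainA",
    marker: str = "markerA",
    rng: np.random.Generator | None = None,
    experiment_id: str = "",
) -> tuple[FluctuationExperiment, dict]:
    """Generate one fluctuation experiment plus its hidden truth record.

    The truth dict carries the true density, Nt, mu and m; the visible
    experiment carries only what could be measured.
    """
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    evap = float(np.clip(rng.normal(design.evaporation_mean, design.evaporation_sd),
                         0.0, 0.3))
    d_true = design.density(glucose) * float(_lognormal_factor(rng, design.biological_cv))
    v_eff = volume_ml * (1.0 - evap)
    nt_true = d_true * v_eff
    n0 = float(design.n0_mean * _lognormal_factor(rng, design.n0_cv))
    mu_true = law.mu(d_true) * 2.0**block_effect
    m_true = mu_true * nt_true
    counts = ld_sample(LDParams(m=m_true, w=design.w), design.n_cultures, rng)
    reps: dict[str, tuple[float, ...]] = {}
    for method, cv in design.nt_cv.items():
        noise = _lognormal_factor(rng, cv, design.nt_replicates)
        if method == "CFU":
            reps[method] = tuple(d_true * noise)  # cells/ml measurements
        else:
            reps[method] = tuple(nt_true * noise)  # whole-culture sizes
    exp = FluctuationExperiment(
        counts=counts,
        N0=n0,
        nt_replicates=reps,
        volume_ml=volume_ml,
        time_h=design.time_h,
        evaporation=evap,
        strain=strain,
        marker=marker,
        medium=f"glucose{glucose:g}",
        block=block,
        experiment_id=experiment_id or f"{strain}-{marker}-g{glucose:g}-v{volume_ml:g}-{block}",
    )
    truth = {
        "experiment_id": exp.experiment_id,
        "D_true": d_true,
        "Nt_true": nt_true,
        "mu_true": mu_true,
        "m_true": m_true,
        "block_effect": block_effect,
        "beta": law.beta,
    }
    return exp, truth


def make_damp_study(
    law: DampLaw | Mapping[str, DampLaw],
    design: StudyDesign,
    markers: tuple[str, ...] = ("markerA",),
) -> tuple[list[FluctuationExperiment], pd.DataFrame]:
    """Full factorial of glucose x volume x block (x strain x marker).

    ``law`` may be one DampLaw or a mapping from strain name to its law
    (strain-specific plasticity).  Returns the experiment list and the hidden
    truth table.  Requires >= 2 distinct densities in the design.
    """
    laws = law if isinstance(law, Mapping) else {"strainA": law}
    densities = {design.density(g) for g in design.glucose_mg_l}
    if len(densities) < 2:
        raise ValueError("design is degenerate: needs >= 2 distinct densities")
    rng = np.random.default_rng(design.seed)
    experiments, truths = [], []
    for b in range(design.n_blocks):
        block = f"block{b + 1}"
        beff = float(rng.normal(0.0, design.block_sd))
        for strain, slaw in laws.items():
            for marker in markers:
                for glucose in design.glucose_mg_l:
                    for volume in design.volumes_ml:
                        exp, truth = make_experiment(
                            slaw, design, glucose, volume,
                            block=block, block_effect=beff,
                            strain=strain, marker=marker, rng=rng,
                        )
                        experiments.append(exp)
                        truths.append(truth)
    return experiments, pd.DataFrame(truths)


def make_literature_corpus(
    n_organisms: int = 10,
    overall_slope: float = -0.67,
    organism_sd: float = 0.15,
    intercept_sd: float = 4.0,  # log2 units: organisms span several orders

    study_sd: float = 0.5,
    medium_sd: float = 0.3,
    marker_sd: float = 0.3,
    resid_sd: float = 0.5,
    n_per_organism: int = 20,
    mu_ref: float = 1e-8,
    d_range: tuple[float, float] = (1e5, 1e10),
    phylo_signal: float = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, dendropy.Tree, dict]:
    """Synthetic published-rates corpus with a matching pure-birth phylogeny.

    Organism slopes and intercepts are drawn with covariance proportional to
    the tree's Brownian correlation; densities are log-uniform over
    ``d_range`` (>= 4 orders of magnitude by default); study, medium and
    marker contribute i.i.d. intercepts on the log2 scale.  Returns (table,
    tree, truth) with truth holding the drawn per-organism slopes.

    ``phylo_signal`` (Pagel's lambda) sets how much of each tip's depth is
    shared: all edges are scaled by lambda and the removed length is returned
    to the terminal edges, preserving depths.  The default is small because
    the corpus being emulated spans all domains of life, where most organism
    pairs diverge close to the root.
    """
    if n_organisms < 3:
        raise ValueError("need at least 3 organisms")
    if not (0.0 < phylo_signal <= 1.0):
        raise ValueError("phylo_signal must be in (0, 1]")
    rng = np.random.default_rng(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_organisms,
        rng=random.Random(int(rng.integers(2**31 - 1))),
    )
    tree.is_rooted = True
    if phylo_signal < 1.0:
        depths = {lf: lf.distance_from_root() for lf in tree.leaf_node_iter()}
        for node in tree.preorder_node_iter():
            if node.edge.length is not None:
                node.edge.length *= phylo_signal
        for lf, d in depths.items():
            lf.edge.length += (1.0 - phylo_signal) * d
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"org{i + 1}"
    organisms = [f"org{i + 1}" for i in range(n_organisms)]
    C = phylo_correlation(tree).loc[organisms, organisms].to_numpy()
    L = np.linalg.cholesky(C + 1e-10 * np.eye(n_organisms))
    slopes = overall_slope + organism_sd * (L @ rng.standard_normal(n_organisms))
    log2_mu_ref = math.log2(mu_ref)
    intercepts = log2_mu_ref + intercept_sd * (L @ rng.standard_normal(n_organisms))
    n_studies = max(3, n_organisms)
    study_eff = study_sd * rng.standard_normal(n_studies)
    media = ["LB", "DM", "M9", "YPD"]
    medium_eff = medium_sd * rng.standard_normal(len(media))
    markers = ["rif", "nal", "5FOA", "hyg"]
    marker_eff = marker_sd * rng.standard_normal(len(markers))
    log2_d_ref = math.log2(math.sqrt(d_range[0] * d_range[1]))

    rows = []
    for i, org in enumerate(organisms):
        study_ids = rng.integers(0, n_studies, n_per_organism)
        med_ids = rng.integers(0, len(media), n_per_organism)
        mark_ids = rng.integers(0, len(markers), n_per_organism)
        log2_d = rng.uniform(math.log2(d_range[0]), math.log2(d_range[1]),
                             n_per_organism)
        log2_rate = (
            intercepts[i]
            + slopes[i] * (log2_d - log2_d_ref)
            + study_eff[study_ids]
            + medium_eff[med_ids]
            + marker_eff[mark_ids]
            + resid_sd * rng.standard_normal(n_per_organism)
        )
        for k in range(n_per_organism):
            rows.append(
                {
                    "organism": org,
                    "mutation_rate": 2.0 ** log2_rate[k],
                    "D": 2.0 ** log2_d[k],
                    "study": f"study{study_ids[k] + 1}",
                    "medium": media[med_ids[k]],
                    "marker": markers[mark_ids[k]],
                    "selective_conditions": False,
                    "manipulated_or_mutator": False,
                    "partial_plating": False,
                    "recalculated": False,
                }
            )
    truth = {
        "overall_slope": overall_slope,
        "organism_slopes": pd.Series(slopes, index=organisms),
    }
    return pd.DataFrame(rows), tree, truth
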