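"""Tests for literature curation, phylogeny handling and the meta-model."""

import math

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dampkit.meta import (
    fit_meta,
    spearman_assoc,
    validate_literature,
    variance_explained,
)
from dampkit.phylo import graft_subtree, phylo_correlation, read_tree, tip_depths
from dampkit.plasticity import lr_test
from dampkit.simulate import make_literature_corpus


def toy_literature(n=5):
    return pd.DataFrame({
        "mutation_rate": np.geomspace(1e-10, 1e-7, n),
        "D": np.geomspace(1e9, 1e6, n),
        "organism": [f"org{i}" for i in range(n)],
        "marker": "rif",
        "medium": "LB",
        "study": "study1",
        "selective_conditions": False,
        "manipulated_or_mutator": False,
        "partial_plating": False,
    })


class TestValidateLiterature:
    def test_compliant_rows_all_retained(self):
        table = toy_literature()
        curated, log = validate_literature(table)
        assert len(curated) == 5 and len(log) == 0

    def test_rules_remove_and_log(self):
        table = toy_literature()
        table.loc[0, "manipulated_or_mutator"] = True   # rule ii (mutator strain)
        table.loc[1, "selective_conditions"] = True     # rule i
        table.loc[2, "partial_plating"] = True          # rule iii
        table.loc[3, "D"] = np.nan
        curated, log = validate_literature(table)
        assert len(curated) == 1
        assert set(log["rule"]) == {"i", "ii", "iii", "missing"}

    def test_missing_columns_named(self):
        with pytest.raises(ValueError, match="organism"):
            validate_literature(pd.DataFrame({"mutation_rate": [1e-9], "D": [1e8]}))


class TestSpearman:
    def test_monotone_decreasing(self):
        assert spearman_assoc(toy_literature()) == pytest.approx(-1.0)

    def test_constant_column_rejected(self):
        t = toy_literature()
        t["D"] = 1e8
        with pytest.raises(ValueError, match="constant"):
            spearman_assoc(t)

    def test_independent_shuffles_center_on_zero(self):
        """Permutation oracle: mean rho over shuffled pairings is ~0."""
        rng = np.random.default_rng(0)
        n = 474
        rate = np.exp(rng.normal(size=n))
        d = np.exp(rng.normal(size=n))
        rhos = []
        for _ in range(1000):
            rho, _ = stats.spearmanr(rate, rng.permutation(d))
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.01


def newick(s):
    t = dendropy.Tree.get(data=s, schema="newick")
    t.is_rooted = True
    return t


class TestGraft:
    def test_identity_scaling_preserves_lengths(self):
        base = newick("((A:1,B:1):1,C:2);")
        donor = newick("(D:0.5,E:0.5);")
        cal = newick("((A:1,B:1):1,C:2);")  # same units as base
        out = graft_subtree(base, donor, ["A", "B", "C"], attach_at=["A", "B"],
                            mode="ratio", calibration_tree=cal)
        d_depths = tip_depths(out, ["D", "E"])
        # attach node (MRCA of A,B) is at depth 1; donor depths 0.5 unchanged
        assert d_depths == pytest.approx([1.5, 1.5])

    def test_gradient_through_origin(self):
        base = newick("(A:2,B:4);")
        cal = newick("(A:1,B:2);")
        donor = newick("(D:1,E:3);")
        out = graft_subtree(base, donor, ["A", "B"], attach_at="A",
                            mode="gradient", calibration_tree=cal)
        # gradient = (1*2 + 2*4) / (1 + 4) = 2 -> donor lengths doubled
        assert tip_depths(out, ["D"])[0] == pytest.approx(2 + 2 * 1)
        assert tip_depths(out, ["E"])[0] == pytest.approx(2 + 2 * 3)

    def test_tip_count_conserved(self):
        base = newick("((A:1,B:1):1,C:2);")
        donor = newick("((D:1,E:1):1,F:2);")
        cal = newick("((A:2,B:2):2,C:4);")
        out = graft_subtree(base, donor, ["A", "C"], attach_at=["A", "B"],
                            mode="ratio", calibration_tree=cal)
        assert len(out.leaf_nodes()) == 3 + 3

    def test_no_shared_calibration_rejected(self):
        base = newick("(A:1,B:1);")
        donor = newick("(D:1,E:1);")
        with pytest.raises(Exception):
            graft_subtree(base, donor, ["Z"], attach_at="A")


class TestPhyloCorrelation:
    def test_star_tree_identity(self):
        star = newick("(A:1,B:1,C:1,D:1);")
        C = phylo_correlation(star)
        np.testing.assert_allclose(C.to_numpy(), np.eye(4), atol=1e-12)

    def test_sister_pair_shared_fraction(self):
        t = newick("((A:0.4,B:0.4):0.6,C:1);")
        C = phylo_correlation(t)
        assert C.loc["A", "B"] == pytest.approx(0.6)
        assert C.loc["A", "C"] == pytest.approx(0.0)

    def test_matches_pairwise_path_oracle(self):
        """Shared path via (d_i + d_j - dist_ij)/2 from patristic distances."""
        _, tree, _ = make_literature_corpus(n_organisms=20, n_per_organism=3,
                                            seed=5)
        C = phylo_correlation(tree)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        depths = {lab: tip_depths(tree, [lab])[0] for lab in C.index}
        for i, a in enumerate(C.index):
            for b in C.index[i + 1:]:
                shared = (depths[a] + depths[b]
                          - pdm.patristic_distance(taxa[a], taxa[b])) / 2
                expect = shared / math.sqrt(depths[a] * depths[b])
                assert C.loc[a, b] == pytest.approx(expect, abs=1e-10)

    def test_invariant_to_uniform_rescaling(self):
        t1 = newick("((A:0.4,B:0.4):0.6,C:1);")
        t2 = newick("((A:4,B:4):6,C:10);")
        pd.testing.assert_frame_equal(phylo_correlation(t1), phylo_correlation(t2))

    def test_psd(self):
        _, tree, _ = make_literature_corpus(n_organisms=12, n_per_organism=3,
                                            seed=6)
        C = phylo_correlation(tree).to_numpy()
        assert np.allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() > -1e-10


class TestFitMeta:
    def test_recovers_overall_slope(self):
        table, tree, truth = make_literature_corpus(
            n_organisms=12, n_per_organism=15, overall_slope=-0.67, seed=7
        )
        corr = phylo_correlation(tree)
        fit = fit_meta(table, corr=corr)
        assert fit.converged
        assert abs(fit.slope - (-0.67)) < 2 * fit.slope_se

    def test_identity_corr_equals_non_phylo_fit(self):
        table, tree, _ = make_literature_corpus(n_organisms=8, n_per_organism=10,
                                                seed=8)
        organisms = sorted(table["organism"].unique())
        ident = pd.DataFrame(np.eye(len(organisms)), index=organisms,
                             columns=organisms)
        a = fit_meta(table, corr=ident)
        b = fit_meta(table, corr=None)
        assert a.slope == pytest.approx(b.slope, abs=1e-3)
        assert not b.used_phylo and a.used_phylo

    def test_blup_shrinkage_toward_fixed_slope(self):
        table, tree, truth = make_literature_corpus(
            n_organisms=10, n_per_organism=12, organism_sd=0.2, seed=9
        )
        fit = fit_meta(table, corr=phylo_correlation(tree))
        for org, g in table.groupby("organism"):
            ols = np.polyfit(np.log2(g["D"]), np.log2(g["mutation_rate"]), 1)[0]
            lo = min(ols, fit.slope) - 0.05
            hi = max(ols, fit.slope) + 0.05
            assert lo <= fit.blup_slopes[org] <= hi

    def test_variance_explained_bounds(self):
        table, tree, _ = make_literature_corpus(
            n_organisms=8, n_per_organism=10, organism_sd=0.0, resid_sd=0.01,
            seed=10
        )
        corr = phylo_correlation(tree)
        full = fit_meta(table, corr=corr)
        assert variance_explained(full, full) == 0.0
        reduced = fit_meta(table, corr=corr, include_density=False)
        assert variance_explained(full, reduced) > 0.95

    def test_lr_density_term(self):
        table, tree, _ = make_literature_corpus(n_organisms=8, n_per_organism=10,
                                                seed=11)
        corr = phylo_correlation(tree)
        full = fit_meta(table, corr=corr)
        nofix = fit_meta(table, corr=corr, include_density=False,
                         random_slope=True)
        res = lr_test(full, nofix)
        assert res.df == 1
        assert res.p_value < 0.01

    def test_missing_organism_in_corr_rejected(self):
        table, tree, _ = make_literature_corpus(n_organisms=6, n_per_organism=5,
                                                seed=12)
        corr = phylo_correlation(tree).iloc[:4, :4]
        with pytest.raises(ValueError, match="missing organisms"):
            fit_meta(table, corr=corr)
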