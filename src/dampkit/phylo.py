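"""Phylogeny assembly and Brownian-motion correlation matrices.

The meta-analysis of published mutation rates spans organisms from all
domains of life plus viruses, so no single published phylogeny covers them.
Trees covering subsets are combined by grafting: the donor tree's branch
lengths are first rescaled into the base tree's units using tips (or
tip-to-ancestor depths) shared between the two, either by the ratio of mean
calibration depths or by a zero-intercept regression of base depths on donor
depths; the scaled donor is then attached at a chosen node of the base.

Organism-level relatedness enters the meta-analytic model through the
Brownian-motion correlation matrix: the covariance of trait values of two
tips is proportional to their shared root-to-tip path length, rescaled here
to unit diagonal.
"""

from __future__ import annotations

from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "read_tree",
    "write_tree",
    "tip_depths",
    "graft_subtree",
    "phylo_correlation",
]


class NewickParseError(ValueError):
    pass


def read_tree(path) -> dendropy.Tree:
    """Read a rooted newick tree; parse errors are re-raised with position."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=False
        )
    except Exception as exc:  # dendropy error messages carry line/column
        raise NewickParseError(f"cannot parse newick file {path}: {exc}") from exc
    tree.is_rooted = True
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate tip labels in tree")
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick")


def _find_tip(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label == label:
            return leaf
    raise KeyError(f"tip {label!r} not on tree")


def _find_node(tree: dendropy.Tree, at) -> dendropy.Node:
    """Locate a node by tip label, internal label, or MRCA of a label list."""
    if isinstance(at, (list, tuple, set)):
        taxa = [_find_tip(tree, lab).taxon for lab in at]
        node = tree.mrca(taxa=taxa)
        if node is None:
            raise KeyError(f"no MRCA for {at}")
        return node
    for node in tree.preorder_node_iter():
        if node.taxon is not None and node.taxon.label == at:
            return node
        if getattr(node, "label", None) == at:
            return node
    raise KeyError(f"node {at!r} not on tree")


def tip_depths(
    tree: dendropy.Tree, tips: Sequence[str], ancestor=None
) -> np.ndarray:
    """Path length from each named tip up to ``ancestor`` (default: root)."""
    tree.is_rooted = True
    anc_depth = 0.0 if ancestor is None else _find_node(tree, ancestor).distance_from_root()
    return np.array(
        [_find_tip(tree, lab).distance_from_root() - anc_depth for lab in tips]
    )


def _copy_subtree(node: dendropy.Node, tns: dendropy.TaxonNamespace) -> dendropy.Node:
    out = dendropy.Node()
    out.edge.length = node.edge.length
    if node.is_leaf() and node.taxon is not None:
        out.taxon = tns.require_taxon(label=node.taxon.label)
    for child in node.child_nodes():
        out.add_child(_copy_subtree(child, tns))
    return out


def graft_subtree(
    base: dendropy.Tree,
    donor: dendropy.Tree,
    calibration: Sequence[str],
    attach_at,
    mode: str = "ratio",
    ancestor_base=None,
    ancestor_donor=None,
    calibration_tree: dendropy.Tree | None = None,
) -> dendropy.Tree:
    """Attach a rescaled donor subtree to the base tree.

    ``calibration`` names tips present in both the base tree and the
    calibration tree (the donor itself by default, or a larger source tree the
    donor was cut from).  Depths are measured to ``ancestor_base`` /
    ``ancestor_donor`` (each a tip/internal label or a list of tips whose MRCA
    is used; default root).  Scaling factor:

    - mode="ratio": mean(base depths) / mean(donor depths);
    - mode="gradient": zero-intercept least squares of base depths on donor
      depths, sum(x*y)/sum(x^2) (needs >= 2 calibration tips).

    All donor branch lengths are multiplied by the factor and the donor root
    becomes a child of ``attach_at`` in a copy of the base tree.
    """
    if len(calibration) == 0:
        raise ValueError("no calibration tips given")
    cal_tree = calibration_tree if calibration_tree is not None else donor
    base.is_rooted = True
    cal_tree.is_rooted = True
    yb = tip_depths(base, calibration, ancestor_base)
    xd = tip_depths(cal_tree, calibration, ancestor_donor)
    if mode == "ratio":
        scale = float(yb.mean() / xd.mean())
    elif mode == "gradient":
        if len(calibration) < 2:
            raise ValueError("gradient mode needs >= 2 calibration tips")
        scale = float((xd * yb).sum() / (xd * xd).sum())
    else:
        raise ValueError(f"unknown mode {mode!r}")

    out = base.clone(depth=1)
    out.is_rooted = True
    attach_node = _find_node(out, attach_at)
    new_root = _copy_subtree(donor.seed_node, out.taxon_namespace)
    for edge in new_root.preorder_iter():
        if edge.edge.length is not None:
            edge.edge.length = edge.edge.length * scale
    if new_root.edge.length is None:
        new_root.edge.length = 0.0
    attach_node.add_child(new_root)
    out.update_bipartitions(suppress_unifurcations=False)  # refresh MRCA caches
    labels = [lf.taxon.label for lf in out.leaf_node_iter() if lf.taxon is not None]
    if len(labels) != len(set(labels)):
        raise ValueError("grafting produced duplicate tip labels; prune donor first")
    return out


def phylo_correlation(
    tree: dendropy.Tree, tips: Sequence[str] | None = None
) -> pd.DataFrame:
    """Brownian-motion correlation among tips, unit diagonal.

    C_ij = (shared root-to-tip path length of i and j) / sqrt(depth_i *
    depth_j).  Symmetric positive semi-definite; invariant to uniform branch
    rescaling; identity for a star tree.
    """
    tree.is_rooted = True
    if tips is None:
        tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    tips = list(tips)
    nodes = {lab: _find_tip(tree, lab) for lab in tips}
    depth = {lab: nodes[lab].distance_from_root() for lab in tips}
    for lab, d in depth.items():
        if d <= 0:
            raise ValueError(f"tip {lab!r} has zero root-to-tip depth")
    q = len(tips)
    C = np.eye(q)
    for i in range(q):
        for j in range(i + 1, q):
            mrca = tree.mrca(taxa=[nodes[tips[i]].taxon, nodes[tips[j]].taxon])
            shared = mrca.distance_from_root()
            C[i, j] = C[j, i] = shared / np.sqrt(depth[tips[i]] * depth[tips[j]])
    return pd.DataFrame(C, index=tips, columns=tips)
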