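"""Combine phylogenies by branch-length calibration and grafting.

When no single tree covers every organism, a donor tree is rescaled into the
base tree's units using tips present in both (ratio of mean depths, or a
zero-intercept regression of base depths on donor depths) and attached at a
chosen node.  The Brownian-motion correlation matrix of the combined tree
then feeds the meta-analysis.
"""

import dendropy

from dampkit import graft_subtree, phylo_correlation


def tree(s):
    t = dendropy.Tree.get(data=s, schema="newick")
    t.is_rooted = True
    return t


base = tree("((Ecoli:1.0,Paeruginosa:1.0):1.0,Halobacterium:2.0);")
# donor organisms measured in different units; the calibration tree carries
# tips shared with the base at twice the donor scale
donor = tree("(Scerevisiae:0.8,Spombe:0.8);")
calibration = tree("((Ecoli:0.5,Paeruginosa:0.5):0.5,Halobacterium:1.0);")

combined = graft_subtree(
    base, donor,
    calibration=["Ecoli", "Paeruginosa", "Halobacterium"],
    attach_at=["Ecoli", "Paeruginosa"],  # MRCA of these tips
    mode="ratio",
    calibration_tree=calibration,
)
print(combined.as_ascii_plot(plot_metric="length"))

C = phylo_correlation(combined)
print("Brownian correlation matrix (unit diagonal):")
print(C.round(2).to_string())
# The donor branch lengths were doubled (base depths are 2x the calibration
# tree's), so the yeasts join at the expected relative depth.
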