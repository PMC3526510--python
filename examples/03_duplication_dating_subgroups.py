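"""Date gene duplications and partition paralogs into functional subgroups.

Builds a gene tree with two planted ancient duplications (predating the
focal clade's ancestor) and one recent one, detects duplications by
species overlap, dates them against the clade, and labels the resulting
functional subgroups cluster-id + letter.
"""

from cazymap.diversification import (
    SpeciesTaxonomy,
    assign_subgroups,
    detect_duplications,
    is_ancient,
    parse_newick,
)
from cazymap.synthetic import FOCAL_CLADE, FOCAL_SPECIES, gen_gene_tree

outside = ("Aspnid1", "Aspfum1", "Pench1", "Sacce1", "Ustma1", "Crypa2")
taxonomy = SpeciesTaxonomy(
    FOCAL_SPECIES, frozenset(FOCAL_CLADE), frozenset(FOCAL_CLADE) | frozenset(outside)
)

newick, truth = gen_gene_tree(n_focal=6, n_ancient=2, n_recent=1, seed=3)
tree = parse_newick(newick)

events = detect_duplications(tree)
ancient = [e for e in events if is_ancient(e, taxonomy)]
print(f"duplication nodes: {len(events)}  ancient (outside the clade): {len(ancient)}")

assignment = assign_subgroups(tree, taxonomy, cluster_id="110")
print("subgroups:", assignment.labels)
print("planted partition:", truth.partition)

# Two ancient duplications split the six focal genes into three subgroups
# (110a-110c): genes separated by a duplication older than the clade's
# ancestor have had time to diverge functionally; recent duplicates share
# a subgroup.
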