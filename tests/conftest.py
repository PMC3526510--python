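import numpy as np
import pytest

from cazymap.annotation import parse_annotation_table
from cazymap.diversification import SpeciesTaxonomy


@pytest.fixture(scope="session")
def curated_rows():
    """The packaged curated annotation table, parsed once."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return parse_annotation_table()


@pytest.fixture(scope="session")
def panel_taxonomy():
    """A small two-level taxonomy: focal species inside a focal clade."""
    clade = frozenset({"Trire2", "Fusox1", "Neucr2", "Maggr1", "Poda1"})
    outside = frozenset({"Aspnid1", "Aspfum1", "Pench1", "Sacce1", "Ustma1", "Crypa2"})
    return SpeciesTaxonomy(
        focal_species="Trire2", focal_clade=clade, universe=clade | outside
    )


def random_newick(rng: np.random.Generator, n_leaves: int, species_pool) -> str:
    """A random rooted binary tree with species-tagged leaves.

    Built by sequential random joins; species drawn with replacement so
    duplications (species overlaps) arise naturally.
    """
    nodes = [
        f"{species_pool[int(rng.integers(len(species_pool)))]}|g{i:03d}"
        for i in range(n_leaves)
    ]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


def brute_force_duplication_nodes(tree):
    """Oracle: every internal node where some pair of children shares a species."""
    dup_nodes = []
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        children = node.child_nodes()
        found = False
        for i in range(len(children)):
            for j in range(i + 1, len(children)):
                si = {l.species_id for l in children[i].leaf_iter()}
                sj = {l.species_id for l in children[j].leaf_iter()}
                if si & sj:
                    found = True
        if found:
            dup_nodes.append(node)
    return dup_nodes


def brute_force_partition(tree, taxonomy):
    """Oracle: pairwise-LCA classification closed under transitivity.

    For every pair of focal genes, they are related when the species set
    under their lowest common ancestor stays inside the focal clade; the
    partition is the transitive closure of that relation.
    """
    focal = [l for l in tree.leaves() if l.species_id == taxonomy.focal_species]
    parent = {l.gene_id: l.gene_id for l in focal}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def ancestors(node):
        chain = []
        while node is not None:
            chain.append(node)
            node = node.parent_node
        return chain

    for i in range(len(focal)):
        for j in range(i + 1, len(focal)):
            ai = ancestors(focal[i])
            aj = set(id(n) for n in ancestors(focal[j]))
            lca = next(n for n in ai if id(n) in aj)
            species = {l.species_id for l in lca.leaf_iter()}
            if species <= taxonomy.focal_clade:
                parent[find(focal[i].gene_id)] = find(focal[j].gene_id)
    groups = {}
    for leaf in focal:
        groups.setdefault(find(leaf.gene_id), set()).add(leaf.gene_id)
    return {frozenset(g) for g in groups.values()}
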