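"""Duplication dating and functional-subgroup partitioning on gene trees.

The input is a rooted gene tree whose leaves are tagged ``SPECIES|GENE``
and a two-level taxonomy: a focal species (the annotated genome) inside a
focal clade (here the Sordariomycetes) inside the full species panel.

Duplications are detected with the species-overlap criterion: an internal
node is a duplication when at least two of its children contain the same
species.  A duplication is *ancient* when the species found below it
extend outside the focal clade — the duplicate copies must then already
have existed in the clade's common ancestor, long enough ago to have
diverged functionally.  Focal-species paralogs separated by an ancient
duplication are placed in different functional subgroups; equivalently,
two focal genes share a subgroup exactly when the species set under their
lowest common ancestor stays inside the focal clade.  Subgroups are
labelled with the homology-cluster id plus a lowercase letter ("110e").
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "GeneTree",
    "SpeciesTaxonomy",
    "DuplicationEvent",
    "SubgroupAssignment",
    "parse_newick",
    "read_newick_file",
    "detect_duplications",
    "is_ancient",
    "partition_focal_subgroups",
    "label_subgroups",
    "assign_subgroups",
]


@dataclass(frozen=True)
class SpeciesTaxonomy:
    """Focal species, focal clade, and the full species universe."""

    focal_species: str
    focal_clade: frozenset[str]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        clade = frozenset(self.focal_clade)
        universe = frozenset(self.universe)
        object.__setattr__(self, "focal_clade", clade)
        object.__setattr__(self, "universe", universe)
        if self.focal_species not in clade:
            raise ValueError(
                f"focal species {self.focal_species!r} not in the focal clade"
            )
        if not clade <= universe:
            raise ValueError("focal clade is not a subset of the species universe")


class GeneTree:
    """A rooted gene tree with (species_id, gene_id) leaf tags.

    Thin wrapper around a :class:`dendropy.Tree`; species/gene tags are
    attached to the leaf nodes and cached species sets to every node.
    """

    def __init__(self, tree: dendropy.Tree, delimiter: str = "|") -> None:
        self.tree = tree
        self.delimiter = delimiter
        seen: set[tuple[str, str]] = set()
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon is not None else None
            if label is None:
                raise ValueError("leaf without a label")
            if delimiter not in label:
                raise ValueError(
                    f"leaf label {label!r} lacks the {delimiter!r} species/gene delimiter"
                )
            species, gene = label.split(delimiter, 1)
            if (species, gene) in seen:
                raise ValueError(f"duplicate leaf {label!r}")
            seen.add((species, gene))
            leaf.species_id = species
            leaf.gene_id = gene
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                node.species_set = frozenset({node.species_id})
            else:
                if len(node.child_nodes()) < 2:
                    # unifurcations carry no information; collapse view
                    node.species_set = node.child_nodes()[0].species_set
                else:
                    node.species_set = frozenset().union(
                        *(c.species_set for c in node.child_nodes())
                    )
            node.support = _parse_support(node)

    @property
    def root(self):
        return self.tree.seed_node

    def leaves(self):
        return list(self.tree.leaf_node_iter())

    def focal_leaves(self, taxonomy: SpeciesTaxonomy):
        return [l for l in self.leaves() if l.species_id == taxonomy.focal_species]

    def species_set(self) -> frozenset[str]:
        return self.root.species_set


def _parse_support(node) -> float | None:
    if node.is_leaf():
        return None
    label = node.label
    if label is None:
        return None
    try:
        return float(label)
    except ValueError:
        return None


def parse_newick(text: str, label_delimiter: str = "|") -> GeneTree:
    """Parse one Newick string into a :class:`GeneTree`.

    Internal-node labels that parse as numbers are kept as support values.
    An unrooted trifurcating tree is accepted and treated as rooted at the
    trifurcation.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    return GeneTree(tree, delimiter=label_delimiter)


def read_newick_file(path, label_delimiter: str = "|") -> list[GeneTree]:
    """Read one or more Newick trees (one per line or per file)."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    trees = []
    for chunk in text.split(";"):
        if chunk.strip():
            trees.append(parse_newick(chunk.strip() + ";", label_delimiter))
    return trees


@dataclass(frozen=True)
class DuplicationEvent:
    node: object = field(repr=False, hash=False, compare=False)
    species_set: frozenset[str] = frozenset()
    support: float | None = None


def detect_duplications(tree: GeneTree) -> list[DuplicationEvent]:
    """Species-overlap duplications, in preorder.

    An internal node is a duplication when at least two of its children
    have overlapping species sets.
    """
    events: list[DuplicationEvent] = []
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        children = node.child_nodes()
        overlap = False
        for i in range(len(children)):
            for j in range(i + 1, len(children)):
                if children[i].species_set & children[j].species_set:
                    overlap = True
                    break
            if overlap:
                break
        if overlap:
            events.append(
                DuplicationEvent(
                    node=node,
                    species_set=node.species_set,
                    support=node.support,
                )
            )
    return events


def is_ancient(event: DuplicationEvent, taxonomy: SpeciesTaxonomy) -> bool:
    """A duplication is ancient when its species set leaves the focal clade."""
    if not event.species_set:
        raise ValueError("duplication event with empty species set")
    unknown = event.species_set - taxonomy.universe
    if unknown:
        raise KeyError(f"species not in taxonomy universe: {sorted(unknown)}")
    return not event.species_set <= taxonomy.focal_clade


def partition_focal_subgroups(
    tree: GeneTree, taxonomy: SpeciesTaxonomy
) -> list[list[str]]:
    """Partition focal-species genes into functional subgroups.

    Two focal genes share a part exactly when the species set under their
    lowest common ancestor is entirely inside the focal clade.  The
    relation is an equivalence: each part is the focal-gene content of a
    maximal clade whose species set stays inside the focal clade.  Parts
    are returned in left-to-right leaf order of their first member.
    """
    unknown = tree.species_set() - taxonomy.universe
    if unknown:
        raise KeyError(f"species not in taxonomy universe: {sorted(unknown)}")
    parts: list[list[str]] = []

    def collect(node) -> None:
        if node.species_set <= taxonomy.focal_clade:
            genes = [
                leaf.gene_id
                for leaf in node.leaf_iter()
                if leaf.species_id == taxonomy.focal_species
            ]
            if genes:
                parts.append(genes)
            return
        for child in node.child_nodes():
            collect(child)

    collect(tree.root)
    return parts


@dataclass(frozen=True)
class SubgroupAssignment:
    cluster_id: str
    labels: dict[str, str]
    n_subgroups: int


def _letter_suffix(index: int) -> str:
    """a, b, ..., z, aa, ab, ... (bijective base-26)."""
    letters = string.ascii_lowercase
    index += 1
    out = ""
    while index > 0:
        index, rem = divmod(index - 1, 26)
        out = letters[rem] + out
    return out


def label_subgroups(
    partition: list[list[str]], cluster_id: str, tree: GeneTree
) -> SubgroupAssignment:
    """Label parts cluster_id + letter in order of first leaf appearance."""
    if any(not part for part in partition):
        raise ValueError("empty subgroup part")
    leaf_order = {leaf.gene_id: i for i, leaf in enumerate(tree.leaves())}
    ordered = sorted(partition, key=lambda part: min(leaf_order[g] for g in part))
    labels: dict[str, str] = {}
    for i, part in enumerate(ordered):
        suffix = _letter_suffix(i)
        for gene in part:
            labels[gene] = f"{cluster_id}{suffix}"
    return SubgroupAssignment(
        cluster_id=cluster_id, labels=labels, n_subgroups=len(ordered)
    )


def assign_subgroups(
    tree: GeneTree, taxonomy: SpeciesTaxonomy, cluster_id: str
) -> SubgroupAssignment:
    """Convenience: partition the focal genes of one tree and label the parts."""
    partition = partition_focal_subgroups(tree, taxonomy)
    return label_subgroups(partition, cluster_id, tree)
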