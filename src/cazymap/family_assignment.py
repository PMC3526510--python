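"""CAZyme membership calls and majority-vote family assignment.

A proteome is screened against a family-labelled reference (the CAZy
database in the original workflow) with a protein BLAST search.  This
module consumes the resulting tabular hit files and turns them into

* per-protein membership calls — a protein is a confident CAZyme when its
  best reference hit aligns at >= 97 % identity over more than 200 amino
  acids;
* per-cluster family calls — each homology cluster (a group of homologous
  proteins across a multi-species fungal panel) receives the CAZy family
  carried by the majority of its members' best hits.

Hit filtering keeps only matches with E-value strictly below 1e-11, the
significance gate applied before any membership reasoning.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ReferenceEntry",
    "HitRecord",
    "HomologyCluster",
    "MembershipCall",
    "FamilyCall",
    "UNASSIGNED",
    "filter_hits_by_evalue",
    "best_hit",
    "best_characterized_hit",
    "is_confident_member",
    "cluster_acceptance",
    "majority_vote_family",
    "membership_calls",
    "read_hit_table",
    "read_reference_table",
    "read_cluster_table",
    "group_hits_by_query",
]

UNASSIGNED = "UNASSIGNED"

_FAMILY_RE = re.compile(r"^(GH|CE|PL|GT|CBM)(\d+)$")


def _validate_family(label: str) -> None:
    if not _FAMILY_RE.match(label):
        raise ValueError(
            f"invalid CAZy family label {label!r}: expected class prefix "
            "GH/CE/PL/GT/CBM followed by a positive integer"
        )


@dataclass(frozen=True)
class ReferenceEntry:
    """One family-labelled reference protein.

    ``characterized`` marks proteins with experimental evidence; the best
    characterized hit is reported separately from the overall best hit.
    """

    protein_id: str
    family: str
    characterized: bool = False
    structure_known: bool = False

    def __post_init__(self) -> None:
        _validate_family(self.family)


@dataclass(frozen=True)
class HitRecord:
    """One pairwise alignment between a query protein and a reference protein."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"percent_identity out of [0, 100]: {self.percent_identity}")
        if self.alignment_length < 1:
            raise ValueError(f"alignment_length must be >= 1: {self.alignment_length}")
        if self.evalue < 0:
            raise ValueError(f"evalue must be non-negative: {self.evalue}")


@dataclass(frozen=True)
class HomologyCluster:
    """A named set of (gene_id, species_id) members across the species panel."""

    cluster_id: str
    members: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"cluster {self.cluster_id!r} has no members")
        genes = [g for g, _ in self.members]
        if len(set(genes)) != len(genes):
            raise ValueError(f"cluster {self.cluster_id!r} has duplicate gene ids")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.members)


@dataclass(frozen=True)
class MembershipCall:
    protein_id: str
    is_cazyme: bool
    supporting_hit: HitRecord | None = None

    def __post_init__(self) -> None:
        if self.is_cazyme:
            if self.supporting_hit is None:
                raise ValueError("is_cazyme=True requires a supporting hit")
            if not is_confident_member(self.supporting_hit):
                raise ValueError("supporting hit does not satisfy the 97 % / 200 aa rule")


@dataclass(frozen=True)
class FamilyCall:
    cluster_id: str
    family: str
    tally: Mapping[str, int] = field(default_factory=dict)
    tie_broken: bool = False


def filter_hits_by_evalue(
    hits: Sequence[HitRecord], max_exclusive: float = 1e-11
) -> list[HitRecord]:
    """Keep hits with E-value strictly below ``max_exclusive``, order preserved."""
    if max_exclusive < 0:
        raise ValueError(f"max_exclusive must be non-negative: {max_exclusive}")
    return [h for h in hits if h.evalue < max_exclusive]


def best_hit(hits_for_one_query: Sequence[HitRecord]) -> HitRecord | None:
    """Best hit of one query: maximal bitscore, ties by lower E-value then subject id."""
    if not hits_for_one_query:
        return None
    queries = {h.query_id for h in hits_for_one_query}
    if len(queries) > 1:
        raise ValueError(f"hits span multiple queries: {sorted(queries)}")
    return min(hits_for_one_query, key=lambda h: (-h.bitscore, h.evalue, h.subject_id))


def best_hit_by_evalue(hits_for_one_query: Sequence[HitRecord]) -> HitRecord | None:
    """Alternative ordering: minimal E-value, ties by higher bitscore then subject id."""
    if not hits_for_one_query:
        return None
    queries = {h.query_id for h in hits_for_one_query}
    if len(queries) > 1:
        raise ValueError(f"hits span multiple queries: {sorted(queries)}")
    return min(hits_for_one_query, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))


def best_characterized_hit(
    hits_for_one_query: Sequence[HitRecord],
    reference: Mapping[str, ReferenceEntry] | Iterable[ReferenceEntry],
) -> HitRecord | None:
    """``best_hit`` restricted to characterized reference subjects."""
    ref = _as_reference_map(reference)
    missing = [h.subject_id for h in hits_for_one_query if h.subject_id not in ref]
    if missing:
        raise KeyError(f"subject ids missing from reference: {sorted(set(missing))}")
    characterized = [h for h in hits_for_one_query if ref[h.subject_id].characterized]
    return best_hit(characterized)


def is_confident_member(hit: HitRecord) -> bool:
    """97 %/200 aa rule: identity >= 97 and aligned length strictly > 200."""
    return hit.percent_identity >= 97.0 and hit.alignment_length > 200


def membership_calls(
    best_hits: Mapping[str, HitRecord | None]
) -> dict[str, MembershipCall]:
    """Apply the confident-membership rule to each protein's best hit."""
    calls: dict[str, MembershipCall] = {}
    for protein_id, hit in best_hits.items():
        member = hit is not None and is_confident_member(hit)
        calls[protein_id] = MembershipCall(
            protein_id=protein_id,
            is_cazyme=member,
            supporting_hit=hit if member else None,
        )
    return calls


def cluster_acceptance(
    cluster: HomologyCluster,
    best_hits: Mapping[str, HitRecord | None],
    min_mean_identity: float = 40.0,
    min_mean_length: float = 100.0,
) -> bool:
    """Accept a cluster when its members' best hits are good on average.

    The screening step keeps clusters whose mean best-hit identity and mean
    alignment length both clear a configurable boundary; members without a
    hit do not contribute to the means, and a cluster with no hits at all
    is rejected.
    """
    hits = [best_hits.get(g) for g in cluster.gene_ids]
    hits = [h for h in hits if h is not None]
    if not hits:
        return False
    mean_identity = sum(h.percent_identity for h in hits) / len(hits)
    mean_length = sum(h.alignment_length for h in hits) / len(hits)
    return mean_identity >= min_mean_identity and mean_length >= min_mean_length


def majority_vote_family(
    cluster: HomologyCluster,
    member_families: Mapping[str, Sequence[str] | str | None],
    bit_weights: Mapping[str, float] | None = None,
) -> FamilyCall:
    """Assign the cluster the family carried by most voting members.

    Each member with a known family contributes one full vote per family it
    carries (a multi-family reference protein votes in each of its
    families).  Ties are broken by the larger summed bitscore weight of the
    voting members, then by the lexicographically smallest family label;
    ``tie_broken`` records that a tie occurred.  A cluster with no voting
    members is UNASSIGNED.
    """
    unknown = set(member_families) - set(cluster.gene_ids)
    if unknown:
        raise ValueError(f"member_families contains non-members: {sorted(unknown)}")
    weights = bit_weights or {}
    tally: dict[str, int] = {}
    weight_sum: dict[str, float] = {}
    for gene, fams in member_families.items():
        if fams is None:
            continue
        if isinstance(fams, str):
            fams = [fams]
        for fam in fams:
            _validate_family(fam)
            tally[fam] = tally.get(fam, 0) + 1
            weight_sum[fam] = weight_sum.get(fam, 0.0) + float(weights.get(gene, 0.0))
    if not tally:
        return FamilyCall(cluster.cluster_id, UNASSIGNED, tally={}, tie_broken=False)
    top = max(tally.values())
    leaders = sorted(f for f, n in tally.items() if n == top)
    if len(leaders) == 1:
        return FamilyCall(cluster.cluster_id, leaders[0], tally=tally, tie_broken=False)
    winner = min(leaders, key=lambda f: (-weight_sum[f], f))
    return FamilyCall(cluster.cluster_id, winner, tally=tally, tie_broken=True)


# ---------------------------------------------------------------------------
# readers for the on-disk dialects


def read_hit_table(path) -> list[HitRecord]:
    """Read a 12-column BLAST tabular file (outfmt 6); extra columns tolerated."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if frame.shape[1] < 12:
        raise ValueError(
            f"{path}: expected >= 12 tab-separated columns, found {frame.shape[1]}"
        )
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            HitRecord(
                query_id=row[0],
                subject_id=row[1],
                percent_identity=float(row[2]),
                alignment_length=int(row[3]),
                evalue=float(row[10]),
                bitscore=float(row[11]),
            )
        )
    return records


def group_hits_by_query(hits: Iterable[HitRecord]) -> dict[str, list[HitRecord]]:
    grouped: dict[str, list[HitRecord]] = {}
    for hit in hits:
        grouped.setdefault(hit.query_id, []).append(hit)
    return grouped


def read_reference_table(path) -> dict[str, ReferenceEntry]:
    """TSV with header protein_id, family, characterized (0/1), structure_known (0/1)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_id", "family", "characterized", "structure_known"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(frame.columns))}")
    entries: dict[str, ReferenceEntry] = {}
    for row in frame.itertuples(index=False):
        entry = ReferenceEntry(
            protein_id=row.protein_id,
            family=row.family,
            characterized=bool(int(row.characterized)),
            structure_known=bool(int(row.structure_known)),
        )
        if entry.protein_id in entries:
            raise ValueError(f"{path}: duplicate protein_id {entry.protein_id!r}")
        entries[entry.protein_id] = entry
    return entries


def read_cluster_table(path) -> dict[str, HomologyCluster]:
    """TSV with header gene_id, species_id, cluster_id."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "species_id", "cluster_id"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(frame.columns))}")
    members: dict[str, list[tuple[str, str]]] = {}
    for row in frame.itertuples(index=False):
        members.setdefault(row.cluster_id, []).append((row.gene_id, row.species_id))
    return {
        cid: HomologyCluster(cluster_id=cid, members=tuple(pairs))
        for cid, pairs in members.items()
    }


def _as_reference_map(
    reference: Mapping[str, ReferenceEntry] | Iterable[ReferenceEntry]
) -> Mapping[str, ReferenceEntry]:
    if isinstance(reference, Mapping):
        return reference
    return {entry.protein_id: entry for entry in reference}
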