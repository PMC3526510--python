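"""Run configuration and orchestration of the annotation and expression stages.

``run_annotate`` composes hit filtering, membership calling, cluster
acceptance, majority-vote family assignment and tree-based subgroup
partitioning into one per-gene table.  ``run_express`` computes every
induced-vs-control contrast and the downstream summaries.  Both embed a
run manifest (config hash, seed, package version) in their reports, so
identical manifests imply identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diversification import SpeciesTaxonomy, assign_subgroups, read_newick_file
from .expression import (
    cluster_coexpression_branches,
    compute_contrasts,
    core_induced_set,
    family_induction_matrix,
    induced_gene_set,
    max_induction_profile,
    read_expression_dataset,
)
from .family_assignment import (
    best_hit,
    best_hit_by_evalue,
    cluster_acceptance,
    filter_hits_by_evalue,
    group_hits_by_query,
    majority_vote_family,
    membership_calls,
    read_cluster_table,
    read_hit_table,
    read_reference_table,
)

__all__ = ["RunConfig", "run_annotate", "run_express", "read_taxonomy_table"]

DEFAULT_SUBSTRATE_CLASSES = {
    "AV1": "cellulose",
    "AV0.75": "cellulose",
    "SP": "cellulose",
    "SO": "cellulose",
    "XO": "xylan",
    "XB": "xylan",
    "BO": "other",
    "BS": "other",
    "BE": "other",
    "WH": "other",
}


@dataclass
class RunConfig:
    """Thresholds and inputs of one pipeline run; defaults are the study's."""

    # inputs
    hits: str | None = None
    reference: str | None = None
    clusters: str | None = None
    trees_dir: str | None = None
    taxonomy: str | None = None
    focal_species: str = "Trire2"
    expression_matrix: str | None = None
    sample_sheet: str | None = None
    annotation_table: str | None = None
    # homology-screen thresholds
    evalue_max: float = 1e-11
    identity_min: float = 97.0
    length_min_exclusive: int = 200
    accept_identity_min: float = 40.0
    accept_length_min: float = 100.0
    best_hit_order: str = "bitscore"  # or "evalue"
    exclude_focal_species: bool = True
    min_support: float = 0.0
    # expression thresholds
    p_max: float = 0.01
    lfc_min: float = 0.4
    core_fraction: float = 0.70
    n_branches: int = 18
    moderation: str = "eb"
    substrate_classes: dict = field(
        default_factory=lambda: dict(DEFAULT_SUBSTRATE_CLASSES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "evalue_max",
            "identity_min",
            "length_min_exclusive",
            "p_max",
            "lfc_min",
            "core_fraction",
            "n_branches",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.best_hit_order not in ("bitscore", "evalue"):
            raise ValueError("best_hit_order must be 'bitscore' or 'evalue'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def manifest(self) -> dict:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return {
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "seed": self.seed,
            "version": __version__,
        }


def read_taxonomy_table(path, focal_species: str) -> SpeciesTaxonomy:
    """TSV with header species_id, in_focal_clade (0/1)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"species_id", "in_focal_clade"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(frame.columns))}")
    universe = frozenset(frame["species_id"])
    clade = frozenset(frame.loc[frame["in_focal_clade"].astype(int) == 1, "species_id"])
    return SpeciesTaxonomy(
        focal_species=focal_species, focal_clade=clade, universe=universe
    )


def _require(path: str | None, what: str) -> Path:
    if path is None:
        raise FileNotFoundError(f"run config does not name a {what} file")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} file not found: {p}")
    return p


def run_annotate(config: RunConfig, out_dir: str | None = None):
    """Per-gene membership, family and subgroup calls plus a JSON report.

    Returns (table, report): the table has one row per focal-species gene
    with columns gene_id, cluster_id, is_cazyme, family, subgroup,
    n_subgroups_in_cluster.
    """
    hits_path = _require(config.hits, "hit table")
    ref_path = _require(config.reference, "reference metadata")
    clusters_path = _require(config.clusters, "cluster membership")
    taxonomy_path = _require(config.taxonomy, "species taxonomy")

    hits = filter_hits_by_evalue(read_hit_table(hits_path), config.evalue_max)
    reference = read_reference_table(ref_path)
    clusters = read_cluster_table(clusters_path)
    taxonomy = read_taxonomy_table(taxonomy_path, config.focal_species)

    pick_best = best_hit if config.best_hit_order == "bitscore" else best_hit_by_evalue
    grouped = group_hits_by_query(hits)
    best = {query: pick_best(query_hits) for query, query_hits in grouped.items()}
    calls = membership_calls(
        {
            gene: best.get(gene)
            for cluster in clusters.values()
            for gene in cluster.gene_ids
        }
    )

    records = []
    cluster_report = {}
    for cluster_id, cluster in sorted(clusters.items()):
        accepted = cluster_acceptance(
            cluster,
            best,
            min_mean_identity=config.accept_identity_min,
            min_mean_length=config.accept_length_min,
        )
        species_of = dict(cluster.members)
        member_families = {}
        weights = {}
        for gene in cluster.gene_ids:
            if config.exclude_focal_species and species_of[gene] == config.focal_species:
                continue
            hit = best.get(gene)
            if hit is None or not calls[gene].is_cazyme:
                continue
            if hit.subject_id not in reference:
                raise KeyError(f"hit subject {hit.subject_id!r} missing from reference")
            member_families[gene] = reference[hit.subject_id].family
            weights[gene] = hit.bitscore
        family_call = majority_vote_family(cluster, member_families, weights)

        subgroups = {}
        n_subgroups = 0
        if config.trees_dir is not None:
            tree_path = Path(config.trees_dir) / f"{cluster_id}.nwk"
            if tree_path.exists():
                tree = read_newick_file(tree_path)[0]
                assignment = assign_subgroups(tree, taxonomy, cluster_id)
                subgroups = assignment.labels
                n_subgroups = assignment.n_subgroups

        cluster_report[cluster_id] = {
            "accepted": accepted,
            "family": family_call.family,
            "tally": family_call.tally,
            "tie_broken": family_call.tie_broken,
            "n_subgroups": n_subgroups,
        }
        for gene, species in cluster.members:
            if species != config.focal_species:
                continue
            records.append(
                {
                    "gene_id": gene,
                    "cluster_id": cluster_id,
                    "cluster_accepted": accepted,
                    "is_cazyme": calls[gene].is_cazyme,
                    "family": family_call.family,
                    "subgroup": subgroups.get(gene, ""),
                    "n_subgroups_in_cluster": n_subgroups,
                }
            )
    table = pd.DataFrame.from_records(
        records,
        columns=[
            "gene_id",
            "cluster_id",
            "cluster_accepted",
            "is_cazyme",
            "family",
            "subgroup",
            "n_subgroups_in_cluster",
        ],
    ).sort_values(["cluster_id", "gene_id"], ignore_index=True)
    report = {
        "manifest": config.manifest(),
        "n_clusters": len(clusters),
        "n_focal_genes": len(table),
        "n_cazyme_calls": int(table["is_cazyme"].sum()) if len(table) else 0,
        "clusters": cluster_report,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "annotation_calls.tsv", sep="\t", index=False)
        (out / "annotate_report.json").write_text(json.dumps(report, indent=2))
    return table, report


def run_express(config: RunConfig, out_dir: str | None = None):
    """All contrasts and summaries; returns a dict of result objects."""
    matrix_path = _require(config.expression_matrix, "expression matrix")
    sheet_path = _require(config.sample_sheet, "sample sheet")
    data = read_expression_dataset(matrix_path, sheet_path)

    contrasts = compute_contrasts(
        data, p_max=config.p_max, lfc_min=config.lfc_min, moderation=config.moderation
    )
    induced = induced_gene_set(contrasts)
    class_map = {s: config.substrate_classes.get(s, "other") for s in data.substrates()}
    core = core_induced_set(contrasts, class_map, fraction=config.core_fraction)

    annotation_map: dict[str, str] = {}
    if config.annotation_table is not None:
        from .annotation import parse_annotation_table

        annotation_map = {
            r.gene_id: r.family for r in parse_annotation_table(config.annotation_table)
        }
    family_matrix, margins = family_induction_matrix(
        contrasts, annotation_map
    ) if annotation_map else (None, None)

    profile = max_induction_profile(contrasts)
    lfc_wide = contrasts.pivot_table(
        index="gene_id", columns=["substrate", "time_h"], values="lfc"
    )
    k = min(config.n_branches, lfc_wide.shape[0])
    branches, linkage_params = cluster_coexpression_branches(lfc_wide, k=k)

    results = {
        "manifest": config.manifest(),
        "contrasts": contrasts,
        "induced_genes": induced,
        "core_induced_genes": core,
        "family_matrix": family_matrix,
        "family_margins": margins,
        "max_induction_profile": profile,
        "branches": branches,
        "linkage_params": linkage_params,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        contrasts.to_csv(out / "contrasts.tsv", sep="\t", index=False)
        pd.Series(branches, name="branch").rename_axis("gene_id").to_csv(
            out / "branches.tsv", sep="\t"
        )
        profile.to_csv(out / "max_induction_profile.tsv", sep="\t")
        if family_matrix is not None:
            family_matrix.to_csv(out / "family_induction_matrix.tsv", sep="\t")
        summary = {
            "manifest": results["manifest"],
            "n_genes": int(lfc_wide.shape[0]),
            "n_induced": len(induced),
            "n_core_induced": len(core),
            "linkage": linkage_params,
        }
        (out / "express_report.json").write_text(json.dumps(summary, indent=2))
    return results
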