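"""Seeded synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its parameters and seed: the same
call reproduces byte-identical files.  The generators emulate the study
conditions of the real workflow — confident CAZyme hits at >= 97 %
identity over > 200 aligned residues, gene trees with duplications
planted before or after the focal clade's ancestor, and log2 expression
data with four biological replicates per condition — without emulating
sequence evolution or array-probe behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import CONTROL, SUBSTRATES, TIMEPOINTS, ExpressionDataset

__all__ = [
    "HitTableTruth",
    "GeneTreeTruth",
    "ExpressionTruth",
    "BundleTruth",
    "gen_hit_table",
    "gen_gene_tree",
    "gen_expression_dataset",
    "gen_annotation_bundle",
    "FOCAL_SPECIES",
    "FOCAL_CLADE",
    "default_batches",
]

FOCAL_SPECIES = "Trire2"
FOCAL_CLADE = ("Trire2", "Fusox1", "Neucr2", "Maggr1", "Poda1")
OUTSIDE_SPECIES = ("Aspnid1", "Aspfum1", "Pench1", "Sacce1", "Ustma1", "Crypa2")

# cultivation set 1 used the defined substrates, set 2 the bagasse/xylan series
BATCH1_SUBSTRATES = ("AV0.75", "WH", "SP", "SO")
BATCH2_SUBSTRATES = ("AV1", "BO", "BS", "BE", "XB", "XO")

_FAMILY_POOL = ("GH3", "GH5", "GH7", "GH11", "GH18", "CE5", "PL7", "GH27")


def default_batches(substrates: Sequence[str]) -> dict[str, int]:
    """Assign each substrate to its cultivation set (unknown names go to set 2)."""
    batches = {}
    for s in substrates:
        batches[s] = 1 if s in BATCH1_SUBSTRATES else 2
    return batches


@dataclass(frozen=True)
class HitTableTruth:
    seed: int
    is_member: dict[str, bool]
    family: dict[str, str]
    violation: dict[str, str] = field(default_factory=dict)


def gen_hit_table(
    n_queries: int,
    member_fraction: float,
    seed: int,
) -> tuple[str, HitTableTruth]:
    """BLAST-tabular hit lines with planted confident-membership labels.

    Members draw identity ~ U(97, 100) and alignment length ~ U(201, 600)
    with E-values log-uniform in [1e-50, 1e-12]; non-members violate the
    identity bound, the length bound, or both (recorded in the truth), and
    half of them additionally carry a non-significant E-value.  Returns
    (file text, truth).
    """
    if n_queries < 1:
        raise ValueError("n_queries must be >= 1")
    if not 0.0 <= member_fraction <= 1.0:
        raise ValueError("member_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_members = int(round(member_fraction * n_queries))
    lines = []
    is_member: dict[str, bool] = {}
    family: dict[str, str] = {}
    violation: dict[str, str] = {}
    for i in range(n_queries):
        query = f"q{i:05d}"
        fam = _FAMILY_POOL[int(rng.integers(len(_FAMILY_POOL)))]
        member = i < n_members
        if member:
            identity = float(rng.uniform(97.0, 100.0))
            length = int(rng.integers(201, 601))
            evalue = 10.0 ** float(rng.uniform(-50.0, -12.0))
        else:
            kind = ("identity", "length", "both")[int(rng.integers(3))]
            violation[query] = kind
            if kind == "identity":
                identity = float(rng.uniform(30.0, 96.9))
                length = int(rng.integers(201, 601))
            elif kind == "length":
                identity = float(rng.uniform(97.0, 100.0))
                length = int(rng.integers(50, 201))
            else:
                identity = float(rng.uniform(30.0, 96.9))
                length = int(rng.integers(50, 201))
            if rng.random() < 0.5:
                evalue = 10.0 ** float(rng.uniform(-10.0, -2.0))
            else:
                evalue = 10.0 ** float(rng.uniform(-50.0, -12.0))
        subject = f"ref_{fam}_{i % 7:02d}"
        bitscore = round(2.0 * length * identity / 100.0, 1)
        mismatch = int(round(length * (100.0 - identity) / 100.0))
        lines.append(
            "\t".join(
                [
                    query,
                    subject,
                    f"{identity:.2f}",
                    str(length),
                    str(mismatch),
                    "0",
                    "1",
                    str(length),
                    "1",
                    str(length),
                    f"{evalue:.3e}",
                    f"{bitscore:.1f}",
                ]
            )
        )
        is_member[query] = member
        family[query] = fam
    truth = HitTableTruth(
        seed=seed, is_member=is_member, family=family, violation=violation
    )
    return "\n".join(lines) + "\n", truth


@dataclass(frozen=True)
class GeneTreeTruth:
    seed: int
    partition: tuple[tuple[str, ...], ...]
    n_ancient: int
    n_recent: int
    focal_genes: tuple[str, ...]


def gen_gene_tree(
    n_focal: int,
    n_ancient: int,
    n_recent: int,
    n_outside_species: int = 2,
    seed: int = 0,
) -> tuple[str, GeneTreeTruth]:
    """A Newick gene tree with planted ancient and recent duplications.

    The tree carries n_ancient + 1 ancestral lineages that split above the
    focal clade's root; each lineage keeps outside-clade witness leaves,
    so focal genes in different lineages are separated by an ancient
    duplication.  Recent duplications (and any focal genes beyond those
    implied by the planted events) are added inside the focal species, so
    they never split the planted partition of n_ancient + 1 parts.
    """
    if n_focal < 1:
        raise ValueError("n_focal must be >= 1")
    if n_ancient < 0 or n_recent < 0:
        raise ValueError("duplication counts must be non-negative")
    if n_ancient + n_recent > n_focal - 1:
        raise ValueError(
            "n_ancient + n_recent must be <= n_focal - 1 "
            f"(got {n_ancient} + {n_recent} > {n_focal} - 1)"
        )
    if n_outside_species < 1:
        raise ValueError("need at least one outside-clade species")
    rng = np.random.default_rng(seed)
    n_lineages = n_ancient + 1
    genes = [f"g{i:03d}" for i in range(n_focal)]
    # every lineage gets one gene; remaining genes (recent copies) go to
    # rng-chosen lineages
    counts = [1] * n_lineages
    for _ in range(n_focal - n_lineages):
        counts[int(rng.integers(n_lineages))] += 1
    assignment: list[list[str]] = []
    cursor = 0
    for c in counts:
        assignment.append(genes[cursor : cursor + c])
        cursor += c

    outside = [OUTSIDE_SPECIES[i % len(OUTSIDE_SPECIES)] for i in range(n_outside_species)]
    sister_clade = [s for s in FOCAL_CLADE if s != FOCAL_SPECIES]

    def focal_subtree(lineage_genes: list[str], lineage_idx: int) -> str:
        # nested recent duplications of the focal species, plus one
        # focal-clade sister leaf so the subtree looks like a clade
        tips = [f"{FOCAL_SPECIES}|{g}" for g in lineage_genes]
        node = tips[0]
        for tip in tips[1:]:
            node = f"({node},{tip})"
        sister = sister_clade[lineage_idx % len(sister_clade)]
        return f"({node},{sister}|s{lineage_idx:02d})"

    def lineage_subtree(lineage_genes: list[str], lineage_idx: int) -> str:
        inner = focal_subtree(lineage_genes, lineage_idx)
        for j, sp in enumerate(outside):
            inner = f"({inner},{sp}|o{lineage_idx:02d}_{j})"
        return inner

    newick = lineage_subtree(assignment[0], 0)
    for idx in range(1, n_lineages):
        newick = f"({newick},{lineage_subtree(assignment[idx], idx)})"
    newick += ";"
    truth = GeneTreeTruth(
        seed=seed,
        partition=tuple(tuple(part) for part in assignment),
        n_ancient=n_ancient,
        n_recent=n_focal - n_lineages,
        focal_genes=tuple(genes),
    )
    return newick, truth


@dataclass(frozen=True)
class ExpressionTruth:
    seed: int
    induced_genes: tuple[str, ...]
    effect_lfc: float
    induced_strata: dict[str, tuple[tuple[str, int], ...]]


def gen_expression_dataset(
    n_genes: int,
    induced_fraction: float,
    effect_lfc: float,
    noise_sd: float,
    substrates: Sequence[str] = SUBSTRATES,
    timepoints: Sequence[int] = TIMEPOINTS,
    replicates: int = 4,
    seed: int = 0,
) -> tuple[ExpressionDataset, ExpressionTruth]:
    """Log2 expression matrix + sample sheet with planted induction.

    Baseline per-gene log2 signals draw from Normal(8, 1).  Induced genes
    receive +effect_lfc in every non-zero time point of every substrate
    (their induced strata are recorded in the truth); all samples carry
    Gaussian noise with standard deviation ``noise_sd``.  An effect of 0
    yields an empty truth set by convention.
    """
    if n_genes < 1 or replicates < 2:
        raise ValueError("need n_genes >= 1 and replicates >= 2")
    if not 0.0 <= induced_fraction <= 1.0:
        raise ValueError("induced_fraction must be in [0, 1]")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    n_induced = int(round(induced_fraction * n_genes)) if effect_lfc != 0 else 0
    induced = set(genes[:n_induced])
    baseline = rng.normal(8.0, 1.0, size=n_genes)

    batches = default_batches(substrates)
    rows = []
    for substrate in list(substrates) + [CONTROL]:
        subs_batches = (
            sorted(set(batches.values())) if substrate == CONTROL else [batches[substrate]]
        )
        for batch in subs_batches:
            for t in timepoints:
                for rep in range(1, replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{substrate}_b{batch}_t{t}_r{rep}",
                            "substrate": substrate,
                            "time_h": int(t),
                            "replicate": rep,
                            "batch": batch,
                        }
                    )
    sheet = pd.DataFrame(rows)
    induced_times = [int(t) for t in timepoints if t != 0]
    induced_idx = np.arange(n_induced)
    matrix = np.empty((n_genes, len(sheet)))
    for j, rec in enumerate(sheet.itertuples(index=False)):
        signal = baseline.copy()
        if rec.substrate != CONTROL and rec.time_h in induced_times:
            signal[induced_idx] += effect_lfc
        matrix[:, j] = signal + rng.normal(0.0, noise_sd, size=n_genes)
    values = pd.DataFrame(matrix, index=genes, columns=sheet["sample_id"])
    strata = {
        g: tuple((s, t) for s in substrates for t in induced_times) for g in sorted(induced)
    }
    truth = ExpressionTruth(
        seed=seed,
        induced_genes=tuple(g for g in genes if g in induced),
        effect_lfc=effect_lfc,
        induced_strata=strata,
    )
    return ExpressionDataset(values=values, sheet=sheet), truth


@dataclass(frozen=True)
class BundleTruth:
    """Ground truth for a full annotation input bundle."""

    seed: int
    membership: dict[str, bool]
    family_per_cluster: dict[str, str]
    partition_per_cluster: dict[str, tuple[tuple[str, ...], ...]]
    subgroup_per_gene: dict[str, str]


def gen_annotation_bundle(
    out_dir,
    n_clusters: int = 6,
    seed: int = 0,
) -> BundleTruth:
    """Write a coherent hits/reference/clusters/trees/taxonomy bundle.

    Each homology cluster receives a family, a gene tree with a planted
    subgroup partition of its focal-species genes, and per-member hits
    against that family's reference proteins.  Focal-species members are
    confident CAZymes by construction; each cluster additionally carries
    non-focal voting members so that family assignment by majority vote
    (with the focal species excluded from voting) recovers the planted
    family.  The planted subgroup labels follow the cluster-id + letter
    convention with parts ordered by first leaf appearance, matching the
    labelling rule of the inference.
    """
    from pathlib import Path

    out = Path(out_dir)
    (out / "trees").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    hit_lines: list[str] = []
    ref_rows: list[tuple[str, str, int, int]] = []
    cluster_rows: list[tuple[str, str, str]] = []
    membership: dict[str, bool] = {}
    family_per_cluster: dict[str, str] = {}
    partition_per_cluster: dict[str, tuple[tuple[str, ...], ...]] = {}
    subgroup_per_gene: dict[str, str] = {}

    for fam in _FAMILY_POOL:
        for j in range(3):
            ref_rows.append((f"ref_{fam}_{j:02d}", fam, int(j == 0), 0))

    def emit_hit(query: str, fam: str, member: bool) -> None:
        if member:
            identity = float(rng.uniform(97.0, 100.0))
            length = int(rng.integers(201, 601))
        else:
            identity = float(rng.uniform(40.0, 96.5))
            length = int(rng.integers(60, 190))
        evalue = 10.0 ** float(rng.uniform(-50.0, -12.0))
        bitscore = round(2.0 * length * identity / 100.0, 1)
        subject = f"ref_{fam}_{int(rng.integers(3)):02d}"
        mismatch = int(round(length * (100.0 - identity) / 100.0))
        hit_lines.append(
            "\t".join(
                [
                    query, subject, f"{identity:.2f}", str(length), str(mismatch),
                    "0", "1", str(length), "1", str(length),
                    f"{evalue:.3e}", f"{bitscore:.1f}",
                ]
            )
        )
        membership[query] = member

    for k in range(n_clusters):
        cid = str(1000 + 7 * k)
        fam = _FAMILY_POOL[k % len(_FAMILY_POOL)]
        family_per_cluster[cid] = fam
        n_focal = int(rng.integers(1, 5))
        n_ancient = int(rng.integers(0, n_focal)) if n_focal > 1 else 0
        n_recent = (
            int(rng.integers(0, n_focal - n_ancient)) if n_focal - n_ancient > 1 else 0
        )
        newick, tree_truth = gen_gene_tree(
            n_focal, n_ancient, n_recent, n_outside_species=2, seed=seed * 1009 + k
        )
        prefix = f"c{cid}_"
        newick = newick.replace("|g", f"|{prefix}g")
        (out / "trees" / f"{cid}.nwk").write_text(newick + "\n")
        partition = tuple(
            tuple(prefix + g for g in part) for part in tree_truth.partition
        )
        partition_per_cluster[cid] = partition
        # planted labels: parts appear left-to-right in tree construction order
        letters = "abcdefghijklmnopqrstuvwxyz"
        for idx, part in enumerate(partition):
            for gene in part:
                subgroup_per_gene[gene] = f"{cid}{letters[idx]}"
        for gene in (prefix + g for g in tree_truth.focal_genes):
            cluster_rows.append((gene, FOCAL_SPECIES, cid))
            emit_hit(gene, fam, member=True)
        # non-focal voting members, all confident members of fam
        n_voters = int(rng.integers(3, 6))
        for v in range(n_voters):
            species = FOCAL_CLADE[1 + v % (len(FOCAL_CLADE) - 1)]
            gene = f"{prefix}v{v:02d}"
            cluster_rows.append((gene, species, cid))
            emit_hit(gene, fam, member=True)

    (out / "hits.tsv").write_text("\n".join(hit_lines) + "\n")
    with (out / "reference.tsv").open("w") as fh:
        fh.write("protein_id\tfamily\tcharacterized\tstructure_known\n")
        for pid, fam, cha, strk in ref_rows:
            fh.write(f"{pid}\t{fam}\t{cha}\t{strk}\n")
    with (out / "clusters.tsv").open("w") as fh:
        fh.write("gene_id\tspecies_id\tcluster_id\n")
        for gene, species, cid in cluster_rows:
            fh.write(f"{gene}\t{species}\t{cid}\n")
    with (out / "taxonomy.tsv").open("w") as fh:
        fh.write("species_id\tin_focal_clade\n")
        for sp in FOCAL_CLADE:
            fh.write(f"{sp}\t1\n")
        for sp in OUTSIDE_SPECIES:
            fh.write(f"{sp}\t0\n")
    return BundleTruth(
        seed=seed,
        membership=membership,
        family_per_cluster=family_per_cluster,
        partition_per_cluster=partition_per_cluster,
        subgroup_per_gene=subgroup_per_gene,
    )
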