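"""The curated CAZyme annotation table: parsing, validation, summaries.

The table lists every glycoside hydrolase (GH), carbohydrate esterase
(CE) and polysaccharide lyase (PL) gene of the annotated genome with its
name, CAZy family, free-text annotation, optional carbohydrate-binding
module, provenance tags, homology-cluster id and functional subgroup.
The packaged copy (``data/cazyme_annotation_table.tsv``) is the curated
reference table for *Trichoderma reesei*.

Provenance coding: a row whose reference column is the literal
``This study`` is a newly identified gene; a row carrying the standalone
token ``A`` after its citation tags had its annotation refined or newly
assigned.  A row is never counted as both.

Keyword counts are Unicode-aware (NFC-normalised, case-insensitive
substring), so "β-glucosidase" matches regardless of composition form.
"""

from __future__ import annotations

import re
import unicodedata
import warnings
from collections import defaultdict
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "AnnotationRow",
    "ANY_FAMILY",
    "bundled_table_path",
    "parse_annotation_table",
    "write_annotation_table",
    "count_by_class",
    "count_distinct_families",
    "count_multicluster_families",
    "count_provenance",
    "count_keyword",
    "summary_report",
]

ANY_FAMILY = "ANY"

_COLUMNS = ["gene_id", "name", "family", "annotation", "cbm", "ref", "cluster", "subgroup"]
_CLASS_RE = re.compile(r"^(GH|CE|PL)(\d*)$")
_CBM_RE = re.compile(r"^CBM\d+$")


@dataclass(frozen=True)
class AnnotationRow:
    """One line of the curated table; empty optional fields are None."""

    gene_id: str
    name: str | None
    family: str
    annotation: str
    cbm: str | None
    provenance: tuple[str, ...]
    cluster_id: str | None
    subgroup: str | None

    @property
    def family_class(self) -> str:
        return _CLASS_RE.match(self.family).group(1)

    @property
    def family_number(self) -> str:
        """Empty string for bare-class rows (family printed as just "GH")."""
        return _CLASS_RE.match(self.family).group(2)

    @property
    def is_new(self) -> bool:
        return self.provenance == ("This study",)

    @property
    def is_refined(self) -> bool:
        return "A" in self.provenance and not self.is_new


def bundled_table_path():
    """Path to the packaged curated annotation table."""
    return resources.files("cazymap").joinpath("data/cazyme_annotation_table.tsv")


def parse_annotation_table(path=None) -> list[AnnotationRow]:
    """Parse the eight-column TSV; defaults to the packaged curated table."""
    if path is None:
        with resources.as_file(bundled_table_path()) as p:
            frame = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    else:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"annotation table missing columns {missing}")
    rows: list[AnnotationRow] = []
    for rec in frame.itertuples(index=False):
        gene_id = rec.gene_id.strip()
        family = rec.family.strip()
        if not _CLASS_RE.match(family):
            raise ValueError(
                f"row {gene_id}: unknown family class in {family!r} (expected GH/CE/PL)"
            )
        cluster = rec.cluster.strip() or None
        subgroup = rec.subgroup.strip() or None
        if subgroup is not None:
            if cluster is not None and not subgroup.startswith(cluster):
                raise ValueError(
                    f"row {gene_id}: subgroup {subgroup!r} does not extend "
                    f"cluster id {cluster!r}"
                )
            if not re.search(r"[a-z]$", subgroup):
                warnings.warn(
                    f"row {gene_id}: subgroup {subgroup!r} lacks a letter suffix",
                    UserWarning,
                )
        provenance = tuple(
            tok.strip() for tok in rec.ref.split(",") if tok.strip()
        )
        rows.append(
            AnnotationRow(
                gene_id=gene_id,
                name=rec.name.strip() or None,
                family=family,
                annotation=unicodedata.normalize("NFC", rec.annotation.strip()),
                cbm=rec.cbm.strip() or None,
                provenance=provenance,
                cluster_id=cluster,
                subgroup=subgroup,
            )
        )
    return rows


def write_annotation_table(rows: list[AnnotationRow], path) -> None:
    frame = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "name": [r.name or "" for r in rows],
            "family": [r.family for r in rows],
            "annotation": [r.annotation for r in rows],
            "cbm": [r.cbm or "" for r in rows],
            "ref": [", ".join(r.provenance) for r in rows],
            "cluster": [r.cluster_id or "" for r in rows],
            "subgroup": [r.subgroup or "" for r in rows],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def count_by_class(rows: list[AnnotationRow]) -> tuple[dict[str, int], int]:
    """Gene counts per enzyme class (GH/CE/PL) and the total row count."""
    counts: dict[str, int] = defaultdict(int)
    for row in rows:
        counts[row.family_class] += 1
    return dict(counts), len(rows)


def count_distinct_families(rows: list[AnnotationRow]) -> int:
    """Distinct fully-specified family labels; bare-class rows excluded."""
    return len({r.family for r in rows if r.family_number})


def count_multicluster_families(
    rows: list[AnnotationRow],
) -> tuple[int, dict[str, int]]:
    """Families spread over more than one homology cluster.

    Returns (count of families with >= 2 clusters, family -> cluster count).
    """
    clusters: dict[str, set[str]] = defaultdict(set)
    for row in rows:
        if row.family_number and row.cluster_id is not None:
            clusters[row.family].add(row.cluster_id)
    per_family = {f: len(cs) for f, cs in clusters.items()}
    return sum(1 for n in per_family.values() if n >= 2), per_family


def count_provenance(rows: list[AnnotationRow]) -> dict[str, int]:
    """Counts of newly identified genes and refined annotations."""
    return {
        "new": sum(r.is_new for r in rows),
        "refined": sum(r.is_refined for r in rows),
    }


def count_keyword(rows: list[AnnotationRow], family: str, keyword: str) -> int:
    """Rows of ``family`` (or ANY) whose annotation contains ``keyword``.

    Matching is case-insensitive NFC-normalised substring.
    """
    needle = unicodedata.normalize("NFC", keyword).casefold()
    n = 0
    for row in rows:
        if family != ANY_FAMILY and row.family != family:
            continue
        if needle in row.annotation.casefold():
            n += 1
    return n


def summary_report(rows: list[AnnotationRow]) -> dict:
    """JSON-ready summary of all the standard counts."""
    by_class, total = count_by_class(rows)
    multi, per_family = count_multicluster_families(rows)
    provenance = count_provenance(rows)
    return {
        "genes_by_class": by_class,
        "genes_total": total,
        "distinct_families": count_distinct_families(rows),
        "multicluster_families": multi,
        "clusters_per_family": per_family,
        "new_genes": provenance["new"],
        "refined_annotations": provenance["refined"],
    }
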