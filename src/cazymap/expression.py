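"""Induction analysis of log2 expression data against time-matched controls.

The experimental design: a fungal culture is split and exposed to one of
ten lignocellulose-derived substrates (or mock-induced as a control);
samples are taken at fixed time points with four biological replicates
per condition.  Cultivations were run in two batches, each with its own
control series, so every contrast is computed within batch: the mean log2
signal of the induced replicates minus the mean of the control replicates
at the same time point.

Significance uses an empirical-Bayes moderated t-statistic: per-gene
pooled variances are shrunk toward a prior variance s0^2 with prior
degrees of freedom d0, both estimated across genes by method of moments
on the log variances (a scaled inverse-chi-square prior).  A gene is
called induced (+1) when p < 0.01 and the log2 fold change exceeds 0.4,
repressed (-1) symmetrically, and unchanged (0) otherwise.

Downstream summaries: the set of genes induced on at least one substrate,
the core set induced on both cellulose- and xylan-class substrates and on
at least 70 % of all substrates, per-family induced-gene count matrices,
maximal-induction profiles, and co-expression branches cut from a
hierarchical clustering of the fold-change profiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "SUBSTRATES",
    "TIMEPOINTS",
    "CONTROL",
    "ExpressionDataset",
    "read_expression_dataset",
    "fold_change_contrast",
    "moderated_variance",
    "moderated_t_p",
    "call_induction",
    "compute_contrasts",
    "induced_gene_set",
    "core_induced_set",
    "family_induction_matrix",
    "max_induction_profile",
    "cluster_coexpression_branches",
    "trigamma_inverse",
]

CONTROL = "CONTROL"
SUBSTRATES = ("BO", "BS", "BE", "XO", "XB", "AV1", "AV0.75", "WH", "SP", "SO")
TIMEPOINTS = (0, 6, 17, 41, 65)

SHEET_COLUMNS = ("sample_id", "substrate", "time_h", "replicate", "batch")


@dataclass
class ExpressionDataset:
    """Log2 signal matrix (genes x samples) plus its sample sheet."""

    values: pd.DataFrame
    sheet: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SHEET_COLUMNS if c not in self.sheet.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns {missing}")
        sheet_ids = list(self.sheet["sample_id"])
        matrix_ids = list(self.values.columns)
        if sorted(sheet_ids) != sorted(matrix_ids):
            orphans = set(sheet_ids) ^ set(matrix_ids)
            raise ValueError(f"sheet/matrix sample mismatch: {sorted(orphans)}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def substrates(self) -> list[str]:
        subs = self.sheet.loc[self.sheet["substrate"] != CONTROL, "substrate"]
        return sorted(subs.unique())

    def batch_of(self, substrate: str) -> int:
        batches = self.sheet.loc[self.sheet["substrate"] == substrate, "batch"].unique()
        if len(batches) != 1:
            raise ValueError(
                f"substrate {substrate!r} maps to batches {sorted(batches)}; expected one"
            )
        return int(batches[0])

    def stratum(self, substrate: str, time_h: int, batch: int | None = None) -> pd.DataFrame:
        """Columns of the matrix for one (substrate, time[, batch]) stratum."""
        mask = (self.sheet["substrate"] == substrate) & (self.sheet["time_h"] == time_h)
        if batch is not None:
            mask &= self.sheet["batch"] == batch
        ids = list(self.sheet.loc[mask, "sample_id"])
        if not ids:
            raise KeyError(
                f"missing stratum: substrate={substrate!r}, time_h={time_h}"
                + (f", batch={batch}" if batch is not None else "")
            )
        return self.values[ids]


def read_expression_dataset(matrix_path, sheet_path) -> ExpressionDataset:
    """Matrix: TSV/CSV, first column gene_id; sheet: TSV with the design columns."""
    sep = "," if str(matrix_path).endswith(".csv") else "\t"
    values = pd.read_csv(matrix_path, sep=sep, index_col=0)
    sheet = pd.read_csv(sheet_path, sep="\t", dtype={"substrate": str, "sample_id": str})
    sheet["time_h"] = sheet["time_h"].astype(int)
    return ExpressionDataset(values=values, sheet=sheet)


def fold_change_contrast(
    data: ExpressionDataset, gene: str, substrate: str, time_h: int
) -> float:
    """Mean log2 signal of induced replicates minus time-matched controls."""
    batch = data.batch_of(substrate)
    induced = data.stratum(substrate, time_h, batch)
    control = data.stratum(CONTROL, time_h, batch)
    return float(induced.loc[gene].mean() - control.loc[gene].mean())


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < 1e-8:
            break
    return float(x)


def moderated_variance(
    per_gene_variances: Sequence[float], df_per_gene: int
) -> tuple[float, float]:
    """Estimate the scaled inverse-chi-square prior (d0, s0^2) across genes.

    Method of moments on log variances: under the model, the corrected log
    variance e = log(s^2) - digamma(d/2) + log(d/2) has mean log(s0^2) +
    digamma(d0/2) - log(d0/2) and excess variance trigamma(d0/2) beyond
    the sampling term trigamma(d/2).  A non-positive excess is encoded as
    d0 = inf (complete shrinkage); identical variances shrink to exactly
    that common value.
    """
    s2 = np.asarray(per_gene_variances, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise ValueError("need at least two genes with positive variance")
    if df_per_gene < 1:
        raise ValueError("df_per_gene must be >= 1")
    d = float(df_per_gene)
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + math.log(d / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1))
    if evar == 0.0:
        return math.inf, float(np.exp(np.mean(z)))
    excess = evar - float(special.polygamma(1, d / 2.0))
    if excess <= 0.0:
        return math.inf, float(np.exp(emean))
    d0 = 2.0 * trigamma_inverse(excess)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)))
    return d0, s0_sq


def _moderated_t_arrays(
    x1: np.ndarray, x2: np.ndarray, d0: float, s0_sq: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised moderated t over rows (genes); x1, x2 are genes x replicates."""
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 replicates")
    dg = n1 + n2 - 2
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    ss1 = ((x1 - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((x2 - m2[:, None]) ** 2).sum(axis=1)
    sg_sq = (ss1 + ss2) / dg
    if math.isinf(d0):
        s_tilde_sq = np.full_like(sg_sq, s0_sq)
        df_total = math.inf
    else:
        s_tilde_sq = (d0 * s0_sq + dg * sg_sq) / (d0 + dg)
        df_total = d0 + dg
    se = np.sqrt(s_tilde_sq * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    zero_var = se == 0.0
    if zero_var.any():
        warnings.warn("zero posterior variance for some genes; p set to 0", RuntimeWarning)
        t = np.where(zero_var, np.where(diff >= 0, np.inf, -np.inf), t)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.where(zero_var, 0.0, p)
    return t, p


def moderated_t_p(
    group_induced: Sequence[float],
    group_control: Sequence[float],
    d0: float,
    s0_sq: float,
) -> tuple[float, float]:
    """Moderated two-sample t and its two-sided p-value for one gene.

    d0 = 0 reduces to the classical pooled two-sample t-test; d0 = inf
    uses the prior variance exactly with a normal reference distribution.
    """
    x1 = np.asarray(group_induced, dtype=float)[None, :]
    x2 = np.asarray(group_control, dtype=float)[None, :]
    t, p = _moderated_t_arrays(x1, x2, d0, s0_sq)
    return float(t[0]), float(p[0])


def call_induction(
    lfc: float, p_value: float, p_max: float = 0.01, lfc_min: float = 0.4
) -> int:
    """+1 induced / -1 repressed / 0 unchanged under the dual threshold.

    Both inequalities are strict: p < p_max and |lfc| > lfc_min.
    """
    if p_value < p_max:
        if lfc > lfc_min:
            return 1
        if lfc < -lfc_min:
            return -1
    return 0


def compute_contrasts(
    data: ExpressionDataset,
    p_max: float = 0.01,
    lfc_min: float = 0.4,
    moderation: str = "eb",
) -> pd.DataFrame:
    """All induced-vs-control contrasts, one row per (gene, substrate, time).

    ``moderation``: "eb" estimates (d0, s0^2) per contrast from all genes'
    pooled variances; "none" uses the plain pooled t (d0 = 0).

    Returns columns gene_id, substrate, time_h, lfc, t_stat, p_value, call.
    """
    if moderation not in ("eb", "none"):
        raise ValueError(f"unknown moderation {moderation!r}")
    frames = []
    genes = np.asarray(data.gene_ids)
    for substrate in data.substrates():
        batch = data.batch_of(substrate)
        times = sorted(
            data.sheet.loc[data.sheet["substrate"] == substrate, "time_h"].unique()
        )
        for time_h in times:
            x1 = data.stratum(substrate, int(time_h), batch).to_numpy(dtype=float)
            x2 = data.stratum(CONTROL, int(time_h), batch).to_numpy(dtype=float)
            n1, n2 = x1.shape[1], x2.shape[1]
            dg = n1 + n2 - 2
            if moderation == "eb":
                ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
                    (x2 - x2.mean(axis=1, keepdims=True)) ** 2
                ).sum(axis=1)
                d0, s0_sq = moderated_variance(ss / dg, dg)
            else:
                d0, s0_sq = 0.0, 0.0
            t, p = _moderated_t_arrays(x1, x2, d0, s0_sq)
            lfc = x1.mean(axis=1) - x2.mean(axis=1)
            calls = np.zeros(len(genes), dtype=int)
            sig = p < p_max
            calls[sig & (lfc > lfc_min)] = 1
            calls[sig & (lfc < -lfc_min)] = -1
            frames.append(
                pd.DataFrame(
                    {
                        "gene_id": genes,
                        "substrate": substrate,
                        "time_h": int(time_h),
                        "lfc": lfc,
                        "t_stat": t,
                        "p_value": p,
                        "call": calls,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def induced_gene_set(calls: pd.DataFrame) -> set[str]:
    """Genes with at least one +1 call on any non-control substrate."""
    mask = (calls["call"] == 1) & (calls["substrate"] != CONTROL)
    return set(calls.loc[mask, "gene_id"])


def core_induced_set(
    calls: pd.DataFrame,
    class_map: Mapping[str, str],
    fraction: float = 0.70,
) -> set[str]:
    """Genes induced on cellulose AND xylan class substrates, on >= 70 % of all.

    ``class_map`` maps each non-control substrate to "cellulose", "xylan"
    or "other"; the fraction threshold is ceil(fraction * n_substrates)
    distinct substrates with at least one +1 call.
    """
    substrates = sorted(set(calls["substrate"]) - {CONTROL})
    missing = [s for s in substrates if s not in class_map]
    if missing:
        raise KeyError(f"substrates missing from class_map: {missing}")
    need = math.ceil(fraction * len(substrates))
    induced = calls.loc[(calls["call"] == 1) & (calls["substrate"] != CONTROL)]
    per_gene = induced.groupby("gene_id")["substrate"].agg(set)
    core = set()
    for gene, subs in per_gene.items():
        classes = {class_map[s] for s in subs}
        if "cellulose" in classes and "xylan" in classes and len(subs) >= need:
            core.add(gene)
    return core


def family_induction_matrix(
    calls: pd.DataFrame, annotation: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-family induced-gene counts by substrate, plus per-substrate margins.

    A cell (family, substrate) counts the family's genes with a +1 call at
    any time on that substrate.  Genes absent from the annotation map are
    counted under UNASSIGNED with a warning.  The margins frame carries,
    per substrate, the induced-gene count and the number of families with
    at least one induced gene.
    """
    induced = calls.loc[(calls["call"] == 1) & (calls["substrate"] != CONTROL)]
    pairs = induced[["gene_id", "substrate"]].drop_duplicates()
    unknown = sorted(set(pairs["gene_id"]) - set(annotation))
    if unknown:
        warnings.warn(
            f"{len(unknown)} induced genes missing from annotation; counted as UNASSIGNED",
            RuntimeWarning,
        )
    pairs = pairs.assign(
        family=[annotation.get(g, "UNASSIGNED") for g in pairs["gene_id"]]
    )
    substrates = sorted(set(calls["substrate"]) - {CONTROL})
    matrix = (
        pairs.groupby(["family", "substrate"])["gene_id"]
        .nunique()
        .unstack(fill_value=0)
        .reindex(columns=substrates, fill_value=0)
    )
    margins = pd.DataFrame(
        {
            "n_genes_induced": [
                int(pairs.loc[pairs["substrate"] == s, "gene_id"].nunique())
                for s in substrates
            ],
            "n_families_induced": [
                int((matrix[s] > 0).sum()) if s in matrix.columns else 0
                for s in substrates
            ],
        },
        index=pd.Index(substrates, name="substrate"),
    )
    return matrix, margins


def max_induction_profile(calls: pd.DataFrame) -> pd.DataFrame:
    """Per (gene, substrate): the fold change at the time of maximal induction."""
    data = calls.loc[calls["substrate"] != CONTROL]
    return (
        data.groupby(["gene_id", "substrate"])["lfc"]
        .max()
        .unstack()
    )


def cluster_coexpression_branches(
    lfc_matrix: pd.DataFrame,
    k: int = 18,
    method: str = "complete",
    metric: str = "euclidean",
) -> tuple[dict[str, str], dict]:
    """Cut an agglomerative clustering of fold-change profiles into k branches.

    Branches are labelled A, B, ... in order of the first member gene in
    the input row order, so the labelling is deterministic given the input.
    Returns (gene -> branch label, linkage parameters used).
    """
    n = lfc_matrix.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    genes = list(lfc_matrix.index)
    if k == 1:
        return {g: "A" for g in genes}, {"method": method, "metric": metric, "k": k}
    values = lfc_matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("fold-change matrix contains non-finite values")
    link = hierarchy.linkage(pdist(values, metric=metric), method=method)
    flat = hierarchy.fcluster(link, t=k, criterion="maxclust")
    labels: dict[str, str] = {}
    branch_of: dict[int, str] = {}
    next_letter = 0
    for gene, cluster_idx in zip(genes, flat):
        if cluster_idx not in branch_of:
            branch_of[cluster_idx] = _branch_letter(next_letter)
            next_letter += 1
        labels[gene] = branch_of[cluster_idx]
    return labels, {"method": method, "metric": metric, "k": k}


def _branch_letter(index: int) -> str:
    out = ""
    index += 1
    while index > 0:
        index, rem = divmod(index - 1, 26)
        out = chr(ord("A") + rem) + out
    return out
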