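"""Single-embryo qPCR analysis: ΔCt expression, genotyping, clustering, correlation map.

Threshold cycles (Ct) from technical replicates are averaged over detected
replicates and converted to expression relative to an endogenous control
(Actb) as 2^(Ct_ref - Ct_gene); a gene undetected in every replicate has
expression 0. Embryos from a heterozygous intercross are genotyped from two
markers: the knocked-out gene itself (Cdx2, absent mRNA in homozygous
mutants) and the Neo selection cassette replacing it (absent in wild types,
dosage-proportional otherwise). Embryos cluster by correlation distance on
log expression, and each assayed gene is placed on a two-axis map of its
correlation with Cdx2 across single cells and across embryos.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "CtTable",
    "ClusterResult",
    "relative_expression",
    "classify_genotypes",
    "cluster_embryos",
    "cdx2_correlation_map",
]

UNDETECTED = "UNDET"
DEFAULT_EPS = 1e-3


@dataclass(frozen=True)
class CtTable:
    """Long-format qPCR table: one row per (embryo, gene, technical replicate).

    ``records`` has columns embryo_id, gene, replicate, ct; an undetected
    reaction is stored as NaN. Every (embryo, gene) pair carries the same
    number of technical replicates (3 by convention).
    """

    records: pd.DataFrame
    panel: tuple[str, ...]

    def __post_init__(self) -> None:
        required = {"embryo_id", "gene", "replicate", "ct"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"CtTable records missing columns: {sorted(missing)}")
        counts = self.records.groupby(["embryo_id", "gene"], sort=False).size()
        if counts.nunique() > 1:
            raise ValueError("unequal replicate counts across (embryo, gene) pairs")

    @property
    def embryos(self) -> list[str]:
        return list(pd.unique(self.records["embryo_id"]))

    def replicate_cts(self, embryo: str, gene: str) -> np.ndarray:
        sel = self.records[
            (self.records["embryo_id"] == embryo) & (self.records["gene"] == gene)
        ]
        return sel["ct"].to_numpy(dtype=float)

    def all_undetected(self) -> pd.DataFrame:
        """Embryos x genes boolean: True where every technical replicate is undetected."""
        flag = self.records.assign(undet=self.records["ct"].isna())
        wide = flag.pivot_table(
            index="embryo_id", columns="gene", values="undet", aggfunc="all", sort=False
        )
        return wide.astype(bool)

    def to_tsv(self, path: str | Path) -> None:
        df = self.records.copy()
        df["ct"] = df["ct"].map(lambda v: UNDETECTED if pd.isna(v) else f"{v:.4f}")
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, panel: Sequence[str] | None = None) -> "CtTable":
        df = pd.read_csv(path, sep="\t", dtype={"embryo_id": str, "gene": str})
        df["ct"] = pd.to_numeric(df["ct"].replace(UNDETECTED, np.nan), errors="raise")
        genes = tuple(panel) if panel is not None else tuple(pd.unique(df["gene"]))
        return cls(records=df, panel=genes)


def relative_expression(ct: CtTable, reference: str = "Actb") -> pd.DataFrame:
    """Embryos x genes expression relative to the reference gene.

    Per embryo and gene the Ct is the mean over detected replicates and
    expression is 2^(Ct_ref - Ct_gene); a gene with every replicate
    undetected gets expression 0 (so the reference itself is exactly 1
    everywhere). The reference must be detected (>= 1 replicate) in every
    embryo.
    """
    mean_ct = ct.records.pivot_table(
        index="embryo_id", columns="gene", values="ct", aggfunc="mean",
        sort=False, dropna=False,
    )
    if reference not in mean_ct.columns:
        raise ValueError(f"reference gene {reference!r} not in panel")
    ref = mean_ct[reference]
    bad = ref.index[ref.isna()]
    if len(bad):
        raise ValueError(f"reference {reference!r} undetected in embryo {bad[0]!r}")
    expr = np.power(2.0, ref.to_numpy()[:, None] - mean_ct.to_numpy())
    out = pd.DataFrame(expr, index=mean_ct.index, columns=mean_ct.columns)
    return out.fillna(0.0)


def classify_genotypes(
    expr: pd.DataFrame,
    ct: CtTable,
    cdx2_gene: str = "Cdx2",
    neo_gene: str = "Neo",
    negligible_frac: float = 0.01,
) -> pd.Series:
    """Per-embryo genotype call: null, het, wt, or ambiguous.

    null: the targeted gene's mRNA is undetected in every technical
    replicate AND the Neo cassette is clearly expressed (two mutant
    alleles). wt: Neo is negligible — undetected or below
    ``negligible_frac`` of the cohort median Neo expression. het: the
    residual class. An embryo with the target fully undetected AND
    negligible Neo contradicts the cross design and is flagged ambiguous.
    """
    for g in (cdx2_gene, neo_gene):
        if g not in expr.columns:
            raise ValueError(f"panel lacks required gene {g!r}")
    undet = ct.all_undetected()
    neo = expr[neo_gene]
    threshold = negligible_frac * float(neo.median())
    calls = {}
    for embryo in expr.index:
        cdx2_out = bool(undet.loc[embryo, cdx2_gene]) if cdx2_gene in undet.columns else False
        neo_negligible = (neo[embryo] == 0.0) or (neo[embryo] < threshold)
        if cdx2_out and neo_negligible:
            calls[embryo] = "ambiguous"
        elif cdx2_out:
            calls[embryo] = "null"
        elif neo_negligible:
            calls[embryo] = "wt"
        else:
            calls[embryo] = "het"
    out = pd.Series(calls, name="genotype")
    out.index.name = "embryo_id"
    return out


@dataclass(frozen=True)
class ClusterResult:
    """Agglomerative clustering of embryos on 1 - Pearson(log2 expression)."""

    linkage: np.ndarray
    ids: tuple[str, ...]

    def labels(self, k: int) -> pd.Series:
        lab = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(lab, index=list(self.ids), name="cluster")

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.ids[node.id]
            return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

        return rec(tree) + ";"


def _correlation_matrix(mat: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlation; rows with zero variance correlate 0."""
    sd = mat.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn("constant-expression rows: correlations set to 0", stacklevel=2)
    z = (mat - mat.mean(axis=1, keepdims=True)) / np.where(flat, 1.0, sd)[:, None]
    corr = z @ z.T / mat.shape[1]
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def cluster_embryos(expr: pd.DataFrame, eps: float = DEFAULT_EPS) -> ClusterResult:
    """Average-linkage hierarchical clustering on 1 - Pearson of log2(expr + eps).

    With a strong knockout effect, cutting the tree at k=2 separates null
    embryos from the rest. A constant-expression embryo would make Pearson
    undefined; its correlations are set to 0 with a warning.
    """
    if len(expr) < 3:
        raise ValueError("need >= 3 embryos to cluster")
    logv = np.log2(expr.to_numpy(dtype=float) + eps)
    corr = _correlation_matrix(logv)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    # exact symmetry for squareform
    dist = (dist + dist.T) / 2.0
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return ClusterResult(linkage=z, ids=tuple(expr.index))


def _pearson_with_anchor(mat: pd.DataFrame, anchor: str, eps: float, method: str) -> pd.Series:
    logv = np.log2(mat.to_numpy(dtype=float) + eps)
    df = pd.DataFrame(logv, index=mat.index, columns=mat.columns)
    if method == "spearman":
        df = df.rank(axis=0)
    x = df[anchor].to_numpy()
    out = {}
    xs = x.std()
    for gene in df.columns:
        y = df[gene].to_numpy()
        if xs == 0 or y.std() == 0:
            out[gene] = 0.0
        else:
            out[gene] = float(np.corrcoef(x, y)[0, 1])
    return pd.Series(out)


def cdx2_correlation_map(
    single_cell_expr: pd.DataFrame,
    embryo_expr: pd.DataFrame,
    anchor: str = "Cdx2",
    tau: float = 0.3,
    eps: float = DEFAULT_EPS,
    method: str = "pearson",
) -> pd.DataFrame:
    """Two-axis correlation map of every gene against the anchor gene.

    r_single_cell: correlation with the anchor across single cells (rows =
    cells); r_embryo: across embryos of the intercross cohort. Cluster
    labels by a quadrant rule with threshold tau: cluster 1 (positively
    regulated) r_sc > tau and r_emb > tau; cluster 3 (negatively regulated,
    the ICM/pluripotency pattern) r_emb < -tau; cluster 2 (parallel
    program) r_sc > tau with |r_emb| <= tau. Zero-variance genes get r = 0
    and no cluster.
    """
    if anchor not in single_cell_expr.columns or anchor not in embryo_expr.columns:
        raise ValueError(f"anchor gene {anchor!r} missing from an expression matrix")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    genes = [g for g in single_cell_expr.columns if g in embryo_expr.columns]
    r_sc = _pearson_with_anchor(single_cell_expr[genes], anchor, eps, method)
    r_emb = _pearson_with_anchor(embryo_expr[genes], anchor, eps, method)

    sc_flat = single_cell_expr[genes].std().to_numpy() == 0
    emb_flat = embryo_expr[genes].std().to_numpy() == 0
    clusters: list[object] = []
    for i, g in enumerate(genes):
        if sc_flat[i] or emb_flat[i]:
            clusters.append(None)
        elif r_sc[g] > tau and r_emb[g] > tau:
            clusters.append(1)
        elif r_emb[g] < -tau:
            clusters.append(3)
        elif r_sc[g] > tau and abs(r_emb[g]) <= tau:
            clusters.append(2)
        else:
            clusters.append(None)
    out = pd.DataFrame(
        {"r_single_cell": r_sc[genes].to_numpy(), "r_embryo": r_emb[genes].to_numpy(),
         "cluster": pd.array(clusters, dtype="Int64")},
        index=pd.Index(genes, name="gene"),
    )
    return out
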