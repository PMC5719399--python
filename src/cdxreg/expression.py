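"""Two-condition differential expression and the sliding-window association profile.

Differential expression follows a fold-change rule: a gene is called when
|log2 fold change| >= log2(cutoff) (default cutoff 2) and the p-value of a
Welch two-sample test on log2(value + pseudocount) is below alpha (default
0.05). No multiple-testing correction is applied. Ranking the genome by
fold change and averaging a TF's association scores in a sliding window of
genes (default 500) profiles how binding strength tracks expression change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import AssociationTable

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "WindowProfile",
    "fold_change_test",
    "de_genes",
    "rank_genome",
    "sliding_window_profile",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of linear-scale expression with condition labels."""

    values: pd.DataFrame
    sample_groups: Mapping[str, str]

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        unknown = set(self.sample_groups) - set(self.values.columns)
        if unknown:
            raise ValueError(f"sample_groups refers to unknown samples: {sorted(unknown)}")

    def group_columns(self, label: str) -> list[str]:
        cols = [s for s, g in self.sample_groups.items() if g == label]
        if not cols:
            raise ValueError(f"unknown group label {label!r}")
        return cols

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


@dataclass(frozen=True)
class WindowProfile:
    """Mean association score per sliding window over a fold-change-ranked genome."""

    window: int
    step: int
    centers: np.ndarray  # midpoint rank of each window (1-based ranks)
    means: np.ndarray

    def __post_init__(self) -> None:
        if len(self.centers) != len(self.means):
            raise ValueError("centers and means length mismatch")

    def __len__(self) -> int:
        return len(self.means)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"center_rank": self.centers, "mean_score": self.means}).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )


def fold_change_test(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene log2 fold change (A over B) and Welch-test p-value.

    log2fc = log2((meanA + pseudocount) / (meanB + pseudocount)) on linear
    values; the p-value comes from an unequal-variance two-sample t-test on
    log2(value + pseudocount). A degenerate test (zero variance in both
    groups with equal means) reports p = 1.
    """
    cols_a = matrix.group_columns(group_a)
    cols_b = matrix.group_columns(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each compared group needs >= 2 samples")
    va = matrix.values[cols_a].to_numpy(dtype=float)
    vb = matrix.values[cols_b].to_numpy(dtype=float)
    log2fc = np.log2(va.mean(axis=1) + pseudocount) - np.log2(vb.mean(axis=1) + pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(
            np.log2(va + pseudocount), np.log2(vb + pseudocount),
            axis=1, equal_var=False,
        )
    p = np.where(np.isfinite(p), p, 1.0)
    out = pd.DataFrame({"log2fc": log2fc, "p_value": p}, index=matrix.values.index)
    out.index.name = "gene_id"
    return out


def de_genes(
    results: pd.DataFrame,
    fc_cutoff: float = 2.0,
    alpha: float = 0.05,
) -> tuple[list[str], list[str]]:
    """Up- and down-regulated gene lists by the fold-change rule.

    up: log2fc >= log2(fc_cutoff) and p < alpha (fold-change boundary
    inclusive, alpha strict); down is symmetric. Lists are sorted by
    |log2fc| descending, ties by gene_id ascending.
    """
    thr = np.log2(fc_cutoff)
    sig = results["p_value"] < alpha

    def _ordered(mask: pd.Series) -> list[str]:
        sel = results.loc[mask].copy()
        sel["absfc"] = sel["log2fc"].abs()
        sel = sel.sort_index().sort_values("absfc", ascending=False, kind="stable")
        return list(sel.index)

    up = _ordered(sig & (results["log2fc"] >= thr))
    down = _ordered(sig & (results["log2fc"] <= -thr))
    return up, down


def rank_genome(results: pd.DataFrame) -> list[str]:
    """Genes ordered by descending log2 fold change; rank 1 = most up-regulated.

    Ties break by gene_id ascending. A non-finite fold change raises,
    naming the offending gene.
    """
    bad = results.index[~np.isfinite(results["log2fc"])]
    if len(bad):
        raise ValueError(f"non-finite fold change for gene {bad[0]!r}")
    ordered = results.sort_index().sort_values("log2fc", ascending=False, kind="stable")
    return list(ordered.index)


def sliding_window_profile(
    ranked: Sequence[str],
    table: AssociationTable,
    window: int = 500,
    step: int = 1,
) -> WindowProfile:
    """Mean association score in a sliding window over the ranked genome.

    Window w covers ranks [w*step + 1, w*step + window]; its center is the
    midpoint rank. Every ranked gene must be present in the table.
    """
    n = len(ranked)
    if not (0 < window <= n):
        raise ValueError(f"window={window} must be in [1, {n}]")
    if step < 1:
        raise ValueError("step must be >= 1")
    missing = [g for g in ranked if g not in table.scores.index]
    if missing:
        raise ValueError(f"gene {missing[0]!r} missing from association table")
    scores = table.scores.reindex(ranked).to_numpy(dtype=float)
    csum = np.concatenate([[0.0], np.cumsum(scores)])
    n_windows = (n - window) // step + 1
    starts = np.arange(n_windows) * step
    means = (csum[starts + window] - csum[starts]) / window
    centers = starts + (window + 1) / 2.0  # 1-based midpoint rank
    return WindowProfile(window=window, step=step, centers=centers, means=means)
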