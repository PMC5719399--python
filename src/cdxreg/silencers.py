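"""Genome-wide calling of candidate lineage-specific silencer elements.

A silencer candidate is a TF-binding peak that is also DNase-I
hypersensitive and lies in H3K27me3-enriched chromatin: the triple rule
TF ∩ DHS ∩ K27 under a configurable border-gap tolerance (default 0,
i.e. >=1 bp overlap or touching borders). The candidate's footprint is the
TF peak itself, carrying the nearest qualifying DHS and K27 witnesses.
Candidates are assigned to the gene whose TSS is closest to the candidate
midpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .intervals import (
    GeneModel,
    GenomicInterval,
    nearest_tss,
    triple_intersect,
)

logger = logging.getLogger(__name__)

__all__ = ["SilencerCandidate", "call_silencers", "assign_genes", "silencer_gene_summary"]


@dataclass(frozen=True)
class SilencerCandidate:
    """A TF-binding footprint with open-chromatin and repressive-mark evidence."""

    locus: GenomicInterval
    dhs_witness: GenomicInterval
    k27_witness: GenomicInterval
    assigned_gene: str | None = None
    signed_distance: int | None = None


def call_silencers(
    tf_peaks: Sequence[GenomicInterval],
    dhs: Sequence[GenomicInterval],
    k27: Sequence[GenomicInterval],
    max_gap: int = 0,
) -> list[SilencerCandidate]:
    """TF peaks overlapping at least one DHS and one H3K27me3 interval.

    Returns one candidate per qualifying TF peak, in coordinate order, with
    the nearest qualifying witnesses attached.
    """
    loci = triple_intersect(tf_peaks, dhs, k27, max_gap=max_gap)
    return [SilencerCandidate(t.locus, t.b_witness, t.c_witness) for t in loci]


def assign_genes(
    candidates: Sequence[SilencerCandidate],
    genes: Sequence[GeneModel],
) -> list[SilencerCandidate]:
    """Attach the nearest-TSS gene and signed midpoint distance to each candidate.

    Candidates on chromosomes with no annotated gene stay unassigned
    (assigned_gene None) rather than raising.
    """
    out = []
    for c in candidates:
        hit = nearest_tss(c.locus, genes)
        out.append(replace(c, assigned_gene=hit.gene_id, signed_distance=hit.signed_distance))
    return out


def silencer_gene_summary(candidates: Sequence[SilencerCandidate]) -> pd.DataFrame:
    """Per-gene candidate counts and minimal |distance|; genes with none are omitted."""
    rows = [
        (c.assigned_gene, abs(c.signed_distance))
        for c in candidates
        if c.assigned_gene is not None
    ]
    if not rows:
        return pd.DataFrame(columns=["gene_id", "n_candidates", "min_abs_distance"])
    df = pd.DataFrame(rows, columns=["gene_id", "dist"])
    summary = (
        df.groupby("gene_id")["dist"]
        .agg(n_candidates="size", min_abs_distance="min")
        .reset_index()
        .sort_values("gene_id", ignore_index=True)
    )
    return summary


def candidates_to_tsv(candidates: Sequence[SilencerCandidate], path: str | Path) -> None:
    rows = []
    for c in candidates:
        rows.append({
            "chrom": c.locus.chrom,
            "start": c.locus.start,
            "end": c.locus.end,
            "name": c.locus.name,
            "intensity": c.locus.intensity,
            "dhs": f"{c.dhs_witness.chrom}:{c.dhs_witness.start}-{c.dhs_witness.end}",
            "k27": f"{c.k27_witness.chrom}:{c.k27_witness.start}-{c.k27_witness.end}",
            "gene": c.assigned_gene if c.assigned_gene is not None else "unassigned",
            "signed_distance": c.signed_distance if c.signed_distance is not None else "NA",
        })
    pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "name", "intensity", "dhs", "k27", "gene",
        "signed_distance",
    ]).to_csv(path, sep="\t", index=False, float_format="%.10g")
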