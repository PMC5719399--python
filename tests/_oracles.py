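"""Independent brute-force oracles used to cross-check the library.

These implement each operation straight from its definition — exhaustive
pair/triple loops and dense per-gene sums — with none of the indexing or
windowing shortcuts of the library code.
"""

from __future__ import annotations

import math

import numpy as np


def gap(a, b) -> int:
    return max(0, b.start - a.end, a.start - b.end)


def brute_overlap(a, b, max_gap: int) -> bool:
    return a.chrom == b.chrom and gap(a, b) <= max_gap


def brute_co_occupied(A, B, max_gap: int):
    pairs = []
    for a in sorted(A):
        for b in sorted(B):
            if brute_overlap(a, b, max_gap):
                pairs.append((a, b))
    return pairs


def brute_triple_members(A, B, C, max_gap: int):
    """The A members satisfying the triple rule (witness choice not checked here)."""
    out = []
    for a in sorted(A):
        if any(brute_overlap(a, b, max_gap) for b in B) and any(
            brute_overlap(a, c, max_gap) for c in C
        ):
            out.append(a)
    return out


def brute_nearest_tss(locus, genes):
    mid = (locus.start + locus.end) // 2
    candidates = [g for g in genes if g.chrom == locus.chrom]
    if not candidates:
        return None, None
    best = min(candidates, key=lambda g: (abs(mid - g.tss), g.gene_id))
    signed = mid - best.tss if best.strand == "+" else best.tss - mid
    return best.gene_id, signed


def brute_association_score(gene, peaks, d0: float, max_dist: float) -> float:
    total = 0.0
    for p in peaks:
        if p.chrom != gene.chrom:
            continue
        d = abs((p.start + p.end) // 2 - gene.tss)
        if d <= max_dist:
            total += p.intensity * math.exp(-d / d0)
    return total


def dense_association_scores(genes, peaks, d0: float, max_dist: float) -> np.ndarray:
    """Dense matrix evaluation of every gene x peak pair, no spatial indexing."""
    scores = np.zeros(len(genes))
    if not peaks:
        return scores
    p_chrom = np.array([p.chrom for p in peaks])
    p_mid = np.array([(p.start + p.end) // 2 for p in peaks], dtype=np.int64)
    p_g = np.array([p.intensity for p in peaks])
    for i, gene in enumerate(genes):
        mask = p_chrom == gene.chrom
        d = np.abs(p_mid[mask] - gene.tss)
        keep = d <= max_dist
        scores[i] = np.sum(p_g[mask][keep] * np.exp(-d[keep] / d0))
    return scores
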