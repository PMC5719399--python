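"""TF-gene association scoring with exponential distance decay.

The association strength of a transcription factor on a gene is the
intensity-weighted sum over its ChIP peaks near the gene's TSS,

    a_i = sum_k g_k * exp(-d_k / D0),

where g_k is the peak intensity, d_k the distance from the peak midpoint to
the TSS, and D0 the decay length (default 10 kb, weighting enhancer/silencer
range peaks). Peaks farther than 1 Mb from the TSS are ignored. Ranking the
genome by this score and taking the top N (default 3000) defines the TF's
target set.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationTable",
    "association_score",
    "association_table",
    "top_targets",
    "target_set_overlap",
    "motif_density_profile",
    "IUPAC",
]

DEFAULT_D0 = 10_000
DEFAULT_MAX_DIST = 1_000_000
DEFAULT_TOP_N = 3000


@dataclass(frozen=True)
class AssociationTable:
    """Per-gene association scores for one TF.

    ``scores`` is indexed by gene_id and contains every annotated gene
    exactly once (0 for genes with no admissible peak).
    """

    scores: pd.Series
    tf_name: str = "TF"
    d0: float = DEFAULT_D0
    max_dist: float = DEFAULT_MAX_DIST

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates:
            raise ValueError("duplicate gene_id in association table")
        if (self.scores < 0).any():
            raise ValueError("association scores must be >= 0")

    def __len__(self) -> int:
        return len(self.scores)

    def ranked(self) -> pd.DataFrame:
        """Scores with 1-based rank: descending score, ties by gene_id ascending."""
        df = self.scores.rename("score").to_frame()
        # gene_id ascending first, then a stable sort on descending score,
        # so ties resolve alphabetically
        df = df.sort_index().sort_values("score", ascending=False, kind="stable")
        df.insert(1, "rank", np.arange(1, len(df) + 1))
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.ranked().to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def _peak_arrays(peaks: Sequence[GenomicInterval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (sorted midpoints, matching intensities)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    out = {}
    for chrom, ps in by_chrom.items():
        mids = np.array([p.midpoint for p in ps], dtype=np.int64)
        gs = np.array([p.intensity for p in ps], dtype=float)
        order = np.argsort(mids, kind="stable")
        out[chrom] = (mids[order], gs[order])
    return out


def association_score(
    gene: GeneModel,
    peaks: Sequence[GenomicInterval],
    d0: float = DEFAULT_D0,
    max_dist: float = DEFAULT_MAX_DIST,
) -> float:
    """Association score of one gene: sum of g_k * exp(-d_k/d0) over nearby peaks.

    d_k is |peak midpoint - TSS|; only peaks on the gene's chromosome with
    d_k <= max_dist contribute. Returns 0.0 when no peak qualifies.
    """
    if d0 <= 0 or max_dist <= 0:
        raise ValueError("d0 and max_dist must be positive")
    total = 0.0
    for p in peaks:
        if p.chrom != gene.chrom:
            continue
        d = abs(p.midpoint - gene.tss)
        if d <= max_dist:
            total += p.intensity * np.exp(-d / d0)
    return float(total)


def association_table(
    genes: Sequence[GeneModel],
    peaks: Sequence[GenomicInterval],
    d0: float = DEFAULT_D0,
    max_dist: float = DEFAULT_MAX_DIST,
    tf_name: str = "TF",
) -> AssociationTable:
    """Genome-wide association scores, one entry per annotated gene."""
    if d0 <= 0 or max_dist <= 0:
        raise ValueError("d0 and max_dist must be positive")
    if not genes:
        raise ValueError("empty gene annotation")
    arrays = _peak_arrays(peaks)
    scores = {}
    for g in genes:
        if g.chrom not in arrays:
            scores[g.gene_id] = 0.0
            continue
        mids, gs = arrays[g.chrom]
        lo = np.searchsorted(mids, g.tss - max_dist, side="left")
        hi = np.searchsorted(mids, g.tss + max_dist, side="right")
        d = np.abs(mids[lo:hi] - g.tss)
        keep = d <= max_dist
        scores[g.gene_id] = float(np.sum(gs[lo:hi][keep] * np.exp(-d[keep] / d0)))
    series = pd.Series(scores, name="score")
    series.index.name = "gene_id"
    return AssociationTable(series, tf_name=tf_name, d0=d0, max_dist=max_dist)


def top_targets(table: AssociationTable, n: int = DEFAULT_TOP_N) -> list[str]:
    """The n highest-scoring genes, score descending, ties by gene_id ascending."""
    if n > len(table):
        raise ValueError(f"n={n} exceeds genome size {len(table)}")
    return list(table.ranked().index[:n])


def target_set_overlap(
    set_a: Iterable[str], set_b: Iterable[str]
) -> tuple[int, int, int]:
    """(|A∩B|, |A\\B|, |B\\A|) for two target gene sets (Venn counts)."""
    a, b = set(set_a), set(set_b)
    return len(a & b), len(a - b), len(b - a)


# ---------------------------------------------------------------------------
# Motif density around binding sites
# ---------------------------------------------------------------------------

IUPAC: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _iupac_regex(consensus: str) -> str:
    try:
        return "".join(
            c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in consensus.upper()
        )
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC symbol {exc.args[0]!r} in consensus") from None


def _load_sequences(sequence: str | Path | Mapping[str, str]) -> Mapping[str, str]:
    if isinstance(sequence, Mapping):
        return {k: str(v).upper() for k, v in sequence.items()}
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(sequence), "fasta")}


def motif_density_profile(
    peaks: Sequence[GenomicInterval],
    sequence: str | Path | Mapping[str, str],
    consensus: str,
    window: int = 4000,
    bin_size: int = 100,
) -> pd.DataFrame:
    """Motif counts per bin across windows centered on peak midpoints.

    Exact IUPAC matches (both strands, no mismatches) are counted at their
    start position within [mid - window/2, mid + window/2), summed over
    peaks. Windows truncated at sequence ends contribute only the covered
    bins. Returns a DataFrame with bin_start_offset (relative to the peak
    midpoint) and count.
    """
    if not consensus:
        raise ValueError("consensus must be non-empty")
    if window % bin_size != 0:
        raise ValueError("window must be divisible by bin_size")
    seqs = _load_sequences(sequence)
    fwd = _iupac_regex(consensus)
    rev = _iupac_regex(consensus.upper().translate(_COMPLEMENT)[::-1])
    patterns = [re.compile(f"(?=({fwd}))")]
    if rev != fwd:
        patterns.append(re.compile(f"(?=({rev}))"))

    n_bins = window // bin_size
    half = window // 2
    counts = np.zeros(n_bins, dtype=np.int64)
    for peak in peaks:
        seq = seqs.get(peak.chrom)
        if seq is None:
            logger.warning("peak %s on %s absent from sequence; skipped",
                           peak.name or f"{peak.start}-{peak.end}", peak.chrom)
            continue
        wstart = peak.midpoint - half
        lo, hi = max(0, wstart), min(len(seq), wstart + window)
        if lo >= hi:
            continue
        # pad the scan region so matches starting in-window but extending past
        # it are still found
        sub = seq[lo : min(len(seq), hi + len(consensus) - 1)]
        for pat in patterns:
            for m in pat.finditer(sub):
                pos = lo + m.start()
                if pos < hi:
                    counts[(pos - wstart) // bin_size] += 1
    offsets = np.arange(n_bins) * bin_size - half
    return pd.DataFrame({"bin_start_offset": offsets, "count": counts})
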