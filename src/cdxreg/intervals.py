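"""Genomic interval model, BED/annotation I/O, and gap-tolerant intersection.

All coordinates are 0-based half-open (BED native). A "gap" between two
intervals on the same chromosome is the distance between their nearer
borders, with touching or overlapping intervals having gap 0; two intervals
are considered co-occupied when their gap does not exceed a configurable
tolerance (200 bp is the convention for peak co-occupancy, 0 for the
silencer triple rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "NearestGene",
    "TripleLocus",
    "read_bed",
    "write_bed",
    "read_genes",
    "write_genes",
    "interval_gap",
    "intervals_overlap",
    "co_occupied_loci",
    "triple_intersect",
    "nearest_tss",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) with an optional peak intensity."""

    chrom: str
    start: int
    end: int
    intensity: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.intensity < 0:
            raise ValueError(f"negative intensity {self.intensity} for {self.name!r}")

    @property
    def midpoint(self) -> int:
        """Integer midpoint, floor((start + end) / 2)."""
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, order=True)
class GeneModel:
    """A gene reduced to the anchor used for all distance computations: its TSS."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"negative TSS {self.tss} for {self.gene_id}")


class NearestGene(NamedTuple):
    """Nearest-TSS assignment; ``gene_id`` is None when no gene shares the chromosome."""

    gene_id: str | None
    signed_distance: int | None


class TripleLocus(NamedTuple):
    """An A-set interval with its nearest qualifying witnesses from sets B and C."""

    locus: GenomicInterval
    b_witness: GenomicInterval
    c_witness: GenomicInterval


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ records; column 4 is the name and column 5 the intensity.

    Returns intervals sorted by (chrom, start, end). Malformed lines raise
    ValueError with the 1-based line number.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 and fields[3] != "." else ""
                intensity = float(fields[4]) if len(fields) > 4 else 0.0
                out.append(GenomicInterval(chrom, start, end, intensity, name))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    out.sort()
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write BED6 (name '.', score = intensity, strand '.'); read_bed round-trips."""
    with open(path, "w") as fh:
        for iv in sorted(intervals):
            name = iv.name if iv.name else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{iv.intensity!r}\t.\n")


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read a gene annotation TSV with header gene_id, chrom, tss, strand."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["gene_id", "chrom", "tss", "strand"]
        if header[:4] != expected:
            raise ValueError(f"{path}: expected header {expected}, got {header[:4]}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields")
            gid = fields[0]
            if gid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gid!r}")
            seen.add(gid)
            genes.append(GeneModel(gid, fields[1], int(fields[2]), fields[3]))
    genes.sort()
    return genes


def write_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\n")
        for g in sorted(genes):
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\n")


# ---------------------------------------------------------------------------
# Intersection with gap tolerance
# ---------------------------------------------------------------------------

def interval_gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Distance between nearer borders on the same chromosome; 0 if touching/overlapping."""
    if a.chrom != b.chrom:
        raise ValueError("gap undefined across chromosomes")
    return max(0, b.start - a.end, a.start - b.end)


def intervals_overlap(a: GenomicInterval, b: GenomicInterval, max_gap: int = 0) -> bool:
    """True iff a and b share a chromosome and their border gap is <= max_gap.

    With max_gap=0 this admits touching intervals in addition to standard
    half-open overlap; the rule is symmetric in its arguments.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    return a.chrom == b.chrom and interval_gap(a, b) <= max_gap


def _build_trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def _query(trees: dict[str, IntervalTree], a: GenomicInterval, max_gap: int) -> list[GenomicInterval]:
    tree = trees.get(a.chrom)
    if tree is None:
        return []
    # envelope widened by max_gap+1: intervaltree uses strict half-open overlap,
    # while the gap rule admits equality (touching borders)
    hits = tree.overlap(a.start - max_gap - 1, a.end + max_gap + 1)
    return sorted(h.data for h in hits)


def co_occupied_loci(
    A: Sequence[GenomicInterval],
    B: Sequence[GenomicInterval],
    max_gap: int = 200,
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """All (a, b) pairs whose border gap is <= max_gap, ordered by a then b."""
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    trees = _build_trees(B)
    pairs: list[tuple[GenomicInterval, GenomicInterval]] = []
    for a in sorted(A):
        for b in _query(trees, a, max_gap):
            pairs.append((a, b))
    return pairs


def _nearest_witness(a: GenomicInterval, hits: Sequence[GenomicInterval]) -> GenomicInterval:
    return min(hits, key=lambda h: (abs(h.midpoint - a.midpoint), h.start, h.end, h.name))


def triple_intersect(
    A: Sequence[GenomicInterval],
    B: Sequence[GenomicInterval],
    C: Sequence[GenomicInterval],
    max_gap: int = 0,
) -> list[TripleLocus]:
    """Members of A overlapping (per the gap rule) at least one B and one C interval.

    Each returned locus records the nearest qualifying witness from B and C
    (by midpoint distance, ties by coordinates).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    b_trees = _build_trees(B)
    c_trees = _build_trees(C)
    loci: list[TripleLocus] = []
    for a in sorted(A):
        b_hits = _query(b_trees, a, max_gap)
        if not b_hits:
            continue
        c_hits = _query(c_trees, a, max_gap)
        if not c_hits:
            continue
        loci.append(TripleLocus(a, _nearest_witness(a, b_hits), _nearest_witness(a, c_hits)))
    return loci


def nearest_tss(locus: GenomicInterval, genes: Sequence[GeneModel]) -> NearestGene:
    """Assign a locus to the gene with the TSS closest to the locus midpoint.

    Distance is measured from floor((start+end)/2); the minimal absolute
    distance wins and equidistant TSSs resolve to the lexicographically
    smaller gene_id. The sign is negative when the midpoint lies 5' of the
    TSS in the gene's orientation (strand changes only the sign, never the
    magnitude). Returns NearestGene(None, None) when no gene shares the
    locus's chromosome.
    """
    mid = locus.midpoint
    best: GeneModel | None = None
    best_abs: int | None = None
    for g in genes:
        if g.chrom != locus.chrom:
            continue
        d = abs(mid - g.tss)
        if best_abs is None or d < best_abs or (d == best_abs and g.gene_id < best.gene_id):
            best, best_abs = g, d
    if best is None:
        return NearestGene(None, None)
    signed = mid - best.tss if best.strand == "+" else best.tss - mid
    return NearestGene(best.gene_id, signed)
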