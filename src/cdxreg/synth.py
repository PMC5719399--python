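"""Synthetic genomes, ChIP peaks, epigenomes, expression and qPCR cohorts.

Every generator is a pure function of its arguments and seed, and each
returns (or updates) a :class:`SyntheticTruth` describing the planted
structure, so downstream recovery — association ranking, silencer calling,
genotype classification, the correlation map — can be scored against known
ground truth. The defaults mirror the study conditions the pipeline is
meant to emulate: peaks decaying exponentially around target TSSs (mean
20 kb, all within 1 Mb), triple TF/DHS/H3K27me3 loci as planted silencers
with two-of-three decoys, two-condition expression with fold change tied to
regulatory sign, and a 27-embryo intercross cohort (6 null, 4 wild type,
rest heterozygous) assayed in technical triplicate with a Ct>28 detection
limit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .intervals import GeneModel, GenomicInterval
from .qpcr import CtTable

logger = logging.getLogger(__name__)

__all__ = [
    "Genome",
    "SyntheticTruth",
    "DEFAULT_PANEL",
    "PANEL_CLASSES",
    "gen_genome",
    "gen_peaks",
    "gen_epigenome",
    "gen_expression",
    "gen_embryo_ct",
    "gen_single_cells",
]

# gene classes for the qPCR panel: the knockout anchor, the selection
# cassette reporting mutant-allele dosage, the endogenous control, TE genes
# downstream of the anchor ("positive" on the correlation map), TE genes in
# a parallel program, and ICM/pluripotency genes repressed by the anchor
# ("negative")
PANEL_CLASSES: Mapping[str, str] = {
    "Cdx2": "anchor",
    "Neo": "cassette",
    "Actb": "reference",
    "Elf5": "positive",
    "Eomes": "positive",
    "Id2": "positive",
    "Lin28a": "positive",
    "Gata3": "parallel",
    "Krt8": "parallel",
    "Tead4": "parallel",
    "Pou5f1": "negative",
    "Nanog": "negative",
    "Sox2": "negative",
}
DEFAULT_PANEL: tuple[str, ...] = tuple(PANEL_CLASSES)

DETECTION_LIMIT_CT = 28.0


@dataclass(frozen=True)
class Genome:
    """A synthetic annotation: genes plus chromosome sizes."""

    genes: tuple[GeneModel, ...]
    chrom_sizes: Mapping[str, int]


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests.

    planted_targets maps gene_id -> regulatory sign (+1 up / -1 down under
    the TF); planted_silencers are the TF-peak footprints of triple loci;
    decoy_loci carry exactly two of the three marks; embryo_genotypes maps
    embryo id -> null/het/wt; gene_classes maps panel gene -> its designed
    correlation-map class.
    """

    rng_seed: int
    planted_targets: dict[str, int] = field(default_factory=dict)
    planted_silencers: list[GenomicInterval] = field(default_factory=list)
    decoy_loci: list[GenomicInterval] = field(default_factory=list)
    embryo_genotypes: dict[str, str] = field(default_factory=dict)
    gene_classes: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def iv(i: GenomicInterval) -> dict:
            return {"chrom": i.chrom, "start": i.start, "end": i.end,
                    "intensity": i.intensity, "name": i.name}

        payload = {
            "rng_seed": self.rng_seed,
            "planted_targets": self.planted_targets,
            "planted_silencers": [iv(i) for i in self.planted_silencers],
            "decoy_loci": [iv(i) for i in self.decoy_loci],
            "embryo_genotypes": self.embryo_genotypes,
            "gene_classes": self.gene_classes,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            rng_seed=d["rng_seed"],
            planted_targets={k: int(v) for k, v in d["planted_targets"].items()},
            planted_silencers=[GenomicInterval(**i) for i in d["planted_silencers"]],
            decoy_loci=[GenomicInterval(**i) for i in d["decoy_loci"]],
            embryo_genotypes=dict(d["embryo_genotypes"]),
            gene_classes=dict(d["gene_classes"]),
        )


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def gen_genome(
    n_chromosomes: int,
    chrom_length: int,
    n_genes: int,
    seed: int,
) -> Genome:
    """Uniformly placed TSSs (>=1 kb apart, on a 1 kb lattice) with random strands."""
    if n_chromosomes <= 0 or chrom_length <= 0 or n_genes < 2:
        raise ValueError("need n_chromosomes > 0, chrom_length > 0, n_genes >= 2")
    per_chrom = [n_genes // n_chromosomes + (1 if i < n_genes % n_chromosomes else 0)
                 for i in range(n_chromosomes)]
    if chrom_length < 10 * max(per_chrom) * 1000:
        raise ValueError("chrom_length too small for the requested gene density")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_genes)))
    genes: list[GeneModel] = []
    gid = 0
    chrom_sizes = {}
    slots = chrom_length // 1000
    for ci, g in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        chrom_sizes[chrom] = chrom_length
        # sorted draw from a reduced range + offset guarantees >=1-slot spacing
        base = np.sort(rng.choice(slots - g, size=g, replace=False))
        tss = (base + np.arange(g)) * 1000
        strands = rng.choice(["+", "-"], size=g)
        for t, s in zip(tss, strands):
            gid += 1
            genes.append(GeneModel(f"g{gid:0{width}d}", chrom, int(t), str(s)))
    return Genome(genes=tuple(genes), chrom_sizes=chrom_sizes)


# ---------------------------------------------------------------------------
# TF ChIP peaks
# ---------------------------------------------------------------------------

def _truncated_exponential(rng: np.random.Generator, mean: float, upper: float, size: int) -> np.ndarray:
    u = rng.random(size)
    return -mean * np.log1p(-u * (1.0 - np.exp(-upper / mean)))


def gen_peaks(
    genome: Genome,
    n_targets: int,
    intensity_law: tuple[float, float] = (2.0, 0.5),
    background_rate: float = 5.0,
    seed: int = 0,
    n_negative: int = 0,
    distance_mean: float = 20_000.0,
    max_distance: float = 1_000_000.0,
    peaks_per_target: tuple[int, int] = (1, 5),
    negative_peaks_per_target: tuple[int, int] = (1, 3),
    negative_intensity_scale: float = 0.4,
) -> tuple[list[GenomicInterval], SyntheticTruth]:
    """Peaks planted around target TSSs plus uniform background peaks.

    Each planted target receives 1-5 peaks (fewer for negative targets,
    with intensities scaled by ``negative_intensity_scale`` to model the
    moderate binding of repressed targets) at truncated-exponential
    distances from its TSS (mean 20 kb, all < 1 Mb). Intensities are
    lognormal with log-space parameters ``intensity_law``. Background peaks
    are Poisson-placed at ``background_rate`` per Mb.
    """
    genes = genome.genes
    if n_targets > len(genes):
        raise ValueError("n_targets exceeds number of genes")
    if not (0 <= n_negative <= n_targets):
        raise ValueError("need 0 <= n_negative <= n_targets")
    if background_rate < 0:
        raise ValueError("background_rate must be >= 0")
    rng = np.random.default_rng(seed)
    mu, sigma = intensity_law

    chosen = rng.choice(len(genes), size=n_targets, replace=False)
    signs = np.ones(n_targets, dtype=int)
    if n_negative:
        signs[rng.choice(n_targets, size=n_negative, replace=False)] = -1
    truth = SyntheticTruth(rng_seed=seed)
    peaks: list[GenomicInterval] = []
    pid = 0

    def add_peak(chrom: str, mid: int, intensity: float) -> None:
        nonlocal pid
        pid += 1
        half = int(rng.integers(100, 301))
        size = genome.chrom_sizes[chrom]
        mid = int(np.clip(mid, half, max(half + 1, size - half)))
        peaks.append(GenomicInterval(chrom, mid - half, mid + half,
                                     float(intensity), f"peak{pid:05d}"))

    for idx, sign in zip(chosen, signs):
        gene = genes[idx]
        truth.planted_targets[gene.gene_id] = int(sign)
        lo, hi = peaks_per_target if sign > 0 else negative_peaks_per_target
        k = int(rng.integers(lo, hi + 1))
        dists = _truncated_exponential(rng, distance_mean, max_distance, k)
        sides = rng.choice([-1, 1], size=k)
        gs = rng.lognormal(mu, sigma, size=k)
        if sign < 0:
            gs = gs * negative_intensity_scale
        for d, s, g in zip(dists, sides, gs):
            add_peak(gene.chrom, gene.tss + int(s * d), g)

    for chrom, size in genome.chrom_sizes.items():
        n_bg = int(rng.poisson(background_rate * size / 1e6))
        mids = rng.integers(0, size, size=n_bg)
        gs = rng.lognormal(mu, sigma, size=n_bg)
        for m, g in zip(mids, gs):
            add_peak(chrom, int(m), g)

    peaks.sort()
    return peaks, truth


# ---------------------------------------------------------------------------
# Epigenome: DHS + H3K27me3 marks with planted triple loci
# ---------------------------------------------------------------------------

_K27_PAD = 800       # K27 extends this far beyond its locus
_SEPARATION = 1_100  # minimum border gap isolating planted loci (>= 1 kb)


def _isolated_peaks(peaks: Sequence[GenomicInterval], min_gap: int) -> list[int]:
    """Indices of peaks whose border gap to every other peak is >= min_gap."""
    ordered = sorted(range(len(peaks)), key=lambda i: peaks[i])
    out = []
    for pos, i in enumerate(ordered):
        p = peaks[i]
        ok = True
        for q in (ordered[pos - 1] if pos else None,
                  ordered[pos + 1] if pos + 1 < len(ordered) else None):
            if q is None:
                continue
            other = peaks[q]
            if other.chrom == p.chrom and max(other.start - p.end, p.start - other.end) < min_gap:
                ok = False
        if ok:
            out.append(i)
    return out


def gen_epigenome(
    tf_peaks: Sequence[GenomicInterval],
    n_silencers: int,
    n_decoys: int,
    seed: int,
    genome: Genome | None = None,
    n_background_marks: int | None = None,
) -> tuple[list[GenomicInterval], list[GenomicInterval], SyntheticTruth]:
    """DHS and H3K27me3 mark sets with exactly ``n_silencers`` triple loci.

    Each planted silencer is a TF peak given an overlapping DHS and a
    broader K27 interval covering both. Decoys carry exactly two of the
    three marks (TF+DHS, TF+K27, or DHS+K27 away from any TF peak) and all
    planted loci are mutually separated by >= 1 kb, so the triple rule
    recovers the silencers unambiguously. Raises if the peak set cannot
    host the requested loci without violating the separation invariant.
    """
    if n_silencers < 0 or n_decoys < 0:
        raise ValueError("counts must be non-negative")
    if n_silencers + n_decoys > len(tf_peaks):
        raise ValueError("n_silencers + n_decoys exceeds the number of TF peaks")
    rng = np.random.default_rng(seed)
    sizes: dict[str, int] = dict(genome.chrom_sizes) if genome is not None else {}
    for p in tf_peaks:
        sizes.setdefault(p.chrom, 0)
        if genome is None:
            sizes[p.chrom] = max(sizes[p.chrom], p.end + 50_000)

    # decoy mix: as even a three-way split as possible
    base, rem = divmod(n_decoys, 3)
    n_tf_dhs, n_tf_k27, n_dhs_k27 = (base + (1 if r < rem else 0) for r in range(3))

    eligible = _isolated_peaks(tf_peaks, _SEPARATION)
    need_peaks = n_silencers + n_tf_dhs + n_tf_k27
    if len(eligible) < need_peaks:
        raise ValueError(
            f"cannot place {need_peaks} isolated loci: only {len(eligible)} TF peaks "
            f"are >= {_SEPARATION} bp from their neighbours"
        )
    picked = [eligible[i] for i in rng.permutation(len(eligible))[:need_peaks]]
    sil_idx = picked[:n_silencers]
    tf_dhs_idx = picked[n_silencers:n_silencers + n_tf_dhs]
    tf_k27_idx = picked[n_silencers + n_tf_dhs:]

    dhs: list[GenomicInterval] = []
    k27: list[GenomicInterval] = []
    truth = SyntheticTruth(rng_seed=seed)

    def dhs_for(p: GenomicInterval, tag: str) -> GenomicInterval:
        half = 150
        return GenomicInterval(p.chrom, max(0, p.midpoint - half), p.midpoint + half,
                               0.0, f"dhs_{tag}")

    def k27_for(p: GenomicInterval, tag: str) -> GenomicInterval:
        return GenomicInterval(p.chrom, max(0, p.start - _K27_PAD), p.end + _K27_PAD,
                               0.0, f"k27_{tag}")

    for j, i in enumerate(sil_idx):
        p = tf_peaks[i]
        dhs.append(dhs_for(p, f"sil{j:03d}"))
        k27.append(k27_for(p, f"sil{j:03d}"))
        truth.planted_silencers.append(p)
    for j, i in enumerate(tf_dhs_idx):
        p = tf_peaks[i]
        dhs.append(dhs_for(p, f"dec{j:03d}"))
        truth.decoy_loci.append(p)
    for j, i in enumerate(tf_k27_idx):
        p = tf_peaks[i]
        k27.append(k27_for(p, f"deck{j:03d}"))
        truth.decoy_loci.append(p)

    # positions that must be avoided by TF-free placements: every TF peak
    # (and planted loci), expanded by the separation margin plus K27 pad
    def far_from_tf(chrom: str, lo: int, hi: int) -> bool:
        margin = _SEPARATION
        for p in tf_peaks:
            if p.chrom == chrom and lo - margin < p.end and p.start < hi + margin:
                return False
        return True

    placed: list[tuple[str, int, int]] = []

    def place_locus(width: int, tag: str) -> GenomicInterval:
        chroms = sorted(sizes)
        for _ in range(5000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            size = sizes[chrom]
            if size < width + 2 * (_K27_PAD + _SEPARATION):
                continue
            start = int(rng.integers(_K27_PAD + _SEPARATION, size - width - _K27_PAD - _SEPARATION))
            lo, hi = start - _K27_PAD, start + width + _K27_PAD
            if not far_from_tf(chrom, lo, hi):
                continue
            if any(c == chrom and lo - _SEPARATION < e and s < hi + _SEPARATION
                   for c, s, e in placed):
                continue
            placed.append((chrom, lo, hi))
            return GenomicInterval(chrom, start, start + width, 0.0, tag)
        raise ValueError("cannot place TF-free loci without violating separation")

    for j in range(n_dhs_k27):
        locus = place_locus(300, f"dhs_deckd{j:03d}")
        dhs.append(locus)
        k27.append(GenomicInterval(locus.chrom, locus.start - _K27_PAD,
                                   locus.end + _K27_PAD, 0.0, f"k27_deckd{j:03d}"))
        truth.decoy_loci.append(locus)

    n_bg = n_background_marks if n_background_marks is not None else max(10, len(tf_peaks) // 10)
    for j in range(n_bg):
        dhs.append(place_locus(300, f"dhs_bg{j:03d}"))
    for j in range(n_bg):
        k27.append(place_locus(2000, f"k27_bg{j:03d}"))

    dhs.sort()
    k27.sort()

    # construction guarantee, verified exhaustively
    from .intervals import triple_intersect

    found = {t.locus for t in triple_intersect(sorted(tf_peaks), dhs, k27, max_gap=0)}
    if found != set(truth.planted_silencers):
        raise ValueError("placement failed to yield exactly the planted triple loci")
    return dhs, k27, truth


# ---------------------------------------------------------------------------
# Two-condition expression
# ---------------------------------------------------------------------------

def gen_expression(
    genome: Genome,
    truth: SyntheticTruth,
    n_reps: int = 3,
    effect_log2fc: float = 2.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    base_log2_mean: float = 7.0,
    base_log2_sd: float = 1.5,
) -> ExpressionMatrix:
    """Linear-scale genes x samples matrix for conditions A and B.

    Planted +1 targets are shifted up in condition A by ``effect_log2fc``
    (in log2), -1 targets down, all other genes are null; multiplicative
    lognormal noise with log2-scale sd ``noise_sd`` applies per cell.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in genome.genes]
    n = len(gene_ids)
    base = np.power(2.0, rng.normal(base_log2_mean, base_log2_sd, size=n))
    sign = np.array([truth.planted_targets.get(g, 0) for g in gene_ids], dtype=float)
    cols_a = [f"A_{i + 1}" for i in range(n_reps)]
    cols_b = [f"B_{i + 1}" for i in range(n_reps)]
    noise = np.power(2.0, rng.normal(0.0, noise_sd, size=(n, 2 * n_reps)))
    va = base[:, None] * np.power(2.0, sign * effect_log2fc)[:, None] * noise[:, :n_reps]
    vb = base[:, None] * noise[:, n_reps:]
    values = pd.DataFrame(np.hstack([va, vb]), index=pd.Index(gene_ids, name="gene_id"),
                          columns=cols_a + cols_b)
    groups = {c: "A" for c in cols_a} | {c: "B" for c in cols_b}
    return ExpressionMatrix(values=values, sample_groups=groups)


# ---------------------------------------------------------------------------
# Embryo qPCR cohort and single cells
# ---------------------------------------------------------------------------

# linear expression relative units by (gene class, genotype); two intact
# alleles express twice the single-allele level, nulls lack the target
# transcript entirely and carry two cassette copies
_LEVELS = {
    "reference": {"null": 1000.0, "het": 1000.0, "wt": 1000.0},
    "anchor": {"null": 0.0, "het": 16.0, "wt": 32.0},
    "cassette": {"null": 32.0, "het": 16.0, "wt": 0.0},
    "positive": {"null": 8.0, "het": 32.0, "wt": 32.0},
    "parallel": {"null": 32.0, "het": 32.0, "wt": 32.0},
    "negative": {"null": 32.0, "het": 16.0, "wt": 16.0},
}


def gen_embryo_ct(
    n_embryos: int = 27,
    n_null: int = 6,
    n_wt: int = 4,
    panel: Sequence[str] | None = None,
    seed: int = 0,
    n_replicates: int = 3,
    baseline_ct: float = 20.0,
    bio_sd: float = 0.3,
    reference_bio_sd: float = 0.05,
    tech_sd: float = 0.2,
    detection_limit: float = DETECTION_LIMIT_CT,
) -> tuple[CtTable, SyntheticTruth]:
    """A single-embryo qPCR cohort from a heterozygous intercross.

    Ct = baseline - log2(expression) + Normal(0, tech_sd) per technical
    replicate, with biological (per embryo-gene) lognormal variation of
    log2-sd ``bio_sd`` (smaller for the reference gene). Zero expression or
    Ct beyond the detection limit is recorded as undetected: nulls have the
    anchor gene undetected in every replicate and the cassette at two-copy
    level; wild types have no cassette signal; ICM genes run ~2-fold high
    and anchor-dependent TE genes low in nulls.
    """
    panel = tuple(panel) if panel is not None else DEFAULT_PANEL
    for required in ("Cdx2", "Neo", "Actb"):
        if required not in panel:
            raise ValueError(f"panel must contain {required!r}")
    if n_null + n_wt > n_embryos:
        raise ValueError("n_null + n_wt exceeds n_embryos")
    rng = np.random.default_rng(seed)
    genotypes = np.array(["null"] * n_null + ["wt"] * n_wt + ["het"] * (n_embryos - n_null - n_wt))
    genotypes = genotypes[rng.permutation(n_embryos)]
    width = max(2, len(str(n_embryos)))
    embryo_ids = [f"E{i + 1:0{width}d}" for i in range(n_embryos)]

    truth = SyntheticTruth(rng_seed=seed)
    truth.embryo_genotypes = dict(zip(embryo_ids, genotypes.tolist()))
    truth.gene_classes = {g: PANEL_CLASSES.get(g, "parallel") for g in panel}

    rows = []
    for embryo, gt in zip(embryo_ids, genotypes):
        for gene in panel:
            cls = truth.gene_classes[gene]
            level = _LEVELS[cls][str(gt)]
            sd = reference_bio_sd if cls == "reference" else bio_sd
            expr = level * float(np.power(2.0, rng.normal(0.0, sd)))
            for rep in range(1, n_replicates + 1):
                if level == 0.0:
                    ct_val = np.nan
                else:
                    ct_val = baseline_ct - np.log2(expr) + rng.normal(0.0, tech_sd)
                    if ct_val > detection_limit:
                        ct_val = np.nan
                rows.append((embryo, gene, rep, ct_val))
    records = pd.DataFrame(rows, columns=["embryo_id", "gene", "replicate", "ct"])
    return CtTable(records=records, panel=panel), truth


def gen_single_cells(
    n_cells: int = 60,
    te_fraction: float = 0.6,
    panel: Sequence[str] | None = None,
    noise_sd: float = 0.4,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Cells x genes expression for a wild-type blastocyst dissociation.

    Cells are TE or ICM; the anchor and both TE gene classes are high in TE
    cells, ICM genes high in ICM cells, the cassette absent. Returns the
    linear expression matrix and the per-cell lineage labels.
    """
    panel = tuple(panel) if panel is not None else DEFAULT_PANEL
    rng = np.random.default_rng(seed)
    n_te = int(round(n_cells * te_fraction))
    lineages = np.array(["TE"] * n_te + ["ICM"] * (n_cells - n_te))
    lineages = lineages[rng.permutation(n_cells)]
    levels = {
        "reference": {"TE": 1000.0, "ICM": 1000.0},
        "anchor": {"TE": 32.0, "ICM": 0.5},
        "cassette": {"TE": 0.0, "ICM": 0.0},
        "positive": {"TE": 32.0, "ICM": 1.0},
        "parallel": {"TE": 32.0, "ICM": 1.0},
        "negative": {"TE": 1.0, "ICM": 16.0},
    }
    width = max(2, len(str(n_cells)))
    cell_ids = [f"C{i + 1:0{width}d}" for i in range(n_cells)]
    data = np.zeros((n_cells, len(panel)))
    for j, gene in enumerate(panel):
        cls = PANEL_CLASSES.get(gene, "parallel")
        base = np.array([levels[cls][lin] for lin in lineages])
        data[:, j] = base * np.power(2.0, rng.normal(0.0, noise_sd, size=n_cells))
    expr = pd.DataFrame(data, index=pd.Index(cell_ids, name="cell_id"), columns=list(panel))
    labels = pd.Series(lineages, index=expr.index, name="lineage")
    return expr, labels
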