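"""End-to-end orchestration: simulate inputs, run every stage, write a manifest.

The pipeline composes the stages in the order the analysis runs: synthetic
inputs (or user-supplied files), genome-wide TF-gene association scores,
differential expression and the fold-change-ranked sliding-window profile,
peak co-occupancy, silencer calling with gene assignment, and the
single-embryo qPCR analysis. A machine-readable manifest records the
effective configuration, seed, and a checksum per artifact; a rerun with
the same configuration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import association, expression, qpcr, silencers, synth
from .intervals import read_bed, read_genes, write_bed, write_genes

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Every tunable of the analysis, defaulted to the study's printed values.

    d0=10 kb decay length, 1 Mb peak admission radius, top 3000 genes as
    the target set, 500-gene sliding window, 200 bp co-occupancy gap,
    fold-change cutoff 2 at alpha 0.05, correlation-map threshold 0.3.
    Simulation sizes are desk-scale defaults.
    """

    seed: int = 0
    d0: float = 10_000.0
    max_dist: float = 1_000_000.0
    top_n: int = 3000
    window: int = 500
    step: int = 1
    max_gap_cooccupancy: int = 200
    max_gap_silencer: int = 0
    fc_cutoff: float = 2.0
    alpha: float = 0.05
    tau: float = 0.3
    simulate: bool = True
    # simulation sizes
    n_chromosomes: int = 2
    chrom_length: int = 20_000_000
    n_genes: int = 1000
    n_targets: int = 200
    n_negative: int = 100
    background_rate: float = 5.0
    n_silencers: int = 20
    n_decoys: int = 40
    n_reps: int = 3
    effect_log2fc: float = 2.0
    noise_sd: float = 0.1
    n_embryos: int = 27
    n_null: int = 6
    n_wt: int = 4
    # input paths used when simulate is false
    paths: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Run every stage, write artifacts under outdir, return the manifest dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    cfg = config

    # --- inputs: simulate or load -----------------------------------------
    if cfg.simulate:
        @_stage("simulate")
        def _simulate():
            genome = synth.gen_genome(cfg.n_chromosomes, cfg.chrom_length,
                                      cfg.n_genes, seed=cfg.seed)
            peaks, truth = synth.gen_peaks(
                genome, cfg.n_targets, background_rate=cfg.background_rate,
                seed=cfg.seed + 1, n_negative=cfg.n_negative)
            dhs, k27, epi_truth = synth.gen_epigenome(
                peaks, cfg.n_silencers, cfg.n_decoys, seed=cfg.seed + 2, genome=genome)
            truth.planted_silencers = epi_truth.planted_silencers
            truth.decoy_loci = epi_truth.decoy_loci
            matrix = synth.gen_expression(
                genome, truth, n_reps=cfg.n_reps, effect_log2fc=cfg.effect_log2fc,
                noise_sd=cfg.noise_sd, seed=cfg.seed + 3)
            ct, emb_truth = synth.gen_embryo_ct(
                cfg.n_embryos, cfg.n_null, cfg.n_wt, seed=cfg.seed + 4)
            truth.embryo_genotypes = emb_truth.embryo_genotypes
            truth.gene_classes = emb_truth.gene_classes
            sc_expr, _ = synth.gen_single_cells(seed=cfg.seed + 5)

            write_genes(genome.genes, out / "genes.tsv")
            write_bed(peaks, out / "tf_peaks.bed")
            write_bed(dhs, out / "dhs.bed")
            write_bed(k27, out / "k27.bed")
            matrix.to_tsv(out / "expression.tsv")
            ct.to_tsv(out / "embryo_ct.tsv")
            sc_expr.to_csv(out / "single_cells.tsv", sep="\t", float_format="%.10g")
            truth.to_json(out / "truth.json")
            for n in ("genes.tsv", "tf_peaks.bed", "dhs.bed", "k27.bed",
                      "expression.tsv", "embryo_ct.tsv", "single_cells.tsv",
                      "truth.json"):
                artifacts[n] = out / n
            return genome.genes, peaks, dhs, k27, matrix, ct, sc_expr

        genes, peaks, dhs, k27, matrix, ct, sc_expr = _simulate()
    else:
        @_stage("load_inputs")
        def _load():
            p = {k: Path(v) for k, v in cfg.paths.items()}
            for key in ("genes", "tf_peaks", "dhs", "k27", "expression",
                        "embryo_ct", "single_cells"):
                if key not in p:
                    raise FileNotFoundError(f"missing input path {key!r}")
                if not p[key].exists():
                    raise FileNotFoundError(f"input {key!r} not found: {p[key]}")
            genes = read_genes(p["genes"])
            peaks = read_bed(p["tf_peaks"])
            dhs = read_bed(p["dhs"])
            k27 = read_bed(p["k27"])
            vals = pd.read_csv(p["expression"], sep="\t", index_col="gene_id")
            groups = {c: c.split("_")[0] for c in vals.columns}
            matrix = expression.ExpressionMatrix(values=vals, sample_groups=groups)
            ct = qpcr.CtTable.from_tsv(p["embryo_ct"])
            sc_expr = pd.read_csv(p["single_cells"], sep="\t", index_col=0)
            return genes, peaks, dhs, k27, matrix, ct, sc_expr

        genes, peaks, dhs, k27, matrix, ct, sc_expr = _load()

    # --- association -------------------------------------------------------
    @_stage("association")
    def _assoc():
        table = association.association_table(genes, peaks, d0=cfg.d0,
                                              max_dist=cfg.max_dist, tf_name="TF")
        table.to_tsv(out / "association.tsv")
        artifacts["association.tsv"] = out / "association.tsv"
        n = min(cfg.top_n, len(table))
        targets = association.top_targets(table, n=n)
        (out / "top_targets.txt").write_text("\n".join(targets) + "\n")
        artifacts["top_targets.txt"] = out / "top_targets.txt"
        return table, targets

    table, targets = _assoc()

    # --- differential expression and ranking -------------------------------
    @_stage("differential_expression")
    def _de():
        res = expression.fold_change_test(matrix, "A", "B")
        up, down = expression.de_genes(res, fc_cutoff=cfg.fc_cutoff, alpha=cfg.alpha)
        de = pd.DataFrame({
            "gene_id": up + down,
            "direction": ["up"] * len(up) + ["down"] * len(down),
        })
        de.to_csv(out / "de_genes.tsv", sep="\t", index=False)
        artifacts["de_genes.tsv"] = out / "de_genes.tsv"
        return res

    results = _de()

    # --- sliding-window profile --------------------------------------------
    @_stage("window_profile")
    def _profile():
        ranked = expression.rank_genome(results)
        window = min(cfg.window, len(ranked))
        profile = expression.sliding_window_profile(ranked, table,
                                                    window=window, step=cfg.step)
        profile.to_tsv(out / "window_profile.tsv")
        artifacts["window_profile.tsv"] = out / "window_profile.tsv"
        return profile

    _profile()

    # --- co-occupancy -------------------------------------------------------
    @_stage("cooccupancy")
    def _cooccupy():
        from .intervals import co_occupied_loci

        pairs = co_occupied_loci(peaks, dhs, max_gap=cfg.max_gap_cooccupancy)
        rows = [(a.chrom, a.start, a.end, a.name, b.chrom, b.start, b.end, b.name)
                for a, b in pairs]
        pd.DataFrame(rows, columns=["a_chrom", "a_start", "a_end", "a_name",
                                    "b_chrom", "b_start", "b_end", "b_name"]
                     ).to_csv(out / "cooccupied.tsv", sep="\t", index=False)
        artifacts["cooccupied.tsv"] = out / "cooccupied.tsv"

    _cooccupy()

    # --- silencers ----------------------------------------------------------
    @_stage("silencers")
    def _silencers():
        cands = silencers.call_silencers(peaks, dhs, k27, max_gap=cfg.max_gap_silencer)
        cands = silencers.assign_genes(cands, genes)
        silencers.candidates_to_tsv(cands, out / "silencers.tsv")
        artifacts["silencers.tsv"] = out / "silencers.tsv"
        summary = silencers.silencer_gene_summary(cands)
        summary.to_csv(out / "silencer_genes.tsv", sep="\t", index=False)
        artifacts["silencer_genes.tsv"] = out / "silencer_genes.tsv"

    _silencers()

    # --- embryo qPCR --------------------------------------------------------
    @_stage("embryos")
    def _embryos():
        expr = qpcr.relative_expression(ct)
        expr.to_csv(out / "embryo_expression.tsv", sep="\t", float_format="%.10g")
        artifacts["embryo_expression.tsv"] = out / "embryo_expression.tsv"
        calls = qpcr.classify_genotypes(expr, ct)
        calls.to_frame().to_csv(out / "genotypes.tsv", sep="\t")
        artifacts["genotypes.tsv"] = out / "genotypes.tsv"
        clust = qpcr.cluster_embryos(expr)
        (out / "dendrogram.nwk").write_text(clust.to_newick() + "\n")
        artifacts["dendrogram.nwk"] = out / "dendrogram.nwk"
        cmap = qpcr.cdx2_correlation_map(sc_expr, expr, tau=cfg.tau)
        cmap.to_csv(out / "correlation_map.tsv", sep="\t", float_format="%.10g",
                    na_rep="none")
        artifacts["correlation_map.tsv"] = out / "correlation_map.tsv"

    _embryos()

    # --- manifest -----------------------------------------------------------
    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "artifacts": {name: _sha256(path) for name, path in sorted(artifacts.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
    return manifest
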