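"""Generators: determinism, planted structure, and parameter validation."""

import numpy as np
import pytest

from cdxreg import (
    SyntheticTruth,
    association_table,
    call_silencers,
    gen_embryo_ct,
    gen_epigenome,
    gen_expression,
    gen_genome,
    gen_peaks,
)
from _oracles import brute_triple_members


class TestGenome:
    def test_counts_bounds_and_spacing(self):
        genome = gen_genome(1, 10_000_000, 100, seed=1)
        assert len(genome.genes) == 100
        tss = sorted(g.tss for g in genome.genes)
        assert all(0 <= t < 10_000_000 for t in tss)
        assert min(b - a for a, b in zip(tss, tss[1:])) >= 1000
        assert len({g.gene_id for g in genome.genes}) == 100
        assert {g.strand for g in genome.genes} <= {"+", "-"}

    def test_deterministic_for_fixed_seed(self):
        a = gen_genome(2, 10_000_000, 50, seed=1)
        b = gen_genome(2, 10_000_000, 50, seed=1)
        assert a.genes == b.genes and a.chrom_sizes == b.chrom_sizes

    def test_seed_changes_layout(self):
        a = gen_genome(1, 10_000_000, 100, seed=1)
        b = gen_genome(1, 10_000_000, 100, seed=2)
        assert [g.tss for g in a.genes] != [g.tss for g in b.genes]

    @pytest.mark.parametrize("args", [(0, 1_000_000, 10), (1, -5, 10), (1, 1_000_000, 1)])
    def test_rejects_nonpositive_sizes(self, args):
        with pytest.raises(ValueError):
            gen_genome(*args, seed=0)

    def test_rejects_overcrowded_chromosome(self):
        with pytest.raises(ValueError):
            gen_genome(1, 100_000, 50, seed=0)


class TestPeaks:
    def test_zero_targets_only_background(self, small_genome):
        peaks, truth = gen_peaks(small_genome, 0, seed=2)
        assert truth.planted_targets == {}
        assert all(p.intensity > 0 for p in peaks)

    def test_no_background_keeps_peaks_near_targets(self, small_genome):
        peaks, truth = gen_peaks(small_genome, 10, background_rate=0.0, seed=3)
        tss = {g.gene_id: (g.chrom, g.tss) for g in small_genome.genes}
        targets = [tss[g] for g in truth.planted_targets]
        for p in peaks:
            assert any(c == p.chrom and abs(p.midpoint - t) <= 1_000_000
                       for c, t in targets)

    def test_planted_targets_score_above_background(self, small_genome):
        peaks, truth = gen_peaks(small_genome, 30, seed=4)
        table = association_table(list(small_genome.genes), peaks)
        planted = table.scores[list(truth.planted_targets)]
        others = table.scores.drop(index=list(truth.planted_targets))
        assert planted.mean() > others.mean()
        # planted-structure recovery: planted genes rank better on median
        ranks = table.ranked()["rank"]
        assert ranks[list(truth.planted_targets)].median() < ranks[others.index].median()

    def test_negative_background_rate_rejected(self, small_genome):
        with pytest.raises(ValueError):
            gen_peaks(small_genome, 5, background_rate=-1.0, seed=0)

    def test_deterministic(self, small_genome):
        a, _ = gen_peaks(small_genome, 20, seed=9)
        b, _ = gen_peaks(small_genome, 20, seed=9)
        assert a == b


class TestEpigenome:
    def test_no_planted_loci_means_no_silencer_calls(self, small_genome):
        peaks, _ = gen_peaks(small_genome, 20, seed=5)
        dhs, k27, truth = gen_epigenome(peaks, 0, 0, seed=6, genome=small_genome)
        assert truth.planted_silencers == [] and truth.decoy_loci == []
        assert call_silencers(peaks, dhs, k27) == []

    def test_exact_triple_count_by_exhaustive_scan(self, small_genome):
        peaks, _ = gen_peaks(small_genome, 30, seed=7)
        dhs, k27, truth = gen_epigenome(peaks, 20, 40, seed=8, genome=small_genome)
        triples = brute_triple_members(peaks, dhs, k27, max_gap=0)
        assert len(triples) == 20
        assert set(triples) == set(truth.planted_silencers)
        assert len(truth.decoy_loci) == 40

    def test_planted_loci_are_separated(self, small_genome):
        peaks, _ = gen_peaks(small_genome, 30, seed=7)
        _, _, truth = gen_epigenome(peaks, 10, 20, seed=8, genome=small_genome)
        loci = sorted(truth.planted_silencers + truth.decoy_loci)
        for a, b in zip(loci, loci[1:]):
            if a.chrom == b.chrom:
                assert b.start - a.end >= 1000

    def test_deterministic_mark_coordinates(self, small_genome):
        peaks, _ = gen_peaks(small_genome, 30, seed=7)
        a = gen_epigenome(peaks, 10, 20, seed=8, genome=small_genome)
        b = gen_epigenome(peaks, 10, 20, seed=8, genome=small_genome)
        assert a[0] == b[0] and a[1] == b[1]

    def test_rejects_demand_beyond_peak_count(self, small_genome):
        peaks, _ = gen_peaks(small_genome, 2, background_rate=0.0, seed=5)
        with pytest.raises(ValueError):
            gen_epigenome(peaks, len(peaks), len(peaks), seed=6, genome=small_genome)


class TestExpression:
    def test_zero_effect_gives_unit_fold_change(self, small_genome):
        truth = SyntheticTruth(rng_seed=0, planted_targets={"g0001": 1})
        m = gen_expression(small_genome, truth, effect_log2fc=0.0, noise_sd=0.1, seed=9)
        ratio = m.values[["A_1", "A_2", "A_3"]].mean(axis=1) / \
            m.values[["B_1", "B_2", "B_3"]].mean(axis=1)
        assert np.abs(np.log2(ratio)).mean() < 0.2

    def test_all_values_positive_and_reproducible(self, small_genome):
        truth = SyntheticTruth(rng_seed=0)
        a = gen_expression(small_genome, truth, seed=10)
        b = gen_expression(small_genome, truth, seed=10)
        assert (a.values.to_numpy() > 0).all()
        assert a.values.equals(b.values)

    def test_invalid_parameters_rejected(self, small_genome):
        truth = SyntheticTruth(rng_seed=0)
        with pytest.raises(ValueError):
            gen_expression(small_genome, truth, noise_sd=-0.1)
        with pytest.raises(ValueError):
            gen_expression(small_genome, truth, n_reps=1)


class TestEmbryoCohort:
    def test_study_composition_27_6_4(self):
        _, truth = gen_embryo_ct(27, 6, 4, seed=7)
        counts = {g: list(truth.embryo_genotypes.values()).count(g)
                  for g in ("null", "wt", "het")}
        assert counts == {"null": 6, "wt": 4, "het": 17}

    def test_nulls_have_no_detectable_cdx2_and_wt_no_neo(self):
        ct, truth = gen_embryo_ct(27, 6, 4, seed=13)
        undet = ct.all_undetected()
        for embryo, gt in truth.embryo_genotypes.items():
            assert bool(undet.loc[embryo, "Cdx2"]) == (gt == "null")
            assert bool(undet.loc[embryo, "Neo"]) == (gt == "wt")

    def test_without_nulls_cdx2_always_detected(self):
        ct, _ = gen_embryo_ct(12, 0, 3, seed=14)
        assert not ct.all_undetected()["Cdx2"].any()

    def test_reference_always_detected_with_lowest_variance(self):
        ct, _ = gen_embryo_ct(27, 6, 4, seed=15)
        mean_ct = ct.records.pivot_table(index="embryo_id", columns="gene",
                                         values="ct", aggfunc="mean")
        assert mean_ct["Actb"].notna().all()
        variances = mean_ct.var().dropna()
        assert variances.idxmin() == "Actb"

    def test_missing_required_panel_gene_rejected(self):
        with pytest.raises(ValueError, match="Neo"):
            gen_embryo_ct(10, 2, 2, panel=("Actb", "Cdx2", "Nanog"), seed=0)

    def test_excess_genotype_demand_rejected(self):
        with pytest.raises(ValueError):
            gen_embryo_ct(5, 4, 3, seed=0)


class TestTruthSerialization:
    def test_json_round_trip(self, tmp_path, small_genome):
        peaks, truth = gen_peaks(small_genome, 10, seed=20)
        dhs, k27, epi = gen_epigenome(peaks, 5, 10, seed=21, genome=small_genome)
        truth.planted_silencers = epi.planted_silencers
        truth.decoy_loci = epi.decoy_loci
        _, emb = gen_embryo_ct(9, 2, 2, seed=22)
        truth.embryo_genotypes = emb.embryo_genotypes
        truth.gene_classes = emb.gene_classes
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = SyntheticTruth.from_json(path)
        assert back == truth
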