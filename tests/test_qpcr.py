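"""ΔCt expression, genotype classification, clustering, and the correlation map."""

import numpy as np
import pandas as pd
import pytest

from cdxreg import (
    CtTable,
    cdx2_correlation_map,
    classify_genotypes,
    cluster_embryos,
    gen_embryo_ct,
    gen_single_cells,
    relative_expression,
)
from cdxreg.qpcr import UNDETECTED


def make_ct(layout: dict, panel=("Actb", "Cdx2", "Neo")) -> CtTable:
    """layout: {embryo: {gene: [ct or None per replicate]}}"""
    rows = []
    for embryo, genes in layout.items():
        for gene, reps in genes.items():
            for i, v in enumerate(reps, start=1):
                rows.append((embryo, gene, i, np.nan if v is None else float(v)))
    df = pd.DataFrame(rows, columns=["embryo_id", "gene", "replicate", "ct"])
    return CtTable(records=df, panel=tuple(panel))


class TestRelativeExpression:
    def test_delta_ct_of_zero_gives_one(self):
        ct = make_ct({"E1": {"Actb": [10, 10, 10], "Cdx2": [10, 10, 10],
                             "Neo": [12, 12, 12]}})
        expr = relative_expression(ct)
        assert expr.loc["E1", "Cdx2"] == pytest.approx(1.0)

    def test_one_cycle_later_halves_expression(self):
        ct = make_ct({"E1": {"Actb": [10, 10, 10], "Cdx2": [11, 11, 11],
                             "Neo": [12, 12, 12]}})
        assert relative_expression(ct).loc["E1", "Cdx2"] == pytest.approx(0.5)

    def test_all_replicates_undetected_is_zero(self):
        ct = make_ct({"E1": {"Actb": [10, 10, 10], "Cdx2": [None, None, None],
                             "Neo": [12, 12, 12]}})
        assert relative_expression(ct).loc["E1", "Cdx2"] == 0.0

    def test_mixed_replicates_use_mean_of_detected(self):
        ct = make_ct({"E1": {"Actb": [10, 10, 10], "Cdx2": [14.0, 16.0, None],
                             "Neo": [12, 12, 12]}})
        # mean detected Ct = 15 -> 2^(10 - 15)
        assert relative_expression(ct).loc["E1", "Cdx2"] == pytest.approx(2.0 ** -5)

    def test_reference_is_exactly_one_everywhere(self):
        ct, _ = gen_embryo_ct(12, 3, 2, seed=3)
        expr = relative_expression(ct)
        assert (expr["Actb"] == 1.0).all()

    def test_undetected_reference_names_embryo(self):
        ct = make_ct({"E7": {"Actb": [None, None, None], "Cdx2": [10, 10, 10],
                             "Neo": [12, 12, 12]}})
        with pytest.raises(ValueError, match="E7"):
            relative_expression(ct)


class TestGenotypes:
    def _cohort(self):
        return make_ct({
            # Cdx2 absent, Neo strong -> null
            "E1": {"Actb": [10] * 3, "Cdx2": [None] * 3, "Neo": [14] * 3},
            # Neo absent -> wild type
            "E2": {"Actb": [10] * 3, "Cdx2": [15] * 3, "Neo": [None] * 3},
            # both present -> het
            "E3": {"Actb": [10] * 3, "Cdx2": [16] * 3, "Neo": [15] * 3},
            # contradictory: no Cdx2 and no Neo
            "E4": {"Actb": [10] * 3, "Cdx2": [None] * 3, "Neo": [None] * 3},
        })

    def test_rule_instantiation(self):
        ct = self._cohort()
        calls = classify_genotypes(relative_expression(ct), ct)
        assert calls.to_dict() == {"E1": "null", "E2": "wt", "E3": "het",
                                   "E4": "ambiguous"}

    def test_invariant_to_replicate_order(self):
        ct = self._cohort()
        shuffled = CtTable(
            records=ct.records.sample(frac=1.0, random_state=1).reset_index(drop=True),
            panel=ct.panel,
        )
        a = classify_genotypes(relative_expression(ct), ct)
        b = classify_genotypes(relative_expression(shuffled), shuffled)
        assert a.sort_index().equals(b.sort_index())

    def test_invariant_to_per_embryo_ct_shift(self):
        ct = self._cohort()
        shifted_records = ct.records.copy()
        mask = shifted_records["embryo_id"] == "E3"
        shifted_records.loc[mask, "ct"] += 2.5
        shifted = CtTable(records=shifted_records, panel=ct.panel)
        a = classify_genotypes(relative_expression(ct), ct)
        b = classify_genotypes(relative_expression(shifted), shifted)
        assert a.sort_index().equals(b.sort_index())

    def test_missing_required_gene_rejected(self):
        ct = make_ct({"E1": {"Actb": [10] * 3, "Cdx2": [15] * 3}},
                     panel=("Actb", "Cdx2"))
        with pytest.raises(ValueError, match="Neo"):
            classify_genotypes(relative_expression(ct), ct)

    def test_recovers_planted_genotypes(self):
        ct, truth = gen_embryo_ct(27, 6, 4, seed=7)
        calls = classify_genotypes(relative_expression(ct), ct)
        assert calls.to_dict() == truth.embryo_genotypes


class TestClustering:
    def test_identical_embryos_merge_first_at_height_zero(self):
        expr = pd.DataFrame(
            [[1.0, 8.0, 2.0, 5.0], [1.0, 8.0, 2.0, 5.0], [9.0, 1.0, 7.0, 0.5]],
            index=["E1", "E2", "E3"], columns=list("abcd"),
        )
        result = cluster_embryos(expr)
        first = result.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_cut_at_two_isolates_planted_nulls(self):
        ct, truth = gen_embryo_ct(27, 6, 4, seed=19)
        expr = relative_expression(ct)
        labels = cluster_embryos(expr).labels(k=2)
        nulls = {e for e, g in truth.embryo_genotypes.items() if g == "null"}
        groups = {lab: set(labels.index[labels == lab]) for lab in labels.unique()}
        assert nulls in groups.values()

    def test_permuting_embryo_order_preserves_partition(self):
        ct, _ = gen_embryo_ct(20, 5, 3, seed=23)
        expr = relative_expression(ct)
        perm = expr.sample(frac=1.0, random_state=5)
        a = cluster_embryos(expr).labels(k=3).sort_index()
        b = cluster_embryos(perm).labels(k=3).sort_index()
        # same partition up to relabelling
        mapping = {}
        for e in a.index:
            mapping.setdefault(a[e], set()).add(e)
        parts_a = {frozenset(v) for v in mapping.values()}
        mapping = {}
        for e in b.index:
            mapping.setdefault(b[e], set()).add(e)
        parts_b = {frozenset(v) for v in mapping.values()}
        assert parts_a == parts_b

    def test_constant_embryo_warns(self):
        expr = pd.DataFrame(
            [[2.0, 2.0, 2.0], [1.0, 5.0, 3.0], [4.0, 1.0, 2.0]],
            index=["flat", "E2", "E3"], columns=list("abc"),
        )
        with pytest.warns(UserWarning, match="constant"):
            cluster_embryos(expr)

    def test_newick_contains_every_embryo(self):
        ct, _ = gen_embryo_ct(8, 2, 2, seed=29)
        result = cluster_embryos(relative_expression(ct))
        nwk = result.to_newick()
        assert nwk.endswith(";") and all(e in nwk for e in result.ids)


class TestCorrelationMap:
    def test_anchor_duplicate_lands_in_cluster_one(self, rng):
        base = rng.lognormal(2, 1, size=30)
        sc = pd.DataFrame({"Cdx2": base, "dup": base,
                           "noise": rng.lognormal(2, 1, size=30)})
        emb = pd.DataFrame({"Cdx2": base[:10], "dup": base[:10],
                            "noise": rng.lognormal(2, 1, size=10)})
        cmap = cdx2_correlation_map(sc, emb)
        row = cmap.loc["dup"]
        assert row["r_single_cell"] == pytest.approx(1.0)
        assert row["r_embryo"] == pytest.approx(1.0)
        assert row["cluster"] == 1

    def test_log_anti_correlated_gene_is_cluster_three(self, rng):
        base = rng.lognormal(2, 1, size=20)
        anti = 1.0 / base  # log2 of anti is -log2(base), exact r = -1 for eps = 0
        sc = pd.DataFrame({"Cdx2": base, "g": base})
        emb = pd.DataFrame({"Cdx2": base, "g": anti})
        cmap = cdx2_correlation_map(sc, emb, eps=0.0)
        assert cmap.loc["g", "r_embryo"] == pytest.approx(-1.0)
        assert cmap.loc["g", "cluster"] == 3

    def test_zero_variance_gene_excluded(self, rng):
        vals = rng.lognormal(2, 1, size=15)
        sc = pd.DataFrame({"Cdx2": vals, "flat": np.ones(15)})
        emb = pd.DataFrame({"Cdx2": vals, "flat": vals})
        cmap = cdx2_correlation_map(sc, emb)
        assert cmap.loc["flat", "r_single_cell"] == 0.0
        assert pd.isna(cmap.loc["flat", "cluster"])

    def test_missing_anchor_rejected(self, rng):
        df = pd.DataFrame({"g": rng.lognormal(2, 1, size=5)})
        with pytest.raises(ValueError, match="Cdx2"):
            cdx2_correlation_map(df, df)

    def test_planted_classes_recovered(self):
        ct, truth = gen_embryo_ct(27, 6, 4, seed=41)
        emb = relative_expression(ct)
        sc, _ = gen_single_cells(seed=42)
        cmap = cdx2_correlation_map(sc, emb)
        designed = {"positive": 1, "parallel": 2, "negative": 3}
        planted = {g: designed[c] for g, c in truth.gene_classes.items()
                   if c in designed}
        hits = sum(1 for g, want in planted.items() if cmap.loc[g, "cluster"] == want)
        assert hits / len(planted) >= 0.9


class TestCtTableIO:
    def test_tsv_round_trip_preserves_undetected(self, tmp_path):
        ct, _ = gen_embryo_ct(6, 2, 1, seed=51)
        path = tmp_path / "ct.tsv"
        ct.to_tsv(path)
        back = CtTable.from_tsv(path)
        assert UNDETECTED in path.read_text()
        assert back.records["ct"].isna().equals(ct.records["ct"].isna())
        detected = ct.records["ct"].notna()
        assert np.allclose(back.records.loc[detected, "ct"],
                           ct.records.loc[detected, "ct"], atol=1e-4)

    def test_unequal_replicate_counts_rejected(self):
        df = pd.DataFrame({
            "embryo_id": ["E1", "E1", "E1", "E1", "E1"],
            "gene": ["Actb", "Actb", "Actb", "Cdx2", "Cdx2"],
            "replicate": [1, 2, 3, 1, 2],
            "ct": [10.0] * 5,
        })
        with pytest.raises(ValueError, match="replicate"):
            CtTable(records=df, panel=("Actb", "Cdx2"))
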