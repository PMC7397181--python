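"""ΔTU computation, empirical significance, switch calling, and the
switch-pair comparisons."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import isoloc as il
from isoloc.models import TranscriptModel
from isoloc.simulate import SimulationConfig

from conftest import make_expression
from _oracles import binomial_two_sided, fisher_two_sided


def _models_for(gene_tx: dict[str, list[str]], n_exons: int = 2):
    models = []
    for gene, tids in gene_tx.items():
        for t in tids:
            exons = tuple((i * 200, i * 200 + 100) for i in range(n_exons))
            models.append(TranscriptModel(t, gene, "chr1", "+", exons))
    return models


class TestComputeUsage:
    def test_arithmetic_forced_by_definition(self):
        # T=30, G=60 (cyto); T=10, G=50 (nuc) -> TU 0.5 and 0.2, dTU=0.3
        expr = make_expression({"cytoplasm_1": [30, 30], "nucleus_1": [10, 40]},
                               transcripts=["T1", "T2"])
        models = _models_for({"G1": ["T1", "T2"]})
        usage = il.compute_usage(expr, models)
        assert usage.loc["T1", "tu_cyto"] == pytest.approx(0.5)
        assert usage.loc["T1", "tu_nuc"] == pytest.approx(0.2)
        assert usage.loc["T1", "delta_tu"] == pytest.approx(0.3)

    def test_single_isoform_gene_has_unit_usage(self):
        expr = make_expression({"cytoplasm_1": [7.0], "nucleus_1": [3.0]},
                               transcripts=["T1"])
        usage = il.compute_usage(expr, _models_for({"G1": ["T1"]}))
        assert usage.loc["T1", "tu_cyto"] == 1.0
        assert usage.loc["T1", "delta_tu"] == 0.0

    def test_low_expression_genes_excluded_not_nan(self):
        expr = make_expression({"cytoplasm_1": [0.2, 0.2], "nucleus_1": [5, 5]},
                               transcripts=["T1", "T2"])
        usage = il.compute_usage(expr, _models_for({"G1": ["T1", "T2"]}))
        assert usage.empty

    def test_conservation_on_random_tables(self, rng):
        """Per gene and fraction sum(TU) = 1; per gene sum(dTU) = 0."""
        for _ in range(100):
            n_genes = int(rng.integers(2, 6))
            tx, genes = [], {}
            for g in range(n_genes):
                ts = [f"G{g}.t{i}" for i in range(rng.integers(1, 5))]
                genes[f"G{g}"] = ts
                tx.extend(ts)
            expr = make_expression(
                {"cytoplasm_1": rng.uniform(1, 50, len(tx)).tolist(),
                 "nucleus_1": rng.uniform(1, 50, len(tx)).tolist()},
                transcripts=tx)
            usage = il.compute_usage(expr, _models_for(genes))
            g = usage.groupby("gene_id")
            assert np.allclose(g["tu_cyto"].sum(), 1.0, atol=1e-9)
            assert np.allclose(g["tu_nuc"].sum(), 1.0, atol=1e-9)
            assert np.allclose(g["delta_tu"].sum(), 0.0, atol=1e-9)


class TestEmpiricalPvalues:
    def test_requires_replicates(self):
        expr = make_expression({"cytoplasm_1": [1.0, 2], "nucleus_1": [1, 2]},
                               transcripts=["T1", "T2"])
        with pytest.raises(ValueError, match="replicates"):
            il.empirical_pvalues(expr, _models_for({"G1": ["T1", "T2"]}))

    def test_zero_delta_tu_gets_p_one(self):
        expr = make_expression(
            {"cytoplasm_1": [10, 10], "cytoplasm_2": [12, 8],
             "nucleus_1": [10, 10], "nucleus_2": [8, 12]},
            transcripts=["T1", "T2"])
        usage = il.empirical_pvalues(expr, _models_for({"G1": ["T1", "T2"]}))
        # observed dTU is 0.0227..; construct an exactly-zero observation
        expr0 = make_expression(
            {"cytoplasm_1": [10, 10], "cytoplasm_2": [12, 8],
             "nucleus_1": [10, 10], "nucleus_2": [12, 8]},
            transcripts=["T1", "T2"])
        usage0 = il.empirical_pvalues(expr0, _models_for({"G1": ["T1", "T2"]}))
        assert (usage0["p_value"] == 1.0).all()
        assert (usage["p_value"] <= 1.0).all()

    def test_planted_switches_significant(self):
        cfg = SimulationConfig(n_genes=220, noise_cv=0.05, n_replicates=3,
                               frac_switching_genes=0.5, ri_nuclear_frac=0,
                               mono_nuclear_frac=0, switch_effect=0.5, seed=21)
        models, truth = il.simulate_annotation(cfg)
        expr = il.simulate_expression(models, truth, cfg)
        usage = il.empirical_pvalues(expr, models, seed=0)
        planted_p = [usage.loc[tc, "p_value"]
                     for tc, _, _ in truth.switching.values()]
        assert len(planted_p) >= 100
        assert np.mean(np.array(planted_p) < 0.05) >= 0.95

    def test_false_positive_rate_near_nominal(self):
        cfg = SimulationConfig(n_genes=500, noise_cv=0.05, n_replicates=3,
                               frac_switching_genes=0, ri_nuclear_frac=0,
                               seed=22)
        models, truth = il.simulate_annotation(cfg)
        expr = il.simulate_expression(models, truth, cfg)
        usage = il.empirical_pvalues(expr, models, seed=0)
        assert (usage["p_value"] < 0.05).mean() <= 0.07


class TestCallSwitches:
    def _usage(self, rows):
        df = pd.DataFrame(rows, columns=["transcript_id", "gene_id",
                                         "delta_tu", "p_value"])
        df = df.set_index("transcript_id")
        df["tu_cyto"] = 0.5
        df["tu_nuc"] = 0.5
        return df

    def test_pair_forced_by_thresholds(self):
        usage = self._usage([("T1", "G1", 0.5, 0.01), ("T2", "G1", -0.4, 0.02),
                             ("T3", "G1", 0.1, 0.3)])
        models = _models_for({"G1": ["T1", "T2", "T3"]})
        pairs = il.call_switches(usage, models)
        assert len(pairs) == 1
        assert pairs.iloc[0]["tc_id"] == "T1"
        assert pairs.iloc[0]["tn_id"] == "T2"

    def test_one_sided_gene_yields_no_pair(self):
        usage = self._usage([("T1", "G1", 0.5, 0.01), ("T2", "G1", -0.1, 0.5)])
        pairs = il.call_switches(usage, _models_for({"G1": ["T1", "T2"]}))
        assert pairs.empty

    def test_monotone_in_threshold_and_alpha(self, rng):
        rows = []
        for g in range(40):
            d = rng.uniform(-0.8, 0.8)
            rows += [(f"G{g}.t1", f"G{g}", d, rng.uniform(0, 0.2)),
                     (f"G{g}.t2", f"G{g}", -d, rng.uniform(0, 0.2))]
        usage = self._usage(rows)
        models = _models_for({f"G{g}": [f"G{g}.t1", f"G{g}.t2"]
                              for g in range(40)})
        n = [len(il.call_switches(usage, models, threshold=t, alpha=a))
             for t, a in [(0.2, 0.05), (0.3, 0.05), (0.4, 0.05),
                          (0.2, 0.01), (0.2, 0.001)]]
        assert n[0] >= n[1] >= n[2]
        assert n[0] >= n[3] >= n[4]

    def test_recovery_on_planted_fixture(self):
        cfg = SimulationConfig(n_genes=200, noise_cv=0.1, n_replicates=3,
                               frac_switching_genes=0.5, ri_nuclear_frac=0,
                               switch_effect=0.5, seed=23)
        models, truth = il.simulate_annotation(cfg)
        expr = il.simulate_expression(models, truth, cfg)
        usage = il.empirical_pvalues(expr, models, seed=0)
        pairs = il.call_switches(usage, models)
        called = set(pairs["gene_id"])
        tp = len(called & truth.switching_genes)
        assert tp / len(truth.switching_genes) >= 0.9
        assert tp / len(called) >= 0.9

    def test_antisymmetry_under_fraction_swap(self):
        cfg = SimulationConfig(n_genes=60, seed=24)
        models, truth = il.simulate_annotation(cfg)
        expr = il.simulate_expression(models, truth, cfg)
        u1 = il.empirical_pvalues(expr, models, seed=0)
        u2 = il.empirical_pvalues(expr.swap_fractions(), models, seed=0)
        assert np.allclose(u1["delta_tu"], -u2["delta_tu"], atol=1e-12)
        assert np.allclose(u1["p_value"], u2["p_value"], atol=1e-12)
        p1 = il.call_switches(u1, models)
        p2 = il.call_switches(u2, models)
        assert list(p1["tc_id"]) == list(p2["tn_id"])
        assert list(p1["tn_id"]) == list(p2["tc_id"])


class TestLengthRatioAndComparisons:
    def test_categories_and_binomial(self):
        pairs = pd.DataFrame({
            "gene_id": [f"G{i}" for i in range(40)],
            "tc_id": ["x"] * 40, "tn_id": ["y"] * 40,
            "category": ["positive"] * 30 + ["negative"] * 10})
        counts, test = il.classify_length_ratio(pairs)
        assert counts["positive"] == 30 and counts["negative"] == 10
        assert test.p_value == pytest.approx(binomial_two_sided(30, 40))

    def test_ratio_thresholds(self):
        models = [TranscriptModel("Tc", "G1", "chr1", "+", ((0, 4000),)),
                  TranscriptModel("Tn", "G1", "chr1", "+", ((0, 1000),)),
                  TranscriptModel("Ta", "G2", "chr1", "+", ((0, 500),)),
                  TranscriptModel("Tb", "G2", "chr1", "+", ((0, 500),))]
        usage = pd.DataFrame(
            {"gene_id": ["G1", "G1", "G2", "G2"],
             "delta_tu": [0.5, -0.5, 0.5, -0.5],
             "p_value": [0.01] * 4, "tu_cyto": 0.5, "tu_nuc": 0.5},
            index=["Tc", "Tn", "Ta", "Tb"])
        pairs = il.call_switches(usage, models)
        cat = dict(zip(pairs["gene_id"], pairs["category"]))
        assert cat == {"G1": "positive", "G2": "neutral"}
        ratios = dict(zip(pairs["gene_id"], pairs["length_ratio_log2"]))
        assert ratios["G1"] == pytest.approx(2.0)
        assert ratios["G2"] == pytest.approx(0.0)

    def test_exon_count_hand_table(self):
        models = []
        for i, (nc, nn) in enumerate([(5, 1), (6, 1), (7, 2)]):
            models += [TranscriptModel(f"c{i}", f"G{i}", "chr1", "+",
                                       tuple((j * 10, j * 10 + 5)
                                             for j in range(nc))),
                       TranscriptModel(f"n{i}", f"G{i}", "chr1", "+",
                                       tuple((j * 10, j * 10 + 5)
                                             for j in range(nn)))]
        pairs = pd.DataFrame({"gene_id": [f"G{i}" for i in range(3)],
                              "tc_id": [f"c{i}" for i in range(3)],
                              "tn_id": [f"n{i}" for i in range(3)],
                              "category": ["positive"] * 3})
        res = il.compare_exon_counts(pairs, models, "positive")
        # table (3,0;0,3): Fisher two-sided on margins 3,3,3
        assert res.p_value == pytest.approx(fisher_two_sided([[3, 0], [0, 3]]))

    def test_exon_counts_detected_within_category_on_fixture(self):
        """Unspliced nuclear isoforms put their switch pairs in the
        negative length category, where the cytoplasmic members carry more
        exons — Mood's median test detects it."""
        cfg = SimulationConfig(n_genes=150, mono_nuclear_frac=1.0,
                               ri_nuclear_frac=0, seed=27)
        models, truth = il.simulate_annotation(cfg)
        expr = il.simulate_expression(models, truth, cfg)
        usage = il.empirical_pvalues(expr, models, seed=0)
        pairs = il.call_switches(usage, models)
        assert (pairs["category"] == "negative").sum() >= 20
        res = il.compare_exon_counts(pairs, models, "negative")
        assert res.effect["median_x"] > res.effect["median_y"]
        assert res.p_value < 0.01

    def test_mono_multi_directions_on_fixture(self):
        cfg = SimulationConfig(n_genes=250, mono_nuclear_frac=0.4,
                               ri_nuclear_frac=0, seed=25)
        models, truth = il.simulate_annotation(cfg)
        expr = il.simulate_expression(models, truth, cfg)
        usage = il.empirical_pvalues(expr, models, seed=0)
        pairs = il.call_switches(usage, models)
        res = il.compare_mono_multi(usage, pairs, models)
        assert res.effect["mean_multi"] > 0 > res.effect["mean_mono"]
        assert res.p_value < 0.01

    def test_biotype_direction_and_significance(self):
        cfg = SimulationConfig(n_genes=250, noncoding_nuclear_prob=0.8,
                               seed=26)
        models, truth = il.simulate_annotation(cfg)
        expr = il.simulate_expression(models, truth, cfg)
        usage = il.empirical_pvalues(expr, models, seed=0)
        members = {t for tc, tn, _ in truth.switching.values()
                   for t in (tc, tn)}
        res = il.compare_biotype(usage.loc[usage.index.isin(members)], models)
        assert res.effect["median_x"] > res.effect["median_y"]  # coding > noncoding
        assert res.p_value < 0.01

    def test_single_biotype_skipped_with_warning(self):
        models = _models_for({"G1": ["T1", "T2"]})
        usage = pd.DataFrame({"gene_id": ["G1", "G1"],
                              "delta_tu": [0.1, -0.1]}, index=["T1", "T2"])
        with pytest.warns(UserWarning):
            assert il.compare_biotype(usage, models) is None


class TestNmd:
    def test_fold_change_definition(self):
        ctrl = make_expression({"cytoplasm_1": [10.0], "nucleus_1": [10.0]},
                               transcripts=["T1"])
        kd = make_expression({"cytoplasm_1": [40.0], "nucleus_1": [40.0]},
                             transcripts=["T1"])
        sens = il.nmd_sensitivity(ctrl, kd, pseudocount=0)
        assert sens["T1"] == pytest.approx(2.0)
        unchanged = il.nmd_sensitivity(ctrl, ctrl)
        assert unchanged["T1"] == pytest.approx(0.0)

    def test_mismatched_transcripts_rejected(self):
        a = make_expression({"cytoplasm_1": [1.0], "nucleus_1": [1.0]},
                            transcripts=["T1"])
        b = make_expression({"cytoplasm_1": [1.0], "nucleus_1": [1.0]},
                            transcripts=["T2"])
        with pytest.raises(ValueError):
            il.nmd_sensitivity(a, b)

    def test_localization_independent_decay_not_significant(self):
        """Decay multipliers drawn independently of Tc/Tn roles leave the
        Tc-vs-Tn comparison non-significant in >= 90% of seeds."""
        ns = 0
        for seed in range(20):
            cfg = SimulationConfig(n_genes=120, seed=400 + seed)
            models, truth = il.simulate_annotation(cfg)
            ctrl, kd = il.simulate_nmd(models, truth, cfg)
            sens = il.nmd_sensitivity(ctrl, kd)
            pairs = pd.DataFrame(
                [(g, tc, tn) for g, (tc, tn, _) in truth.switching.items()],
                columns=["gene_id", "tc_id", "tn_id"])
            res = il.compare_nmd(sens, pairs)
            ns += res.p_value >= 0.05
        assert ns >= 18


def test_shared_switching_genes_counts_runs():
    tables = [pd.DataFrame({"gene_id": ["A", "B"]}),
              pd.DataFrame({"gene_id": ["A", "C"]}),
              pd.DataFrame({"gene_id": ["A", "B"]})]
    shared = il.shared_switching_genes(tables, min_runs=2)
    assert set(shared.index) == {"A", "B"}
    assert shared["A"] == 3
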