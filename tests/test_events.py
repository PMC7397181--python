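"""Event classification against definitions and the junction-set oracle;
Ψ/ΔΨ quantification and nuclear-RI selection."""
import numpy as np
import pandas as pd
import pytest

import isoloc as il
from isoloc.models import TranscriptModel
from isoloc.simulate import SimulationConfig

from conftest import make_expression
from _oracles import oracle_event_kinds


def _tx(tid, exons, gene="G1", strand="+"):
    return TranscriptModel(tid, gene, "chr1", strand, tuple(exons))


class TestClassification:
    def test_skipped_exon_pair(self):
        t1 = _tx("t1", [(100, 200), (300, 400), (500, 600)])
        t2 = _tx("t2", [(100, 200), (500, 600)])
        events, residual = il.extract_events([t1, t2])
        assert [e.kind for e in events] == ["SE"]
        ev = events[0]
        assert ev.inclusion_transcripts == {"t1"}
        assert ev.exclusion_transcripts == {"t2"}
        assert residual.empty

    def test_retained_intron_pair(self):
        t1 = _tx("t1", [(100, 200), (300, 400)])
        t2 = _tx("t2", [(100, 400)])
        events, _ = il.extract_events([t1, t2])
        assert [e.kind for e in events] == ["RI"]
        ev = events[0]
        assert ev.coords == (200, 300)  # the intron interval itself
        assert ev.inclusion_transcripts == {"t2"}  # retaining isoform

    @pytest.mark.parametrize("strand,expected", [("+", "A3"), ("-", "A5")])
    def test_alternative_acceptor_strand_resolved(self, strand, expected):
        t1 = _tx("t1", [(100, 200), (300, 400)], strand=strand)
        t2 = _tx("t2", [(100, 200), (320, 400)], strand=strand)
        events, _ = il.extract_events([t1, t2])
        assert [e.kind for e in events] == [expected]
        # shorter intron (300 acceptor) is the inclusion form
        assert events[0].inclusion_transcripts == {"t1"}

    def test_mutually_exclusive_exons(self):
        t1 = _tx("t1", [(0, 100), (200, 300), (600, 700)])
        t2 = _tx("t2", [(0, 100), (400, 500), (600, 700)])
        events, _ = il.extract_events([t1, t2])
        assert [e.kind for e in events] == ["MX"]
        assert events[0].inclusion_transcripts == {"t1"}  # 5'-proximal exon

    def test_alternative_first_exon(self):
        t1 = _tx("t1", [(500, 600), (900, 1000)])
        t2 = _tx("t2", [(100, 200), (900, 1000)])
        events, _ = il.extract_events([t1, t2])
        assert [e.kind for e in events] == ["AF"]
        assert events[0].inclusion_transcripts == {"t2"}  # 5'-distal start

    def test_gene_wide_sets_use_all_isoforms(self):
        t1 = _tx("t1", [(100, 200), (300, 400), (500, 600)])
        t2 = _tx("t2", [(100, 200), (500, 600)])
        t3 = _tx("t3", [(0, 50), (100, 200), (300, 400), (500, 600)])
        events, _ = il.extract_events([t1, t2, t3])
        se = [e for e in events if e.kind == "SE"][0]
        assert se.inclusion_transcripts == {"t1", "t3"}
        assert se.exclusion_transcripts == {"t2"}

    def test_matches_junction_set_oracle_on_small_genes(self):
        """Rule classifier agrees with the exhaustive definition-level
        oracle on every generated two-isoform gene with <= 6 exons."""
        cfg = SimulationConfig(n_genes=300, n_exons_range=(3, 6),
                               mono_nuclear_frac=0, seed=31)
        models, truth = il.simulate_annotation(cfg)
        by_gene = il.group_by_gene(models)
        checked = 0
        for gene_id, txs in by_gene.items():
            if len(txs) != 2 or max(t.n_exons for t in txs) > 6:
                continue
            events, _ = il.extract_events(txs)
            got = {e.kind for e in events}
            expected = oracle_event_kinds(txs[0].exons, txs[1].exons,
                                          txs[0].strand)
            assert got == expected, gene_id
            checked += 1
        assert checked >= 200

    def test_planted_kind_recovery_at_scale(self):
        cfg = SimulationConfig(n_genes=1100, mono_nuclear_frac=0, seed=32)
        models, truth = il.simulate_annotation(cfg)
        events, _ = il.extract_events(models)
        by_gene_kind = {}
        for e in events:
            by_gene_kind.setdefault((e.gene_id, e.kind), []).append(e)
        assert len(truth.events) >= 1000
        hits = 0
        for pe in truth.events:
            found = by_gene_kind.get((pe.gene_id, pe.kind), [])
            if pe.kind == "RI":
                hits += any(tuple(e.coords) == tuple(pe.intron) for e in found)
            else:
                hits += bool(found)
        assert hits / len(truth.events) >= 0.99


class TestPsi:
    def _event(self):
        t1 = _tx("t1", [(100, 200), (300, 400)])
        t2 = _tx("t2", [(100, 400)])
        events, _ = il.extract_events([t1, t2])
        return events, [t1, t2]

    def test_inclusion_ratio_arithmetic(self):
        events, _ = self._event()
        expr = make_expression({"cytoplasm_1": [10.0, 30.0],
                                "nucleus_1": [10.0, 30.0]},
                               transcripts=["t1", "t2"])
        psi = il.compute_psi(events[0], expr, "cytoplasm")
        assert psi == pytest.approx(0.75)  # include=t2 (30) / total (40)

    def test_balanced_expression_gives_half_and_zero_delta(self):
        events, _ = self._event()
        expr = make_expression({"cytoplasm_1": [20.0, 20.0],
                                "nucleus_1": [20.0, 20.0]},
                               transcripts=["t1", "t2"])
        df = il.compute_delta_psi(events, expr)
        assert df.iloc[0]["psi_cyto"] == pytest.approx(0.5)
        assert df.iloc[0]["delta_psi"] == pytest.approx(0.0)

    def test_low_expression_events_skipped(self):
        events, _ = self._event()
        expr = make_expression({"cytoplasm_1": [0.1, 0.2],
                                "nucleus_1": [10.0, 10.0]},
                               transcripts=["t1", "t2"])
        df = il.compute_delta_psi(events, expr)
        assert df.empty

    def test_bounds_and_complementarity(self, rng):
        """Ψ in [0,1], ΔΨ in [-1,1]; swapping inclusion/exclusion maps
        ΔΨ to -ΔΨ; swapping fractions negates ΔΨ."""
        events, _ = self._event()
        ev = events[0]
        flipped = il.SpliceEvent(ev.event_id, ev.gene_id, ev.kind, ev.chrom,
                                 ev.strand, ev.coords,
                                 ev.exclusion_transcripts,
                                 ev.inclusion_transcripts)
        for _ in range(100):
            vals = rng.uniform(0.6, 50, size=4)
            expr = make_expression(
                {"cytoplasm_1": vals[:2].tolist(),
                 "nucleus_1": vals[2:].tolist()}, transcripts=["t1", "t2"])
            df = il.compute_delta_psi([ev], expr)
            if df.empty:
                continue
            row = df.iloc[0]
            assert 0 <= row["psi_cyto"] <= 1 and 0 <= row["psi_nuc"] <= 1
            assert -1 <= row["delta_psi"] <= 1
            flip = il.compute_delta_psi([flipped], expr).iloc[0]
            assert flip["delta_psi"] == pytest.approx(-row["delta_psi"])
            swap = il.compute_delta_psi([ev], expr.swap_fractions()).iloc[0]
            assert swap["delta_psi"] == pytest.approx(-row["delta_psi"])

    def test_planted_inclusion_shift_recovered(self):
        cfg = SimulationConfig(n_genes=220, event_mix={"RI": 1.0},
                               frac_switching_genes=0, mono_nuclear_frac=0,
                               ri_nuclear_frac=0.5, psi_effect=0.4,
                               noise_cv=0.1, seed=33)
        models, truth = il.simulate_annotation(cfg)
        expr = il.simulate_expression(models, truth, cfg)
        events, _ = il.extract_events(models)
        psi = il.compute_delta_psi(events, expr, seed=0)
        nuclear = truth.nuclear_ri_set()
        by_id = {e.event_id: e for e in events}
        planted = [row["delta_psi"] for _, row in psi.iterrows()
                   if (by_id[row["event_id"]].chrom,
                       *by_id[row["event_id"]].coords,
                       by_id[row["event_id"]].strand) in nuclear]
        assert len(planted) >= 100
        assert abs(np.mean(planted) - (-0.4)) < 0.05


class TestNuclearRiSelection:
    def test_threshold_rules(self):
        psi = pd.DataFrame({"event_id": ["a", "b", "c"],
                            "kind": ["RI", "RI", "SE"],
                            "delta_psi": [-0.4, -0.4, -0.5],
                            "p_value": [0.01, 0.2, 0.01]})
        nuclear, all_ri = il.select_nuclear_ris(psi)
        assert list(nuclear["event_id"]) == ["a"]
        assert list(all_ri["event_id"]) == ["a", "b"]

    def test_recovery_of_planted_nuclear_ris(self):
        cfg = SimulationConfig(n_genes=200, event_mix={"RI": 1.0},
                               frac_switching_genes=0, mono_nuclear_frac=0,
                               ri_nuclear_frac=0.5, psi_effect=0.4,
                               noise_cv=0.1, seed=34)
        models, truth = il.simulate_annotation(cfg)
        expr = il.simulate_expression(models, truth, cfg)
        events, _ = il.extract_events(models)
        psi = il.compute_delta_psi(events, expr, seed=0)
        nuclear, _ = il.select_nuclear_ris(psi)
        by_id = {e.event_id: e for e in events}
        got = {(by_id[eid].chrom, *by_id[eid].coords, by_id[eid].strand)
               for eid in nuclear["event_id"]}
        planted = truth.nuclear_ri_set()
        recall = len(got & planted) / len(planted)
        false_rate = len(got - planted) / max(1, len(got))
        assert recall >= 0.9
        assert false_rate <= 0.1


class TestPsiByKind:
    def test_single_kind_table(self):
        psi = pd.DataFrame({"event_id": list("abcde"), "kind": ["RI"] * 5,
                            "delta_psi": [-0.1, -0.2, 0.0, 0.1, -0.3],
                            "p_value": [0.5] * 5})
        table = il.psi_by_kind(psi)
        assert len(table) == 1
        assert table.iloc[0]["kind"] == "RI"

    def test_nuclear_bias_only_in_ri(self):
        cfg = SimulationConfig(n_genes=350, frac_switching_genes=0,
                               mono_nuclear_frac=0, ri_nuclear_frac=1.0,
                               psi_effect=0.4, seed=35)
        models, truth = il.simulate_annotation(cfg)
        expr = il.simulate_expression(models, truth, cfg)
        events, _ = il.extract_events(models)
        psi = il.compute_delta_psi(events, expr, seed=0)
        table = il.psi_by_kind(psi).set_index("kind")
        assert table.loc["RI", "median_delta_psi"] < -0.2
        others = table.drop(index="RI")
        assert others["median_delta_psi"].abs().max() < 0.05

    def test_all_null_medians_near_zero(self):
        cfg = SimulationConfig(n_genes=300, frac_switching_genes=0,
                               mono_nuclear_frac=0, ri_nuclear_frac=0,
                               seed=36)
        models, truth = il.simulate_annotation(cfg)
        expr = il.simulate_expression(models, truth, cfg)
        events, _ = il.extract_events(models)
        psi = il.compute_delta_psi(events, expr, seed=0)
        table = il.psi_by_kind(psi)
        assert table["median_delta_psi"].abs().max() < 0.05
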