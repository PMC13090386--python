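"""MAF strata, DE flagging, altered transcripts, enrichment tests, networks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rewirekit.celltype_enrichment import (
    DEFAULT_STRATA,
    ExpressionProfile,
    altered_transcripts,
    enrichment_test1,
    enrichment_test2,
    flag_de_genes,
    network_degree_stats,
    stratify_by_maf,
)
from rewirekit.core_model import Variant
from rewirekit.interaction_qc import filter_interactions
from rewirekit.rewiring_engine import RewiringEvent, enumerate_events
from rewirekit.synthetic_data import evaluate_recovery


def _event(maf=0.01, component="promoter", concordance="concordant",
           cohort="case_specific", gene="G1", variant_key=None):
    v = Variant(
        chrom="chr1", pos=100, end=101, ref="A", alt="G", maf=maf,
        genotypes={"P1": 1, "P2": 0, "P3": 0, "P4": 0},
    )
    key = variant_key or v.key
    return RewiringEvent(
        variant=v, interaction_key=(("chr1", 0, 800), ("chr1", 5000, 5600)),
        component=component, direction="GoI", concordance=concordance,
        cohort=cohort, carriers=frozenset({"P1"}), presence=frozenset({"P1"}),
        genes=(gene,),
    )


class TestStrata:
    @pytest.mark.parametrize(
        "maf, label", [(0.01, "MAFa"), (0.02, "MAFb"), (0.039, "MAFb"), (0.07, "MAFc")]
    )
    def test_half_open_binning(self, maf, label):
        out = stratify_by_maf([_event(maf=maf)])
        assert [len(v) for k, v in out.items() if k == label] == [1]

    def test_maf_at_or_above_cap_rejected(self):
        with pytest.raises(ValueError, match="upstream"):
            stratify_by_maf([_event(maf=0.10)])

    @given(st.lists(st.floats(0, 0.0999), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_strata_partition_all_events(self, mafs):
        events = [_event(maf=m) for m in mafs]
        out = stratify_by_maf(events)
        assert sum(len(v) for v in out.values()) == len(events)


class TestDeFlags:
    def _cells(self, rng, n_genes=30, n_cells=50, special=None):
        mats = {}
        for ct in ("CT1", "CT2", "CT3"):
            base = rng.lognormal(0, 0.3, size=(n_genes, n_cells))
            if special and ct == special[0]:
                base[special[1]] *= special[2]
            mats[ct] = pd.DataFrame(base, index=[f"G{i}" for i in range(n_genes)])
        return mats

    def test_exclusive_expression_is_flagged(self):
        rng = np.random.default_rng(1)
        mats = self._cells(rng)
        mats["CT2"].iloc[0] = 0.0
        mats["CT3"].iloc[0] = 0.0
        flags = flag_de_genes(mats)
        assert flags.loc["G0", "CT1"]
        assert not flags.loc["G0", "CT2"]

    def test_constant_gene_never_flagged(self):
        rng = np.random.default_rng(2)
        mats = self._cells(rng)
        for ct in mats:
            mats[ct].iloc[0] = 1.0  # identical in every cell of every type
        flags = flag_de_genes(mats)
        assert not flags.loc["G0"].any()

    def test_identically_distributed_genes_rarely_flagged(self):
        # under the global null the BH-controlled flag rate stays at/below 5%
        rng = np.random.default_rng(2)
        flags = flag_de_genes(self._cells(rng))
        assert flags.to_numpy().mean() <= 0.05

    def test_twofold_de_recovered_with_high_sensitivity(self):
        rng = np.random.default_rng(3)
        planted = np.arange(10)
        mats = self._cells(rng, n_genes=60, n_cells=100, special=("CT1", planted, 2.0))
        flags = flag_de_genes(mats)
        sensitivity = flags.iloc[planted]["CT1"].mean()
        assert sensitivity >= 0.9


class TestAlteredTranscripts:
    def _profile(self):
        mean = pd.DataFrame(
            {"CT1": [1.0, 0.0, 2.0], "CT2": [1.0, 1.0, 0.0]},
            index=["G1", "G2", "TF1"],
        )
        return ExpressionProfile(mean=mean)

    def test_expressed_gene_with_expressed_tf_included(self):
        ev = _event(gene="G1")
        out = altered_transcripts([ev], self._profile(), {ev.variant.key: ["TF1"]}, "CT1")
        assert out == {"G1"}

    def test_unexpressed_tf_excludes_gene(self):
        ev = _event(gene="G1")
        out = altered_transcripts([ev], self._profile(), {ev.variant.key: ["TF1"]}, "CT2")
        assert out == set()

    def test_unexpressed_gene_excluded(self):
        ev = _event(gene="G2")
        out = altered_transcripts([ev], self._profile(), {ev.variant.key: ["TF1"]}, "CT1")
        assert out == set()

    def test_event_without_motif_annotation_counted(self):
        ev = _event(gene="G1")
        counters = {}
        out = altered_transcripts([ev], self._profile(), {}, "CT1", counters=counters)
        assert out == set()
        assert counters["events_without_motif_annotation"] == 1

    def test_noiseless_planted_altered_set_recovered(self, default_bundle):
        b = default_bundle
        kept, _ = filter_interactions(b.interactions)
        events = enumerate_events(b.variants, kept, b.regions, b.cohort)
        target = b.truth_burden["target_cell_type"]
        out = altered_transcripts(events, b.expression, b.tf_map, target)
        expected = {
            r.gene
            for r in b.truth_events.itertuples()
            if r.concordance == "concordant"
            and b.expression.mean.loc[r.gene, target] > 0
            and b.expression.mean.loc[r.tf, target] > 0
        }
        assert out == expected


class TestEnrichment:
    def test_identical_cohort_behaviour_gives_unit_or(self, small_cohort):
        mean = pd.DataFrame({"CT1": [1.0, 1.0, 1.0], "CT2": [1.0, 1.0, 1.0]},
                            index=["G1", "G2", "TF1"])
        profile = ExpressionProfile(mean=mean)
        ev_case = _event(gene="G1", cohort="case_specific")
        ev_ctrl = _event(gene="G1", cohort="control_specific")
        tf_map = {ev_case.variant.key: ["TF1"]}
        rows = enrichment_test1([ev_case, ev_ctrl], profile, tf_map, small_cohort)
        mafa = [r for r in rows if r.stratum == "MAFa"]
        assert all(r.odds_ratio == pytest.approx(1.0) and r.p == 1.0 for r in mafa)

    def test_swapping_cohorts_inverts_odds_ratios(self, default_bundle):
        import dataclasses as dc
        b = default_bundle
        kept, _ = filter_interactions(b.interactions)
        events = enumerate_events(b.variants, kept, b.regions, b.cohort)
        rows = enrichment_test1(events, b.expression, b.tf_map, b.cohort)
        flip = {"case_specific": "control_specific", "control_specific": "case_specific"}
        swapped_events = [
            dc.replace(e, cohort=flip.get(e.cohort, e.cohort)) for e in events
        ]
        rows2 = enrichment_test1(swapped_events, b.expression, b.tf_map, b.cohort)
        by_key = {(r.cell_type, r.stratum): r for r in rows2}
        for r in rows:
            other = by_key[(r.cell_type, r.stratum)]
            if np.isfinite(r.odds_ratio) and r.odds_ratio > 0:
                assert other.odds_ratio == pytest.approx(1 / r.odds_ratio)

    def test_test2_classes_are_disjoint_rows(self, default_bundle):
        b = default_bundle
        kept, _ = filter_interactions(b.interactions)
        events = enumerate_events(b.variants, kept, b.regions, b.cohort)
        rows = enrichment_test2(events, b.expression, b.tf_map, b.cohort)
        keys = [(r.cell_type, r.stratum, r.concordance) for r in rows]
        assert len(keys) == len(set(keys))
        assert {r.concordance for r in rows} <= {"concordant", "discordant"}
        assert all(r.component == "enhancer" for r in rows)

    def test_planted_burden_cell_type_attains_minimum_q(self, default_bundle):
        b = default_bundle
        kept, _ = filter_interactions(b.interactions)
        events = enumerate_events(b.variants, kept, b.regions, b.cohort)
        rows = enrichment_test1(events, b.expression, b.tf_map, b.cohort)
        rep = evaluate_recovery(b, events, enrichment=rows)
        assert rep["burden_target_hit"]


class TestNetworkStats:
    def test_reported_degree_statistics(self):
        nodes = [f"n{i}" for i in range(200)]
        edges = [(nodes[i], nodes[(i + 1 + j) % 200]) for j in range(2) for i in range(137)]
        edges = edges[:273]
        assert network_degree_stats(nodes, edges) == (200, 273, 2.73)
        nodes2 = [f"m{i}" for i in range(103)]
        edges2 = [(nodes2[i], nodes2[(i + 1) % 103]) for i in range(74)]
        assert network_degree_stats(nodes2, edges2) == (103, 74, 1.44)

    def test_single_node_zero_degree(self):
        assert network_degree_stats(["a"], []) == (1, 0, 0.0)

    def test_duplicate_and_reversed_edges_deduplicated(self):
        assert network_degree_stats(["a", "b"], [("a", "b"), ("b", "a"), ("a", "b")]) == (2, 1, 1.0)

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            network_degree_stats(["a"], [("a", "a")])

    @given(
        n=st.integers(2, 30),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=40, deadline=None)
    def test_handshake_identity_on_random_graphs(self, n, seed):
        rng = np.random.default_rng(seed)
        nodes = [f"v{i}" for i in range(n)]
        edges = set()
        for _ in range(int(rng.integers(0, n * 2))):
            i, j = rng.integers(0, n, size=2)
            if i != j:
                edges.add((nodes[min(i, j)], nodes[max(i, j)]))
        n_nodes, n_edges, avg = network_degree_stats(nodes, list(edges))
        degree_sum = sum(
            sum(1 for e in edges if v in e) for v in nodes
        )
        assert avg == round(degree_sum / n_nodes, 2)
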