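"""Event classification, cohort specificity, Fisher statistics and summaries."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from rewirekit.core_model import Cohort, RegulatoryRegion, Variant
from rewirekit.interaction_qc import filter_interactions
from rewirekit.rewiring_engine import (
    ContingencyTable2x2,
    assign_cohort_specificity,
    classify_event,
    enumerate_events,
    fisher_two_tailed,
    goi_share_of_concordant,
    loi_goi_shares,
    rate_ratio,
    table1_summary,
)
from rewirekit.synthetic_data import SimConfig, simulate_cohort
from tests.test_interaction_qc import make_interaction

P16 = {f"P{i}" for i in range(16)}


class TestClassify:
    def test_single_carrier_with_matching_presence_is_concordant_goi(self):
        assert classify_event({"P1"}, {"P1"}, P16) == ("GoI", "concordant")

    def test_presence_on_all_noncarriers_is_concordant_loi(self):
        assert classify_event({"P1"}, P16 - {"P1"}, P16) == ("LoI", "concordant")

    def test_presence_spanning_both_classes_is_discordant(self):
        direction, conc = classify_event({"P1", "P2"}, {"P1", "P3"}, P16)
        assert conc == "discordant"

    def test_presence_subset_of_carriers_is_concordant_goi(self):
        # subset semantics: not every carrier needs to show the interaction
        assert classify_event({"P1", "P2"}, {"P1"}, P16) == ("GoI", "concordant")

    def test_equality_semantics_demotes_proper_subsets(self):
        assert classify_event({"P1", "P2"}, {"P1"}, P16, concordance="equality") == (
            "GoI", "discordant",
        )
        assert classify_event({"P1"}, {"P1"}, P16, concordance="equality") == (
            "GoI", "concordant",
        )

    def test_uninformative_carrier_sets_yield_no_event(self):
        assert classify_event(set(), {"P1"}, P16) is None
        assert classify_event(set(P16), {"P1"}, P16) is None

    def test_exhaustive_enumeration_partitions_the_domain(self):
        """All (carriers, presence) pairs over 4 patients: the classifier is
        total and its three outcomes match the set predicate directly."""
        patients = frozenset({"A", "B", "C", "D"})
        subsets = [
            frozenset(c)
            for r in range(5)
            for c in itertools.combinations(sorted(patients), r)
        ]
        n_checked = 0
        for carriers in subsets:
            for presence in subsets:
                if not presence:
                    continue
                if not carriers or carriers == patients:
                    assert classify_event(set(carriers), set(presence), set(patients)) is None
                    continue
                direction, conc = classify_event(set(carriers), set(presence), set(patients))
                non = patients - carriers
                if presence <= carriers:
                    assert (direction, conc) == ("GoI", "concordant")
                elif presence <= non:
                    assert (direction, conc) == ("LoI", "concordant")
                else:
                    assert conc == "discordant"
                    rate_c = len(presence & carriers) / len(carriers)
                    rate_n = len(presence & non) / len(non)
                    assert direction == ("GoI" if rate_c >= rate_n else "LoI")
                n_checked += 1
        assert n_checked > 150


class TestSpecificity:
    def test_three_outcomes(self, small_cohort):
        assert assign_cohort_specificity({"P1", "P2"}, small_cohort) == "case_specific"
        assert assign_cohort_specificity({"P3"}, small_cohort) == "control_specific"
        assert assign_cohort_specificity({"P1", "P3"}, small_cohort) == "shared"


class TestEnumerate:
    def _setup(self, small_cohort):
        prom = RegulatoryRegion("chr1", 0, 800, "promoter", gene_ids=("G1",))
        pir = RegulatoryRegion("chr1", 100_000, 100_600, "enhancer")
        interaction = make_interaction(patient="P1", prom_start=0, pir_start=100_000)
        regions = [prom, pir]
        return prom, pir, interaction, regions

    def test_variant_in_pir_of_carrier_only_interaction(self, small_cohort):
        prom, pir, interaction, regions = self._setup(small_cohort)
        v = Variant(
            chrom="chr1", pos=100_010, end=100_011, ref="A", alt="G", maf=0.01,
            genotypes={"P1": 1, "P2": 0, "P3": 0, "P4": 0},
        )
        events = enumerate_events([v], [interaction], regions, small_cohort)
        assert len(events) == 1
        e = events[0]
        assert e.component == "enhancer"
        assert (e.direction, e.concordance) == ("GoI", "concordant")
        assert e.cohort == "case_specific"
        assert e.genes == ("G1",)

    def test_variant_outside_all_anchors_yields_nothing(self, small_cohort):
        _, _, interaction, regions = self._setup(small_cohort)
        v = Variant(
            chrom="chr1", pos=50_000, end=50_001, ref="A", alt="G", maf=0.01,
            genotypes={"P1": 1, "P2": 0, "P3": 0, "P4": 0},
        )
        assert enumerate_events([v], [interaction], regions, small_cohort) == []

    def test_patient_relabeling_leaves_counts_invariant(self, default_bundle):
        b = default_bundle
        kept, _ = filter_interactions(b.interactions)
        events = enumerate_events(b.variants, kept, b.regions, b.cohort)

        mapping = {p: f"X{i}" for i, p in enumerate(b.cohort.patients)}
        cohort2 = Cohort(
            patients=[mapping[p] for p in b.cohort.patients],
            group={mapping[p]: g for p, g in b.cohort.group.items()},
        )
        variants2 = [
            Variant(
                chrom=v.chrom, pos=v.pos, end=v.end, ref=v.ref, alt=v.alt, maf=v.maf,
                genotypes={mapping[p]: d for p, d in v.genotypes.items()}, kind=v.kind,
            )
            for v in b.variants
        ]
        import dataclasses as dc
        kept2 = [dc.replace(i, patient=mapping[i.patient]) for i in kept]
        events2 = enumerate_events(variants2, kept2, b.regions, cohort2)

        def signature(evts):
            return sorted(
                (e.variant.pos, e.interaction_key, e.component, e.direction, e.concordance, e.cohort)
                for e in evts
            )

        assert signature(events) == signature(events2)


class TestFisher:
    def test_reported_tier_gene_table(self):
        oddsratio, p = fisher_two_tailed(ContingencyTable2x2(851, 7839, 230, 3853))
        assert round(oddsratio, 3) == 1.819
        assert p < 1e-10

    def test_reported_discordant_table(self):
        oddsratio, p = fisher_two_tailed(ContingencyTable2x2(15355, 228717, 8587, 116859))
        assert abs(oddsratio - 0.913) < 1e-3  # printed value; exact cross-product 0.9136
        assert p < 1e-9

    def test_symmetric_table(self):
        oddsratio, p = fisher_two_tailed(ContingencyTable2x2(1, 1, 1, 1))
        assert oddsratio == 1.0 and p == 1.0

    def test_zero_cross_product_is_infinite_and_0_0_rejected(self):
        oddsratio, _ = fisher_two_tailed(ContingencyTable2x2(3, 0, 1, 5))
        assert oddsratio == float("inf")
        with pytest.raises(ValueError):
            fisher_two_tailed(ContingencyTable2x2(0, 0, 1, 5))

    def test_or_equals_exact_rational_cross_product(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 500, size=4))
            oddsratio, _ = fisher_two_tailed(ContingencyTable2x2(a, b, c, d))
            assert oddsratio == pytest.approx(float(Fraction(a * d, b * c)), rel=1e-12)


class TestSummaryStatistics:
    def test_concordant_loi_shares(self):
        assert loi_goi_shares(373, 79_586)[0] == 0.47
        assert loi_goi_shares(91, 42_512)[0] == 0.21

    def test_goi_share_of_all_concordant_events(self):
        assert goi_share_of_concordant(373, 79_586, 91, 42_512) == 99.6

    def test_zero_loi_share(self):
        assert loi_goi_shares(0, 10)[0] == 0.0

    def test_rate_ratios_from_reported_counts(self):
        assert round(rate_ratio(ContingencyTable2x2(851, 7839, 230, 3853)), 1) == 1.8
        assert round(rate_ratio(ContingencyTable2x2(15355, 228717, 8587, 116859)), 1) == 0.9

    def test_table1_summary_on_synthetic_events(self, default_bundle):
        b = default_bundle
        kept, _ = filter_interactions(b.interactions)
        events = enumerate_events(b.variants, kept, b.regions, b.cohort)
        annotation = {g.gene_id: g for g in b.gene_table}
        summary = table1_summary(events, annotation)
        truth = b.truth_events
        conc = truth[truth.concordance == "concordant"]
        for spec in ("case_specific", "control_specific"):
            loi, goi = summary.loi_goi[spec]
            sub = conc[conc.cohort == spec]
            assert loi == (sub.direction == "LoI").sum()
            assert goi == (sub.direction == "GoI").sum()
        assert 0 <= summary.goi_share_concordant <= 100
        assert set(summary.tier_vs_housekeeping) <= {"concordant", "discordant"}
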