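import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import marrowtrace as mt
from marrowtrace.concordance import PairedVariant, recommend
from marrowtrace.io import ValidationError, VariantObservation


def obs(pid, gene, analyte, vaf, tp="T1", mutation="m1"):
    return VariantObservation(pid, gene, mutation, analyte, tp, vaf)


def pair(vaf_cf, vaf_g, pid="P1", gene="JAK2", mutation="m1", tp="T1", thr=0.02):
    return PairedVariant(
        pid, gene, mutation, tp, vaf_cf, vaf_g,
        vaf_cf is not None and vaf_cf > thr,
        vaf_g is not None and vaf_g > thr,
    )


class TestPairing:
    def test_full_match(self):
        pairs = mt.pair_variants([obs("P1", "JAK2", "cfDNA", 0.45),
                                  obs("P1", "JAK2", "gDNA_PB", 0.40)])
        assert len(pairs) == 1 and pairs[0].both_detected

    def test_one_sided_detection(self):
        pairs = mt.pair_variants([obs("P1", "JAK2", "cfDNA", 0.05)])
        assert pairs[0].detected_cf and not pairs[0].detected_g

    def test_exactly_at_threshold_not_detected(self):
        # the reporting rule is strictly greater than 2%
        pairs = mt.pair_variants([obs("P1", "JAK2", "cfDNA", 0.02),
                                  obs("P1", "JAK2", "gDNA_PB", 0.02)])
        assert pairs == []

    def test_duplicate_key_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            mt.pair_variants([obs("P1", "JAK2", "cfDNA", 0.4),
                              obs("P1", "JAK2", "cfDNA", 0.5)])


class TestOverlap:
    def test_printed_cohort_counts(self):
        pairs = (
            [pair(0.4, 0.4, pid=f"B{i}") for i in range(148)]
            + [pair(0.4, None, pid=f"C{i}") for i in range(3)]
            + [pair(None, 0.4, pid=f"G{i}") for i in range(14)]
        )
        s = mt.overlap_summary(pairs)
        assert s["total"] == 165
        assert s["percentages"] == {"both": 89.7, "cfDNA_only": 1.8, "gDNA_only": 8.5}

    def test_degenerate_all_both(self):
        s = mt.overlap_summary([pair(0.4, 0.4, pid=f"P{i}") for i in range(10)])
        assert s["percentages"] == {"both": 100.0, "cfDNA_only": 0.0, "gDNA_only": 0.0}

    def test_hand_counted_partition(self):
        pairs = [pair(0.4, 0.4), pair(0.4, None, pid="P2"),
                 pair(None, 0.4, pid="P3"), pair(None, 0.3, pid="P4")]
        s = mt.overlap_summary(pairs)
        assert s["percentages"] == {"both": 25.0, "cfDNA_only": 25.0, "gDNA_only": 50.0}

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            mt.overlap_summary([])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.sampled_from(["both", "cf", "g"]), min_size=1, max_size=60))
    def test_counts_partition_and_percentages_sum(self, kinds):
        pairs = []
        for i, kind in enumerate(kinds):
            cf = 0.4 if kind in ("both", "cf") else None
            g = 0.3 if kind in ("both", "g") else None
            pairs.append(pair(cf, g, pid=f"P{i}"))
        s = mt.overlap_summary(pairs)
        assert sum(s["counts"].values()) == len(pairs)
        assert sum(s["percentages"].values()) == pytest.approx(100.0, abs=0.11)


class TestAdvantage:
    def test_identity_pairs_zero_advantage(self):
        s = mt.cfdna_advantage([pair(0.3, 0.3), pair(0.5, 0.5, pid="P2")])
        assert s.mean_advantage == 0.0

    def test_single_pair_hand_arithmetic(self):
        s = mt.cfdna_advantage([pair(0.6, 0.4)])
        assert s.mean_advantage == pytest.approx(50.0)

    def test_negative_advantage_valid(self):
        s = mt.cfdna_advantage([pair(0.4, 0.5)])
        assert s.mean_advantage == pytest.approx(-20.0)

    def test_gene_restriction_and_missing_gene(self):
        pairs = [pair(0.6, 0.4, gene="CALR"), pair(0.3, 0.3, gene="JAK2", pid="P2")]
        assert mt.cfdna_advantage(pairs, gene="CALR").mean_advantage == pytest.approx(50.0)
        with pytest.raises(ValidationError, match="MPL"):
            mt.cfdna_advantage(pairs, gene="MPL")

    def test_identical_vectors_flag_undefined_p(self):
        s = mt.cfdna_advantage([pair(0.3, 0.3), pair(0.5, 0.5, pid="P2")])
        assert np.isnan(s.p_value)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(st.floats(0.05, 0.95), st.floats(0.05, 0.95)),
            min_size=1, max_size=20,
        )
    )
    def test_analyte_swap_maps_advantage_to_minus_a_over_one_plus_a(self, vafs):
        pairs = [pair(cf, g, pid=f"P{i}") for i, (cf, g) in enumerate(vafs)]
        swapped = [pair(g, cf, pid=f"P{i}") for i, (cf, g) in enumerate(vafs)]
        # the identity holds per pair on the fraction scale, hence for the
        # mean only when each pair is mapped individually; assert pairwise
        for p, q in zip(pairs, swapped):
            a = (p.vaf_cf - p.vaf_g) / p.vaf_g
            b = (q.vaf_cf - q.vaf_g) / q.vaf_g
            assert b == pytest.approx(-a / (1 + a), rel=1e-9)

    def test_recommendation_rubric_reproduces_reported_labels(self):
        table = {
            "CALR": (59.30, 0.009, "Prioritize cfDNA"),
            "SF3B1": (43.60, 0.031, "Prioritize cfDNA"),
            "MPL": (36.10, 0.063, "cfDNA preferred"),
            "JAK2": (11.90, 0.002, "Consider cfDNA"),
            "ASXL1": (15.70, 0.160, "Consider cfDNA"),
            "TET2": (-0.33, 0.960, "Consider gDNA"),
            "DNMT3A": (-2.80, 0.757, "Consider gDNA"),
        }
        for gene, (adv, p, expected) in table.items():
            assert recommend(adv, p) == expected, gene


class TestCorrelation:
    def test_perfect_line(self):
        pairs = [pair(v, v, pid=f"P{i}") for i, v in enumerate([0.1, 0.3, 0.5, 0.7])]
        r, _ = mt.vaf_correlation(pairs)
        assert r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        pairs = [pair(1 - v, v, pid=f"P{i}") for i, v in enumerate([0.1, 0.3, 0.5, 0.7])]
        r, _ = mt.vaf_correlation(pairs)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        g = np.array([0.10, 0.20, 0.40, 0.50, 0.80])
        cf = np.array([0.15, 0.30, 0.35, 0.60, 0.70])
        pairs = [pair(c, gv, pid=f"P{i}") for i, (c, gv) in enumerate(zip(cf, g))]
        # closed-form product-moment correlation
        expected = float(
            np.sum((g - g.mean()) * (cf - cf.mean()))
            / np.sqrt(np.sum((g - g.mean()) ** 2) * np.sum((cf - cf.mean()) ** 2))
        )
        r, _ = mt.vaf_correlation(pairs)
        assert r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        pairs = [pair(0.4, v, pid=f"P{i}") for i, v in enumerate([0.1, 0.2, 0.3])]
        with pytest.raises(ValidationError, match="variance"):
            mt.vaf_correlation(pairs)

    def test_spearman_on_monotone_data(self):
        pairs = [pair(v**2, v, pid=f"P{i}") for i, v in enumerate([0.1, 0.3, 0.5, 0.9])]
        r, _ = mt.vaf_correlation(pairs, method="spearman")
        assert r == pytest.approx(1.0)


class TestWbcStratification:
    def clinical(self, wbc_by_pid, tp="T1", lymph=20.0):
        return [
            mt.ClinicalRecord(pid, tp, wbc=w, lymph_pct=lymph)
            for pid, w in wbc_by_pid.items()
        ]

    def test_single_populated_stratum_flagged(self):
        pairs = [pair(0.4, 0.4, pid=f"P{i}") for i in range(4)]
        clin = self.clinical({f"P{i}": 12.0 for i in range(4)})
        out = mt.stratify_by_wbc(pairs, clin, threshold=10.0)
        assert out["strata"]["wbc<10"]["insufficient"]
        assert not out["strata"]["wbc>=10"]["insufficient"]

    def test_quartiles_split_eight_patients_evenly(self):
        wbc = {f"P{i}": float(2 + i) for i in range(8)}
        pairs = [pair(0.4, 0.4, pid=p) for p in wbc]
        out = mt.stratify_by_wbc(pairs, self.clinical(wbc), mode="quartiles")
        sizes = [out["strata"][q]["n_pairs"] for q in ("Q1", "Q2", "Q3", "Q4")]
        assert sizes == [2, 2, 2, 2]

    def test_missing_wbc_is_an_error(self):
        with pytest.raises(ValidationError, match="no clinical"):
            mt.stratify_by_wbc([pair(0.4, 0.4)], [], threshold=10.0)

    def test_wbc_dependent_gdna_detected_independent_cfdna_not(self):
        """In cohorts where gDNA VAF is generated proportional to WBC and
        cfDNA VAF independent of it, the across-strata test fires for gDNA
        and stays at the nominal level for cfDNA."""
        reps, n = 500, 40
        rng = np.random.default_rng(99)
        hits_g = hits_cf = 0
        for _ in range(reps):
            wbc = rng.uniform(4, 20, n)
            g = np.clip(0.02 + 0.04 * wbc + rng.normal(0, 0.02, n), 0.03, 1)
            cf = rng.uniform(0.3, 0.7, n)
            pairs = [pair(cf[i], g[i], pid=f"P{i}") for i in range(n)]
            clin = self.clinical({f"P{i}": float(wbc[i]) for i in range(n)})
            out = mt.stratify_by_wbc(pairs, clin, threshold=10.0)
            if out["across_strata_p"]["gDNA"] < 0.05:
                hits_g += 1
            if out["across_strata_p"]["cfDNA"] < 0.05:
                hits_cf += 1
        assert hits_g / reps >= 0.9  # powered for the generated effect
        assert hits_cf / reps <= 0.12  # near the nominal false-positive rate
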