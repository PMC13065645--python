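import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import marrowtrace as mt
from marrowtrace.io import ValidationError, VariantObservation
from marrowtrace.monitoring import MolecularCall


def obs(pid, gene, vaf, tp="T1", analyte="cfDNA"):
    return VariantObservation(pid, gene, "m1", analyte, tp, vaf)


class TestSummary:
    def test_singleton_mean(self):
        assert mt.summarize_patient_vaf([obs("P1", "JAK2", 0.45)], "cfDNA") == 0.45

    def test_class_all_hand_mean(self):
        vals = [obs("P1", "JAK2", 0.5), obs("P1", "TET2", 0.2)]
        assert mt.summarize_patient_vaf(vals, "cfDNA", "all") == pytest.approx(0.35)
        assert mt.summarize_patient_vaf(vals, "cfDNA", "driver") == pytest.approx(0.5)
        assert mt.summarize_patient_vaf(vals, "cfDNA", "non_driver") == pytest.approx(0.2)

    def test_empty_class_is_absent(self):
        assert mt.summarize_patient_vaf([obs("P1", "TET2", 0.3)], "cfDNA", "driver") is None

    def test_subthreshold_mutations_ignored(self):
        assert mt.summarize_patient_vaf([obs("P1", "JAK2", 0.01)], "cfDNA") is None


class TestClassification:
    # hand-enumerated truth table over the boundary deltas
    @pytest.mark.parametrize(
        "t1,t2,category,progression",
        [
            (0.50, 0.50, "stable", False),
            (0.40, 0.52, "resistance", True),  # +0.12 >= 0.10
            (0.40, 0.35, "response", False),  # -0.05 boundary inclusive
            (0.40, 0.45, "resistance", False),  # +0.05 boundary inclusive
            (0.40, 0.50, "resistance", True),  # +0.10 boundary inclusive
            (0.40, 0.30, "response", False),  # -0.10
            (0.40, 0.44, "stable", False),
            (0.40, 0.36, "stable", False),
        ],
    )
    def test_truth_table(self, t1, t2, category, progression):
        delta, cat, prog = mt.classify_molecular(t1, t2)
        assert cat == category
        assert prog is progression
        assert delta == pytest.approx(t2 - t1)

    def test_relative_mode(self):
        _, cat, _ = mt.classify_molecular(0.40, 0.39, relative=True)
        assert cat == "stable"  # -2.5% relative change
        _, cat, _ = mt.classify_molecular(0.40, 0.36, relative=True)
        assert cat == "response"  # -10% relative change

    def test_missing_timepoint_distinguished(self):
        with pytest.raises(ValidationError, match="T1"):
            mt.classify_molecular(None, 0.4)
        with pytest.raises(ValidationError, match="T2"):
            mt.classify_molecular(0.4, None)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_total_function_and_threshold_coherence(self, t1, t2):
        delta, cat, prog = mt.classify_molecular(t1, t2)
        assert cat in ("response", "stable", "resistance")
        if prog:  # progression implies resistance under default thresholds
            assert cat == "resistance"


class TestCallPatients:
    def test_calls_invariant_to_input_order(self):
        rows = [
            obs("P1", "JAK2", 0.50, "T1"), obs("P1", "JAK2", 0.40, "T2"),
            obs("P2", "CALR", 0.30, "T1"), obs("P2", "CALR", 0.42, "T2"),
        ]
        fwd = mt.call_patients(rows, "cfDNA")
        rev = mt.call_patients(rows[::-1], "cfDNA")
        assert fwd == rev
        assert {c.patient_id: c.category for c in fwd} == {
            "P1": "response", "P2": "resistance",
        }

    def test_patient_missing_timepoint_skipped(self):
        rows = [obs("P1", "JAK2", 0.5, "T1")]
        assert mt.call_patients(rows, "cfDNA") == []


class TestCohort:
    def call(self, pid, analyte, delta, category, progression=False):
        return MolecularCall(pid, analyte, delta, category, progression)

    def test_printed_cohort_scale_proportion(self):
        calls = [
            self.call(f"P{i}", "cfDNA", 0.06, "resistance") for i in range(10)
        ] + [self.call(f"P{i+10}", "cfDNA", 0.0, "stable") for i in range(29)]
        out = mt.cohort_classification(calls)
        assert out["analytes"]["cfDNA"]["proportions"]["resistance"] == 25.6

    def test_all_stable_full_concordance(self):
        calls = [self.call(f"P{i}", a, 0.0, "stable")
                 for i in range(5) for a in ("cfDNA", "gDNA_PB")]
        out = mt.cohort_classification(calls)
        for a in ("cfDNA", "gDNA_PB"):
            assert out["analytes"][a]["proportions"] == {
                "response": 0.0, "stable": 100.0, "resistance": 0.0,
            }
        assert out["cross_analyte"] == {"n_shared": 5, "concordant": 5, "discordant": 0}

    def test_hand_counted_discordance(self):
        calls = [
            self.call("P1", "gDNA_PB", -0.06, "response"),
            self.call("P1", "cfDNA", 0.0, "stable"),
            self.call("P2", "gDNA_PB", 0.0, "stable"),
            self.call("P2", "cfDNA", 0.0, "stable"),
        ]
        assert mt.cohort_classification(calls)["cross_analyte"]["discordant"] == 1

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.sampled_from(["response", "stable", "resistance"]),
                    min_size=1, max_size=50))
    def test_proportions_sum_to_hundred(self, cats):
        calls = [self.call(f"P{i}", "cfDNA", 0.0 if c == "stable" else
                           (0.06 if c == "resistance" else -0.06), c)
                 for i, c in enumerate(cats)]
        out = mt.cohort_classification(calls)
        total = sum(out["analytes"]["cfDNA"]["proportions"].values())
        assert total == pytest.approx(100.0, abs=0.11)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            mt.cohort_classification([])


class TestGroupDelta:
    def test_hand_set_group_means(self):
        calls = [
            MolecularCall("P1", "cfDNA", 0.02, "stable", False),
            MolecularCall("P1", "gDNA_PB", -0.04, "stable", False),
            MolecularCall("P2", "cfDNA", 0.04, "stable", False),
            MolecularCall("P2", "gDNA_PB", 0.00, "stable", False),
            MolecularCall("P3", "cfDNA", -0.10, "response", False),
            MolecularCall("P3", "gDNA_PB", -0.10, "response", False),
        ]
        groups = {"P1": "HU", "P2": "HU", "P3": "IFN"}
        out = mt.group_delta_summary(calls, groups)
        assert out["HU"]["analytes"]["cfDNA"]["mean_delta"] == pytest.approx(0.03)
        assert out["HU"]["analytes"]["gDNA_PB"]["mean_delta"] == pytest.approx(-0.02)
        assert out["IFN"]["n_patients"] == 1
        assert "flag" in out["IFN"]

    def test_identical_deltas_flag_undefined_test(self):
        calls = []
        for i in range(4):
            calls.append(MolecularCall(f"P{i}", "cfDNA", 0.03, "stable", False))
            calls.append(MolecularCall(f"P{i}", "gDNA_PB", 0.03, "stable", False))
        out = mt.group_delta_summary(calls, {f"P{i}": "NR" for i in range(4)})
        assert np.isnan(out["NR"]["paired_p"])

    def test_powered_to_detect_divergent_dynamics(self):
        """Groups generated with a cfDNA delta of +0.05 against a null gDNA
        delta (sd 0.03, n=17 as in a non-responder group) are detected by
        the paired cross-analyte test in most replicates."""
        rng = np.random.default_rng(123)
        reps, n, hits = 500, 17, 0
        for _ in range(reps):
            d_cf = rng.normal(0.05, 0.03, n)
            d_g = rng.normal(0.0, 0.03, n)
            calls = []
            for i in range(n):
                calls.append(MolecularCall(
                    f"P{i}", "cfDNA", d_cf[i],
                    "resistance" if d_cf[i] >= 0.05 else "stable", False))
                calls.append(MolecularCall(
                    f"P{i}", "gDNA_PB", d_g[i],
                    "resistance" if d_g[i] >= 0.05 else "stable", False))
            out = mt.group_delta_summary(calls, {f"P{i}": "NR" for i in range(n)})
            if out["NR"]["paired_p"] < 0.05:
                hits += 1
        assert hits / reps >= 0.8
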