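"""AGO-preference classification, knockdown statistics, methylation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirsort import annotation, preference, simulate
from mirsort.errors import ValidationError

from oracles import binomial_direction_enumeration


class TestClassifyPreference:
    @pytest.mark.parametrize(
        "fraction,expected",
        [
            (0.95, "AGO1_strong"),
            (0.75, "AGO1"),
            (0.9, "AGO1"),  # strict inequality at the strong threshold
            (0.7, "none"),
            (0.5, "none"),
            (0.3, "none"),
            (0.25, "AGO2"),
            (0.1, "AGO2"),  # mirror of 0.9: strict inequality at the boundary
            (0.05, "AGO2_strong"),
        ],
    )
    def test_thresholds(self, fraction, expected):
        assert preference.classify_preference(fraction) == expected

    @settings(max_examples=60, derandomize=True)
    @given(st.floats(0.0, 1.0))
    def test_antisymmetric(self, f):
        mirror = {
            "AGO1": "AGO2", "AGO2": "AGO1",
            "AGO1_strong": "AGO2_strong", "AGO2_strong": "AGO1_strong",
            "none": "none",
        }
        assert preference.classify_preference(1.0 - f) == mirror[
            preference.classify_preference(f)
        ]

    def test_out_of_range(self):
        with pytest.raises(ValidationError):
            preference.classify_preference(1.2)


class TestPreferenceTable:
    def _libs(self):
        libs = []
        for pd_ in ("AGO1_IP", "AGO2_IP"):
            for rep in (1, 2):
                libs.append(
                    simulate.SmallRNALibrary(
                        library_id=f"planula_{pd_}_rep{rep}",
                        stage="planula", pulldown=pd_, replicate=rep,
                        genome_mapped_total=10**6,
                    )
                )
        return libs

    def test_examples(self):
        libs = self._libs()
        rpm = pd.DataFrame(
            {
                "planula_AGO1_IP_rep1": [75.0, 95.0, 50.0],
                "planula_AGO1_IP_rep2": [75.0, 95.0, 50.0],
                "planula_AGO2_IP_rep1": [25.0, 5.0, 50.0],
                "planula_AGO2_IP_rep2": [25.0, 5.0, 50.0],
            },
            index=["m1", "m2", "m3"],
        )
        table = preference.preference_table(rpm, libs).set_index("mirna_id")
        assert table.loc["m1", "preference_ago1"] == pytest.approx(0.75)
        assert table.loc["m1", "class_label"] == "AGO1"
        assert table.loc["m2", "class_label"] == "AGO1_strong"
        assert table.loc["m3", "class_label"] == "none"

    def test_expression_filter_drops_low_mirnas(self):
        libs = self._libs()
        rpm = pd.DataFrame(
            {l.library_id: [19.0] for l in libs}, index=["dim"]
        )
        assert preference.preference_table(rpm, libs).empty

    def test_missing_arm_rejected(self):
        libs = [l for l in self._libs() if l.pulldown == "AGO1_IP"]
        rpm = pd.DataFrame({l.library_id: [30.0] for l in libs}, index=["m"])
        with pytest.raises(ValidationError, match="arm"):
            preference.preference_table(rpm, libs)

    def test_recovery_from_simulation(self, preference_bundle):
        """Planted AGO1 fractions recovered within 0.05 MAE; strongly
        preferring miRNAs land in the strong classes."""
        design, hairpins, truth, libraries, stacks = preference_bundle
        spans = {h.id: truth.hairpins[h.id].guide_span for h in hairpins}
        _, rpm = annotation.guide_count_matrix(stacks, spans, libraries)
        table = preference.preference_table(rpm, libraries)
        est = table.groupby("mirna_id")["preference_ago1"].mean()
        errors = [abs(est[h] - truth.hairpins[h].preference_ago1) for h in est.index]
        assert np.mean(errors) <= 0.05
        for hid, t in truth.hairpins.items():
            if t.preference_ago1 > 0.9 or t.preference_ago1 < 0.1:
                classes = set(table[table["mirna_id"] == hid]["class_label"])
                assert classes <= {"AGO1_strong", "AGO2_strong"}

    def test_depth_rescaling_invariance(self):
        libs = self._libs()
        rpm = pd.DataFrame(
            {l.library_id: [40.0, 120.0] for l in libs}, index=["m1", "m2"]
        )
        t1 = preference.preference_table(rpm, libs)
        t2 = preference.preference_table(rpm * 3.0, libs)
        assert np.allclose(t1["preference_ago1"], t2["preference_ago1"])


def test_overall_preference_rule():
    assert preference.overall_preference(["none", "none", "none"]) == "none"
    assert preference.overall_preference(["AGO1", "none", "AGO1_strong"]) == "AGO1_strong"
    assert preference.overall_preference(["AGO1", "AGO2", "none"]) == "mixed"
    assert preference.overall_preference(["AGO2", "none"]) == "AGO2"


class TestKDDirection:
    def test_six_of_seven_both_tails(self):
        assert preference.binomial_direction_p(6, 1, "two_tailed") == pytest.approx(0.125)
        assert preference.binomial_direction_p(6, 1, "one_tailed") == pytest.approx(0.0625)

    @pytest.mark.parametrize("tail", ["two_tailed", "one_tailed"])
    def test_matches_enumeration_all_n_le_12(self, tail):
        for n in range(0, 13):
            for down in range(n + 1):
                expected = binomial_direction_enumeration(down, n - down, tail)
                got = preference.binomial_direction_p(down, n - down, tail)
                if expected is None:
                    assert got is None
                else:
                    assert got == pytest.approx(expected, abs=1e-12), (n, down, tail)

    def test_ties_excluded(self):
        ctrl = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        kd = pd.Series({"a": 0.5, "b": 2.0, "c": 4.0})
        res = preference.kd_direction_test(ctrl, kd)
        assert res.n_down == 1 and res.n_up == 1 and res.n_ties == 1

    def test_all_ties_undefined(self):
        s = pd.Series({"a": 1.0, "b": 2.0})
        res = preference.kd_direction_test(s, s.copy())
        assert res.p is None and res.n_down == res.n_up == 0

    def test_empty_subset_rejected(self):
        s = pd.Series({"a": 1.0})
        with pytest.raises(ValidationError):
            preference.kd_direction_test(s, s, subset=[])


class TestStrandShift:
    def test_no_shift(self):
        fc = pd.Series({f"m{i}": 1.0 for i in range(10)})
        res = preference.strand_selection_shift(fc, fc.copy())
        assert np.allclose(res.ratios, 1.0)
        assert res.p is None  # log-ratios identically zero

    def test_planted_guide_specific_depletion(self):
        guide_fc = pd.Series({f"m{i}": 0.5 for i in range(10)})
        star_fc = pd.Series({f"m{i}": 1.0 for i in range(10)})
        res = preference.strand_selection_shift(guide_fc, star_fc)
        assert np.allclose(res.ratios, 0.5)

    def test_zero_star_excluded(self):
        guide_fc = pd.Series({"a": 0.5, "b": 0.5})
        star_fc = pd.Series({"a": 1.0, "b": 0.0})
        res = preference.strand_selection_shift(guide_fc, star_fc)
        assert list(res.ratios.index) == ["a"]

    def test_recovers_planted_shift_from_simulation(self, preference_bundle):
        design, hairpins, truth, _, _ = preference_bundle
        kd_eff = {h.id: {"KD_AGO1": 0.5, "KD_AGO2": 1.0, "KD_control": 1.0} for h in hairpins}
        star_eff = {h.id: {"KD_AGO1": 1.0, "KD_AGO2": 1.0, "KD_control": 1.0} for h in hairpins}
        libs, stacks = simulate.simulate_kd_libraries(
            design, hairpins, truth, kd_eff, star_eff, rng=np.random.default_rng(5)
        )
        gspans = {h.id: truth.hairpins[h.id].guide_span for h in hairpins}
        sspans = {h.id: truth.hairpins[h.id].star_span for h in hairpins}
        ng = preference.spikein_normalized_counts(stacks, gspans, libs)
        ns = preference.spikein_normalized_counts(stacks, sspans, libs)
        gfc = preference.condition_means(ng, libs, "KD_AGO1") / preference.condition_means(
            ng, libs, "KD_control"
        )
        sfc = preference.condition_means(ns, libs, "KD_AGO1") / preference.condition_means(
            ns, libs, "KD_control"
        )
        res = preference.strand_selection_shift(gfc, sfc)
        assert res.ratios.median() == pytest.approx(0.5, rel=0.25)
        assert res.p < 1e-6


class TestMethylation:
    def test_identity_gives_t_zero(self):
        ids = [f"m{i}" for i in range(8)]
        s = pd.Series(100.0, index=ids)
        raw = pd.Series(200, index=ids)
        res = preference.methylation_comparison(s, s.copy(), raw, {i: "AGO1" for i in ids})
        assert res.t == 0.0 and np.allclose(res.retention, 1.0)

    def test_low_raw_reads_excluded(self):
        ids = ["keep", "drop"]
        norm = pd.Series({"keep": 10.0, "drop": 10.0})
        raw = pd.Series({"keep": 50, "drop": 49})
        res = preference.methylation_comparison(norm, norm, raw, {})
        assert list(res.retention.index) == ["keep"]

    def test_class_retention_recovered(self):
        rng = np.random.default_rng(0)
        classes = {f"m{i}": ("AGO1" if i % 2 == 0 else "AGO2") for i in range(40)}
        nonox = pd.Series(100.0, index=list(classes))
        true_ret = {"AGO1": 0.9, "AGO2": 0.2}
        ox = pd.Series(
            {i: 100.0 * true_ret[classes[i]] * rng.uniform(0.9, 1.1) for i in classes}
        )
        raw = pd.Series(500, index=list(classes))
        res = preference.methylation_comparison(ox, nonox, raw, classes)
        assert res.class_means["AGO1"] == pytest.approx(0.9, abs=0.05)
        assert res.class_means["AGO2"] == pytest.approx(0.2, abs=0.05)
        assert res.p < 1e-6

    def test_no_survivors_rejected(self):
        norm = pd.Series({"a": 1.0})
        raw = pd.Series({"a": 10})
        with pytest.raises(ValidationError):
            preference.methylation_comparison(norm, norm, raw, {})
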