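"""Triplicate MRD engine: ratios, noise correction, LOD/LOQ, patient calls."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from liqbio_mrd.mrd import (
    ControlCalibration,
    MRDCaller,
    TriplicateMeasurement,
    calibrate_lod_loq,
    call_mutation,
    correct_noise,
    match_reads,
    patient_mrd,
    replicate_ratio,
    reverse_complement,
)

ratios3 = st.lists(
    st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=3, max_size=3
)


class TestMatchReads:
    WT = "ACGTACGTACGTACG" + "C" + "GTACGTACGTACGTA"
    MUT = "ACGTACGTACGTACG" + "T" + "GTACGTACGTACGTA"

    def test_all_wildtype(self):
        assert match_reads([self.WT] * 10, self.WT, self.MUT) == (0, 10, 0)

    def test_mixed_assignment(self):
        reads = [self.MUT] * 7 + [self.WT] * 3 + ["GGGGGGGGGGGGGGGGGGGG", "AAAA"]
        assert match_reads(reads, self.WT, self.MUT) == (7, 3, 2)

    def test_counts_sum_to_input(self):
        reads = [self.MUT, self.WT, "NNNN", self.WT]
        assert sum(match_reads(reads, self.WT, self.MUT)) == len(reads)

    def test_mismatch_outside_variant_base_unmatched(self):
        read = "T" + self.MUT[1:]  # one substitution in the flank
        assert match_reads([read], self.WT, self.MUT) == (0, 0, 1)

    def test_reverse_complement_reads_normalized(self):
        assert match_reads([reverse_complement(self.MUT)], self.WT, self.MUT) == (1, 0, 0)

    def test_identical_contexts_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            match_reads([], self.WT, self.WT)

    def test_short_read_spanning_variant(self):
        assert match_reads([self.MUT[10:22]], self.WT, self.MUT) == (1, 0, 0)


class TestReplicateRatio:
    @pytest.mark.parametrize(
        "mut,wt,expected",
        [(0, 1000, 0.0), (100, 499_900, 2.0e-4), (5, 5, 0.5), (10, 0, 1.0)],
    )
    def test_ratio_values(self, mut, wt, expected):
        assert replicate_ratio(mut, wt) == pytest.approx(expected)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            replicate_ratio(0, 0)


class TestCorrectNoise:
    def test_equal_values_all_retained(self):
        corrected, mask = correct_noise([1e-4, 1e-4, 1e-4])
        assert corrected == pytest.approx(1e-4)
        assert mask == (True, True, True)

    def test_outlier_removed_hand_computed(self):
        # mean 3e-3, sample SD sqrt(27e-6) ~ 5.196e-3, threshold ~ 8.196e-3 < 9e-3
        corrected, mask = correct_noise([0.0, 0.0, 9e-3])
        assert mask == (True, True, False)
        assert corrected == 0.0

    def test_boundary_retained_by_strict_inequality(self):
        # mean 2e-5, SD 1e-5, threshold exactly 3e-5: the max equals it, kept
        corrected, mask = correct_noise([1e-5, 2e-5, 3e-5])
        assert mask == (True, True, True)
        assert corrected == pytest.approx(2e-5)

    def test_requires_three_finite_ratios(self):
        with pytest.raises(ValueError):
            correct_noise([0.1, 0.2])
        with pytest.raises(ValueError):
            correct_noise([0.1, 0.2, float("nan")])

    @given(ratios3)
    @settings(max_examples=200, deadline=None)
    def test_min_never_removed_and_mean_never_increases(self, ratios):
        corrected, mask = correct_noise(ratios)
        assert mask[ratios.index(min(ratios))]
        assert any(mask)
        assert corrected <= statistics.fmean(ratios) + 1e-12


class TestCalibration:
    def test_all_zero_controls(self):
        c = calibrate_lod_loq([0.0] * 9)
        assert c.lod == 0.0 and c.loq == 0.0

    def test_zero_sd_controls(self):
        c = calibrate_lod_loq([1e-5] * 9)
        assert c.lod == pytest.approx(1e-5)
        assert c.loq == pytest.approx(1e-5)

    def test_hand_computed_moments(self):
        # mean 1e-5, sample SD 3e-5 -> LOD 1e-4, LOQ 3.1e-4
        c = calibrate_lod_loq([0.0] * 8 + [9e-5])
        assert c.lod == pytest.approx(1e-4)
        assert c.loq == pytest.approx(3.1e-4)

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            calibrate_lod_loq([1e-5])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1e-2, allow_nan=False),
                 min_size=2, max_size=12),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(max_examples=200, deadline=None)
    def test_scale_equivariance_and_ordering(self, ratios, c):
        base = calibrate_lod_loq(ratios)
        scaled = calibrate_lod_loq([c * r for r in ratios])
        assert scaled.lod == pytest.approx(c * base.lod, rel=1e-9, abs=1e-15)
        assert scaled.loq == pytest.approx(c * base.loq, rel=1e-9, abs=1e-15)
        assert base.loq >= base.lod >= statistics.fmean(ratios) - 1e-15


class TestCallMutation:
    CAL = ControlCalibration("m", (0.0,) * 9, lod=2.6e-5, loq=8e-5)

    def test_below_lod(self):
        assert call_mutation(0.0, ControlCalibration("m", (), 1e-5, 3e-5)).status == "below_LOD"

    def test_quantifiable(self):
        call = call_mutation(2e-4, self.CAL)
        assert call.status == "quantifiable"
        assert not call.lod_excluded

    def test_detected_between_lod_and_loq(self):
        assert call_mutation(5e-5, self.CAL).status == "detected"

    def test_noisy_lod_excluded_regardless_of_ratio(self):
        noisy = ControlCalibration("m", (), lod=2e-4, loq=9e-4)
        call = call_mutation(0.5, noisy)
        assert call.lod_excluded
        assert call.status == "quantifiable"  # status still computed

    def test_boundary_at_lod_is_not_eliminated(self):
        assert call_mutation(2.6e-5, self.CAL).status != "below_LOD"


class TestPatientMRD:
    def _call(self, mean, status="detected", excluded=False):
        from liqbio_mrd.mrd import MutationMRD
        return MutationMRD("m", (mean,) * 3, (True,) * 3, mean,
                           1e-5, 3e-5, status, excluded)

    def test_all_below_lod_negative(self):
        res = patient_mrd([self._call(0.0, "below_LOD")], "P", "EOT")
        assert res.mrd_value == 0.0 and not res.positive

    def test_max_over_eligible(self):
        res = patient_mrd([self._call(3e-4), self._call(7e-4, "quantifiable")], "P", "EOT")
        assert res.mrd_value == pytest.approx(7e-4)
        assert res.positive

    def test_lod_excluded_mutation_cannot_drive_positivity(self):
        res = patient_mrd([self._call(5e-3, "quantifiable", excluded=True)], "P", "EOT")
        assert not res.positive and res.mrd_value == 0.0

    def test_empty_call_list_rejected(self):
        with pytest.raises(ValueError, match="no trackable"):
            patient_mrd([], "P", "EOT")

    def test_below_assay_floor_flag(self):
        res = patient_mrd([self._call(1e-4)], "P", "EOT")
        assert res.positive and res.below_assay_floor

    @given(st.floats(min_value=1e-4, max_value=1e-2),
           st.floats(min_value=0.0, max_value=1e-2))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_eligible_corrected_mean(self, base, bump):
        lo = patient_mrd([self._call(base), self._call(2e-4)], "P", "t")
        hi = patient_mrd([self._call(base + bump), self._call(2e-4)], "P", "t")
        assert hi.mrd_value >= lo.mrd_value


class TestMRDCaller:
    def _controls(self):
        rows = []
        for mid, background in [("m1", 5), ("m2", 10)]:
            for rep in range(9):
                rows.append({"mutation_id": mid, "donor": f"HC{rep // 3}",
                             "replicate": rep % 3, "mut_reads": background + rep % 2,
                             "wt_reads": 500_000 - background})
        return pd.DataFrame(rows)

    def test_fit_builds_calibrations(self):
        caller = MRDCaller().fit(self._controls())
        assert set(caller.calibrations_) == {"m1", "m2"}
        assert caller.n_mutations_ == 2
        for c in caller.calibrations_.values():
            assert c.loq >= c.lod

    def test_evaluate_and_predict_on_counts(self):
        caller = MRDCaller().fit(self._controls())
        rows = []
        for rep in range(1, 4):
            rows.append({"patient": "P1", "timepoint": "EOT", "mutation_id": "m1",
                         "replicate": rep, "mut_reads": 500, "wt_reads": 499_500})
            rows.append({"patient": "P1", "timepoint": "EOT", "mutation_id": "m2",
                         "replicate": rep, "mut_reads": 0, "wt_reads": 500_000})
        counts = pd.DataFrame(rows)
        results = caller.evaluate(counts)
        assert len(results) == 1
        assert results[0].positive
        assert results[0].mrd_value == pytest.approx(1e-3, rel=1e-6)
        assert caller.predict(counts).tolist() == [True]

    def test_missing_calibration_skipped(self):
        caller = MRDCaller().fit(self._controls())
        counts = pd.DataFrame([
            {"patient": "P1", "timepoint": "EOT", "mutation_id": "unknown",
             "replicate": r, "mut_reads": 100, "wt_reads": 499_900} for r in (1, 2, 3)
        ])
        assert caller.evaluate(counts) == []

    def test_get_set_params_roundtrip(self):
        caller = MRDCaller(lod_multiplier=4.0)
        params = caller.get_params()
        assert params["lod_multiplier"] == 4.0
        caller.set_params(loq_multiplier=12.0)
        assert caller.loq_multiplier == 12.0

    def test_loq_below_lod_multiplier_rejected(self):
        with pytest.raises(ValueError, match="loq_multiplier"):
            MRDCaller(lod_multiplier=10.0, loq_multiplier=3.0).fit(self._controls())


class TestTriplicateMeasurement:
    def test_requires_three_replicates(self):
        with pytest.raises(ValueError, match="3 replicates"):
            TriplicateMeasurement("m", "t", ((1, 2), (3, 4)))

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            TriplicateMeasurement("m", "t", ((0, 0), (0, 0), (0, 0)))
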