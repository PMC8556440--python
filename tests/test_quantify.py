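import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from renalpet.acquisition import simulate_acquisition
from renalpet.phantom import Biokinetics, TissueCurve
from renalpet.quantify import (
    TissueConcInputs,
    lru_percent,
    measure_voi,
    noise_metric,
    peak_time,
    summarize_patient,
    tissue_concentration,
)

finite_activity = st.floats(min_value=0.0, max_value=1e6, allow_nan=False)


def make_frame(truth, duration=60.0, seed=0, poisson=True, voxel_size=4.0):
    return simulate_acquisition(
        truth, 60.0, duration, sensitivity=5.0, psf_fwhm=0.0,
        voxel_size=voxel_size, seed=seed, poisson=poisson,
    )


class TestMeasureVoi:
    def test_full_coverage_mask_recovers_total_frame_activity(self):
        truth = np.zeros((10, 10, 10))
        truth[2:8, 2:8, 2:8] = 15.0
        frame = make_frame(truth, seed=3)
        m = measure_voi(frame, np.ones_like(truth, dtype=bool))
        assert m.activity_mbq == pytest.approx(frame.total_activity_mbq, rel=1e-12)

    def test_uniform_region_arithmetic(self):
        # 100 voxels of 0.064 mL at 10 kBq/mL -> 64 kBq = 0.064 MBq
        truth = np.zeros((10, 10, 10))
        mask = np.zeros_like(truth, dtype=bool)
        mask.flat[:100] = True
        truth[mask] = 10.0
        frame = make_frame(truth, poisson=False)
        m = measure_voi(frame, mask)
        assert m.activity_mbq == pytest.approx(0.064, rel=1e-9)
        assert m.volume_ml == pytest.approx(6.4, rel=1e-12)
        assert m.concentration_kbq_per_ml == pytest.approx(10.0, rel=1e-9)

    def test_replicate_mean_recovers_truth(self, rng):
        truth = np.full((8, 8, 8), 5.0)
        mask = np.zeros_like(truth, dtype=bool)
        mask[2:6, 2:6, 2:6] = True
        true_activity = truth[mask].sum() * 0.064 / 1000.0
        acts = [
            measure_voi(make_frame(truth, seed=rng), mask).activity_mbq
            for _ in range(500)
        ]
        se = np.std(acts, ddof=1) / np.sqrt(len(acts))
        assert abs(np.mean(acts) - true_activity) < 3 * se

    def test_empty_mask_and_shape_mismatch_rejected(self):
        frame = make_frame(np.ones((5, 5, 5)))
        with pytest.raises(ValueError, match="empty"):
            measure_voi(frame, np.zeros((5, 5, 5), dtype=bool))
        with pytest.raises(ValueError, match="shape"):
            measure_voi(frame, np.ones((4, 4, 4), dtype=bool))


class TestLruPercent:
    @pytest.mark.parametrize(
        "left,right,expected",
        [(1.0, 1.0, 50.0), (0.0, 2.5, 0.0), (0.483, 0.517, 48.3)],
    )
    def test_arithmetic(self, left, right, expected):
        assert lru_percent(left, right) == pytest.approx(expected, abs=1e-9)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            lru_percent(0.0, 0.0)

    @given(left=finite_activity, right=finite_activity)
    def test_complement_identity(self, left, right):
        if left + right == 0:
            return
        assert lru_percent(left, right) + lru_percent(right, left) == pytest.approx(
            100.0, abs=1e-9
        )

    @given(
        left=st.floats(min_value=1e-3, max_value=1e3),
        right=st.floats(min_value=1e-3, max_value=1e3),
        k=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_invariant_under_global_scaling(self, left, right, k):
        assert lru_percent(k * left, k * right) == pytest.approx(
            lru_percent(left, right), rel=1e-9
        )


class TestSummarizePatient:
    def test_example_series(self):
        s = summarize_patient([44.6, 48.5, 46.7], patient_id=1)
        assert s.delta_max == pytest.approx(3.9)
        assert s.range_lru == (44.6, 48.5)
        assert s.median_lru == pytest.approx(46.7)

    def test_constant_series_has_zero_spread(self):
        s = summarize_patient([50.0] * 5)
        assert s.sd_lru == 0.0
        assert s.delta_max == 0.0

    def test_sd_uses_sample_denominator(self):
        vals = [1.0, 2.0, 3.0]
        assert summarize_patient(vals).sd_lru == pytest.approx(1.0)

    def test_single_record_rejected(self):
        with pytest.raises(ValueError):
            summarize_patient([48.0])


class TestTissueConcentration:
    def test_homogeneous_mixture_is_identity(self):
        assert tissue_concentration(TissueConcInputs(7.0, 7.0)) == pytest.approx(7.0)

    def test_blood_free_scaling(self):
        assert tissue_concentration(TissueConcInputs(7.5, 0.0)) == pytest.approx(10.0)

    def test_purely_vascular_voi_gives_zero(self):
        c_blood = 12.0
        out = tissue_concentration(TissueConcInputs(0.25 * c_blood, c_blood))
        assert out == pytest.approx(0.0, abs=1e-12)

    def test_negative_result_warned_not_clipped(self):
        with pytest.warns(UserWarning, match="negative"):
            out = tissue_concentration(TissueConcInputs(0.1, 10.0))
        assert out < 0

    def test_invalid_blood_fraction_rejected(self):
        with pytest.raises(ValueError):
            TissueConcInputs(1.0, 1.0, blood_fraction=1.0)

    @given(
        ck=st.floats(-100, 100),
        cb=st.floats(-100, 100),
        a=st.floats(-5, 5),
        b=st.floats(-5, 5),
    )
    def test_linearity_in_both_concentrations(self, ck, cb, a, b):
        import warnings

        def f(x, y):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return tissue_concentration(TissueConcInputs(x, y))

        assert f(a * ck, a * cb) + f(b * ck, b * cb) == pytest.approx(
            f((a + b) * ck, (a + b) * cb), abs=1e-6
        )


class TestPeakTime:
    def test_strictly_decreasing_curve_peaks_first(self):
        assert peak_time([5, 30, 60], [3.0, 2.0, 1.0]) == 5

    def test_unique_maximum(self):
        assert peak_time([30, 60, 120], [2.0, 5.0, 1.0]) == 60

    def test_ties_break_earlier(self):
        assert peak_time([30, 60], [5.0, 5.0]) == 30

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            peak_time([], [])

    def test_modal_peak_is_one_hour_across_jittered_cohorts(self, rng):
        """Under default kinetics with between-patient uptake-rate jitter,
        the majority of patients peak at the 1 h sample in each cohort."""
        times = np.array([5, 12, 20, 30, 60, 120, 210, 330], dtype=float)
        majorities = []
        for _ in range(30):
            peaks = []
            for _ in range(12):
                kin = Biokinetics(
                    tissue=TissueCurve(uptake_rate=0.03 * rng.lognormal(0, 0.4))
                )
                concs = kin.tissue_conc(times)
                peaks.append(peak_time(times, concs))
            majorities.append(np.mean(np.array(peaks) == 60.0) > 0.5)
        assert np.mean(majorities) >= 0.9


class TestNoiseMetric:
    def test_noiseless_uniform_region_has_zero_cv(self):
        truth = np.full((8, 8, 8), 30.0)
        frame = make_frame(truth, poisson=False)
        assert noise_metric(frame, np.ones_like(truth, dtype=bool)) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_cv_decreases_with_duration_in_expectation(self, rng):
        truth = np.full((10, 10, 10), 10.0)
        mask = np.ones_like(truth, dtype=bool)
        mean_cv = []
        for duration in (10, 20, 30, 60, 90, 120):
            cvs = [
                noise_metric(make_frame(truth, duration=duration, seed=rng), mask)
                for _ in range(100)
            ]
            mean_cv.append(np.mean(cvs))
        assert all(a > b for a, b in zip(mean_cv, mean_cv[1:]))

    def test_small_mask_and_zero_mean_rejected(self):
        frame = make_frame(np.full((8, 8, 8), 1.0))
        small = np.zeros((8, 8, 8), dtype=bool)
        small.flat[:5] = True
        with pytest.raises(ValueError, match="10 voxels"):
            noise_metric(frame, small)
        zero_frame = make_frame(np.zeros((8, 8, 8)))
        with pytest.raises(ValueError, match="zero"):
            noise_metric(zero_frame, np.ones((8, 8, 8), dtype=bool))
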