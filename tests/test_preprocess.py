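import warnings

import numpy as np
import pandas as pd
import pytest

from pupilkit import (
    BaselineSpec,
    BlinkParams,
    PipelineOrderError,
    PupilTrace,
    SeriesMeta,
    TimeWindow,
    TrialTable,
    SyntheticSpec,
    apply_calibration,
    baseline_correct,
    baseline_correct_table,
    downsample,
    downsample_table,
    exclude_baseline_outliers,
    fit_calibration,
    inject_blink,
    reconstruct_blinks,
    reconstruct_blinks_table,
    simulate_dataset,
)

NA = np.nan


def one_blink_dataset(seed, n_participants=2, trials=10, dur_ms=(100, 400)):
    """Blink-free simulated traces plus one manually injected blink each."""
    spec = SyntheticSpec(n_participants=n_participants,
                         trials_per_participant=trials,
                         blink_rate=0.0, seed=seed)
    table, truth = simulate_dataset(spec)
    rng = np.random.default_rng(seed + 10_000)
    arr = table.series["pupil_cue"]
    extents = []
    for i in range(arr.shape[0]):
        dur = int(rng.uniform(*dur_ms))
        start = int(rng.integers(300, arr.shape[1] - dur - 300))
        extents.append(inject_blink(arr[i], start, dur, 20))
    return table, truth, extents


class TestReconstructBlinks:
    def test_injected_blink_recovered_by_cubic_spline(self):
        table, truth, extents = one_blink_dataset(0, dur_ms=(200, 201))
        errs = []
        for i, (s, e) in enumerate(extents):
            rec, rep = reconstruct_blinks(table.trace("pupil_cue", i))
            assert rep.n_blinks >= 1
            assert rep.n_cubic_samples > 0  # interior blink: spline route
            assert not np.isnan(rec.values[s:e]).any()
            err = np.max(np.abs(rec.values[s:e] - truth.clean_pupil[i, s:e]))
            errs.append(err / np.ptp(truth.clean_pupil[i]))
        assert np.median(errs) < 0.05

    def test_long_gap_is_never_interpolated(self):
        table, truth, extents = one_blink_dataset(1, dur_ms=(600, 601))
        for i, (s, e) in enumerate(extents):
            rec, rep = reconstruct_blinks(table.trace("pupil_cue", i))
            inner = rec.values[s + 25:e - 25]  # plateau, well inside ramps
            assert np.isnan(inner).all()
            assert rep.n_cubic_samples == 0
            assert rep.n_linear_samples == 0

    def test_constant_trace_returned_identical(self):
        tr = PupilTrace(np.full(2000, 1800.0), 1000.0)
        rec, rep = reconstruct_blinks(tr)
        assert np.array_equal(rec.values, tr.values)
        assert rep.n_blinks == 0 and rep.n_marked_missing == 0

    def test_blink_at_trace_start_has_no_anchor_and_no_error(self):
        spec = SyntheticSpec(n_participants=1, trials_per_participant=1,
                             blink_rate=0.0, seed=2)
        table, _ = simulate_dataset(spec)
        values = table.series["pupil_cue"][0]
        inject_blink(values, 0, 200, 20)
        rec, rep = reconstruct_blinks(PupilTrace(values, 1000.0))
        # onset-side values stay missing up to the first valid anchor
        assert np.isnan(rec.values[:100]).any()

    def test_idempotent_on_simulator_output(self, small_dataset):
        table, _ = small_dataset
        for i in range(table.n_trials):
            r1, _ = reconstruct_blinks(table.trace("pupil_cue", i))
            r2, rep2 = reconstruct_blinks(r1)
            assert rep2.n_blinks == 0
            assert np.array_equal(r1.values, r2.values, equal_nan=True)

    def test_valid_data_far_from_events_is_bit_identical(self):
        table, truth, extents = one_blink_dataset(3)
        params = BlinkParams()
        pad = int(params.blink_margin_ms + params.smooth_winlen_ms) + 1
        for i, (s, e) in enumerate(extents):
            tr = table.trace("pupil_cue", i)
            rec, _ = reconstruct_blinks(tr, params)
            far = np.ones(tr.n_samples, dtype=bool)
            far[max(0, s - pad):min(tr.n_samples, e + pad)] = False
            assert np.array_equal(rec.values[far], tr.values[far])

    def test_all_missing_trace_warns_and_passes_through(self):
        with pytest.warns(UserWarning, match="entirely missing"):
            rec, rep = reconstruct_blinks(PupilTrace(np.full(100, NA), 1000.0))
        assert rep.all_missing

    def test_trace_shorter_than_smoothing_window_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            reconstruct_blinks(PupilTrace(np.ones(10), 1000.0))

    def test_param_invariants(self):
        with pytest.raises(ValueError):
            BlinkParams(maxdur_ms=15.0, blink_margin_ms=10.0)
        with pytest.raises(ValueError):
            BlinkParams(std_thresh=0.0)

    def test_table_wrapper_records_stage(self, small_dataset):
        table, _ = small_dataset
        out, reports = reconstruct_blinks_table(table, "pupil_cue")
        assert out.history[-1] == "reconstruct"
        assert len(reports) == table.n_trials
        down = downsample_table(out, 10)
        with pytest.raises(PipelineOrderError):
            reconstruct_blinks_table(down, "pupil_cue")


class TestDownsample:
    def test_epoch_grid(self):
        tr = PupilTrace(np.arange(3000.0), 1000.0)
        out = downsample(tr, 10)
        assert out.n_samples == 300
        assert out.rate_hz == 100.0

    @pytest.mark.parametrize(
        "values,factor,expected",
        [
            ([1.0, 1, 3, 3], 2, [1, 3]),
            ([2.0, NA], 2, [2]),
            ([NA, NA, 1.0, 1.0], 2, [NA, 1]),
            ([1.0, 2, 3, 4, 5], 2, [1.5, 3.5]),  # trailing partial dropped
        ],
    )
    def test_block_means_ignore_missing(self, values, factor, expected):
        got = downsample(np.array(values), factor)
        assert np.allclose(got, expected, equal_nan=True)

    def test_factor_one_is_identity(self):
        tr = PupilTrace(np.arange(5.0), 100.0)
        assert np.array_equal(downsample(tr, 1).values, tr.values)

    @pytest.mark.parametrize("factor", [0, -1, 1.5])
    def test_invalid_factor(self, factor):
        with pytest.raises(ValueError):
            downsample(np.arange(10.0), factor)

    def test_mean_conserved_on_full_blocks(self, rng):
        x = rng.normal(size=300)
        assert np.isclose(downsample(x, 10).mean(), x.mean())

    def test_2d_column(self):
        arr = np.arange(12.0).reshape(2, 6)
        out = downsample(arr, 3)
        assert out.shape == (2, 2)
        assert np.allclose(out[0], [1, 4])


class TestCalibration:
    def test_generate_and_refit_power_law(self, rng):
        u = np.linspace(500, 3000, 15)
        mm = 0.05 * u ** 0.5 * (1 + rng.normal(0, 1e-4, 15))
        model = fit_calibration(np.column_stack([mm, u]))
        a, b = model.params
        assert abs(a - 0.05) / 0.05 < 0.01
        assert abs(b - 0.5) / 0.5 < 0.01

    def test_identity_pairs_predict_identity(self):
        u = np.linspace(1, 15, 15)
        model = fit_calibration(np.column_stack([u, u]))
        assert np.allclose(model.predict(u), u, rtol=1e-6)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            fit_calibration([(1.0, 10.0), (2.0, 20.0)])

    def test_nonpositive_units_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(1.0, 0.0), (2.0, 20.0), (3.0, 30.0)])

    def test_degenerate_pairs_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_calibration([(1.0, 10.0), (1.0, 10.0), (1.0, 10.0)])

    def test_transform_inverse_round_trip(self):
        u = np.linspace(500, 3000, 15)
        model = fit_calibration(np.column_stack([0.05 * u ** 0.5, u]))
        x = np.array([[600.0, NA, 2500.0]])
        mm = apply_calibration(model, x)
        assert np.isnan(mm[0, 1])  # missing passes through
        back = model.inverse(mm)
        assert np.allclose(back[0, [0, 2]], [600.0, 2500.0])

    def test_below_range_warns_but_transforms(self):
        u = np.linspace(500, 3000, 15)
        model = fit_calibration(np.column_stack([0.05 * u ** 0.5, u]))
        with pytest.warns(UserWarning, match="extrapolat"):
            out = apply_calibration(model, np.array([100.0]))
        assert np.isfinite(out[0])

    def test_linear_form(self):
        u = np.linspace(500, 3000, 15)
        model = fit_calibration(np.column_stack([0.001 * u + 1, u]), "linear")
        assert np.allclose(model.params, (1.0, 0.001), atol=1e-9)


class TestBaselineCorrect:
    def test_subtractive_example(self):
        col = np.array([[4.0, 4, 6, 8]])
        out, b = baseline_correct(col, 1000.0, 0.0,
                                  BaselineSpec(TimeWindow(0, 2)))
        assert np.allclose(out, [[0, 0, 2, 4]])
        assert b[0] == 4.0

    def test_divisive_example(self):
        col = np.array([[4.0, 4, 6, 8]])
        out, _ = baseline_correct(col, 1000.0, 0.0,
                                  BaselineSpec(TimeWindow(0, 2), "divisive"))
        assert np.allclose(out, [[1, 1, 1.5, 2]])

    def test_corrected_baseline_window_mean_is_zero_or_one(self, rng):
        col = rng.normal(1800, 50, size=(40, 300))
        for mode, target in (("subtractive", 0.0), ("divisive", 1.0)):
            out, _ = baseline_correct(col, 100.0, 0.0,
                                      BaselineSpec(TimeWindow(0, 50), mode))
            means = out[:, :5].mean(axis=1)
            assert np.allclose(means, target, atol=1e-12)

    def test_all_missing_window_voids_the_trial(self):
        col = np.array([[NA, NA, 6.0, 8.0], [1.0, 1, 2, 3]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out, b = baseline_correct(col, 1000.0, 0.0,
                                      BaselineSpec(TimeWindow(0, 2)))
        assert np.isnan(out[0]).all()
        assert np.isnan(b[0])
        assert np.allclose(out[1], [0, 0, 1, 2])

    def test_divisive_zero_baseline_warns_and_voids(self):
        col = np.array([[0.0, 0, 6, 8]])
        with pytest.warns(UserWarning, match="zero baseline"):
            out, b = baseline_correct(col, 1000.0, 0.0,
                                      BaselineSpec(TimeWindow(0, 2), "divisive"))
        assert np.isnan(out).all()

    def test_table_wrapper_stores_baselines(self, small_dataset):
        table, _ = small_dataset
        out, b = baseline_correct_table(table, "pupil_cue",
                                        BaselineSpec(TimeWindow(0, 50)))
        assert "baseline_pupil_cue" in out.scalars.columns
        assert out.history[-1] == "baseline"


class TestExcludeBaselineOutliers:
    def make_table(self, participants):
        return TrialTable(pd.DataFrame({"participant": participants}))

    def test_single_extreme_trial_excluded(self):
        t = self.make_table([0] * 10)
        baselines = np.array([0.0] * 9 + [10.0])
        filt, mask, counts = exclude_baseline_outliers(t, baselines, 2.0)
        # brute-force z with sample SD: only the 10-valued trial exceeds 2
        z = (baselines - baselines.mean()) / baselines.std(ddof=1)
        assert np.array_equal(mask, np.abs(z) > 2)
        assert mask.sum() == 1 and mask[-1]
        assert filt.n_trials == 9
        assert counts["n_excluded"].sum() == 1

    def test_zero_variance_excludes_nothing(self):
        t = self.make_table([0] * 5)
        with pytest.warns(UserWarning, match="zero baseline variance"):
            _, mask, _ = exclude_baseline_outliers(t, np.ones(5), 2.0)
        assert not mask.any()

    def test_matches_brute_force_per_participant_zscores(self, rng):
        part = np.repeat([0, 1, 2], 50)
        t = self.make_table(part)
        b = rng.normal(5, 2, 150)
        _, mask, _ = exclude_baseline_outliers(t, b, 2.0)
        expect = np.zeros(150, dtype=bool)
        for p in (0, 1, 2):
            sel = part == p
            z = (b[sel] - b[sel].mean()) / b[sel].std(ddof=1)
            expect[sel] = np.abs(z) > 2
        assert np.array_equal(mask, expect)

    def test_missing_baseline_always_excluded(self):
        t = self.make_table([0] * 5)
        b = np.array([1.0, 2.0, 3.0, NA, 2.0])
        _, mask, _ = exclude_baseline_outliers(t, b, 2.0)
        assert mask[3]

    def test_misaligned_baselines_rejected(self):
        with pytest.raises(ValueError, match="align"):
            exclude_baseline_outliers(self.make_table([0, 0]), np.ones(3))
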