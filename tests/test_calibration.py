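"""Calibration: manual-score handling, grid search, selection cascade, persistence."""

import dataclasses
import json
import math

import numpy as np
import pytest

from freezeframe import (
    CalibrationError,
    CalibrationFileError,
    DetectionParams,
    GridResult,
    GridSpec,
    ManualFractionStatus,
    ManualScore,
    MotionTrace,
    ValidationError,
    calibrate,
    check_manual_fraction,
    grid_search,
    load_calibration,
    manual_to_bins,
    motion_trace,
    save_calibration,
    select_parameters,
    validate_calibration,
)


class TestManualScore:
    def test_intervals_normalized_and_merged(self):
        score = ManualScore(((30.0, 40.0), (0.0, 10.0), (10.0, 15.0)), 120.0)
        assert score.intervals == ((0.0, 15.0), (30.0, 40.0))
        assert score.freezing_s == pytest.approx(25.0)

    def test_interval_outside_video_rejected(self):
        with pytest.raises(ValidationError):
            ManualScore(((100.0, 130.0),), 120.0)

    def test_empty_interval_rejected(self):
        with pytest.raises(ValidationError):
            ManualScore(((10.0, 10.0),), 120.0)

    def test_frame_timestamp_importer_merges_consecutive_frames(self):
        fps = 5.0
        # frames 10..24 and 50..54 marked freezing
        ts = [i / fps for i in range(10, 25)] + [i / fps for i in range(50, 55)]
        score = ManualScore.from_frame_timestamps(ts, fps, 60.0)
        assert score.intervals == ((2.0, 5.0), (10.0, 11.0))

    def test_intervals_csv_importer(self, tmp_path):
        path = tmp_path / "manual.csv"
        path.write_text("start_s,end_s\n0,20\n40.5,60\n")
        score = ManualScore.from_intervals_csv(path, 120.0)
        assert score.intervals == ((0.0, 20.0), (40.5, 60.0))

    def test_csv_without_header_rejected(self, tmp_path):
        path = tmp_path / "manual.csv"
        path.write_text("0,20\n40,60\n")
        with pytest.raises(ValidationError):
            ManualScore.from_intervals_csv(path, 120.0)


class TestManualFraction:
    @pytest.mark.parametrize(
        "fraction,expected",
        [
            (0.50, ManualFractionStatus.OK),
            (0.09, ManualFractionStatus.WARN_LOW),
            (0.95, ManualFractionStatus.WARN_HIGH),
            (0.10, ManualFractionStatus.OK),  # boundaries are inclusive
            (0.90, ManualFractionStatus.OK),
        ],
    )
    def test_warning_bands(self, fraction, expected):
        score = ManualScore(((0.0, fraction * 120.0),), 120.0)
        assert check_manual_fraction(score) is expected


class TestManualToBins:
    def test_full_coverage_fills_all_bins(self):
        score = ManualScore(((0.0, 120.0),), 120.0)
        series = manual_to_bins(score, 20.0, fps=10.0)
        assert series.n_bins == 6
        # 1199 frame pairs in 120 s at 10 fps
        assert series.values.sum() == pytest.approx(119.9)
        assert (series.values >= 19.8).all()

    def test_empty_score_gives_zero_bins(self):
        series = manual_to_bins(ManualScore((), 120.0), 20.0, fps=10.0)
        assert (series.values == 0).all()

    def test_partial_interval_lands_in_right_bins(self):
        score = ManualScore(((10.0, 30.0),), 120.0)
        series = manual_to_bins(score, 20.0, fps=10.0)
        assert series.values[0] == pytest.approx(10.0, abs=0.1)
        assert series.values[1] == pytest.approx(10.0, abs=0.1)
        assert (series.values[2:] == 0).all()


def pearson_ols_oracle(x, y):
    """Textbook formulas, independent of scipy."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    sxy = ((x - xm) * (y - ym)).sum()
    sxx = ((x - xm) ** 2).sum()
    syy = ((y - ym) ** 2).sum()
    r = sxy / math.sqrt(sxx * syy)
    slope = sxy / sxx
    return r, slope, ym - slope * xm


class TestGridSearch:
    @pytest.fixture()
    def contrived(self):
        """Hand-built trace: movement pattern with varied per-bin freezing."""
        rng = np.random.default_rng(42)
        fps = 5.0
        counts = rng.integers(0, 1200, size=599)  # 120 s
        trace = MotionTrace(counts=counts, fps=fps, n_pixels=10_000)
        score = ManualScore(((0.0, 25.0), (50.0, 60.0), (80.0, 115.0)), 120.0)
        return trace, manual_to_bins(score, 20.0, fps)

    def test_results_match_textbook_formulas(self, contrived):
        trace, manual_bins = contrived
        grid = GridSpec(thresholds=(200, 600, 1000), min_freeze_times=(0.0, 0.5))
        from freezeframe import bin_freezing, detect_freezing

        for res in grid_search(trace, manual_bins, grid):
            track = detect_freezing(trace, res.params)
            auto = bin_freezing(track, 20.0).full_bin_values
            manual = manual_bins.full_bin_values
            if np.ptp(auto) == 0:
                assert not res.defined
                continue
            r, slope, intercept = pearson_ols_oracle(manual, auto)
            assert res.r == pytest.approx(r)
            assert res.slope == pytest.approx(slope)
            assert res.intercept == pytest.approx(intercept)

    def test_default_grid_has_540_combinations(self, contrived):
        trace, manual_bins = contrived
        results = grid_search(trace, manual_bins)
        assert len(results) == 540

    def test_constant_manual_bins_rejected(self, contrived):
        trace, _ = contrived
        flat = manual_to_bins(ManualScore(((0.0, 120.0),), 120.0), 20.0, trace.fps)
        with pytest.raises(CalibrationError, match="constant"):
            grid_search(trace, flat)

    def test_zero_variance_automated_bins_are_undefined(self, contrived):
        trace, manual_bins = contrived
        # threshold 0 freezes nothing anywhere -> constant (zero) automated bins
        grid = GridSpec(thresholds=(0,), min_freeze_times=(0.0,))
        (res,) = grid_search(trace, manual_bins, grid)
        assert not res.defined

    def test_too_few_bins_rejected(self):
        trace = MotionTrace(counts=np.zeros(199, int), fps=5.0, n_pixels=1000)  # 40 s
        manual_bins = manual_to_bins(ManualScore(((0.0, 15.0),), 40.0), 20.0, 5.0)
        with pytest.raises(CalibrationError, match="full"):
            grid_search(trace, manual_bins)


def cascade_oracle(results):
    """Brute-force three-stage sort, written independently of the implementation."""
    defined = [g for g in results if math.isfinite(g.r)]
    key = lambda g: (g.params.threshold_px, g.params.min_freeze_s)
    top_r = sorted(defined, key=lambda g: (-g.r, key(g)))[:10]
    top_slope = sorted(top_r, key=lambda g: (abs(g.slope - 1), key(g)))[:5]
    return min(top_slope, key=lambda g: (abs(g.intercept), key(g)))


def random_results(rng, n=540):
    out = []
    thresholds = range(100, 6001, 100)
    times = [i * 0.25 for i in range(9)]
    for t in thresholds:
        for m in times:
            if len(out) >= n:
                break
            out.append(
                GridResult(
                    params=DetectionParams(t, m),
                    r=float(rng.uniform(-1, 1)),
                    slope=float(rng.uniform(-0.5, 2.5)),
                    intercept=float(rng.uniform(-30, 30)),
                )
            )
    return out[:n]


class TestSelectParameters:
    def test_perfect_fit_wins(self, rng):
        results = random_results(rng)
        winner = GridResult(DetectionParams(700, 0.5), r=1.0, slope=1.0, intercept=0.0)
        results[123] = winner
        # clamp competitors below r=1 so the perfect entry tops stage 1
        results = [
            dataclasses.replace(g, r=min(g.r, 0.999)) if g is not winner else g
            for g in results
        ]
        assert select_parameters(results) == winner

    def test_matches_brute_force_cascade_on_randomized_grids(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            results = random_results(rng)
            assert select_parameters(results) == cascade_oracle(results)

    def test_short_list_keeps_all_then_five(self):
        rng = np.random.default_rng(0)
        results = random_results(rng, n=7)
        assert select_parameters(results) == cascade_oracle(results)

    def test_all_undefined_rejected(self):
        nan = float("nan")
        results = [GridResult(DetectionParams(100, 0.0), nan, nan, nan)]
        with pytest.raises(CalibrationError):
            select_parameters(results)

    def test_ties_break_toward_smaller_parameters(self):
        results = [
            GridResult(DetectionParams(t, m), r=0.9, slope=1.0, intercept=0.0)
            for t in (300, 200, 100)
            for m in (0.5, 0.0)
        ]
        assert select_parameters(results).params == DetectionParams(100, 0.0)


class TestValidateCalibration:
    @pytest.mark.parametrize(
        "r,slope,expected",
        [
            (0.99, 1.0, True),
            (0.963, 1.0, False),  # strict boundary on r
            (0.99, 0.84, False),  # strict boundary on slope
            (0.9631, 0.8401, True),
            (0.5, 1.0, False),
        ],
    )
    def test_strict_thresholds(self, r, slope, expected):
        assert validate_calibration(r, slope) is expected


class TestPersistence:
    def make_result(self):
        from freezeframe.calibration import CalibrationResult

        return CalibrationResult(
            params=DetectionParams(800, 0.75),
            r=0.981,
            slope=0.97,
            intercept=-0.4,
            valid=True,
            bin_width_s=20.0,
            manual_fraction=0.42,
            source_video="clip.avi",
            created="2026-01-01T00:00:00+00:00",
        )

    def test_round_trip_is_field_identical(self, tmp_path):
        result = self.make_result()
        path = tmp_path / "cal.json"
        save_calibration(result, path)
        assert load_calibration(path) == result

    def test_truncated_file_rejected(self, tmp_path):
        path = tmp_path / "cal.json"
        save_calibration(self.make_result(), path)
        path.write_text(path.read_text()[:40])
        with pytest.raises(CalibrationFileError):
            load_calibration(path)

    def test_future_schema_version_rejected(self, tmp_path):
        path = tmp_path / "cal.json"
        save_calibration(self.make_result(), path)
        payload = json.loads(path.read_text())
        payload["schema_version"] = 99
        path.write_text(json.dumps(payload))
        with pytest.raises(CalibrationFileError, match="version"):
            load_calibration(path)

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(CalibrationFileError):
            load_calibration(tmp_path / "absent.json")


class TestEndToEndCalibration:
    def test_ground_truth_recovery_on_synthetic_video(self, mixed_video, mixed_trace):
        score = ManualScore(
            tuple(mixed_video.schedule.freezing_intervals()),
            mixed_video.schedule.total_duration_s,
        )
        result = calibrate(mixed_trace, score, source_video="synthetic")
        assert result.r >= 0.99
        assert 0.9 <= result.slope <= 1.1
        assert result.valid

    def test_calibration_is_deterministic(self, mixed_video, mixed_trace):
        score = ManualScore(
            tuple(mixed_video.schedule.freezing_intervals()),
            mixed_video.schedule.total_duration_s,
        )
        a = calibrate(mixed_trace, score)
        b = calibrate(mixed_trace, score)
        assert (a.params, a.r, a.slope, a.intercept) == (b.params, b.r, b.slope, b.intercept)
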