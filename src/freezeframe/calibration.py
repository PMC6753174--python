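"""Self-calibration of the freezing detector against one manual score.

The two detection parameters (freezing threshold in pixels, minimum
freezing time in seconds) are tuned on a single manually scored video,
canonically 2 minutes long. The video's motion trace is evaluated under
every parameter combination of a grid — by default thresholds 100..6000 in
steps of 100 crossed with minimum times 0..2 s in steps of 0.25 s, 540
combinations — and each combination's automated freezing seconds per 20-s
bin are regressed on the observer's manual seconds per bin (ordinary least
squares, automated as response).

Selection proceeds in three stages: the 10 combinations with the highest
Pearson r are kept, then the 5 of those with slope closest to 1, then the
single one with intercept closest to 0 — so a combination with good
correlation but poor absolute agreement cannot win. The chosen calibration
is considered a reliable template for scoring other videos recorded under
similar conditions only when r > 0.963 and slope > 0.84; these validity
cutoffs were established empirically (ROC analysis over multi-laboratory
video sets) and are adopted here as constants.

A manual score covering less than 10% or more than 90% of the video length
leaves too little variance across bins for a meaningful fit, so such
scores are flagged with a warning (the calibration still runs).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path

import numpy as np
from scipy import stats

from .detection import (
    BinSeries,
    DetectionParams,
    bin_freezing,
    detect_freezing,
)
from .errors import CalibrationError, CalibrationFileError, ValidationError
from .motion import MotionTrace

#: Validity cutoffs for a calibration to count as a reliable template.
MIN_VALID_R = 0.963
MIN_VALID_SLOPE = 0.84

#: Manual-score coverage outside [10%, 90%] of video time triggers a warning.
MANUAL_FRACTION_LOW = 0.10
MANUAL_FRACTION_HIGH = 0.90

#: Bin width used during calibration (seconds).
CALIBRATION_BIN_S = 20.0

_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ManualScore:
    """Observer-scored freezing intervals for one video (the ground truth)."""

    intervals: tuple[tuple[float, float], ...]
    video_duration_s: float

    def __post_init__(self) -> None:
        norm: list[tuple[float, float]] = []
        for start, end in sorted(self.intervals):
            if not (start < end):
                raise ValidationError(f"empty manual interval [{start}, {end})")
            if start < 0 or end > self.video_duration_s + 1e-9:
                raise ValidationError(
                    f"interval [{start}, {end}) outside [0, {self.video_duration_s}]"
                )
            if norm and start <= norm[-1][1]:  # merge overlapping/abutting
                norm[-1] = (norm[-1][0], max(norm[-1][1], end))
            else:
                norm.append((start, end))
        object.__setattr__(self, "intervals", tuple(norm))

    @property
    def freezing_s(self) -> float:
        return sum(e - s for s, e in self.intervals)

    @property
    def fraction(self) -> float:
        return self.freezing_s / self.video_duration_s

    @classmethod
    def from_intervals_csv(cls, path: str | Path, video_duration_s: float) -> "ManualScore":
        """Read a two-column CSV ``start_s,end_s`` (header required)."""
        import pandas as pd

        df = pd.read_csv(path)
        required = {"start_s", "end_s"}
        if not required.issubset(df.columns):
            raise ValidationError(
                f"{path}: manual-score CSV needs columns start_s,end_s; found {list(df.columns)}"
            )
        intervals = tuple(zip(df["start_s"].astype(float), df["end_s"].astype(float)))
        return cls(intervals=intervals, video_duration_s=video_duration_s)

    @classmethod
    def from_frame_timestamps(
        cls, timestamps_s, fps: float, video_duration_s: float
    ) -> "ManualScore":
        """Build intervals from per-frame freezing timestamps.

        Consecutive timestamps (spacing one frame, with tolerance for
        float jitter) are merged into a single interval; each frame
        contributes one frame-duration of freezing.
        """
        ts = np.sort(np.asarray(list(timestamps_s), dtype=float))
        if ts.size == 0:
            return cls(intervals=(), video_duration_s=video_duration_s)
        step = 1.0 / fps
        intervals: list[tuple[float, float]] = []
        run_start = ts[0]
        prev = ts[0]
        for t in ts[1:]:
            if t - prev > 1.5 * step:
                intervals.append((run_start, prev + step))
                run_start = t
            prev = t
        intervals.append((run_start, prev + step))
        return cls(intervals=tuple(intervals), video_duration_s=video_duration_s)


class ManualFractionStatus(Enum):
    OK = "OK"
    WARN_LOW = "WARN_LOW"
    WARN_HIGH = "WARN_HIGH"


def check_manual_fraction(score: ManualScore) -> ManualFractionStatus:
    """Warn when the manual score covers <10% or >90% of the video time."""
    if score.fraction < MANUAL_FRACTION_LOW:
        return ManualFractionStatus.WARN_LOW
    if score.fraction > MANUAL_FRACTION_HIGH:
        return ManualFractionStatus.WARN_HIGH
    return ManualFractionStatus.OK


def manual_to_bins(score: ManualScore, bin_width_s: float, fps: float) -> BinSeries:
    """Rasterize manual intervals to the frame-pair grid, then bin.

    A frame pair is manually freezing iff its timestamp lies inside one of
    the intervals; the pair then contributes 1/fps seconds to the bin
    containing that timestamp — exactly how automated tracks are binned, so
    the two series are commensurable.
    """
    from .detection import _bin_labels

    n_pairs = round(score.video_duration_s * fps) - 1
    if n_pairs < 1:
        raise ValidationError("video too short to rasterize a manual score")
    pair_times = (np.arange(n_pairs) + 1) / fps
    manual = np.zeros(n_pairs, dtype=bool)
    for start, end in score.intervals:
        manual |= (pair_times >= start) & (pair_times < end)
    return _bin_labels(manual, fps, score.video_duration_s, bin_width_s)


@dataclass(frozen=True)
class GridSpec:
    """The calibration search grid over the two detection parameters."""

    thresholds: tuple[int, ...] = tuple(range(100, 6001, 100))
    min_freeze_times: tuple[float, ...] = tuple(i * 0.25 for i in range(9))

    def __post_init__(self) -> None:
        if not self.thresholds or not self.min_freeze_times:
            raise ValidationError("grid must be non-empty")
        if list(self.thresholds) != sorted(self.thresholds) or list(
            self.min_freeze_times
        ) != sorted(self.min_freeze_times):
            raise ValidationError("grid values must be ascending")

    def combinations(self) -> list[DetectionParams]:
        return [
            DetectionParams(threshold_px=t, min_freeze_s=m)
            for t in self.thresholds
            for m in self.min_freeze_times
        ]


@dataclass(frozen=True)
class GridResult:
    """Linear fit of automated on manual bin values for one combination."""

    params: DetectionParams
    r: float  # NaN when the automated bins have zero variance
    slope: float
    intercept: float

    @property
    def defined(self) -> bool:
        return math.isfinite(self.r)


@dataclass(frozen=True)
class CalibrationResult:
    """The selected parameters with their calibration fit and provenance."""

    params: DetectionParams
    r: float
    slope: float
    intercept: float
    valid: bool
    bin_width_s: float = CALIBRATION_BIN_S
    manual_fraction: float = float("nan")
    source_video: str = ""
    created: str = ""


def validate_calibration(r: float, slope: float) -> bool:
    """True iff the calibration fit clears both validity cutoffs (strictly)."""
    return r > MIN_VALID_R and slope > MIN_VALID_SLOPE


def grid_search(
    trace: MotionTrace, manual_bins: BinSeries, grid: GridSpec | None = None
) -> list[GridResult]:
    """Fit automated vs manual bin values for every grid combination.

    Only full-width bins enter the fit (a trailing partial bin is
    dropped). Combinations whose automated bins are constant get an
    undefined r (NaN) and are excluded from selection downstream.
    """
    grid = grid or GridSpec()
    manual = manual_bins.full_bin_values
    if len(manual) < 3:
        raise CalibrationError(
            f"calibration needs at least 3 full {manual_bins.bin_width_s:g}-s bins, "
            f"got {len(manual)}"
        )
    # a wall-to-wall (or empty) manual score leaves only fencepost jitter of
    # a frame-duration or two across bins; treat that as constant
    if np.ptp(manual) < 2.0 / trace.fps:
        raise CalibrationError(
            "manual score is constant across bins; Pearson r is undefined — "
            "choose a calibration video with more varied freezing"
        )

    results: list[GridResult] = []
    for params in grid.combinations():
        track = detect_freezing(trace, params)
        auto = bin_freezing(track, manual_bins.bin_width_s).full_bin_values
        n = min(len(auto), len(manual))
        auto, man = auto[:n], manual[:n]
        if np.ptp(auto) == 0:
            results.append(
                GridResult(params=params, r=float("nan"), slope=float("nan"), intercept=float("nan"))
            )
            continue
        fit = stats.linregress(man, auto)  # automated = slope * manual + intercept
        results.append(
            GridResult(
                params=params,
                r=float(fit.rvalue),
                slope=float(fit.slope),
                intercept=float(fit.intercept),
            )
        )
    return results


def select_parameters(results: list[GridResult]) -> GridResult:
    """Apply the three-stage selection cascade and return the winner.

    Stage 1 keeps the 10 highest-r combinations (all, if fewer are
    defined); stage 2 keeps the 5 of those with slope closest to 1;
    stage 3 picks the one with intercept closest to 0. Ties at every stage
    break toward the smaller threshold, then the smaller minimum freezing
    time, so selection is deterministic.
    """
    defined = [g for g in results if g.defined]
    if not defined:
        raise CalibrationError(
            "no parameter combination produced a defined correlation; "
            "the motion trace may be degenerate"
        )

    def param_key(g: GridResult) -> tuple[int, float]:
        return (g.params.threshold_px, g.params.min_freeze_s)

    stage1 = sorted(defined, key=lambda g: (-g.r, *param_key(g)))[:10]
    stage2 = sorted(stage1, key=lambda g: (abs(g.slope - 1.0), *param_key(g)))[:5]
    stage3 = sorted(stage2, key=lambda g: (abs(g.intercept), *param_key(g)))
    return stage3[0]


def calibrate(
    trace: MotionTrace,
    score: ManualScore,
    grid: GridSpec | None = None,
    bin_width_s: float = CALIBRATION_BIN_S,
    source_video: str = "",
) -> CalibrationResult:
    """Full calibration pipeline: bin the manual score, search, select, validate."""
    manual_bins = manual_to_bins(score, bin_width_s, trace.fps)
    results = grid_search(trace, manual_bins, grid)
    best = select_parameters(results)
    return CalibrationResult(
        params=best.params,
        r=best.r,
        slope=best.slope,
        intercept=best.intercept,
        valid=validate_calibration(best.r, best.slope),
        bin_width_s=bin_width_s,
        manual_fraction=score.fraction,
        source_video=source_video,
        created=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )


def save_calibration(result: CalibrationResult, path: str | Path) -> None:
    """Persist a calibration as versioned JSON (lossless round trip)."""
    payload = {
        "schema_version": _SCHEMA_VERSION,
        "params": {
            "threshold_px": result.params.threshold_px,
            "min_freeze_s": result.params.min_freeze_s,
        },
        "r": result.r,
        "slope": result.slope,
        "intercept": result.intercept,
        "valid": result.valid,
        "bin_width_s": result.bin_width_s,
        "manual_fraction": result.manual_fraction,
        "source_video": result.source_video,
        "created": result.created,
    }
    Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True) + "\n")


def load_calibration(path: str | Path) -> CalibrationResult:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except OSError as exc:
        raise CalibrationFileError(f"cannot read calibration file {path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise CalibrationFileError(f"corrupt calibration file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise CalibrationFileError(f"{path}: not a calibration file (no schema_version)")
    version = payload["schema_version"]
    if version != _SCHEMA_VERSION:
        raise CalibrationFileError(
            f"{path}: calibration schema version {version} is not supported "
            f"(this build reads version {_SCHEMA_VERSION})"
        )
    try:
        return CalibrationResult(
            params=DetectionParams(
                threshold_px=int(payload["params"]["threshold_px"]),
                min_freeze_s=float(payload["params"]["min_freeze_s"]),
            ),
            r=float(payload["r"]),
            slope=float(payload["slope"]),
            intercept=float(payload["intercept"]),
            valid=bool(payload["valid"]),
            bin_width_s=float(payload["bin_width_s"]),
            manual_fraction=float(payload["manual_fraction"]),
            source_video=str(payload["source_video"]),
            created=str(payload["created"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise CalibrationFileError(f"{path}: malformed calibration file: {exc}") from exc
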