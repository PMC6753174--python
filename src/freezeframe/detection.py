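"""Freezing classification: threshold + minimum-duration filtering, binning.

A frame pair is *provisionally* freezing when its non-overlap count is
strictly below the freezing threshold ("below a given threshold" is read
strictly, so a threshold of 0 can never label anything freezing). A maximal
run of provisionally freezing pairs becomes a freezing epoch only if it
lasts at least the minimum freezing time; shorter runs are discarded
entirely. Each surviving pair contributes 1/fps seconds of freezing.

For reporting and calibration, freezing seconds are aggregated into
fixed-width time bins (20 s during calibration): a pair's 1/fps seconds are
assigned wholly to the bin containing the pair's timestamp, so bin values
always sum exactly to the total freezing time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .motion import MotionTrace


@dataclass(frozen=True)
class DetectionParams:
    """The two calibrated detection parameters.

    threshold_px
        Non-overlap pixel count below which a frame pair is provisionally
        freezing.
    min_freeze_s
        Shortest below-threshold run (seconds) counted as a freezing epoch;
        converted to frames by half-up rounding of ``min_freeze_s * fps``.
    """

    threshold_px: int
    min_freeze_s: float

    def __post_init__(self) -> None:
        if self.threshold_px < 0 or self.min_freeze_s < 0:
            raise ValidationError(f"detection parameters must be non-negative: {self}")


#: Fallback parameters when the user skips calibration.
DEFAULT_PARAMS = DetectionParams(threshold_px=500, min_freeze_s=0.0)


def min_freeze_frames(min_freeze_s: float, fps: float) -> int:
    """Convert a minimum freezing time in seconds to frames (half-up rounding)."""
    return int(np.floor(min_freeze_s * fps + 0.5))


def filter_short_runs(provisional: np.ndarray, min_run: int) -> np.ndarray:
    """Zero out maximal True runs shorter than ``min_run`` elements."""
    provisional = np.asarray(provisional, dtype=bool)
    if min_run <= 1:
        return provisional.copy()
    labels = provisional.copy()
    padded = np.concatenate(([False], provisional, [False])).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    for s, e in zip(starts, ends):
        if e - s < min_run:
            labels[s:e] = False
    return labels


@dataclass(frozen=True)
class FreezingTrack:
    """Boolean freezing labels per frame pair plus derived epochs."""

    labels: np.ndarray
    fps: float
    params: DetectionParams
    duration_s: float = field(default=0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=bool))
        if self.duration_s == 0.0:
            object.__setattr__(self, "duration_s", (len(self.labels) + 1) / self.fps)

    @property
    def pair_times_s(self) -> np.ndarray:
        return (np.arange(len(self.labels)) + 1) / self.fps

    @property
    def total_freezing_s(self) -> float:
        return float(np.count_nonzero(self.labels)) / self.fps

    @property
    def percent_freezing(self) -> float:
        return 100.0 * self.total_freezing_s / self.duration_s

    @property
    def epochs(self) -> list[tuple[float, float]]:
        """Maximal freezing runs as (start_s, end_s) in video time.

        A run of pairs i..j spans frames i..j+1, i.e. video time
        [i/fps, (j+1)/fps); its duration is the run's freezing seconds.
        """
        padded = np.concatenate(([False], self.labels, [False])).astype(np.int8)
        edges = np.diff(padded)
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        return [(s / self.fps, e / self.fps) for s, e in zip(starts, ends)]


@dataclass(frozen=True)
class BinSeries:
    """Freezing seconds aggregated into fixed-width time bins."""

    bin_width_s: float
    values: np.ndarray
    partial_last_bin: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))

    @property
    def n_bins(self) -> int:
        return len(self.values)

    @property
    def full_bin_values(self) -> np.ndarray:
        """Values of the full-width bins only (drops a trailing partial bin)."""
        return self.values[:-1] if self.partial_last_bin else self.values


def _bin_labels(
    labels: np.ndarray, fps: float, duration_s: float, bin_width_s: float
) -> BinSeries:
    if bin_width_s <= 0:
        raise ValidationError(f"bin width must be positive, got {bin_width_s}")
    n_bins = int(np.ceil(duration_s / bin_width_s - 1e-9))
    pair_times = (np.arange(len(labels)) + 1) / fps
    idx = np.minimum((pair_times / bin_width_s).astype(np.int64), n_bins - 1)
    values = np.bincount(idx[labels], minlength=n_bins) / fps
    partial = bool(abs(duration_s / bin_width_s - round(duration_s / bin_width_s)) > 1e-9)
    return BinSeries(bin_width_s=bin_width_s, values=values, partial_last_bin=partial)


def detect_freezing(trace: MotionTrace, params: DetectionParams) -> FreezingTrack:
    """Classify every frame pair of a motion trace as freezing or not."""
    provisional = trace.counts < params.threshold_px
    min_run = min_freeze_frames(params.min_freeze_s, trace.fps)
    labels = filter_short_runs(provisional, min_run)
    return FreezingTrack(
        labels=labels, fps=trace.fps, params=params, duration_s=trace.duration_s
    )


def bin_freezing(track: FreezingTrack, bin_width_s: float) -> BinSeries:
    """Aggregate a track's freezing seconds into fixed-width bins."""
    return _bin_labels(track.labels, track.fps, track.duration_s, bin_width_s)


def epochs_report(track: FreezingTrack) -> list[tuple[float, float, float]]:
    """One (start_s, end_s, duration_s) row per freezing epoch."""
    return [(s, e, e - s) for s, e in track.epochs]
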