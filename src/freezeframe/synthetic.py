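"""Synthetic conditioning-chamber videos with a known freezing schedule.

Real validation recordings are a single rodent in a chamber filmed by a
fixed camera: a compact high-contrast animal over an essentially uniform
background, alternating bouts of locomotion and complete immobility. The
generator emulates exactly that geometry — a filled bright ellipse on a
dark background whose center performs a bounded random walk while MOVING
and is pinned while FREEZING — plus optional i.i.d. Gaussian pixel noise to
stress the binarization. It makes no attempt at photorealism, multiple
animals, shadows, or reflections; its role is to provide ground truth the
detector can be scored against.

Every run is fully determined by its seed, and the schedule that drove the
rendering is returned alongside the frames so tests can compare detected
freezing to the truth.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np

from ._avi import write_avi
from .errors import ValidationError
from .video_io import MIN_FPS, MIN_HEIGHT, MIN_WIDTH


class State(str, Enum):
    FREEZING = "FREEZING"
    MOVING = "MOVING"


@dataclass(frozen=True)
class EpochSchedule:
    """Contiguous alternating FREEZING/MOVING epochs covering [0, total)."""

    epochs: tuple[tuple[float, float, State], ...]
    total_duration_s: float

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValidationError("schedule must contain at least one epoch")
        merged: list[tuple[float, float, State]] = []
        prev_end = 0.0
        for start, end, state in self.epochs:
            if not (start < end):
                raise ValidationError(f"empty epoch [{start}, {end})")
            if abs(start - prev_end) > 1e-9:
                raise ValidationError(f"epochs not contiguous at t={start}")
            if merged and merged[-1][2] == state:  # merge adjacent same-state epochs
                merged[-1] = (merged[-1][0], end, state)
            else:
                merged.append((start, end, State(state)))
            prev_end = end
        if abs(prev_end - self.total_duration_s) > 1e-9:
            raise ValidationError(
                f"epochs cover [0, {prev_end}) but total duration is {self.total_duration_s}"
            )
        object.__setattr__(self, "epochs", tuple(merged))

    def state_at(self, t: float) -> State:
        """Schedule state at time t (last epoch is closed on the right)."""
        for start, end, state in self.epochs:
            if start <= t < end:
                return state
        return self.epochs[-1][2]

    @property
    def freezing_s(self) -> float:
        return sum(e - s for s, e, st in self.epochs if st is State.FREEZING)

    def freezing_intervals(self) -> list[tuple[float, float]]:
        return [(s, e) for s, e, st in self.epochs if st is State.FREEZING]


@dataclass(frozen=True)
class SceneConfig:
    """Rendering geometry and noise model for the simulated chamber."""

    width: int = 384
    height: int = 288
    fps: float = 10.0
    blob_axes: tuple[int, int] = (40, 25)
    blob_intensity: int = 220
    background_intensity: int = 30
    jitter_px: int = 6
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValidationError("fps must be positive")
        ax, ay = self.blob_axes
        margin = self.jitter_px + 1
        if 2 * (ax + margin) >= self.width or 2 * (ay + margin) >= self.height:
            raise ValidationError(
                f"blob axes {self.blob_axes} with jitter {self.jitter_px} do not fit "
                f"inside a {self.width}x{self.height} frame"
            )

    @property
    def below_minimum(self) -> bool:
        return self.width < MIN_WIDTH or self.height < MIN_HEIGHT or self.fps < MIN_FPS


def make_schedule(
    total_duration_s: float,
    freezing_fraction: float,
    mean_epoch_s: float,
    seed: int,
) -> EpochSchedule:
    """Draw an alternating movement/immobility schedule with a set freezing budget.

    Epoch durations are drawn from an exponential distribution with mean
    ``mean_epoch_s`` (floored at 0.5 s so epochs survive frame snapping),
    alternating between the two states, and each state's durations are then
    rescaled so the summed FREEZING time equals
    ``freezing_fraction * total_duration_s`` exactly. Fractions of 0 or 1
    collapse to a single epoch.
    """
    if not 0.0 <= freezing_fraction <= 1.0:
        raise ValidationError(f"freezing_fraction must be in [0, 1], got {freezing_fraction}")
    if total_duration_s <= 0 or mean_epoch_s <= 0:
        raise ValidationError("durations must be positive")

    if freezing_fraction == 0.0:
        return EpochSchedule(((0.0, total_duration_s, State.MOVING),), total_duration_s)
    if freezing_fraction == 1.0:
        return EpochSchedule(((0.0, total_duration_s, State.FREEZING),), total_duration_s)

    rng = np.random.default_rng(seed)
    freeze_budget = freezing_fraction * total_duration_s
    move_budget = total_duration_s - freeze_budget
    # at least one epoch per state; enough of each to spend its budget
    n_freeze = max(1, round(freeze_budget / mean_epoch_s))
    n_move = max(1, round(move_budget / mean_epoch_s))
    freeze_durs = np.maximum(rng.exponential(mean_epoch_s, n_freeze), 0.5)
    move_durs = np.maximum(rng.exponential(mean_epoch_s, n_move), 0.5)
    freeze_durs *= freeze_budget / freeze_durs.sum()
    move_durs *= move_budget / move_durs.sum()

    first = State.MOVING if rng.random() < 0.5 else State.FREEZING
    seqs = {State.FREEZING: list(freeze_durs), State.MOVING: list(move_durs)}
    epochs: list[tuple[float, float, State]] = []
    t = 0.0
    state = first
    while seqs[State.FREEZING] or seqs[State.MOVING]:
        if not seqs[state]:
            state = State.MOVING if state is State.FREEZING else State.FREEZING
        dur = seqs[state].pop(0)
        epochs.append((t, t + dur, state))
        t += dur
        state = State.MOVING if state is State.FREEZING else State.FREEZING
    # guard against float accumulation on the final boundary
    s0, _, st0 = epochs[-1]
    epochs[-1] = (s0, total_duration_s, st0)
    return EpochSchedule(tuple(epochs), total_duration_s)


def _ellipse_mask(height: int, width: int, cy: float, cx: float, ay: float, ax: float) -> np.ndarray:
    yy, xx = np.ogrid[:height, :width]
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def render_video(
    schedule: EpochSchedule, scene: SceneConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Render a schedule into a grayscale frame stack plus per-frame labels.

    Returns
    -------
    (frames, labels)
        ``frames``: uint8 stack of shape (n, height, width);
        ``labels``: boolean array, True where frame ``i`` (at time
        ``i / fps``) falls in a FREEZING epoch.

    During FREEZING the blob center is pinned, so with ``noise_sd = 0``
    consecutive frames inside a freezing epoch are bit-identical. During
    MOVING the center takes a uniform step of up to ``jitter_px`` pixels
    per axis per frame, clamped so the blob never leaves the frame.
    """
    rng = np.random.default_rng(scene.seed)
    n_frames = round(schedule.total_duration_s * scene.fps)
    ax, ay = scene.blob_axes
    lo_x, hi_x = ax + 1, scene.width - ax - 2
    lo_y, hi_y = ay + 1, scene.height - ay - 2

    cx = float(rng.integers(lo_x, hi_x + 1))
    cy = float(rng.integers(lo_y, hi_y + 1))

    frames = np.empty((n_frames, scene.height, scene.width), dtype=np.uint8)
    labels = np.empty(n_frames, dtype=bool)
    background = np.full(
        (scene.height, scene.width), scene.background_intensity, dtype=np.uint8
    )
    for i in range(n_frames):
        state = schedule.state_at(i / scene.fps)
        labels[i] = state is State.FREEZING
        if state is State.MOVING and i > 0 and scene.jitter_px > 0:
            step = rng.integers(-scene.jitter_px, scene.jitter_px + 1, size=2)
            if np.all(step == 0):  # movement epochs must move
                step[rng.integers(0, 2)] = rng.choice([-scene.jitter_px, scene.jitter_px])
            cx = float(np.clip(cx + step[0], lo_x, hi_x))
            cy = float(np.clip(cy + step[1], lo_y, hi_y))
        frame = background.copy()
        frame[_ellipse_mask(scene.height, scene.width, cy, cx, ay, ax)] = scene.blob_intensity
        frames[i] = frame

    if scene.noise_sd > 0:
        noisy = frames.astype(np.float64) + rng.normal(0.0, scene.noise_sd, frames.shape)
        frames = np.clip(noisy.round(), 0, 255).astype(np.uint8)
    return frames, labels


@dataclass(frozen=True)
class SyntheticVideo:
    """A rendered synthetic recording with its ground truth."""

    frames: np.ndarray
    labels: np.ndarray
    schedule: EpochSchedule
    scene: SceneConfig

    @property
    def ground_truth_freezing_s(self) -> float:
        return float(np.count_nonzero(self.labels)) / self.scene.fps


def generate(schedule: EpochSchedule, scene: SceneConfig) -> SyntheticVideo:
    frames, labels = render_video(schedule, scene)
    return SyntheticVideo(frames=frames, labels=labels, schedule=schedule, scene=scene)


def export(video: SyntheticVideo, path: str | Path, sidecar: bool = True) -> Path:
    """Write an AVI (lossless) plus a ground-truth CSV sidecar.

    The sidecar ``<stem>_truth.csv`` has columns frame_index, time_s, state.
    """
    path = Path(path)
    write_avi(path, video.frames, video.scene.fps)
    if sidecar:
        sidecar_path = path.with_name(path.stem + "_truth.csv")
        with open(sidecar_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["frame_index", "time_s", "state"])
            for i, frozen in enumerate(video.labels):
                state = State.FREEZING if frozen else State.MOVING
                writer.writerow([i, f"{i / video.scene.fps:.6f}", state.value])
    return path
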