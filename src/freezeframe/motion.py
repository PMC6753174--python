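"""The motion signal: Otsu binarization and frame-pair non-overlap counts.

Each frame is thresholded into a two-class (black/white) image with Otsu's
method, and consecutive binarized frames are compared pixel by pixel. The
number of positions whose binary values differ — the non-overlap count —
is the per-frame-pair measure of animal movement that the freezing
classifier consumes.

Otsu's level is recomputed for every frame from its own 256-bin histogram,
which makes the binarization robust to slow illumination drift; the cost is
that a pair's count compares two independently thresholded images. The XOR
count is symmetric in the white/black labeling, so whether the animal or
the background ends up white does not affect the signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class MotionTrace:
    """Per-frame-pair non-overlap pixel counts with timing metadata.

    ``counts[i]`` compares frames ``i`` and ``i+1`` and is assigned time
    ``(i+1)/fps``; ``n_pixels`` is the pixel count of the (cropped) frame,
    an upper bound on every entry.
    """

    counts: np.ndarray
    fps: float
    n_pixels: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.int64))
        if self.counts.ndim != 1 or len(self.counts) < 1:
            raise ValidationError("a motion trace needs at least one frame pair")
        if self.fps <= 0:
            raise ValidationError(f"fps must be positive, got {self.fps}")
        if (self.counts < 0).any() or (self.counts > self.n_pixels).any():
            raise ValidationError("counts must lie in [0, n_pixels]")

    @property
    def pair_times_s(self) -> np.ndarray:
        return (np.arange(len(self.counts)) + 1) / self.fps

    @property
    def duration_s(self) -> float:
        """Duration of the underlying video segment."""
        return (len(self.counts) + 1) / self.fps

    def to_csv(self, path: str | Path) -> None:
        """Debug export: one (pair_time_s, count) row per frame pair."""
        import pandas as pd

        pd.DataFrame({"pair_time_s": self.pair_times_s, "count": self.counts}).to_csv(
            path, index=False, float_format="%.6f"
        )


def otsu_level(histogram: np.ndarray) -> int:
    """Otsu threshold level for a 256-bin gray-level histogram.

    Returns the level ``t`` maximizing the between-class variance of the
    split ``{0..t} | {t+1..255}`` (equivalently minimizing the within-class
    variance). Ties are broken toward the lowest level. A histogram with a
    single occupied bin is degenerate and returns that bin's level, so that
    thresholding with ``value > level`` yields a single class.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.shape != (256,):
        raise ValidationError(f"histogram must have 256 bins, got shape {hist.shape}")
    if (hist < 0).any() or hist.sum() == 0:
        raise ValidationError("histogram must be non-negative with at least one count")

    levels = np.arange(256, dtype=np.float64)
    total = hist.sum()
    # cumulative class-0 weight and mean for every candidate split t
    w0 = np.cumsum(hist)
    mu0_sum = np.cumsum(hist * levels)
    mu_total = mu0_sum[-1]
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu0_sum / w0
        mu1 = (mu_total - mu0_sum) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -np.inf  # empty class: split undefined
    if np.all(np.isneginf(between)):  # single occupied bin
        return int(np.argmax(hist))
    return int(np.argmax(between))  # argmax takes the first (lowest) maximizer


def binarize(frame: np.ndarray) -> np.ndarray:
    """Threshold a grayscale frame into a boolean image (white = above Otsu level)."""
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValidationError("cannot binarize an empty frame")
    hist = np.bincount(frame.astype(np.uint8).ravel(), minlength=256)
    return frame > otsu_level(hist)


def nonoverlap_count(a: np.ndarray, b: np.ndarray) -> int:
    """Number of pixel positions where two binary images differ (XOR sum)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    return int(np.count_nonzero(a ^ b))


def motion_trace(frames: np.ndarray, fps: float) -> MotionTrace:
    """Binarize a grayscale stack and count non-overlapping pixels per pair.

    The trace is computed once per video; every downstream parameter
    combination (thresholds, minimum durations) re-reads the same counts.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or len(frames) < 2:
        raise ValidationError("motion_trace needs a stack of at least 2 grayscale frames")
    binary = np.empty(frames.shape, dtype=bool)
    for i, frame in enumerate(frames):
        binary[i] = binarize(frame)
    counts = np.count_nonzero(binary[:-1] ^ binary[1:], axis=(1, 2))
    return MotionTrace(counts=counts, fps=fps, n_pixels=frames.shape[1] * frames.shape[2])
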