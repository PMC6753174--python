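"""Video input: decode to grayscale frame stacks, trim, and crop.

Coordinates are 0-based and half-open everywhere: a crop rectangle
``(x0, y0, x1, y1)`` selects the pixel block ``[x0, x1) x [y0, y1)``, and a
trim window ``[start_s, end_s)`` keeps frames whose timestamps fall inside
it. Frame ``i`` is assigned timestamp ``i / fps``.

AVI files are decoded with the package's built-in lossless codec; other
containers (e.g. MP4) fall back to :mod:`imageio` when a suitable plugin is
available. The automated scorer has only been characterized down to
384 x 288 pixels at 5 frames/s; smaller inputs are accepted with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _avi
from .errors import ValidationError, VideoIOError

#: Minimum characterized input size; below this a warning is issued.
MIN_WIDTH = 384
MIN_HEIGHT = 288
MIN_FPS = 5.0


@dataclass(frozen=True)
class VideoMeta:
    """Timing and geometry metadata for a (possibly trimmed) frame stack."""

    path: str
    fps: float
    n_frames: int
    width: int
    height: int

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass(frozen=True)
class CropRect:
    """Half-open pixel rectangle [x0, x1) x [y0, y1), 0-based."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (0 <= self.x0 < self.x1 and 0 <= self.y0 < self.y1):
            raise ValidationError(f"degenerate crop rectangle {self}")

    @classmethod
    def parse(cls, text: str) -> "CropRect":
        """Parse 'x0,y0,x1,y1'."""
        try:
            x0, y0, x1, y1 = (int(v) for v in text.split(","))
        except ValueError as exc:
            raise ValidationError(f"cannot parse crop rectangle {text!r}") from exc
        return cls(x0, y0, x1, y1)


def _to_grayscale(frames: np.ndarray) -> np.ndarray:
    if frames.ndim == 3:
        return frames
    if frames.ndim == 4 and frames.shape[-1] in (3, 4):
        luma = frames[..., :3].astype(np.float64) @ _avi.LUMA_WEIGHTS
        return np.clip(luma.round(), 0, 255).astype(np.uint8)
    raise VideoIOError(f"unsupported frame stack shape {frames.shape}")


def _read_with_imageio(path: Path) -> tuple[np.ndarray, float]:
    try:
        import imageio.v3 as iio

        meta = iio.immeta(path, plugin=None)
        fps = float(meta.get("fps", 0.0))
        frames = np.asarray(iio.imread(path, index=None))
    except Exception as exc:  # plugin missing, codec unsupported...
        raise VideoIOError(f"cannot decode video file {path}: {exc}") from exc
    if fps <= 0:
        raise VideoIOError(f"{path}: container reports no usable frame rate")
    return _to_grayscale(frames), fps


def read_video(
    path: str | Path,
    start_s: float | None = None,
    end_s: float | None = None,
) -> tuple[VideoMeta, np.ndarray]:
    """Decode a video file to a grayscale uint8 stack plus metadata.

    Parameters
    ----------
    path
        Video file. AVI is decoded natively; other containers require an
        imageio plugin.
    start_s, end_s
        Optional trim window in seconds; frames with timestamp in
        ``[start_s, end_s)`` are kept. Metadata reflects the trimmed stack.

    Returns
    -------
    (VideoMeta, frames)
        ``frames`` has shape ``(n_frames, height, width)``, dtype uint8.
    """
    path = Path(path)
    if not path.is_file():
        raise VideoIOError(f"video file not found: {path}")
    if start_s is not None and end_s is not None and start_s >= end_s:
        raise ValidationError(f"start_s ({start_s}) must be < end_s ({end_s})")

    if _avi.is_avi(path):
        frames, fps = _avi.read_avi(path)
    else:
        frames, fps = _read_with_imageio(path)

    if start_s is not None or end_s is not None:
        times = np.arange(len(frames)) / fps
        keep = np.ones(len(frames), dtype=bool)
        if start_s is not None:
            keep &= times >= start_s
        if end_s is not None:
            keep &= times < end_s
        frames = frames[keep]

    if len(frames) < 2:
        raise ValidationError(
            f"{path}: fewer than 2 frames after trimming; motion analysis needs frame pairs"
        )

    n, height, width = frames.shape
    if width < MIN_WIDTH or height < MIN_HEIGHT or fps < MIN_FPS:
        warnings.warn(
            f"{path}: {width}x{height} @ {fps:g} fps is below the characterized "
            f"minimum of {MIN_WIDTH}x{MIN_HEIGHT} @ {MIN_FPS:g} fps; results may be unreliable",
            stacklevel=2,
        )
    return VideoMeta(str(path), fps, n, width, height), frames


def apply_crop(frames: np.ndarray, rect: CropRect) -> np.ndarray:
    """Restrict every frame to ``rect``; pixel values are unchanged."""
    frames = np.asarray(frames)
    height, width = frames.shape[-2:]
    if rect.x1 > width or rect.y1 > height:
        raise ValidationError(
            f"crop rectangle {rect} exceeds frame bounds {width}x{height}"
        )
    return frames[..., rect.y0 : rect.y1, rect.x0 : rect.x1]
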