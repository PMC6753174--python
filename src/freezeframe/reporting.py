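"""Batch analysis of video sets with a saved calibration, plus table export.

Each video runs independently through decode → crop → motion trace →
freezing detection using the calibrated parameters; one failing video
yields an error record without aborting the batch. Results are exported as
a long table of per-bin freezing seconds plus a per-video summary, either
as a single CSV (a ``row_type`` column distinguishes bin rows from summary
rows) or as an XLSX workbook with ``bins`` and ``summary`` sheets. Floats
are written with 3 decimals so re-runs are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .calibration import CalibrationResult
from .detection import (
    BinSeries,
    bin_freezing,
    detect_freezing,
    epochs_report,
)
from .errors import FreezeframeError, ValidationError
from .motion import motion_trace
from .video_io import CropRect, apply_crop, read_video

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisRecord:
    """Per-video analysis output (or a decode error, with ``error`` set)."""

    video: str
    params: object = None
    total_freezing_s: float = 0.0
    percent_freezing: float = 0.0
    bins: BinSeries | None = None
    epochs: list[tuple[float, float, float]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    error: str | None = None


class InvalidCalibrationError(FreezeframeError):
    """Raised when analyzing with a calibration that failed validity checks."""


def analyze_videos(
    paths: list[str | Path],
    calibration: CalibrationResult,
    bin_width_s: float = 20.0,
    crop: CropRect | None = None,
    start_s: float | None = None,
    end_s: float | None = None,
    allow_invalid: bool = False,
) -> list[AnalysisRecord]:
    """Score a set of videos with calibrated parameters.

    Refuses to run with an invalid calibration (r or slope below the
    validity cutoffs) unless ``allow_invalid`` is set; the refusal names
    the criteria so the user knows what failed.
    """
    if not calibration.valid and not allow_invalid:
        raise InvalidCalibrationError(
            f"calibration is not valid (r={calibration.r:.3f}, slope={calibration.slope:.3f}; "
            "requires r > 0.963 and slope > 0.84) — recalibrate with a better video "
            "or pass allow_invalid to override"
        )

    records: list[AnalysisRecord] = []
    for i, path in enumerate(paths):
        path = str(path)
        logger.info("analyzing video %d/%d: %s", i + 1, len(paths), path)
        warnings_list: list[str] = []
        if not calibration.valid:
            warnings_list.append("analyzed with an invalid calibration (override in effect)")
        try:
            import warnings as _warnings

            with _warnings.catch_warnings(record=True) as caught:
                _warnings.simplefilter("always")
                meta, frames = read_video(path, start_s=start_s, end_s=end_s)
                if crop is not None:
                    frames = apply_crop(frames, crop)
                warnings_list.extend(str(w.message) for w in caught)
            trace = motion_trace(frames, meta.fps)
            track = detect_freezing(trace, calibration.params)
            records.append(
                AnalysisRecord(
                    video=path,
                    params=calibration.params,
                    total_freezing_s=track.total_freezing_s,
                    percent_freezing=track.percent_freezing,
                    bins=bin_freezing(track, bin_width_s),
                    epochs=epochs_report(track),
                    warnings=warnings_list,
                )
            )
        except (FreezeframeError, ValidationError, OSError) as exc:
            logger.warning("failed to analyze %s: %s", path, exc)
            records.append(AnalysisRecord(video=path, error=str(exc), warnings=warnings_list))
    ok = sum(1 for r in records if r.error is None)
    logger.info("batch done: %d/%d videos analyzed", ok, len(paths))
    return records


def _tables(
    records: list[AnalysisRecord], calibration: CalibrationResult | None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    bin_rows = []
    summary_rows = []
    for rec in records:
        if rec.error is not None:
            summary_rows.append(
                {
                    "video": rec.video,
                    "total_freezing_s": float("nan"),
                    "percent_freezing": float("nan"),
                    "n_epochs": 0,
                    "threshold_px": float("nan"),
                    "min_freeze_s": float("nan"),
                    "calibration_r": float("nan"),
                    "calibration_slope": float("nan"),
                    "error": rec.error,
                }
            )
            continue
        for k, value in enumerate(rec.bins.values):
            bin_rows.append(
                {
                    "video": rec.video,
                    "bin_index": k,
                    "bin_start_s": k * rec.bins.bin_width_s,
                    "freezing_s": value,
                }
            )
        summary_rows.append(
            {
                "video": rec.video,
                "total_freezing_s": rec.total_freezing_s,
                "percent_freezing": rec.percent_freezing,
                "n_epochs": len(rec.epochs),
                "threshold_px": rec.params.threshold_px,
                "min_freeze_s": rec.params.min_freeze_s,
                "calibration_r": calibration.r if calibration else float("nan"),
                "calibration_slope": calibration.slope if calibration else float("nan"),
                "error": "",
            }
        )
    return pd.DataFrame(bin_rows), pd.DataFrame(summary_rows)


def export_results(
    records: list[AnalysisRecord],
    path: str | Path,
    format: str = "csv",
    calibration: CalibrationResult | None = None,
) -> Path:
    """Write per-bin and per-video tables as CSV or XLSX.

    CSV: one file, ``row_type`` column ∈ {bin, summary}. XLSX: sheets
    ``bins`` and ``summary``. Both carry identical numbers.
    """
    if not records:
        raise ValidationError("no analysis records to export")
    path = Path(path)
    bins_df, summary_df = _tables(records, calibration)
    if format == "csv":
        bins_df = bins_df.assign(row_type="bin")
        summary_df = summary_df.assign(row_type="summary")
        combined = pd.concat([bins_df, summary_df], ignore_index=True)
        cols = ["row_type"] + [c for c in combined.columns if c != "row_type"]
        combined[cols].to_csv(path, index=False, float_format="%.3f")
    elif format == "xlsx":
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            bins_df.round(3).to_excel(writer, sheet_name="bins", index=False)
            summary_df.round(3).to_excel(writer, sheet_name="summary", index=False)
    else:
        raise ValidationError(f"unknown export format {format!r} (use csv or xlsx)")
    return path
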