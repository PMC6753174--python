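# Methods

## Motion signal

Frames are converted to single-channel grayscale (BT.601 luma for color
input) and each frame is binarized with Otsu's method: the level `t`
maximizing the between-class variance of the frame's 256-bin gray-level
histogram, a pixel being white iff its value is strictly greater than `t`.
The per-frame-pair motion signal is the non-overlap count — the number of
pixel positions whose binary values differ between the two binarized
frames (an XOR sum). Pair `i` (frames `i` and `i+1`) is assigned timestamp
`(i+1)/fps`.

Choices worth knowing:

- **Per-frame Otsu.** The threshold is recomputed from each frame's own
  histogram rather than once per video, which tolerates slow illumination
  drift. The consequence is that a pair's count compares two independently
  thresholded images; on high-contrast footage the thresholds agree and
  the effect is negligible.
- **Degenerate frames.** A constant frame has no two-class split; it
  binarizes to all-black, which minimizes spurious XOR against its
  neighbors. Otsu ties break toward the lowest level, making binarization
  deterministic.
- **Cropping.** Counts are computed on the user's crop rectangle only
  (0-based, half-open coordinates). Cropping reduces the pixel budget, so
  thresholds calibrated on one crop do not transfer to another.
- The XOR count is invariant to which class (animal or background) ends up
  white, so no foreground assumption is needed.

## Freezing classification

Given a threshold θ (pixels) and minimum freezing time τ (seconds), pair
`i` is provisionally freezing iff `count[i] < θ` — strictly below, so θ = 0
can never label anything freezing. A maximal run of provisionally freezing
pairs is kept iff its length in frames is at least `round(τ · fps)`
(half-up rounding; e.g. 0.25 s at 30 fps → 8 frames, at 10 fps → 3).
Rounding half-up rather than to-even keeps the seconds→frames conversion
monotone and unsurprising across the calibration grid. Run-length
comparison is inclusive (`≥`): a run exactly at the minimum counts. Runs
are filtered independently; near-adjacent runs are never merged.

Each surviving pair contributes `1/fps` seconds of freezing, assigned
wholly to the time bin containing the pair's timestamp (no splitting
across bin edges), so bin values always sum exactly to the total freezing
time and no bin can exceed its width. A 120-s video therefore yields
`n_frames − 1` pairs and its six 20-s bins carry 119.9 s at 10 fps — the
first bin is one pair short, an inherent fencepost of pairwise
differencing.

Total freezing time is non-decreasing in θ and non-increasing in τ; both
properties are tested.

## Calibration

The calibration grid is θ ∈ {100, …, 6000} px (step 100) × τ ∈ {0, …, 2} s
(step 0.25), 540 combinations; the motion trace is computed once and
re-thresholded per combination. For each combination, automated freezing
seconds per 20-s bin are regressed on the manual score's seconds per bin
(ordinary least squares, automated as response); only full-width bins
enter the fit, and the manual score is rasterized to the same frame-pair
grid as the automated track so both series are commensurable.

Selection cascade: keep the 10 combinations with highest Pearson r, of
those the 5 with slope closest to 1, of those the single one with
intercept closest to 0. Ties at every stage break toward the smaller
threshold, then the smaller minimum time, so calibration is fully
deterministic. Combinations whose automated bins are constant (e.g. a
threshold below every count) have undefined r and are excluded *before*
the top-10 cut — scoring them r = 0 would let degenerate fits compete.
Manual bins whose spread is below two frame-durations (an all-freezing or
all-moving score, up to fencepost jitter) abort calibration with an error
telling the user to pick a different video.

A calibration is **valid** iff r > 0.963 and slope > 0.84 (both strict).
These constants were established empirically by ROC analysis over
multi-laboratory video sets and are adopted as fixed criteria, not
re-derived. A manual score covering < 10% or > 90% of the video time
yields a warning (never an error): near-constant freezing leaves too
little between-bin variance for the fit to be meaningful. Calibration uses
exactly one video; with none, the documented fallback parameters are
θ = 500 px, τ = 0 s.

Calibrations persist as versioned JSON (schema_version 1) carrying the
parameters, fit statistics, validity flag, bin width, manual fraction and
provenance; unknown versions are rejected rather than misread. Manual
scores are read from interval CSVs (`start_s,end_s`) or converted from
per-frame freezing timestamps by merging consecutive frames.

## Synthetic videos

The generator emulates the relevant structure of a conditioning-chamber
recording: a single high-contrast animal (filled bright ellipse, default
gray 220 on background 30) on a uniform background, whose center performs
a bounded random walk of up to `jitter_px` per axis per frame while MOVING
and is pinned while FREEZING, with optional i.i.d. additive Gaussian pixel
noise (clipped to [0, 255]) to stress the binarization. Schedules
alternate MOVING/FREEZING epochs with exponential-like durations (mean
`mean_epoch_s`, floored at 0.5 s) rescaled so the freezing fraction is
exact before epochs are snapped to the frame grid. Defaults mirror the
recommended recording floor: 384×288 px at 10 fps, 120-s duration,
freezing fraction 0.5, mean epoch 10 s, noiseless; everything is
reproducible from a single seed.

What the generator does *not* model — and what passing tests therefore do
not show: textured or drifting backgrounds, shadows and mirror artifacts,
posture changes during immobility (respiration), low animal/background
contrast, compression artifacts, multiple animals. Ground-truth recovery
on this synthetic data demonstrates the pipeline's correctness (on
separable input, calibration finds r ≈ 1 at unit slope and generalizes
across seeds), not its accuracy on real footage, which depends on contrast
and recording quality.

On-disk fixtures use the built-in uncompressed 8-bit AVI codec so the
write/read round trip is bit-exact; a lossy codec would inject pixel
differences that read as motion.

## Problem sizes and numerical notes

Unit tests run on small scenes (120×90 px, 5 fps, 20–60 s) for speed;
end-to-end recovery tests use the full 384×288 @ 10 fps, 120-s
configuration (six calibration-scale videos). The acceptance script
renders one such video, calibrates it against its own schedule, and
locates the validity boundaries by bisection to 1e-6. Float comparisons in
conservation checks use absolute tolerances of ~1e-9 s; exports fix floats
at 3 decimals so repeated runs are byte-identical.

## Known limitations

- Pixel-count thresholds are resolution- and crop-dependent; a calibration
  is only a template for videos recorded and cropped under similar
  conditions.
- Variable-frame-rate containers are treated as having their nominal fps;
  timing within a pair is assumed uniform.
- The dual start/stop-threshold variant and darting/active-response
  detection are deliberately out of scope; a single threshold plus minimum
  duration is the supported model.
- MAT-format calibration files from other tools are not read; the JSON
  schema is the canonical format and a MAT import shim is a possible
  extension.
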