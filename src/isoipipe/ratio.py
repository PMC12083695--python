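"""Raw trial stacks -> trial-averaged fractional-change (dR/R) ratio series.

The analysis chain is: sum 100 ms raw frames to 500 ms analysis frames,
divide every post-onset frame by the single pre-stimulus frame collected
immediately before stimulus onset (fractional change = ratio - 1), average
across the trials of a block, Gaussian-smooth individual frames, and select
the frame carrying the maximum areal extent of each signal phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .protocols import DEFAULT_MM_PER_PIXEL, PhaseSpec, SMOOTH_HALF_WIDTH_PX, hwhm_to_sigma

#: Intensities at or above this count are treated as saturated 16-bit pixels.
SATURATION_LEVEL = 65535.0


class NoSuprathresholdActivityError(ValueError):
    """No frame in the search window has any suprathreshold pixel in the ROI."""


@dataclass
class TrialStack:
    """One trial's frame sequence with timing and spatial calibration.

    frames are (time, height, width), non-negative, 16-bit-compatible counts
    (stored as floats so downstream ratios are not quantisation-limited).
    ``onset_frame`` indexes the first frame during which the stimulus is on.
    """

    frames: np.ndarray
    frame_duration_ms: float
    onset_frame: int
    mm_per_pixel: float = DEFAULT_MM_PER_PIXEL
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (time, height, width) array")
        if self.onset_frame < 1:
            raise ValueError("onset_frame must leave at least one pre-stimulus frame")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class RatioSeries:
    """Post-onset fractional-change frames at 500 ms resolution.

    ``fc_frames[k]`` covers ``[0.5 k, 0.5 (k+1))`` seconds after stimulus
    onset; ``times_s`` holds the frame mid-times.  ``saturated`` marks pixels
    that hit the 16-bit ceiling in any contributing frame; they are excluded
    from downstream statistics.
    """

    fc_frames: np.ndarray
    times_s: np.ndarray
    n_trials_averaged: int = 1
    mm_per_pixel: float = DEFAULT_MM_PER_PIXEL
    saturated: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fc_frames = np.asarray(self.fc_frames, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.fc_frames.shape[0] != self.times_s.shape[0]:
            raise ValueError("times_s length must match number of frames")
        if not np.all(np.isfinite(self.fc_frames)):
            raise ValueError("fractional-change values must be finite")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times_s must be strictly increasing")
        if self.saturated is None:
            self.saturated = np.zeros(self.fc_frames.shape[1:], dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.fc_frames.shape[0]

    def frame_at(self, t: float) -> int:
        """Index of the frame whose half-open interval contains time ``t``."""
        dt = self.times_s[1] - self.times_s[0] if self.n_frames > 1 else 0.5
        start = self.times_s[0] - dt / 2.0
        k = int(np.floor((t - start) / dt))
        if k < 0 or k >= self.n_frames:
            raise IndexError(f"time {t} s outside series")
        return k


def sum_to_analysis_frames(stack: TrialStack, factor: int = 5) -> TrialStack:
    """Sum consecutive raw frames into longer analysis frames.

    Output frame ``i`` is the elementwise sum of input frames
    ``[factor*i, factor*(i+1))``; a trailing remainder that does not fill a
    full analysis frame is dropped with a warning.  The stimulus-onset index
    is remapped; raw onset must fall on an analysis-frame boundary.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    n = stack.n_frames
    n_out = n // factor
    if n_out == 0:
        raise ValueError("stack shorter than one analysis frame")
    if n % factor:
        warnings.warn(
            f"dropping {n % factor} trailing raw frame(s) not filling an analysis frame",
            stacklevel=2,
        )
    if stack.onset_frame % factor:
        raise ValueError(
            "stimulus onset does not fall on an analysis-frame boundary "
            f"(onset_frame={stack.onset_frame}, factor={factor})"
        )
    frames = stack.frames[: n_out * factor].astype(np.float64, copy=False)
    summed = frames.reshape(n_out, factor, *stack.shape).sum(axis=1)
    return TrialStack(
        frames=summed,
        frame_duration_ms=stack.frame_duration_ms * factor,
        onset_frame=stack.onset_frame // factor,
        mm_per_pixel=stack.mm_per_pixel,
        meta={**stack.meta, "summed_by": factor},
    )


def compute_ratio_series(stack: TrialStack) -> RatioSeries:
    """Fractional change of each post-onset frame against the pre-onset frame.

    The reference is the single analysis frame collected immediately before
    stimulus onset: ``FC[k] = frames[onset+k] / frames[onset-1] - 1``.
    Pixels saturating the 16-bit range anywhere in the series are flagged.
    """
    if stack.onset_frame < 1:
        raise ValueError("onset_frame must be >= 1 to leave a reference frame")
    ref = stack.frames[stack.onset_frame - 1].astype(np.float64)
    if np.any(ref <= 0):
        bad = np.argwhere(ref <= 0)[0]
        raise ValueError(
            f"non-positive reference-frame pixel at (row={bad[0]}, col={bad[1]})"
        )
    post = stack.frames[stack.onset_frame :].astype(np.float64)
    fc = post / ref - 1.0
    dt = stack.frame_duration_ms / 1000.0
    times = (np.arange(post.shape[0]) + 0.5) * dt
    saturated = (post >= SATURATION_LEVEL).any(axis=0) | (ref >= SATURATION_LEVEL)
    return RatioSeries(
        fc_frames=fc,
        times_s=times,
        n_trials_averaged=1,
        mm_per_pixel=stack.mm_per_pixel,
        saturated=saturated,
        provenance={
            "reference_frame": stack.onset_frame - 1,
            "frame_duration_ms": stack.frame_duration_ms,
            **stack.meta,
        },
    )


def average_trials(series_list: list[RatioSeries]) -> RatioSeries:
    """Pixelwise mean of co-registered single-trial ratio series."""
    if not series_list:
        raise ValueError("empty series list")
    first = series_list[0]
    for s in series_list[1:]:
        if s.fc_frames.shape != first.fc_frames.shape:
            raise ValueError("mismatched frame shapes across trials")
        if not np.allclose(s.times_s, first.times_s):
            raise ValueError("mismatched frame timing across trials")
        if s.mm_per_pixel != first.mm_per_pixel:
            raise ValueError("mismatched spatial calibration across trials")
    mean_fc = np.mean([s.fc_frames for s in series_list], axis=0)
    saturated = np.any([s.saturated for s in series_list], axis=0)
    n = sum(s.n_trials_averaged for s in series_list)
    return RatioSeries(
        fc_frames=mean_fc,
        times_s=first.times_s.copy(),
        n_trials_averaged=n,
        mm_per_pixel=first.mm_per_pixel,
        saturated=saturated,
        provenance={**first.provenance, "n_trials_averaged": n},
    )


def smooth_frame(frame: np.ndarray, half_width: float = SMOOTH_HALF_WIDTH_PX) -> np.ndarray:
    """Gaussian-filter a single dR/R frame.

    ``half_width`` is the kernel's half-width at half-maximum in pixels
    (sigma = half_width / sqrt(2 ln 2)); boundaries are handled by
    reflection, so constant images pass through unchanged.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite pixels")
    return ndimage.gaussian_filter(frame, sigma=hwhm_to_sigma(half_width), mode="reflect")


def _suprathreshold_count(
    frame: np.ndarray, spec: PhaseSpec, roi: np.ndarray
) -> int:
    return int(np.count_nonzero((spec.polarity * frame >= spec.threshold) & roi))


def select_phase_frame(
    series: RatioSeries,
    spec: PhaseSpec,
    roi: np.ndarray,
    half_width: float = SMOOTH_HALF_WIDTH_PX,
) -> int:
    """Frame carrying the maximum areal extent of a phase within an ROI.

    Frames whose mid-time lies in ``spec.window_s`` are smoothed and the
    suprathreshold pixel count inside ``roi`` (excluding saturated pixels) is
    maximised; ties go to the earliest frame.  Raises
    :class:`NoSuprathresholdActivityError` when no frame shows any
    suprathreshold pixel, so an abolished response is reported rather than
    silently mapped to frame 0.
    """
    roi = np.asarray(roi, dtype=bool) & ~series.saturated
    if not roi.any():
        raise ValueError("empty ROI")
    lo, hi = spec.window_s
    idx = [k for k, t in enumerate(series.times_s) if lo <= t < hi]
    if not idx:
        raise ValueError(f"no frames in search window {spec.window_s}")
    counts = [
        _suprathreshold_count(smooth_frame(series.fc_frames[k], half_width), spec, roi)
        for k in idx
    ]
    best = int(np.argmax(counts))
    if counts[best] == 0:
        raise NoSuprathresholdActivityError(
            f"no suprathreshold {spec.phase} activity in window {spec.window_s}"
        )
    return idx[best]


def select_condensed_frame(series: RatioSeries) -> int:
    """The fixed 500 ms frame spanning 0.5-1.0 s after stimulus delivery.

    The condensed protocol is quantified on this frame regardless of content.
    """
    dt = series.times_s[1] - series.times_s[0] if series.n_frames > 1 else 0.5
    if not np.isclose(dt, 0.5):
        raise ValueError("condensed selection expects 500 ms analysis frames")
    k = series.frame_at(0.75)
    start = series.times_s[k] - 0.25
    if not np.isclose(start, 0.5):
        raise ValueError("series frames are not aligned to the 0.5-1.0 s window")
    return k
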