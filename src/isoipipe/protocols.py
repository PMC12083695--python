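"""Stimulation protocols and signal-phase definitions.

Two whisker-stimulation trial structures are used throughout: a *sparse*
protocol with a long post-stimulus window that captures the full triphasic
intrinsic signal (initial dip, overshoot, undershoot), and a *condensed*
protocol with a short post-stimulus window that captures only a growing
initial dip.  Raw frames are acquired at 100 ms and summed to 500 ms
analysis frames; areal extent of the evoked patch is quantified against
phase-specific fractional-change (dR/R) thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: Side of the cortical imaging window in mm (7 x 7 mm field of view).
IMAGING_FIELD_MM = 7.0
#: Native camera resolution (512 x 512 px) -> default spatial calibration.
DEFAULT_MM_PER_PIXEL = IMAGING_FIELD_MM / 512.0

#: Gaussian smoothing half-width at half-maximum, in pixels.
SMOOTH_HALF_WIDTH_PX = 5.0

#: Areal-extent thresholds in fractional-change (dR/R) units, "away from zero".
DIP_THRESHOLD = 1.75e-4
OVERSHOOT_THRESHOLD = 3.5e-4
CONDENSED_THRESHOLD = 2.5e-4


def hwhm_to_sigma(half_width: float) -> float:
    """Convert a Gaussian half-width at half-maximum to a standard deviation."""
    return half_width / math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing structure of one stimulation trial.

    Attributes
    ----------
    name : str
        ``"sparse"`` or ``"condensed"``.
    pre_s, stim_s, post_s : float
        Pre-stimulus, stimulus and post-stimulus durations in seconds.
    frame_ms_raw : float
        Raw acquisition frame duration (100 ms).
    frame_ms_analysis : float
        Analysis frame duration after temporal summation (500 ms).
    trials_per_block : int
        Number of stimulation trials in one acquisition block.
    stim_rate_hz : float
        Whisker deflection rate during the 1 s stimulus.
    deflection_deg : float
        Deflection angle in the rostral-caudal direction.
    iti : str
        Inter-trial interval description (metadata only; no dead-time frames
        are modelled).
    """

    name: str
    pre_s: float
    stim_s: float
    post_s: float
    trials_per_block: int
    frame_ms_raw: float = 100.0
    frame_ms_analysis: float = 500.0
    stim_rate_hz: float = 5.0
    deflection_deg: float = 9.0
    iti: str = ""
    notes: str = ""

    def __post_init__(self) -> None:
        if self.name not in ("sparse", "condensed"):
            raise ValueError(f"unknown protocol name {self.name!r}")
        factor = self.frame_ms_analysis / self.frame_ms_raw
        if abs(factor - round(factor)) > 1e-9 or factor < 1:
            raise ValueError(
                "analysis frame duration must be an integer multiple of the "
                f"raw frame duration (got {self.frame_ms_analysis} / {self.frame_ms_raw})"
            )

    @property
    def sum_factor(self) -> int:
        """Raw frames summed into one analysis frame (5)."""
        return int(round(self.frame_ms_analysis / self.frame_ms_raw))

    @property
    def total_s(self) -> float:
        return self.pre_s + self.stim_s + self.post_s

    @property
    def n_frames_raw(self) -> int:
        return int(round(self.total_s * 1000.0 / self.frame_ms_raw))

    @property
    def onset_frame_raw(self) -> int:
        """Index of the first raw frame during which the stimulus is on."""
        return int(round(self.pre_s * 1000.0 / self.frame_ms_raw))


#: Sparse protocol: 1.5 s pre / 1 s stim / 13.5 s post, blocks of 64 trials.
#: The nominal "15 s trial" label disagrees with the component sum (16 s);
#: the component durations win and the discrepancy is kept as metadata.
SPARSE = ProtocolSpec(
    name="sparse",
    pre_s=1.5,
    stim_s=1.0,
    post_s=13.5,
    trials_per_block=64,
    iti="random 6 +/- 5 s",
    notes="nominal 15 s trial label vs 16 s component sum; components used",
)

#: Condensed protocol: 1.5 s pre / 1 s stim / 2 s post, blocks of 40 trials.
CONDENSED = ProtocolSpec(
    name="condensed",
    pre_s=1.5,
    stim_s=1.0,
    post_s=2.0,
    trials_per_block=40,
    iti="constant 1 s (+1 s disk write)",
)


@dataclass(frozen=True)
class PhaseSpec:
    """A named intrinsic-signal phase and how its extent is thresholded.

    ``polarity`` is -1 for dark-going phases (initial dip) and +1 for
    bright-going phases (overshoot); a pixel is suprathreshold when
    ``polarity * FC >= threshold``.  ``window_s`` restricts the frame search
    to an interval (seconds post stimulus onset).
    """

    phase: str
    polarity: int
    threshold: float
    window_s: tuple[float, float] = (0.0, 7.0)

    def __post_init__(self) -> None:
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be -1 or +1")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.window_s[1] <= self.window_s[0]:
            raise ValueError("empty search window")


#: Sparse-protocol initial dip: dark phase, threshold 1.75e-4, first 7 s.
INITIAL_DIP = PhaseSpec("initial_dip", polarity=-1, threshold=DIP_THRESHOLD)

#: Sparse-protocol overshoot: bright phase, threshold 3.5e-4, first 7 s.
OVERSHOOT = PhaseSpec("overshoot", polarity=+1, threshold=OVERSHOOT_THRESHOLD)

#: Condensed-protocol dip: fixed 0.5-1.0 s frame, threshold 2.5e-4,
#: dip (negative) polarity since the condensed signal shows only the dip.
CONDENSED_DIP = PhaseSpec(
    "condensed_dip", polarity=-1, threshold=CONDENSED_THRESHOLD, window_s=(0.5, 1.0)
)
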