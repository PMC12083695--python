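"""Seedable synthetic data emulating the rat pMCAo / lidocaine imaging study.

Three layers of generation, each with retained ground truth:

* **Trial stacks** — 16-bit-compatible widefield reflectance frames at 100 ms
  carrying a triphasic fractional-change signal (initial dip, overshoot,
  undershoot) as a temporal kernel times a 2-D Gaussian spatial profile, on
  a smooth baseline field with static dark vessel streaks.  The temporal
  kernel uses raised-cosine lobes with flat plateaus aligned to the 500 ms
  analysis grid, so the analysis-frame mean on the plateau equals the
  ground-truth amplitude exactly and the forward model can be inverted.
* **TTC slice series** — RGB coronal slices (red viable tissue, white
  infarct, dark background) with an ipsilateral edema swelling factor and an
  optional surgical-site lesion excluded from infarct scoring.
* **Full study** — 5 groups x 8 animals, baseline and 24 h blocks for both
  stimulation protocols, per-animal drug-slit sizes, and group-dependent
  24 h outcomes: groups 1-2 recover fully with zero infarct; groups 3-4 lose
  the representation inside the drug-diffusion area and develop an infarct
  whose volume is a linear function of slit size; group 5 draws from a
  protected / large-infarct mixture.

All randomness flows from ``numpy.random.SeedSequence`` spawns of a single
master seed, so identical (design, seed) pairs are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .infarct import TtcSlice
from .protocols import CONDENSED, SPARSE, ProtocolSpec
from .ratio import TrialStack
from .wfr import RoiSet

# --------------------------------------------------------------------------
# ISOI signal ground truth


@dataclass
class SignalGroundTruth:
    """Generating parameters of one animal's evoked intrinsic signal.

    Amplitudes are fractional change (dR/R): the dip and undershoot are
    dark-going (<= 0), the overshoot bright-going (>= 0), all within the
    physiological |dR/R| <= 1e-2 scale.  The spatial profile is a 2-D
    Gaussian of ``sigma_px`` at ``center`` (defaults to the image centre);
    ``block_mask`` zeroes the signal where drug diffusion has silenced the
    cortex.  ``noise_sd`` is the per-raw-frame pixel noise relative to the
    local baseline.  The baseline reflectance field (smooth spatial
    variation around ``baseline_counts`` with multiplicative dark vessel
    streaks) is itself seeded by ``baseline_seed`` so that all trials and
    timepoints of one animal share the same cortex.
    """

    dip_amp: float = -5e-4
    overshoot_amp: float = 7e-4
    undershoot_amp: float = -3e-4
    dip_peak_s: float = 2.5
    overshoot_peak_s: float = 5.0
    undershoot_peak_s: float = 8.0
    sigma_px: float = 7.3
    center: tuple[float, float] | None = None
    noise_sd: float = 0.0
    baseline_counts: float = 10000.0
    baseline_seed: int = 0
    n_vessels: int = 2
    block_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dip_amp > 0 or self.undershoot_amp > 0 or self.overshoot_amp < 0:
            raise ValueError("dip/undershoot must be <= 0 and overshoot >= 0")
        for a in (self.dip_amp, self.overshoot_amp, self.undershoot_amp):
            if abs(a) > 1e-2:
                raise ValueError("amplitudes exceed the physiological 1e-2 dR/R scale")
        if not (self.dip_peak_s < self.overshoot_peak_s < self.undershoot_peak_s):
            raise ValueError("phase peak times must be ordered dip < overshoot < undershoot")
        if self.baseline_counts <= 0:
            raise ValueError("baseline_counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _raised_cos_lobe(t: np.ndarray, r0: float, p0: float, p1: float, f1: float) -> np.ndarray:
    """Unit lobe: cosine rise r0->p0, plateau p0->p1, cosine fall p1->f1."""
    out = np.zeros_like(t)
    rise = (t >= r0) & (t < p0)
    if p0 > r0:
        out[rise] = 0.5 * (1.0 - np.cos(np.pi * (t[rise] - r0) / (p0 - r0)))
    out[(t >= p0) & (t <= p1)] = 1.0
    fall = (t > p1) & (t < f1)
    if f1 > p1:
        out[fall] = 0.5 * (1.0 + np.cos(np.pi * (t[fall] - p1) / (f1 - p1)))
    return out


def temporal_kernel(truth: SignalGroundTruth, t_post: np.ndarray, protocol: str) -> np.ndarray:
    """Fractional-change time course at times ``t_post`` (s after onset).

    The sparse protocol carries all three phases; the condensed protocol
    carries only a fast-growing initial dip (rise 0-0.5 s, plateau from
    0.5 s) because its quantification window is 0.5-1.0 s post delivery.
    """
    t = np.asarray(t_post, dtype=float)
    if protocol == "condensed":
        return truth.dip_amp * _raised_cos_lobe(t, 0.0, 0.5, 2.0, 2.5)
    d, o, u = truth.dip_peak_s, truth.overshoot_peak_s, truth.undershoot_peak_s
    k = truth.dip_amp * _raised_cos_lobe(t, 0.5, d - 0.5, d + 0.5, o - 0.5)
    k += truth.overshoot_amp * _raised_cos_lobe(t, d + 0.5, o - 0.5, o + 0.5, u - 0.5)
    k += truth.undershoot_amp * _raised_cos_lobe(t, o + 0.5, u - 0.5, u + 0.5, u + 2.0)
    return k


def spatial_profile(truth: SignalGroundTruth, shape: tuple[int, int]) -> np.ndarray:
    """Unit-amplitude Gaussian blob, zeroed inside the block mask."""
    h, w = shape
    cy, cx = truth.center if truth.center is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
    yy, xx = np.mgrid[0:h, 0:w]
    prof = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * truth.sigma_px**2))
    if truth.block_mask is not None:
        bm = np.asarray(truth.block_mask, dtype=bool)
        if bm.shape != shape:
            raise ValueError("block_mask shape does not match image shape")
        prof = prof * ~bm
    return prof


def baseline_field(truth: SignalGroundTruth, shape: tuple[int, int]) -> np.ndarray:
    """Smooth reflectance baseline (~1e4 counts) with static dark vessel streaks."""
    rng = np.random.default_rng(truth.baseline_seed)
    h, w = shape
    rough = rng.standard_normal((h, w))
    smooth = ndimage.gaussian_filter(rough, sigma=max(h, w) / 8.0, mode="reflect")
    smooth = smooth / max(np.abs(smooth).max(), 1e-12)
    base = truth.baseline_counts * (1.0 + 0.04 * smooth)
    vessel = np.zeros((h, w), dtype=bool)
    for _ in range(truth.n_vessels):
        r0, c0 = rng.integers(0, h), rng.integers(0, w)
        ang = rng.uniform(0, np.pi)
        r1 = int(np.clip(r0 + (h + w) * math.sin(ang), 0, h - 1))
        c1 = int(np.clip(c0 + (h + w) * math.cos(ang), 0, w - 1))
        n = max(abs(r1 - r0), abs(c1 - c0)) + 1
        rr = np.round(np.linspace(r0, r1, n)).astype(int)
        cc = np.round(np.linspace(c0, c1, n)).astype(int)
        vessel[rr, cc] = True
    vessel = ndimage.binary_dilation(vessel)
    base = np.where(vessel, base * 0.75, base)
    return base


def make_trial_stack(
    protocol: ProtocolSpec,
    truth: SignalGroundTruth,
    seed: int,
    shape: tuple[int, int] = (64, 64),
    mm_per_pixel: float | None = None,
) -> TrialStack:
    """One trial's raw 100 ms frame stack.

    Pixel value = baseline * (1 + kernel(t) * profile(x, y)) + noise, with
    noise drawn per raw frame at sd ``noise_sd * baseline``.  Frames are
    float32 within the 16-bit count range so downstream ratios are not
    quantisation-limited.
    """
    if mm_per_pixel is None:
        mm_per_pixel = 7.0 / shape[1]
    rng = np.random.default_rng(seed)
    base = baseline_field(truth, shape)
    n = protocol.n_frames_raw
    onset = protocol.onset_frame_raw
    dt = protocol.frame_ms_raw / 1000.0
    t_mid = (np.arange(n) - onset + 0.5) * dt
    kern = temporal_kernel(truth, t_mid, protocol.name)
    prof = spatial_profile(truth, shape)
    frames = base[None, :, :] * (1.0 + kern[:, None, None] * prof[None, :, :])
    if truth.noise_sd > 0:
        frames = frames + rng.normal(0.0, truth.noise_sd, size=frames.shape) * base[None]
    frames = np.clip(frames, 0.0, None).astype(np.float32)
    return TrialStack(
        frames=frames,
        frame_duration_ms=protocol.frame_ms_raw,
        onset_frame=onset,
        mm_per_pixel=mm_per_pixel,
        meta={"protocol": protocol.name, "seed": int(seed), "notes": protocol.notes},
    )


def make_block(
    protocol: ProtocolSpec,
    truth: SignalGroundTruth,
    n_trials: int,
    seed: int,
    shape: tuple[int, int] = (64, 64),
    mm_per_pixel: float | None = None,
) -> list[TrialStack]:
    """A block of independent trials with per-trial seeds spawned from ``seed``."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_trials)
    return [
        make_trial_stack(
            protocol,
            truth,
            seed=int(child.generate_state(1)[0] % (2**31)),
            shape=shape,
            mm_per_pixel=mm_per_pixel,
        )
        for child in children
    ]


# --------------------------------------------------------------------------
# TTC histology ground truth


@dataclass
class TtcGroundTruth:
    """Generating parameters for one animal's TTC-stained slice series.

    ``infarct_areas_mm2`` gives the per-slice target infarct area; an
    explicit ``infarct_masks`` list (one boolean mask or None per slice)
    overrides it.  ``edema_factor`` multiplies the ipsilateral hemisphere
    area (>= 1).  Realised pixel counts are retained in the returned
    ground-truth record, so volumetry can be checked exactly.
    """

    n_slices: int = 7
    slice_thickness_mm: float = 2.0
    mm_per_pixel: float = 0.1
    shape: tuple[int, int] = (120, 160)
    hemisphere_axes_px: tuple[float, float] = (42.0, 55.0)
    edema_factor: float = 1.0
    infarct_areas_mm2: list[float] | None = None
    infarct_masks: list[np.ndarray | None] | None = None
    surgical_site: bool = False
    color_noise_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.edema_factor < 1.0:
            raise ValueError("edema_factor must be >= 1")
        if self.n_slices < 1:
            raise ValueError("need at least one slice")
        if self.slice_thickness_mm <= 0:
            raise ValueError("slice thickness must be positive")


_VIABLE_RGB = np.array([200.0, 58.0, 52.0])
_INFARCT_RGB = np.array([236.0, 233.0, 230.0])
_BACKGROUND_RGB = np.array([28.0, 28.0, 30.0])


def _half_ellipse(shape, cy, cx, ry, rx, side: str) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    return inside & (xx < cx if side == "left" else xx >= cx)


def make_ttc_series(
    truth: TtcGroundTruth, seed: int
) -> tuple[list[TtcSlice], dict]:
    """Render a coronal TTC slice series and its ground-truth record.

    The contralateral (left) hemisphere is a half-ellipse of the nominal
    axes; the ipsilateral (right) hemisphere is dilated by
    ``sqrt(edema_factor)`` per axis so its area scales by ``edema_factor``.
    Infarct blobs sit in the ipsilateral dorsolateral cortex.  Returns the
    slice list and a record with per-slice infarct pixel counts, hemisphere
    pixel counts and the derived ground-truth volumes (raw and
    edema-corrected with the contra/ipsi convention).
    """
    rng = np.random.default_rng(seed)
    h, w = truth.shape
    # centre between pixel columns so the two hemispheres tile symmetrically
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = truth.hemisphere_axes_px
    s = math.sqrt(truth.edema_factor)
    areas = truth.infarct_areas_mm2 or [0.0] * truth.n_slices
    if len(areas) != truth.n_slices:
        raise ValueError("infarct_areas_mm2 length must equal n_slices")
    if truth.infarct_masks is not None and len(truth.infarct_masks) != truth.n_slices:
        raise ValueError("infarct_masks length must equal n_slices")

    slices: list[TtcSlice] = []
    infarct_px: list[int] = []
    ipsi_px: list[int] = []
    contra_px: list[int] = []
    for i in range(truth.n_slices):
        contra = _half_ellipse((h, w), cy, cx, ry, rx, "left")
        ipsi = _half_ellipse((h, w), cy, cx, ry * s, rx * s, "right")
        tissue = contra | ipsi
        if truth.infarct_masks is not None and truth.infarct_masks[i] is not None:
            infarct = np.asarray(truth.infarct_masks[i], dtype=bool)
            if infarct.shape != (h, w):
                raise ValueError(f"infarct mask {i} does not match slice shape")
            if np.any(infarct & contra):
                raise ValueError("infarct masks must be confined to one hemisphere")
            infarct = infarct & ipsi
        else:
            target_px = areas[i] / truth.mm_per_pixel**2
            if target_px > 0:
                b = math.sqrt(target_px / (math.pi * 1.5))
                blob = _half_ellipse(
                    (h, w), cy - 0.25 * ry * s, cx + 0.40 * rx * s, 1.5 * b, b, "right"
                ) | _half_ellipse(
                    (h, w), cy - 0.25 * ry * s, cx + 0.40 * rx * s, 1.5 * b, b, "left"
                )
                infarct = blob & ipsi
            else:
                infarct = np.zeros((h, w), dtype=bool)

        excl = None
        if truth.surgical_site and i == 0:
            site = np.zeros((h, w), dtype=bool)
            sy, sx = int(cy - 0.55 * ry * s), int(cx + 0.15 * rx * s)
            yy, xx = np.mgrid[0:h, 0:w]
            site = (yy - sy) ** 2 + (xx - sx) ** 2 <= 3**2
            site &= ipsi & ~infarct
            excl = ndimage.binary_dilation(site, iterations=1)
            white = infarct | site
        else:
            white = infarct

        img = np.empty((h, w, 3))
        img[:] = _BACKGROUND_RGB
        img[tissue] = _VIABLE_RGB
        img[white] = _INFARCT_RGB
        if truth.color_noise_sd > 0:
            img = img + rng.normal(0.0, truth.color_noise_sd, size=img.shape)
        img = np.clip(img, 0, 255).astype(np.uint8)

        slices.append(
            TtcSlice(
                image=img,
                mm_per_pixel=truth.mm_per_pixel,
                thickness_mm=truth.slice_thickness_mm,
                midline_col=cx,
                exclusion_mask=excl,
            )
        )
        infarct_px.append(int(infarct.sum()))
        ipsi_px.append(int((tissue & (np.arange(w)[None, :] >= cx)).sum()))
        contra_px.append(int((tissue & (np.arange(w)[None, :] < cx)).sum()))

    a2 = truth.mm_per_pixel**2
    th = truth.slice_thickness_mm
    raw = sum(n * a2 * th for n in infarct_px)
    ipsi_vol = sum(n * a2 * th for n in ipsi_px)
    contra_vol = sum(n * a2 * th for n in contra_px)
    record = {
        "infarct_px": infarct_px,
        "ipsi_px": ipsi_px,
        "contra_px": contra_px,
        "raw_volume_mm3": raw,
        "ipsi_volume_mm3": ipsi_vol,
        "contra_volume_mm3": contra_vol,
        "corrected_volume_mm3": raw * (contra_vol / ipsi_vol) if ipsi_vol else 0.0,
        "edema_factor": truth.edema_factor,
    }
    return slices, record


# --------------------------------------------------------------------------
# Full study design


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group's interventions."""

    occlusion: bool
    drug: str  # "PBS" | "lidocaine"
    stimulation: str  # "plus0h" | "none"

    def __post_init__(self) -> None:
        if self.drug not in ("PBS", "lidocaine"):
            raise ValueError(f"unknown drug {self.drug!r}")
        if self.stimulation not in ("plus0h", "none"):
            raise ValueError(f"unknown stimulation {self.stimulation!r}")


#: The five experimental groups: 1 vehicle+stim, 2 sham+lidocaine+stim,
#: 3 pMCAo+lidocaine+no-stim, 4 pMCAo+lidocaine+stim, 5 pMCAo+PBS+no-stim.
DEFAULT_GROUPS: dict[int, GroupSpec] = {
    1: GroupSpec(occlusion=True, drug="PBS", stimulation="plus0h"),
    2: GroupSpec(occlusion=False, drug="lidocaine", stimulation="plus0h"),
    3: GroupSpec(occlusion=True, drug="lidocaine", stimulation="none"),
    4: GroupSpec(occlusion=True, drug="lidocaine", stimulation="plus0h"),
    5: GroupSpec(occlusion=True, drug="PBS", stimulation="none"),
}


@dataclass
class StudyDesign:
    """The 5-group x 2-timepoint study and the generator's scale settings.

    Outcome rules: no occlusion, or occlusion with vehicle plus immediate
    stimulation, recovers fully with zero infarct; occlusion plus lidocaine
    abolishes the representation inside the drug-diffusion area and yields
    an infarct whose volume is ``infarct_intercept + infarct_slope * slit``
    plus noise; occlusion plus vehicle without stimulation (group 5) draws
    from a ``group5_affected_p`` mixture of protected vs large-infarct
    outcomes.
    """

    groups: dict[int, GroupSpec] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    n_per_group: int = 8
    # imaging scale
    img_px: int = 64
    n_trials_sparse: int = 64
    n_trials_condensed: int = 40
    #: per-pixel raw-frame noise (relative to baseline) at the native
    #: 512 px camera resolution; the simulation grid bins (512/img_px)^2
    #: photons per pixel, so the effective per-pixel noise scales down by
    #: the linear binning factor.  Override with ``noise_sd`` to pin the
    #: per-pixel value directly.
    noise_sd_native_512: float = 2e-3
    noise_sd: float | None = None
    dip_amp: float = -5e-4
    overshoot_amp: float = 7e-4
    undershoot_amp: float = -3e-4
    sigma_mm: float = 0.8
    amp_jitter: float = 0.1
    roi_margin_px: int = 3
    #: minimum ROI coverage radius (mm) around the slit centroid, so the
    #: counted baseline extent does not scale with the slit size drawn
    roi_min_radius_mm: float = 1.5
    #: drug diffusion reaches this many px beyond the analysis ROI
    diffusion_margin_px: int = 2
    slit_aspect: float = 2.5
    #: per-group (lo, hi) uniform slit-size range, mm^2 of dura opening
    slit_range_mm2: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {1: (0.5, 2.0), 2: (0.5, 2.0), 3: (0.5, 2.0), 4: (1.0, 4.0), 5: (0.5, 2.0)}
    )
    # infarct outcome rules
    infarct_slope: float = 3.0  # mm^3 per mm^2 of slit
    infarct_intercept: float = 2.0  # mm^3
    infarct_noise_sd: float = 0.5  # mm^3
    #: group 5 (occlusion + vehicle + no stimulation) loses the functional
    #: representation in every animal but its infarct is bimodal: with this
    #: probability the infarct extends well beyond the barrel field,
    #: otherwise it stays localized (slit-linked, like the lidocaine groups)
    group5_extended_p: float = 0.5
    group5_volume_mean: float = 40.0  # mm^3 (extended mode)
    group5_volume_sd: float = 8.0
    edema_factor_infarct: float = 1.08
    # histology scale
    n_slices: int = 7
    slice_thickness_mm: float = 2.0
    ttc_mm_per_pixel: float = 0.1

    def __post_init__(self) -> None:
        if len(self.groups) != 5:
            raise ValueError("the study design requires exactly 5 groups")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")

    @property
    def mm_per_pixel(self) -> float:
        return 7.0 / self.img_px

    @property
    def frame_noise_sd(self) -> float:
        """Effective per-pixel raw-frame noise at the simulation grid."""
        if self.noise_sd is not None:
            return self.noise_sd
        return self.noise_sd_native_512 * self.img_px / 512.0

    @property
    def sigma_px(self) -> float:
        return self.sigma_mm / self.mm_per_pixel


def sample_group_outcomes(
    design: StudyDesign, group: int, n: int, seed: int
) -> list[dict]:
    """Draw ``n`` per-animal outcome records for one group.

    Each record carries the slit size, whether the animal's cortex was
    functionally blocked at 24 h, and the target infarct volume.  This is
    the rule ``make_study`` applies per animal; it is exposed separately so
    the group-5 outcome mixture can be examined at large n cheaply.
    """
    spec = design.groups[group]
    rng = np.random.default_rng(seed)
    lo, hi = design.slit_range_mm2[group]
    out = []
    for _ in range(n):
        slit = float(rng.uniform(lo, hi))
        extended = False
        if not spec.occlusion:
            affected = False  # sham surgery: full recovery
        elif spec.drug == "lidocaine":
            affected = True  # blocked cortex deteriorates (groups 3-4)
        elif spec.stimulation == "plus0h":
            affected = False  # vehicle + immediate stimulation protects
        else:
            # occlusion + vehicle + no stimulation (group 5): the cortex is
            # functionally impaired in every animal; the infarct is bimodal,
            # localized (slit-linked) vs extended beyond the barrel field
            affected = True
            extended = bool(rng.random() < design.group5_extended_p)
        if not affected:
            volume = 0.0
        elif extended:
            volume = max(15.0, rng.normal(design.group5_volume_mean, design.group5_volume_sd))
        else:
            volume = max(
                0.3,
                design.infarct_intercept
                + design.infarct_slope * slit
                + rng.normal(0.0, design.infarct_noise_sd),
            )
        out.append(
            {
                "group": group,
                "slit_size_mm2": slit,
                "affected": affected,
                "extended_infarct": extended,
                "infarct_volume_mm3": volume,
                "edema_factor": design.edema_factor_infarct if volume > 0 else 1.0,
            }
        )
    return out


def _slit_mask(design: StudyDesign, center: tuple[float, float], slit_mm2: float) -> np.ndarray:
    """Rectangular slit footprint of the given area centred on the blob."""
    px_area = slit_mm2 / design.mm_per_pixel**2
    h_px = max(2, int(round(math.sqrt(px_area * design.slit_aspect))))
    w_px = max(1, int(round(px_area / h_px)))
    n = design.img_px
    cy, cx = center
    r0 = int(np.clip(round(cy - h_px / 2), 0, n - h_px))
    c0 = int(np.clip(round(cx - w_px / 2), 0, n - w_px))
    mask = np.zeros((n, n), dtype=bool)
    mask[r0 : r0 + h_px, c0 : c0 + w_px] = True
    return mask


def _infarct_slice_areas(design: StudyDesign, volume_mm3: float) -> list[float]:
    """Distribute an infarct volume across slices with a tapered profile."""
    areas = [0.0] * design.n_slices
    if volume_mm3 <= 0:
        return areas
    mid = design.n_slices // 2
    weights = (
        {mid - 1: 0.25, mid: 0.5, mid + 1: 0.25}
        if volume_mm3 <= 20
        else {mid - 2: 0.1, mid - 1: 0.2, mid: 0.4, mid + 1: 0.2, mid + 2: 0.1}
    )
    for i, wgt in weights.items():
        if 0 <= i < design.n_slices:
            areas[i] = volume_mm3 * wgt / design.slice_thickness_mm
    return areas


@dataclass
class AnimalArtifacts:
    """One animal's raw synthetic data: imaging blocks, masks, histology."""

    animal: str
    group: int
    slit_mask: np.ndarray
    rois: RoiSet
    blocks: dict[tuple[str, str], list[TrialStack]]
    ttc_slices: list[TtcSlice]
    ttc_truth: dict


class StudyData:
    """Ground-truth table plus lazy per-animal artifact generation.

    Artifacts for one animal can be tens of MB, so they are generated on
    demand (deterministically from stored per-animal seeds) rather than all
    held in memory.
    """

    def __init__(self, design: StudyDesign, seed: int):
        self.design = design
        self.seed = int(seed)
        rows = []
        master = np.random.SeedSequence(self.seed)
        group_seeds = master.spawn(len(design.groups))
        self._animal_seeds: dict[str, int] = {}
        rng = np.random.default_rng(master.generate_state(1)[0] % (2**31))
        idx = 0
        for g, gseed in zip(sorted(design.groups), group_seeds):
            outcomes = sample_group_outcomes(
                design, g, design.n_per_group, int(gseed.generate_state(1)[0] % (2**31))
            )
            for rec in outcomes:
                idx += 1
                animal = f"A{idx:02d}"
                jit = 1.0 + rng.uniform(-design.amp_jitter, design.amp_jitter)
                c = design.img_px / 2.0 - 0.5
                center = (
                    float(c + rng.integers(-2, 3)),
                    float(c + rng.integers(-2, 3)),
                )
                rows.append(
                    {
                        "animal": animal,
                        **rec,
                        "occlusion": design.groups[g].occlusion,
                        "drug": design.groups[g].drug,
                        "stimulation": design.groups[g].stimulation,
                        "dip_amp": design.dip_amp * jit,
                        "overshoot_amp": design.overshoot_amp * jit,
                        "undershoot_amp": design.undershoot_amp * jit,
                        "sigma_px": design.sigma_px * (1.0 + rng.uniform(-0.1, 0.1)),
                        "center_row": center[0],
                        "center_col": center[1],
                    }
                )
                self._animal_seeds[animal] = int(
                    np.random.SeedSequence([self.seed, idx]).generate_state(1)[0] % (2**31)
                )
        import pandas as pd

        self.truth = pd.DataFrame(rows)

    @property
    def animals(self) -> list[str]:
        return list(self.truth["animal"])

    def artifacts(self, animal: str) -> AnimalArtifacts:
        """Generate (deterministically) one animal's full raw dataset."""
        design = self.design
        row = self.truth.set_index("animal").loc[animal]
        aseed = self._animal_seeds[animal]
        ss = np.random.SeedSequence(aseed)
        block_seeds = iter(int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5))

        center = (float(row["center_row"]), float(row["center_col"]))
        slit = _slit_mask(design, center, float(row["slit_size_mm2"]))
        rois = RoiSet.around_slit(
            slit,
            margin_px=design.roi_margin_px,
            min_radius_px=design.roi_min_radius_mm / design.mm_per_pixel,
        )
        # drug diffusion covers the whole analysis ROI plus a margin, so a
        # blocked cortex shows no residual extent inside the counted region
        diffusion = ndimage.binary_dilation(
            rois.analysis_roi, iterations=design.diffusion_margin_px
        )

        base_truth = SignalGroundTruth(
            dip_amp=float(row["dip_amp"]),
            overshoot_amp=float(row["overshoot_amp"]),
            undershoot_amp=float(row["undershoot_amp"]),
            sigma_px=float(row["sigma_px"]),
            center=center,
            noise_sd=design.frame_noise_sd,
            baseline_seed=aseed,
        )
        blocked_truth = replace(base_truth, block_mask=diffusion)
        affected = bool(row["affected"])

        blocks: dict[tuple[str, str], list[TrialStack]] = {}
        shape = (design.img_px, design.img_px)
        for protocol, n_trials in (
            (SPARSE, design.n_trials_sparse),
            (CONDENSED, design.n_trials_condensed),
        ):
            for tp in ("baseline", "h24"):
                truth = blocked_truth if (affected and tp == "h24") else base_truth
                blocks[(protocol.name, tp)] = make_block(
                    protocol, truth, n_trials, next(block_seeds), shape=shape,
                    mm_per_pixel=design.mm_per_pixel,
                )

        ttc_slices, ttc_record = self.ttc_artifacts(animal)
        return AnimalArtifacts(
            animal=animal,
            group=int(row["group"]),
            slit_mask=slit,
            rois=rois,
            blocks=blocks,
            ttc_slices=ttc_slices,
            ttc_truth=ttc_record,
        )

    def ttc_artifacts(self, animal: str) -> tuple[list[TtcSlice], dict]:
        """Generate only the histology series for one animal (cheap)."""
        design = self.design
        row = self.truth.set_index("animal").loc[animal]
        seeds = np.random.SeedSequence(self._animal_seeds[animal]).spawn(5)
        ttc_seed = int(seeds[4].generate_state(1)[0] % (2**31))
        ttc_truth = TtcGroundTruth(
            n_slices=design.n_slices,
            slice_thickness_mm=design.slice_thickness_mm,
            mm_per_pixel=design.ttc_mm_per_pixel,
            edema_factor=float(row["edema_factor"]),
            # the rendered (swollen) infarct carries the edema factor, so
            # the contra/ipsi correction recovers the intended volume
            infarct_areas_mm2=_infarct_slice_areas(
                design, float(row["infarct_volume_mm3"]) * float(row["edema_factor"])
            ),
            surgical_site=bool(row["occlusion"]),
        )
        return make_ttc_series(ttc_truth, ttc_seed)

    def iter_animals(self):
        """Yield (truth row, artifacts) one animal at a time."""
        for animal in self.animals:
            yield self.truth.set_index("animal").loc[animal], self.artifacts(animal)


def make_study(design: StudyDesign, seed: int) -> StudyData:
    """Build the full study's ground truth with lazy raw-artifact access."""
    return StudyData(design, seed)
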