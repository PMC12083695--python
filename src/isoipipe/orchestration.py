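"""End-to-end binding: simulate -> quantify -> stats, in memory or on disk.

The in-memory entry points (`process_block`, `quantify_study`,
`run_study_stats`) are what tests and scripted analyses use; the `cmd_*`
functions add file I/O (TIFF stacks + JSON sidecars, PNG masks and TTC
slices, CSV tables, JSON stats report) for the command-line verbs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .infarct import TtcSlice, infarct_volume, slit_regression
from .protocols import (
    CONDENSED_THRESHOLD,
    DIP_THRESHOLD,
    OVERSHOOT_THRESHOLD,
    SMOOTH_HALF_WIDTH_PX,
    CONDENSED,
    SPARSE,
)
from .ratio import RatioSeries, TrialStack, average_trials, compute_ratio_series, sum_to_analysis_frames
from .stats import baseline_equality_check, infarct_group_tests, posthoc_time_contrasts, rm_anova
from .synthetic import StudyData, StudyDesign, make_study
from .wfr import RoiSet, quantify_animal

log = logging.getLogger("isoipipe")


@dataclass
class RunConfig:
    """Flat run configuration (YAML-serialisable)."""

    out_dir: str = "isoipipe_out"
    seed: int = 0
    n_per_group: int = 8
    img_px: int = 64
    n_trials_sparse: int = 64
    n_trials_condensed: int = 40
    noise_sd: float | None = None  # per-pixel override; default scales with binning
    groups: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5])
    save_mode: str = "averaged"  # "trials" writes every raw trial stack
    dip_threshold: float = DIP_THRESHOLD
    overshoot_threshold: float = OVERSHOOT_THRESHOLD
    condensed_threshold: float = CONDENSED_THRESHOLD
    smooth_half_width: float = SMOOTH_HALF_WIDTH_PX
    alpha: float = 0.05
    correction: str = "sidak"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_design(self) -> StudyDesign:
        return StudyDesign(
            n_per_group=self.n_per_group,
            img_px=self.img_px,
            n_trials_sparse=self.n_trials_sparse,
            n_trials_condensed=self.n_trials_condensed,
            noise_sd=self.noise_sd,
        )


# --------------------------------------------------------------------------
# In-memory pipeline

def process_block(trials: list[TrialStack]) -> RatioSeries:
    """Raw trial stacks -> trial-averaged ratio series (sum, ratio, average)."""
    series = [compute_ratio_series(sum_to_analysis_frames(t)) for t in trials]
    return average_trials(series)


def quantify_study(study: StudyData) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every animal of a synthetic study; returns (WFR table, infarct table).

    Streams one animal at a time (artifacts are generated lazily) and
    assembles the tidy long-format measurement table the statistics module
    consumes, plus a per-animal infarct volumetry table.
    """
    wfr_rows: list[dict] = []
    inf_rows: list[dict] = []
    for truth, art in study.iter_animals():
        series_by = {key: process_block(trials) for key, trials in art.blocks.items()}
        wfr_rows.extend(
            quantify_animal(
                art.animal,
                art.group,
                series_by,
                art.rois,
                slit_size_mm2=float(truth["slit_size_mm2"]),
            )
        )
        res = infarct_volume(art.ttc_slices, ipsi_side="right")
        inf_rows.append(
            {
                "animal": art.animal,
                "group": art.group,
                "slit_size_mm2": float(truth["slit_size_mm2"]),
                "raw_volume_mm3": res.raw_volume_mm3,
                "corrected_volume_mm3": res.corrected_volume_mm3,
                "ipsi_volume_mm3": res.ipsi_hemisphere_volume_mm3,
                "contra_volume_mm3": res.contra_hemisphere_volume_mm3,
            }
        )
        log.info("quantified %s (group %d)", art.animal, art.group)
    return pd.DataFrame(wfr_rows), pd.DataFrame(inf_rows)


def run_study_stats(
    wfr: pd.DataFrame,
    infarct: pd.DataFrame,
    correction: str = "sidak",
    regression_groups: tuple[int, ...] = (3, 4),
) -> dict:
    """The full statistical battery on quantified study tables.

    For every (protocol, phase) and each response (areal extent, peak
    amplitude): RM-ANOVA group x time plus corrected per-group
    baseline-vs-24 h contrasts.  Baseline equality one-way ANOVA; Welch
    t-tests and one-way ANOVA on corrected infarct volumes; per-group OLS
    of volume on slit size.
    """
    results: dict = {"wfr": {}, "infarct": {}, "baseline_check": {}}
    for (protocol, phase), sub in wfr.groupby(["protocol", "phase"]):
        for response in ("area_mm2", "peak_amplitude"):
            if sub[response].isna().all():
                continue
            anova = rm_anova(sub, response)
            contrasts = posthoc_time_contrasts(anova, correction=correction)
            results["wfr"][f"{protocol}:{phase}:{response}"] = {
                "anova": anova,
                "contrasts": contrasts,
            }
        try:
            results["baseline_check"][f"{protocol}:{phase}:area_mm2"] = (
                baseline_equality_check(sub, "area_mm2")
            )
        except ValueError as e:
            log.warning("baseline check skipped for %s/%s: %s", protocol, phase, e)
    results["infarct"]["tests"] = infarct_group_tests(infarct)
    results["infarct"]["regressions"] = {}
    for g in regression_groups:
        sub = infarct[infarct["group"] == g]
        try:
            results["infarct"]["regressions"][g] = slit_regression(
                sub["slit_size_mm2"].to_numpy(), sub["corrected_volume_mm3"].to_numpy()
            )
        except ValueError as e:
            log.warning("slit regression skipped for group %s: %s", g, e)
    return results


# --------------------------------------------------------------------------
# Disk-backed verbs

def _write_mask_png(path: Path, mask: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


def _read_mask_png(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    return np.asarray(iio.imread(path)) > 0


def cmd_simulate(config: RunConfig, seed: int | None = None) -> Path:
    """Generate the synthetic study and write it under ``config.out_dir``.

    Layout: ``animals/<id>/`` holds per-block imaging data (one multi-page
    float32 TIFF per trial in "trials" mode, or the trial-averaged ratio
    series in "averaged" mode) with JSON sidecars, mask PNGs and the TTC
    slice PNGs; ``ground_truth.csv`` and ``manifest.json`` sit at the root.
    """
    seed = config.seed if seed is None else seed
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = make_study(config.to_design(), seed)
    keep = [a for a in study.animals
            if int(study.truth.set_index("animal").loc[a, "group"]) in config.groups]
    import imageio.v3 as iio

    for animal in keep:
        art = study.artifacts(animal)
        adir = out / "animals" / animal
        adir.mkdir(parents=True, exist_ok=True)
        _write_mask_png(adir / "slit_mask.png", art.slit_mask)
        _write_mask_png(adir / "analysis_roi.png", art.rois.analysis_roi)
        for (protocol, tp), trials in art.blocks.items():
            bdir = adir / f"{protocol}_{tp}"
            bdir.mkdir(exist_ok=True)
            sidecar = {
                "protocol": protocol,
                "timepoint": tp,
                "frame_duration_ms": trials[0].frame_duration_ms,
                "onset_frame": trials[0].onset_frame,
                "mm_per_pixel": trials[0].mm_per_pixel,
                "n_trials": len(trials),
                "mode": config.save_mode,
            }
            if config.save_mode == "trials":
                for i, t in enumerate(trials):
                    tifffile.imwrite(bdir / f"trial_{i:03d}.tif", t.frames.astype(np.float32))
            else:
                avg = process_block(trials)
                tifffile.imwrite(bdir / "ratio_series.tif", avg.fc_frames.astype(np.float32))
                sidecar["times_s"] = avg.times_s.tolist()
                sidecar["n_trials_averaged"] = avg.n_trials_averaged
            (bdir / "block.json").write_text(json.dumps(sidecar, indent=1))
        tdir = adir / "ttc"
        tdir.mkdir(exist_ok=True)
        for i, slc in enumerate(art.ttc_slices):
            iio.imwrite(tdir / f"slice_{i}.png", slc.image)
            if slc.exclusion_mask is not None:
                _write_mask_png(tdir / f"exclusion_{i}.png", slc.exclusion_mask)
        (tdir / "ttc.json").write_text(
            json.dumps(
                {
                    "mm_per_pixel": art.ttc_slices[0].mm_per_pixel,
                    "thickness_mm": art.ttc_slices[0].thickness_mm,
                    "midline_col": art.ttc_slices[0].midline_col,
                    "n_slices": len(art.ttc_slices),
                }
            )
        )
        log.info("wrote %s", adir)
    study.truth[study.truth["animal"].isin(keep)].to_csv(out / "ground_truth.csv", index=False)
    manifest = {"seed": int(seed), "version": __version__, "config": dataclasses.asdict(config)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def _load_block(bdir: Path) -> RatioSeries:
    meta = json.loads((bdir / "block.json").read_text())
    if meta["mode"] == "trials":
        trials = []
        for f in sorted(bdir.glob("trial_*.tif")):
            frames = tifffile.imread(f)
            trials.append(
                TrialStack(
                    frames=frames,
                    frame_duration_ms=meta["frame_duration_ms"],
                    onset_frame=meta["onset_frame"],
                    mm_per_pixel=meta["mm_per_pixel"],
                )
            )
        if not trials:
            raise FileNotFoundError(f"no trial TIFFs in {bdir}")
        return process_block(trials)
    fc = tifffile.imread(bdir / "ratio_series.tif")
    return RatioSeries(
        fc_frames=np.asarray(fc, dtype=float),
        times_s=np.asarray(meta["times_s"], dtype=float),
        n_trials_averaged=meta["n_trials_averaged"],
        mm_per_pixel=meta["mm_per_pixel"],
    )


def cmd_quantify(config: RunConfig, data_dir: str | Path | None = None) -> tuple[Path, Path]:
    """Quantify an on-disk dataset; writes wfr_metrics.csv and infarct.csv."""
    root = Path(data_dir or config.out_dir)
    truth = pd.read_csv(root / "ground_truth.csv").set_index("animal")
    wfr_rows, inf_rows = [], []
    for adir in sorted((root / "animals").iterdir()):
        animal = adir.name
        try:
            slit = _read_mask_png(adir / "slit_mask.png")
            roi = _read_mask_png(adir / "analysis_roi.png")
        except FileNotFoundError:
            log.warning("skipping %s: missing mask", animal)
            continue
        rois = RoiSet(roi, slit, provenance="loaded from disk")
        series_by = {}
        for bdir in sorted(adir.glob("*_*")):
            if not (bdir / "block.json").exists():
                continue
            meta = json.loads((bdir / "block.json").read_text())
            series_by[(meta["protocol"], meta["timepoint"])] = _load_block(bdir)
        row = truth.loc[animal]
        wfr_rows.extend(
            quantify_animal(
                animal,
                int(row["group"]),
                series_by,
                rois,
                slit_size_mm2=float(row["slit_size_mm2"]),
                half_width=config.smooth_half_width,
            )
        )
        tdir = adir / "ttc"
        if tdir.exists():
            import imageio.v3 as iio

            tmeta = json.loads((tdir / "ttc.json").read_text())
            slices = []
            for i in range(tmeta["n_slices"]):
                excl_p = tdir / f"exclusion_{i}.png"
                slices.append(
                    TtcSlice(
                        image=iio.imread(tdir / f"slice_{i}.png"),
                        mm_per_pixel=tmeta["mm_per_pixel"],
                        thickness_mm=tmeta["thickness_mm"],
                        midline_col=tmeta["midline_col"],
                        exclusion_mask=_read_mask_png(excl_p) if excl_p.exists() else None,
                    )
                )
            res = infarct_volume(slices, ipsi_side="right")
            inf_rows.append(
                {
                    "animal": animal,
                    "group": int(row["group"]),
                    "slit_size_mm2": float(row["slit_size_mm2"]),
                    "raw_volume_mm3": res.raw_volume_mm3,
                    "corrected_volume_mm3": res.corrected_volume_mm3,
                    "ipsi_volume_mm3": res.ipsi_hemisphere_volume_mm3,
                    "contra_volume_mm3": res.contra_hemisphere_volume_mm3,
                }
            )
    wfr_df = pd.DataFrame(wfr_rows)
    for col, val in (
        ("dip_threshold", config.dip_threshold),
        ("overshoot_threshold", config.overshoot_threshold),
        ("condensed_threshold", config.condensed_threshold),
        ("smooth_half_width", config.smooth_half_width),
        ("software_version", __version__),
    ):
        wfr_df[col] = val
    p1, p2 = root / "wfr_metrics.csv", root / "infarct.csv"
    wfr_df.to_csv(p1, index=False)
    pd.DataFrame(inf_rows).to_csv(p2, index=False)
    return p1, p2


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable({f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)})
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def cmd_stats(config: RunConfig, data_dir: str | Path | None = None) -> Path:
    """Run the statistical battery on quantified tables; writes stats.json."""
    root = Path(data_dir or config.out_dir)
    wfr = pd.read_csv(root / "wfr_metrics.csv")
    infarct = pd.read_csv(root / "infarct.csv")
    results = run_study_stats(wfr, infarct, correction=config.correction)
    # strip the non-serialisable pivot before writing
    for key in results["wfr"]:
        res = results["wfr"][key]["anova"]
        results["wfr"][key] = {
            "anova": res.effects,
            "note": res.note,
            "n_excluded": res.n_excluded,
            "contrasts": results["wfr"][key]["contrasts"],
        }
    out = root / "stats.json"
    out.write_text(json.dumps(_jsonable(results), indent=1))
    return out
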