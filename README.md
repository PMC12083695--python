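# isoipipe

Quantitative analysis of widefield **intrinsic-signal optical imaging
(ISOI)** and **TTC histology** for the rat permanent middle-cerebral-artery
occlusion (pMCAo) model — the kind of study that asks whether neuronal
activity in the ischemic cortex (spontaneous, or evoked by whisker
stimulation) protects the tissue from deteriorating to infarct, and that
reads the answer out of (a) the whisker functional representation (WFR)
imaged before and 24 h after occlusion and (b) post-mortem infarct
volumetry.

It is written for imaging labs running baseline-vs-24 h designs with
multiple intervention groups: the same code quantifies real TIFF stacks and
TTC photographs, and ships a fully seeded synthetic-data generator that
emulates the whole experiment, so every stage of the pipeline is testable
end-to-end with known ground truth.

## What it computes

**Ratio images.** Reflectance frames acquired at 100 ms are summed to
500 ms analysis frames; each post-stimulus frame is divided by the 500 ms
frame collected immediately before stimulus onset:

    FC(x, y, t) = R(x, y, t) / R(x, y, pre) − 1        (fractional change, ΔR/R)

The evoked signal is triphasic: initial dip (dark, deoxyhemoglobin),
overshoot (bright, blood-flow influx), undershoot. Trials are averaged per
block (64 trials for the sparse protocol, 40 for the condensed one).

**WFR scoring.** The ratio frame with maximum areal extent per phase is
selected (condensed protocol: the fixed 0.5–1.0 s frame), Gaussian-filtered
(half-width 5 px), and thresholded *away from zero* at 1.75 × 10⁻⁴ (initial
dip), 3.5 × 10⁻⁴ (overshoot) or 2.5 × 10⁻⁴ (condensed dip). Areal extent is
the suprathreshold pixel count inside an analyst ROI drawn around the
skull-dura drug slit (7 × 7 mm field, default 7/512 mm/px); peak amplitude
is read at the pixel of peak activity inside the slit footprint.

**Infarct volumetry.** TTC-stained 2 mm coronal slices are segmented into
viable (red) vs unstained (white) tissue; surgical-site damage is excluded.
Volume = Σ areaᵢ × thickness, corrected for edema by the hemispheric ratio

    V_corrected = V_raw × V_contra / V_ipsi

**Statistics.** Mixed-design RM-ANOVA (between: group 1–5; within:
baseline vs 24 h) with Bonferroni/Sidak-corrected per-group contrasts,
baseline-equality one-way ANOVA, Welch t-tests and one-way ANOVA on infarct
volumes, and OLS of infarct volume on dura-slit size.

## Worked example

Simulate one block of 64 noisy sparse-protocol trials with a known dip of
−5 × 10⁻⁴ ΔR/R and quantify it:

```python
import numpy as np
from isoipipe import (SPARSE, INITIAL_DIP, SignalGroundTruth, make_trial_stack,
                      process_block, select_phase_frame, smooth_frame,
                      areal_extent, peak_amplitude_sparse)

truth = SignalGroundTruth(dip_amp=-5e-4, center=(32, 32), sigma_px=7.3, noise_sd=2.5e-4)
trials = [make_trial_stack(SPARSE, truth, seed=s) for s in range(64)]
series = process_block(trials)                      # sum to 500 ms, ratio, average
roi = np.ones((64, 64), dtype=bool)
k = select_phase_frame(series, INITIAL_DIP, roi)    # max-extent dip frame
smoothed = smooth_frame(series.fc_frames[k])
area_px, area_mm2, extent = areal_extent(smoothed, INITIAL_DIP, roi, series.mm_per_pixel)
slit = np.zeros((64, 64), dtype=bool); slit[28:37, 28:37] = True
amp, px, _ = peak_amplitude_sparse(series.fc_frames[k], extent, slit,
                                   locator_frame=smoothed, polarity=-1)
print(f"dip frame {k} (mid-time {series.times_s[k]:.2f} s post onset)")
print(f"areal extent: {area_px} px = {area_mm2:.2f} mm^2 at threshold 1.75e-4")
print(f"peak amplitude {amp:.2e} dR/R at pixel {px}")
```

prints

```
dip frame 5 (mid-time 2.75 s post onset)
areal extent: 344 px = 4.12 mm^2 at threshold 1.75e-4
peak amplitude -5.30e-04 dR/R at pixel (32, 32)
```

— the dip frame falls on the kernel plateau (2.0–3.0 s post onset), the
extent is the thresholded blob clipped to the ROI, and the amplitude is
read from the unsmoothed ratio image at the peak pixel located on the
smoothed one (−5.3 × 10⁻⁴ vs the generating −5 × 10⁻⁴; single-pixel noise).

## The simulated study

`analysis/` reruns the full study as numbered steps:

```sh
python analysis/01_simulate_study.py --seed 1       # 5 groups x 8 animals
python analysis/02_quantify_wfr_and_infarct.py --seed 1
python analysis/03_statistics.py
```

Group 1 (pMCAo + vehicle + stimulation) and group 2 (sham + lidocaine +
stimulation) recover fully; groups 3–4 (pMCAo + lidocaine, ± stimulation)
lose the WFR inside the drug-diffusion area and develop slit-size-dependent
infarcts; group 5 (pMCAo + vehicle, no stimulation) is functionally
impaired with a bimodal (localized vs extended) infarct. Step 03 prints the
per-metric RM-ANOVA interaction p, which groups changed significantly from
baseline, and the slit-size regressions. Tables land in `results/`.

A `isoipipe` CLI (`simulate`, `quantify`, `stats`, `report`) provides the
same workflow over on-disk datasets (TIFF stacks + JSON sidecars, PNG
masks/slices, CSV tables) for use with real acquisitions.

## Layout

    src/isoipipe/
      protocols.py     stimulation protocols, phases, thresholds
      synthetic.py     seeded generators: trial stacks, TTC series, full study
      ratio.py         frame summation, ratio images, averaging, smoothing,
                       phase-frame selection
      wfr.py           areal extent, peak amplitude, ROI handling
      infarct.py       TTC segmentation, volumetry, edema correction, regression
      stats.py         mixed-design RM-ANOVA, post hocs, group tests
      orchestration.py end-to-end pipeline + file I/O
      cli.py           command-line verbs
    analysis/          numbered study drivers (simulate, quantify, stats)
    tests/             pytest suite (unit, property, acceptance)
    docs/methods.md    model and methods note
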