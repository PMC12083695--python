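# Models and methods

This note records the generative model behind the synthetic data, the
analysis conventions the pipeline commits to, the statistical procedures,
and the choices made where the underlying experimental description left the
design open. Nothing here states an empirical result; all numbers quoted as
defaults are parameters, and everything measurable is computed by the test
suite and `scripts/acceptance.py`.

## The evoked-signal forward model

A trial stack is

    R(x, y, t) = B(x, y) · (1 + k(t) · g(x, y) · [1 − block(x, y)]) + ε

* **Baseline** `B` is a smooth spatial field around 10⁴ counts (±4%
  large-scale variation) with static dark vessel streaks (25% darker,
  ~2 px wide). Because the streaks are static they cancel exactly in the
  ratio images; streak jitter is not modelled.
* **Temporal kernel** `k(t)` is a sum of raised-cosine lobes with *flat
  plateaus aligned to the 500 ms analysis grid*: initial dip (rise from
  0.5 s post onset, plateau 2.0–3.0 s, i.e. peak 2.5 s), overshoot (plateau
  4.5–5.5 s, peak 5.0 s), undershoot (plateau 7.5–8.5 s). A plateau spanning
  two whole analysis frames makes the 500 ms frame mean equal the
  ground-truth amplitude exactly, so the forward model is invertible by the
  pipeline to within float32 round-off (~1 × 10⁻⁷ ΔR/R) — this is what the
  noise-free recovery tests exploit. The condensed protocol carries only a
  fast-growing dip (rise 0–0.5 s, plateau 0.5–2.0 s): its quantification
  window is 0.5–1.0 s after stimulus delivery, so a slow sparse-style dip
  would be invisible there; the fast rise is the model of a "growing
  initial dip" under naturalistic whisking.
* **Spatial profile** `g` is a 2-D Gaussian (default σ = 0.8 mm) centred
  under the drug slit. `block` is the drug-diffusion footprint in which the
  signal is abolished (simulated lidocaine).
* **Amplitudes** default to dip −5 × 10⁻⁴, overshoot +7 × 10⁻⁴, undershoot
  −3 × 10⁻⁴ ΔR/R (physiological 10⁻⁴–10⁻³ scale), jittered ±10% per animal.
* **Noise** ε is white Gaussian per raw 100 ms frame, specified at the
  native 512 px camera grid (default sd 2 × 10⁻³ of local baseline) and
  scaled by the linear binning factor to the simulation grid — a 64 px
  simulation pixel aggregates 8×8 camera pixels, so its per-pixel noise is
  2.5 × 10⁻⁴. Frames are stored as float32 within the 16-bit count range:
  integer quantisation at 10⁴ counts would add ~2 × 10⁻⁵ relative error and
  mask the sub-10⁻⁶ recovery checks.

## Pipeline conventions

* Fractional change is `ratio − 1`, so thresholds "away from zero" and the
  ± phase polarities are meaningful.
* The reference frame is the single 500 ms frame immediately preceding
  stimulus onset, not a pre-stimulus average.
* Analysis frame `k` spans `[0.5k, 0.5(k+1))` s post onset (half-open).
* "Half width = 5" for the Gaussian filter is interpreted as the HWHM in
  pixels (σ = 5/√(2 ln 2) ≈ 4.25 px), reflection boundaries. The parameter
  is configurable and recorded in output provenance.
* Sparse phase-frame selection maximises the suprathreshold pixel count
  inside the ROI over the first 7 s post onset; ties break to the earliest
  frame (deterministic). A series with no suprathreshold pixel anywhere
  raises a named error; per-animal assembly converts that into a zero-area
  row flagged `no_suprathreshold_activity`, scored at the nominal phase
  peak time.
* **Peak amplitude is read from the unsmoothed ratio frame** at the peak
  pixel *located on the smoothed frame* within slit ∩ extent. Locating on
  the filtered image is noise-robust; reading the unfiltered value avoids
  the systematic attenuation a finite blob suffers under convolution
  (factor σ_b²/(σ_b²+σ_k²)), so the reported amplitude is an unbiased
  estimate of the true peak. If slit ∩ extent is empty (abolished
  representation) the read falls back to the slit alone and the row is
  flagged, so 24 h comparisons stay numerically defined.
* Condensed amplitude is read at the *baseline* peak pixel for both
  timepoints (paired at the same pixel); condensed extent uses the fixed
  0.5–1.0 s frame with the 2.5 × 10⁻⁴ threshold at dip (negative) polarity,
  since the condensed signal has only the dip phase.
* Pixels reaching the 16-bit ceiling are flagged and excluded from ROI
  statistics.
* The analysis ROI is generated around the slit (dilation by 3 px) unioned
  with a disk of 1.5 mm radius about the slit centroid, so the counted
  baseline extent does not scale with the (randomised) slit size; with real
  data, hand-drawn mask images are supplied instead.

## TTC model and segmentation

Slices are half-ellipse hemisphere pairs (2 mm thick, 0.1 mm/px); the
ipsilateral half's axes are scaled by √(edema_factor) so its area scales by
the factor itself. Rendered infarct blobs sit in the ipsilateral
dorsolateral cortex and carry the edema factor, so the hemisphere-ratio
correction recovers the intended pre-edema volume. Segmentation: tissue by
an Otsu cut on luminance; infarct within tissue by red-channel dominance
`(R − max(G,B))/255` below a margin (default 0.10) *and* lightness above an
Otsu cut over the tissue region — the lightness guard is dropped when the
tissue is uniformly one class, so an all-red slice yields an empty infarct
mask instead of an arbitrary split. Surgical-site pixels (explicit
exclusion mask) are removed from the infarct. Edema correction defaults to
`V_raw × V_contra/V_ipsi`; the Swanson-style indirect difference
`V_contra − (V_ipsi − V_raw)` is available via `correction="indirect"`.
The hemisphere midline is a supplied vertical line, or the tissue-centroid
column when absent.

## Study design and outcome rules

Five groups × 8 animals, baseline and 24 h, both protocols: (1) pMCAo +
vehicle + stimulation, (2) sham + lidocaine + stimulation, (3) pMCAo +
lidocaine, no stimulation, (4) pMCAo + lidocaine + stimulation, (5) pMCAo +
vehicle, no stimulation. Rules applied at 24 h:

* groups 1–2: unchanged generating truth (fresh noise only), zero infarct;
* groups 3–4: signal zeroed inside the drug-diffusion footprint (the
  analysis ROI dilated by 2 px), infarct volume
  `2.0 + 3.0 · slit + N(0, 0.5)` mm³ (slit in mm² of dura opening, drawn
  uniformly per group; group 4 uses a wider slit range);
* group 5: signal blocked in every animal; infarct volume drawn from a
  50/50 mixture of the localized slit-linked rule above vs an extended mode
  ~N(40, 8) mm³ (clipped ≥ 15). The mixture weights are configurable; the
  two volume components are deliberately well separated so the bimodality
  is recoverable at realistic n.
* Infarcted animals get edema_factor 1.08; volumes spread over 3 (≤20 mm³)
  or 5 slices with a tapered profile.

Inter-trial intervals are metadata only — no dead-time frames are
generated, since no analysis step uses them. The sparse protocol's nominal
"15 s trial" label conflicts with its 1.5 + 1 + 13.5 s components; the
components win and the discrepancy is recorded in the protocol metadata.

## Simulation scale

The generator's defaults keep the experimental conditions — 5 × 8 animals,
two timepoints, 64 sparse / 40 condensed trials per block, the protocol
timings and thresholds above — but render images on a 64 × 64 grid at
7/64 mm/px rather than the native 512 × 512. All reported quantities are in
physical units (mm², ΔR/R, mm³) and the noise model scales with binning,
so the grid choice affects only discretisation, not the study-level
conclusions; full-resolution rendering is a parameter away
(`StudyDesign(img_px=512)`).

## Statistics

The mixed-design RM-ANOVA is computed from the classic sums-of-squares
decomposition on the subject × time pivot (between: group,
subjects-within-groups; within: time, group × time, residual). The
between- and within-subject halves are computed independently so the
partition `SS_total = SS_between + SS_within` is a genuine consistency
check (asserted to 1 × 10⁻⁸ relative); the implementation is cross-checked
in the tests against pingouin's `mixed_anova` and against a one-way ANOVA
on difference scores (to which the interaction test is algebraically
equivalent with two within-levels). With two within-levels sphericity holds
trivially; no epsilon correction is applied and every result says so.
Unbalanced groups (after listwise exclusion of subjects missing a
timepoint, which is logged) use subject-weighted marginal means.

Post hoc baseline-vs-24 h contrasts default to the pooled within-subject
error term (se = √(2·MS_error/n_g), df = N − g), the convention of
RM-ANOVA post hocs in mainstream stats packages; a per-group paired t is
available. Both Bonferroni (`min(1, p·k)`) and Sidak (`1 − (1−p)^k`)
corrected p values are always reported; the decision column defaults to
Sidak (the less conservative of the two). Infarct comparisons default to
Welch t-tests (configurable to pooled); a zero-variance pair with equal
means reports t = 0, p = 1 flagged degenerate rather than NaN. Peak
amplitudes are analysed as signed values (dip negative); "reduction" for a
dip therefore appears as a positive contrast estimate toward zero.

## What the generator does and does not emulate

It reproduces the *statistical structure of the measurements*: triphasic
ratio-image dynamics with realistic amplitudes and noise, vessel artifacts
that cancel in ratios, abolished representations under drug diffusion,
slit-size-linked infarct volumes, hemispheric edema, and the group design.
It does not model collateral blood-flow physiology, LFP synchronisation,
anesthesia, acquisition-hardware effects (shot-noise statistics, photon
transfer curves, motion), registration error between sessions, or manual
ROI drawing from vasculature landmarks (ROIs are generated geometrically).
Passing tests therefore validate the *analysis chain* — not the biological
claims — and real-data results additionally depend on registration and
mask quality that the synthetic path sidesteps.

## Numerical and degenerate-input choices

* Seeds: all randomness flows through `numpy.random.SeedSequence` spawns of
  one master seed; identical (design, seed) is bit-identical output.
* Ratio computation refuses a non-positive reference pixel by name;
  constant responses in the ANOVA are flagged degenerate, not raised.
* Tie-breaks: earliest frame (selection), lowest raster-order pixel
  (amplitude), documented above.
* The Monte-Carlo type-I check uses 5000 replicates in the test suite: the
  0.05 ± 0.015 acceptance band is ~2 SE wide at 1000 replicates, so a
  fixed-seed run can fail by estimator noise alone; more replicates tighten
  the estimator without touching the band.
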