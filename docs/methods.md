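# Methods

## Scope and model

`laryngodyn` analyses dynamic laryngeal CT acquisitions reconstructed at a
fixed frame interval (default 100 ms) during a task of five short /i/
phonations inside a ≤ 5 s scan. Its inputs are per-frame left/right arytenoid
fiducial coordinates (mm) and a per-frame segmented glottic area (mm²); all
downstream quantities derive from these.

Per frame: IAD is the Euclidean distance between the markers; IAI = GA / IAD
(computed per frame — the mean IAI is a mean of ratios, never a ratio of
means); arytenoid velocity is the sum of the two markers' displacements over
one frame interval, direction-classified by the sign of the IAD change
(|ΔIAD| < 10⁻⁶ mm counts as stationary — a pure float-safety tie-break). An
alternative velocity definition, |ΔIAD| itself, is available behind
`variant="iad-delta"`; the two agree for purely symmetric mediolateral
motion and differ under rotation or drift, which is why the
displacement-sum is the primary definition. Per participant: means over the
vocalization period, plus *effective* extrema defined as the median of the
five lowest (GA, IAD) or highest (IAI, velocities) per-frame values — five
because the task contains five phonations, one extreme per phonation; the
median over the five resists a single outlying frame. When fewer than five
values exist the available ones are used and a warning is logged.

Missingness is per measure: a frame may lack a placeable marker or a GA
value, so the IAD, GA and IAI series of one participant can have different
lengths; IAI requires both. All counts are carried into the summary.

## Trimming

Before and after vocalization the glottis is wide open and GA/IAD are far
above their phonatory range. The pipeline replaces manual/visual exclusion
of these periods with a deterministic rule: in the leading and trailing
maximal runs, frames whose GA exceeds `factor × median(GA)` (default factor
2.0) are marked non-vocalizing; interior frames are never touched. The
pipeline additionally applies a one-frame guard band just inside each
non-empty trimmed run (`guard_frames=1` in the default run configuration;
the bare rule has `guard_frames=0`). The guard exists because the frame that
straddles the vocalization onset/offset mixes open and phonatory
configurations: whether the threshold happens to catch it depends on the
participant's GA level, which in a disease cohort correlates with severity,
and that dependence measurably attenuated the mixed-model slope in
simulation (see calibration below). A human trimming visually would exclude
such ambiguous boundary frames as a matter of course. If every frame ends up
excluded the series is reported as unusable rather than silently empty.

## Segmentation

`segment_glottic_area` binarizes the ROI below an attenuation threshold
(default −400 HU, between air ≈ −1000 HU and soft tissue ≈ +40 HU), labels
4-connected components and returns the largest component's pixel count ×
pixel area. The matching phantom renderer draws a glottal aperture (triangle
from the anterior commissure to a posterior edge of width IAD, with an
optional mid-membranous bowing bulge that leaves the posterior width fixed)
and chooses the aperture length so that the *rasterized* air area matches
the requested target: a bisection over length followed by a pixel-level
top-up from the next-larger aperture's shell, most-interior pixels first,
keeping 4-connectivity. This guarantees round-trip agreement within two
pixel areas for any achievable target, which the test suite sweeps over
1–100 mm².

## Synthetic cohorts

The generator emulates the data structure of a 30 PD / 19 control
cross-sectional cohort:

- **Waveform.** Each phonation is a raised-cosine adduction gate
  (rise 100 ms, hold 500 ms, fall 100 ms, inter-phonation gap 100 ms, onset
  jitter SD 30 ms). Between phonations the gate falls only to 0.55 of full
  adduction: a speaker producing five quick phonations does not fully abduct
  in the gaps. Acquisition starts with a 300 ms open-glottis lead-in and is
  terminated ~300 ms after the task ends (scans end early once the task is
  complete), so fully-open frames are a small minority of each series.
- **Kinematics.** IAD runs from a resting open baseline (15 mm) down to a
  phonatory minimum (3.7 mm) along the gate, plus a participant-level
  baseline shift (SD 0.4 mm) realising the mixed model's random intercept.
- **Hyperadduction.** Disease shifts the *entire* IAD trace inward by
  0.011 mm per month of duration. Modelling the shift as uniform (rather
  than deepening only the phonatory minimum) follows the physiology of
  increased adductor muscle tone at rest, and makes the frame-level
  duration→IAD slope a single well-defined estimand equal to the
  configuration parameter.
- **Bowing.** GA is `5 mm²/mm × IAD` plus a bowing term
  `0.09 mm²/month × duration × gate`, floored at 0. Scaling by the gate
  encodes that a fold-edge closure deficit adds area only as the folds
  approach closure; with duration 0 or bowing 0, GA is exactly linear in
  IAD.
- **Noise.** Isotropic Gaussian jitter on each fiducial coordinate
  (SD 0.15 mm, sub-pixel at typical CT resolution) and additive Gaussian GA
  noise (SD 2 mm²), floored to physical ranges. Noise-free channels are
  retained on every series for oracle tests.
- **Covariates.** Durations ~ log-normal (median 83.5 months, log-SD 0.77)
  truncated to [6, 160]; UPDRS-III = 5 + 0.18 × duration + N(0, 5), rounded
  and clipped to [0, 132]; ages ~ N(69.7/70.8, 7.35) by group; sex by the
  cohort's observed proportions. Age and sex have no effect on the
  kinematics, so the model's age/sex adjustments estimate true zeros.
- **Determinism.** Each participant consumes an independent child stream of
  the cohort seed; identical configs give bit-identical cohorts. An optional
  extra participant acquired at 300 ms/frame exercises the reader's
  interval validation.

Effect sizes were fixed once by pilot simulation so that group differences
at n = 30/19 are comfortably detectable (power ≈ 0.8 or better for the
positional measures) while the trimming rule's threshold stays at least
~4σ of GA noise away from the open-glottis GA across the whole duration
range — the constraint that actually binds the bowing slope. Velocity
measures have no disease effect, matching their null group comparisons.

What the generator does *not* emulate: arytenoid rotation (only
mediolateral sliding is modelled, so the displacement-sum and |ΔIAD|
velocities coincide up to noise), vocal tremor, acoustic covariates
(volume/pitch/cadence), anatomical detail beyond the glottal-plane slice,
and any non-Gaussian measurement pathology (streak artefacts, marker
misplacement). Passing tests therefore demonstrate the pipeline's
correctness and calibration under a plausible data-generating process, not
clinical validity on patient data.

## Inference

- **Group comparisons**: two-sided Wilcoxon rank-sum per summary measure;
  exact null distribution when both groups have ≤ 10 untied values, else the
  tie-corrected normal approximation. Benjamini–Hochberg q-values are
  annotated as supplementary columns without changing any headline decision,
  matching common practice in this literature of reporting raw α = 0.05
  tests.
- **Correlations**: tie-corrected Spearman ρ with t-approximation p-values.
  Velocity measures enter the correlation stage only if their group
  comparison is significant (configurable), mirroring the analysis logic the
  comparisons motivate. Duration analyses use PD participants only (controls
  have no duration); UPDRS analyses include controls at their recorded score
  of 0 — both scopes are switchable.
- **Mixed models**: per-frame `measure ~ predictor + age + sex` with a
  participant random intercept, REML via statsmodels `MixedLM`. The
  optimizer chain is BFGS → Powell → Nelder-Mead; L-BFGS is avoided because
  it reproducibly stalls on a zero-variance boundary for this data shape.
  GA and IAI are log-transformed (offset 1.0, since both can be exactly 0;
  the offset and transform are configurable and the label travels with
  every fit). Inference on the predictor uses the between-participant
  convention df = n_participants − 3 − 1 (three participant-level fixed
  effects), with t-based p-values and CIs. R² follows the variance-partition
  (marginal = fixed / total, conditional = fixed+random / total) method.
  Degenerate fits — boundary variance estimates or too few participants —
  are returned flagged (`singular`, `converged`), never raised. Within each
  predictor the fitted response with the highest marginal R² is marked as
  the preferred model.

## Calibration (what the simulation studies show)

With the default generator and pipeline settings, over 400 independent
cohorts: the IAD~duration mixed-model slope is recovered with < 3% mean
bias; the 95% CI covers the true slope in ≈ 95% of cohorts (model-based SE
0.00216 vs empirical sampling SD 0.00222); permutation-null rejection rates
are ≈ 4–5% for both the Wilcoxon and the mixed-model t test; and the
disease-direction pattern (lower PD effective-minimum IAD, higher mean GA
and effective-maximum IAI, negative IAD slopes and positive transformed
GA/IAI slopes) appears in ≈ 96–100% of replicate cohorts. Two pipeline
refinements were required to reach this calibration and are part of the
design: the trim guard band (above) and an open-baseline IAD high enough
that the trim threshold never approaches the open-glottis GA within the
duration range.

## Numerical and degenerate-input choices

- CSVs are written at full float precision (round trips are lossless);
  missing values are empty fields, never sentinels.
- The fiducial reader validates per participant: uniform frame interval
  (tolerance 10⁻⁶ ms), strictly increasing frame indices, finite
  coordinates, no duplicate (participant, frame). Structural defects raise
  errors naming the file line; an off-nominal frame interval rejects only
  that participant, with the reason logged and reported.
- All artifacts embed a provenance block (package version, seed, config
  hash excluding file locations); no timestamps, so identical configurations
  produce byte-identical outputs.
- `run_full_analysis` is a pure function of its inputs and configuration.

## Known limitations

- The trimming rule assumes open-glottis GA well above phonatory GA; series
  violating this (e.g. extreme bowing with near-open phonation) may go
  untrimmed, which the pipeline reports via trimmed-frame counts.
- The mixed-model SE is the usual plug-in REML estimate; with ~30
  participants it runs ~2–3% below the empirical sampling SD (no
  Kenward–Roger-style correction is applied).
- Rank-test p-values for large groups rely on the normal approximation.
- Rotational arytenoid kinematics, tremor spectra and vocal-fold edge
  tracking are out of scope.
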