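# Methods

## The cascade model

The package tests an exploratory hierarchical hypothesis: aging degrades
cerebral arterial elasticity; stiffer arteries injure white and gray
matter; structural injury erodes the functional segregation of
resting-state networks; and lower segregation manifests as poorer
cognition in age-sensitive domains. The observable signature is a
correlation matrix between level composites whose entries decay with the
number of intervening levels. No causal or mediation model is fitted —
the statistics are pairwise correlations, composite correlations and a
bootstrap ordering test, which is all a 46-subject cross-sectional
design supports.

Levels and default variables (signs align "healthier = larger"):

| level | variables (sign) |
|---|---|
| vascular | PReFx (+) |
| structure | mean cortical thickness (+), adjusted WMSA (−) |
| function | association segregation (+), sensorimotor segregation (+) |
| cognition | episodic memory (+), reasoning (+) |

## Functional-connectivity preprocessing

Fixed stage order per run: censor-mask construction → demean + nuisance
regression (betas fitted on retained frames only, fitted values
subtracted everywhere, so interpolation operates on residuals) → linear
interpolation across censored frames → band-pass → removal of censored
frames; runs are then concatenated. Run boundaries are never filtered or
interpolated across.

* **FD<sub>filt</sub>**: each of the six rigid-body parameters is
  low-pass filtered at 0.1 Hz (order-2 Butterworth, forward–backward; the
  cutoff suppresses respiratory oscillation), first-differenced, and the
  absolute differences are summed per frame. Rotations (radians) are
  converted to arc displacement on a 50-mm sphere — the standard
  frame-wise-displacement convention — before summation. Frame 0 gets 0.
* **Censoring**: frames with FD<sub>filt</sub> > 0.1 mm (strict
  inequality), the first and last 5 frames of each run, and any surviving
  retained segment shorter than 5 frames. Subjects with fewer than 50
  retained frames in any run are excluded.
* **Nuisance regression**: 27 regressors — global signal (mean over
  ROIs), CSF and WM means, and the Volterra expansion of the motion
  parameters (current and previous frame, each also squared; the
  previous-frame copy of frame 0 is zero-padded). A rank-deficient
  design is an error that names the offending columns.
* **Band-pass**: 0.009–0.08 Hz Butterworth of order 1, applied
  forward–backward (zero phase; phase handling is a package choice, the
  order-1 design is the convention adopted).

## Segregation

Pearson correlations for all ROI pairs → Fisher Z (atanh) → negative
entries set to zero (per subject, before any averaging) → class-wise
means. Within pairs are unordered pairs inside one network of the class;
between pairs span two *different networks of the same class*; pairs
touching excluded networks (cerebellar, subcortical, undefined) never
enter either mean, and the diagonal is excluded. Segregation is
(Z̄w − Z̄b)/Z̄w, undefined (error) when Z̄w ≤ 0. The statistic is
invariant to ROI permutation and to positive rescaling of the matrix.
The ROI roster and network membership are data-driven from the partition
file; nothing is hard-coded to a particular atlas size.

## PReFx

R-peaks are local EKG maxima above a per-recording threshold (median +
`threshold_scale` × excursion, default 0.5 — EKG gain varies by
participant); candidates closer than the minimum plausible interbeat
interval (0.33 s) resolve to the taller peak, which dismisses artifact
spikes riding near a true R wave. The optical channel is band-passed
0.5–5 Hz (order-2 Butterworth, zero phase — the order is a package
choice) and averaged over beats from each R peak to the median interbeat
interval on a common 100-point grid; beats truncated by recording edges
are dropped. Polarity is normalized by the upstroke asymmetry: the
systolic rise is steeper than the relaxation decay, so the waveform is
flipped when the largest negative sample-to-sample slope exceeds the
largest positive one. (Comparing excursion magnitudes instead fails
after band-passing, because the pre-systolic foot can be deeper than the
systolic peak is high.) Landmarks: systole = global maximum in the first
40% of the cycle; diastole = global minimum after it. The
systole→diastole segment is rescaled to unit time and unit amplitude
(diastole 0, systole 1) and integrated by the trapezoidal rule; PReFx =
area − 0.5. It is invariant to affine amplitude transforms, uniform time
dilation and polarity, and lies in [−0.5, 0.5] whenever the segment
stays within the landmark amplitudes. A global score is the mean over
regional values (missing regions skipped and counted). Movement
correction of the optical series and 3-D optical reconstruction are out
of scope; the scorer accepts channel-level or externally reconstructed
regional waveforms.

## Constructs and WMSA

Z-scores use the divide-by-(n−1) SD convention (so scores {10, 20, 30}
map to {−1, 0, 1}) on raw, never age-normed, scores. Trail A is
sign-inverted after standardization. The working-memory member
"Trail A − Trail B" is computed on raw seconds and then standardized; it
is averaged with OSPAN as stated, without an additional orientation
flip — whether A−B should be flipped before averaging is genuinely
ambiguous (A−B is negative, and larger when B is relatively fast), so
the stated form is implemented and flagged here. A Mental Control
construct is deliberately absent. WMSA adjustment is OLS
residualization of log-volume on intercept, intracranial volume and a
binary sex code; residuals are in log-mm³ units.

## Cascade statistics

* One-tailed Pearson p-values from t = r√((n−2)/(1−r²)) on n−2 df,
  pairwise-complete.
* Partial correlation by OLS residualization of both variables on the
  covariate block (equals the textbook single-covariate closed form to
  machine precision; cross-checked against pingouin in the tests).
* Composites re-standardize within whatever sample is being analyzed —
  including within each bootstrap resample.
* Off-diagonal means: m₁ over {(1,2),(2,3),(3,4)}, m₂ over {(1,3),(2,4)},
  m₃ = (1,4). Reported summaries use absolute correlations (display
  convention); the bootstrap contrasts use **signed** Fisher-transformed
  means. The sign-coherence step makes the expected correlations
  positive, so the two agree on coherent data; folding near-zero
  correlations to absolute values would bias their means upward and make
  the null test conservative (measured: 0/200 null rejections at .05
  with folded means vs. 0.06 with signed means, inside the plausible
  band for a calibrated .05-level test).
* Bootstrap: resample subjects with replacement at the original n,
  recompute composites and the 4×4 matrix per resample, p(contrast) =
  fraction of resamples with contrast ≤ 0. Subjects are sorted by ID
  before resampling so results are invariant to row order;
  zero-variance resamples are redrawn and counted. One root seed drives
  all randomness.
* Age is excluded from the cascade analysis (it correlates with every
  level and is measured without error, so it would dominate the
  pattern); a covariate-partialing option exists for the pairwise
  statistics.
* Bonferroni: alpha/m, with m = 6 constructs by default.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes;
it is study-condition plumbing, not a biophysical simulator.

* **Latent chain**: age ~ Uniform(18, 75), standardized; each level is
  path × previous + Gaussian noise. Linear-Gaussian is the simplest
  model with the correlation-decay signature. Defaults: paths
  (−0.6, +0.7, +0.7, +0.7), noise SD 0.7, n = 46 — giving
  adjacent-level correlations around .5–.7, the observed range.
* **ROI series**: exact block-structured correlation via a shared factor
  (loading √between), per-network factors (√(within − between)) and
  unit-completing noise; requesting between > within or within ≥ 1 is a
  non-positive-definite error. Three low-frequency drift channels
  (global/CSF/WM) are returned; with `confound_strength > 0` a partially
  shared mixture of them is added to the ROIs (the cohort simulator uses
  0.3), at the cost of perturbing the exact block structure — hence the
  default 0 for the convergence guarantees.
* **Motion**: smoothed random-walk baseline (step SD 0.01 mm; rotations
  matched on the 50-mm sphere) plus single-frame 1-mm spikes at 3%
  probability; spike frames are returned as ground truth and are
  reliably caught by the 0.1-mm censoring rule.
* **Pulse**: each cycle is a sharp gamma-shaped forward wave (peak at
  0.15 of the cycle, shape 3) plus a broader, lower reflected wave (peak
  fraction 0.30, shape 2, amplitude 0.9) delayed by
  0.175 · period · (1 − overlap). The broadened reflection is essential:
  a same-shape delayed copy creates a separate late bump whose preceding
  trough captures the diastole landmark and breaks the monotone
  overlap→PReFx relationship. With this template PReFx decreases
  strictly from ≈ +0.17 (overlap 0) to ≈ −0.13 (overlap 1) through the
  full detection/averaging/landmarking pipeline, robust to additive
  noise and interbeat jitter. The EKG channel carries ~8-ms R spikes and
  a small T wave. Defaults: 39.0625 Hz optical, 200 Hz EKG sampling.
* **Observed cohort**: cognition loads on the test scores (timed tests
  log-linearly, keeping times positive), structure on log-normal lesion
  volume (negatively, plus ICV and sex effects) and thickness, vascular
  on the reflection overlap through a logistic map, function on the
  within/between correlation targets. Default scale: 11 networks × 4
  ROIs, two 160-frame runs at TR 2 s, 60-s pulse recordings — small
  enough to simulate a 46-subject cohort in about a second while keeping
  every downstream stage exercised at realistic parameter values.

What the generator does **not** emulate: voxel-level imaging, scanner or
optode physics, spatially structured noise, heteroscedastic or
non-Gaussian latent effects, floor/ceiling effects in test scores, and
any direct age path that bypasses the chain. Passing tests therefore
show the pipeline recovers the structure it assumes, not that real data
satisfy those assumptions.

## Numerical choices

* Zero-phase (filtfilt) filtering throughout; filter transients are the
  reason pipeline idempotence holds only approximately at run edges.
* Censor threshold comparisons are strict (> 0.1 mm censors).
* Fisher Z of |r| = 1 off-diagonal entries is an error, not a clip; the
  bootstrap clips at 1 − 10⁻¹² only to guard atanh overflow in
  resamples.
* Trapezoidal integration is exact for the linear-relaxation reference,
  making the PReFx = 0 anchor exact.
* Bootstrap calibration (B = 1000, n = 200, 50/200 seeds) keeps the
  simulation acceptance checks under a minute while the binomial error
  of the measured rates stays well inside the asserted bands.

## Known limitations

* The bootstrap ordering test is exploratory; it quantifies ordering
  stability under resampling, not causal structure.
* Segregation requires Z̄w > 0 after negative-zeroing; pathological
  matrices (all-nonpositive within-class connectivity) are errors by
  design.
* The closed-form composite correlation assumes the printed matrix is a
  correlation matrix of the same sample; applying it to a matrix rounded
  to 3 decimals reproduces rounded summaries, not unrounded
  subject-level values.
* Pairwise-complete handling of missing data can use different subject
  subsets per correlation.
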