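# Methods

This note documents the models, the numerical choices and what the synthetic
cohorts do and do not establish.

## Experimental model

The pipeline assumes a self-paced event-related design: after a 10-s blank
baseline, stimuli are shown back to back; each trial ends with a yes/no
button press and the next trial starts immediately. Repetition time defaults
to TR = 0.545 s (sub-second multiband acquisition), 25 trials per subject,
20 subjects. Response times (RT) are free, roughly 4–45 s, with
between-subject variability exceeding within-subject variability.

Two consequences shape every stage:

* **Trials are not comparable point by point.** All trial-resolved analyses
  first map each trial onto a normalized decision-time axis (0 % = stimulus
  onset, 100 % = button press). The mapping back to seconds is
  `t = pct/100 × RT`, e.g. 10 % of a 45-s decision is 4.5 s.
* **There is no inter-trial gap.** Combined with the deliberate choice *not*
  to correct for the 4–6 s hemodynamic delay, activity tied to the end of a
  trial peaks after the press, i.e. in the first ~0–15 % of the *next*
  trial. The normalized axis is therefore effectively circular across
  consecutive trials; stage orderings are interpretable up to a circular
  rotation, and the order-recovery checks assert exactly that. Correcting
  the delay would require assuming the HRF shape the FIR stage is designed
  not to assume.

## Synthetic cohorts

The generator plants known ground truth so that recovery is checkable:

* **Timing.** RT ~ truncated normal on [rt_min, rt_max] with per-subject
  mean (default spread 3 s); onsets are cumulative (no gaps); labels are
  Bernoulli(yes_probability). The study-scale preset gives 14 subjects RT
  centers of 13–30 s and plants six fast deciders (~6 s) so the inclusion
  rule (RT > 10 s in ≥ 13 of 25 trials) keeps exactly 14 of 20 subjects.
* **Signal.** A stage is a boxcar on [start_frac·RT, end_frac·RT) in a set
  of ROIs, with separate yes/no amplitudes (percent signal change, ~1 by
  default), convolved with the same canonical double-gamma HRF the GLM
  uses. The preset plants an early visual stage (0–20 %), a mid-trial
  evaluation stage (35–70 %), a yes-only late decision stage (55–85 %), a
  no-only mid-trial stage and a motor burst at the press.
* **Noise.** AR(1) Gaussian noise (marginal SD `white_sd`, lag-one
  autocorrelation `ar_coef`, default 0.85) plus one slow sinusoid and a
  linear ramp. BOLD noise at sub-second TR is strongly autocorrelated; the
  AR default also yields realistic fALFF values (> 1 for retained
  components). Correlation blocks plant exact population correlation r via
  a shared-factor decomposition of the innovations, optionally restricted
  to a trial epoch (e.g. the last 10 s of every trial) or one response
  condition; negative r is supported for ROI pairs only (an equicorrelated
  block with negative r and more than two members is not positive
  definite).

What the generator does **not** emulate: head motion, cardiac/respiratory
noise, multiband reconstruction artifacts, spatial anatomy, non-Gaussian
spontaneous fluctuations, or genuinely unknown effect sizes — the planted
amplitudes are free parameters. Passing recovery tests therefore shows the
*estimators* are correct and calibrated under the stated model, not that
real data would yield these rates.

## Stage-specific choices

**Detrending** projects each ROI series onto Legendre polynomials of order
0–3 (configurable) and removes the fit. This implements the drift-removal
contract (slow trends out, task-band content essentially untouched: white
noise keeps r > 0.99 with its detrended version at order 3); it is
idempotent and zero-means each ROI.

**Smoothing** uses an isotropic spatial Gaussian with
σ = FWHM/(2√(2 ln 2)) per axis in voxel units (8 mm FWHM at 3.3 mm voxels →
σ ≈ 1.03 voxels), nearest-edge boundary handling.

**fALFF** is the ratio of summed periodogram power in [0.01, 0.08] Hz to
(0.08, Nyquist] Hz, computed on the detrended series with a plain FFT
periodogram (no taper — downstream windows are ~18 samples, so spectral
sophistication buys nothing). The band edges follow common fALFF practice
and are configurable; components below threshold 1 are discarded. A
component with zero high-band power scores +inf and is kept (logged). In
the pipeline a ROI is kept when its median fALFF across subjects passes the
threshold; the filter feeds only the connectivity stage (the
spatiotemporal stage uses the full, anatomically curated ROI list supplied
by the user).

**GLM.** Canonical double-gamma HRF: gamma densities with shape
delay/dispersion and scale dispersion, peak delay 6 s, undershoot delay
16 s, dispersions 1 s, undershoot 1/6 of the peak, 32-s support, unit peak;
the sampled kernel peaks at ~5 s. Events are 1-s boxcars ending at the
press (duration configurable; the 1-s choice is conventional, not
principled), convolved and fit per ROI by OLS with an intercept. Contrast
t = c′β/√(σ̂² c′(X′X)⁻¹c). An exact fit (RSS at rounding level) reports
σ̂² = 0 and flags the t as undefined rather than returning a huge number.
Group summaries are fixed-effects medians across subjects.

**dFC.** Window length 10 s = 18 samples at TR 0.545 (floor). Trials
shorter than the window are skipped, never padded — padding would fabricate
samples, and the subject filter guarantees ≥ 13 eligible trials. The
end-anchored window ends at onset + ⌊RT/TR⌋ samples so it always lies
inside the trial and coincides with the start-anchored window when
RT equals the window length. Correlation p values use the t transform
(r√((n−2)/(1−r²)), two-sided), cross-checked against a permutation oracle.
A subject's edge is significant when more than half of its eligible trials
are retained at α = 0.05; the subject-level average is over retained trials
by default (averaging over all eligible trials is available — the two
differ only in the denominator). Group consensus keeps edges significant in
≥ 8 of 14 subjects; the sign is the sign of the across-subject mean of
subject means. Edges are undirected; no directionality is estimated.

Calibration caveat: the per-trial p value assumes temporally white series.
On 18-sample windows of autocorrelated BOLD-like noise the effective dof is
far below n−2 and per-trial significance is anticonservative — a property
inherited from the windowed-correlation method itself, not a bug in the
implementation. The type-I guarantee tested (and met: < 1 % spurious
consensus edges) is therefore stated for temporally independent noise;
under autocorrelated noise the consensus count measures cross-subject
*consistency*, and planted blocks still dominate the retained graph.

**Spatiotemporal mapping.** L = round(mean RT/TR) is computed over the
selected trials (all/yes/no); each trial segment is linearly interpolated
to L samples (endpoints preserved; Fourier resampling was rejected because
segments are short and non-periodic). The FIR design has one impulse
regressor per lag 0..L−1 repeated at every trial onset; for concatenated
equal-length segments the least-squares solution equals the per-lag
across-trial mean, which serves as the test oracle. Responses are then
linearly resampled to 100 points (percent decision time). A peak is a
strict local maximum (both neighbors lower), interior points only. Windows
are 20 points long starting at 0, 5, …, 80 (17 windows); per subject and
window all peaks inside the window are ranked by amplitude (ties: earlier
time, then lower ROI id — deterministic), and the ROIs owning the top-20
peaks are counted once each. Cells with ≥ 8 of 14 subjects form the
consensus; the yes/no difference keeps cells with |N_yes − N_no| ≥ 7. The
consensus threshold is 8 by default with the threshold exposed
(`--min-subjects`), since 7 is also a defensible majority cut for 14
subjects. Note the top-K rule is *rank-based*: a condition difference
requires near-zero amplitude in the other condition (or strong competition
for the K slots), not merely a weaker response.

**Decoding.** Features are per-trial pairwise Pearson correlations of the
resampled trial segments for a chosen ROI panel, in lexicographic pair
order of the panel (C(10,2) = 45 features for 10 ROIs). Pairs involving a
constant segment are zeroed and flagged. The classifier is a standardized
logistic regression (C = 1) — the minimal regularized linear family for
~45 features on a few hundred trials; the family is a configuration
option. Folds are stratified at the trial level by default; subject-grouped
folds are available because trial-level cross-validation can leak subject
identity. Chance is calibrated by label permutation (p = fraction of null
accuracies ≥ observed; the null mean sits at the majority-class
frequency).

## Problem sizes

The shipped experiments use cohorts of 10–20 subjects, 25 trials, 10–120
ROIs and runs of ~500 s at TR 0.545 s; consensus/recovery rates are
estimated over 10–20 independent seeds (tests) — sizes chosen so planted
effects are comfortably identified while a full suite plus the acceptance
script completes in a few minutes on one CPU. All randomness flows from
explicit integer seeds through `numpy.random.SeedSequence`; reruns are
bitwise identical, and each pipeline run writes a SHA-256 manifest to prove
it.

## Known limitations

* Registration, motion correction, slice-timing and group ICA are out of
  scope: inputs must already be aligned ROI/component series (or a 4-D
  volume plus a matching-grid integer atlas).
* Statistical inference is fixed-effects and per-subject; no random-effects
  group model or multiple-comparison correction over edges/cells beyond the
  consensus-count thresholds.
* The fALFF filter treats any supplied series like a component time course;
  ICA-specific normalizations are not modeled.
* Condition splits inherit carry-over contamination: activity from the end
  of trial k leaks into the first windows of trial k+1 regardless of the
  next trial's label. This is a property of gap-free designs, visible in
  the synthetic cohorts and documented above.
* Windowed-correlation p values are anticonservative under temporal
  autocorrelation (see the dFC caveat).
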