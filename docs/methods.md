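# Methods

`fatiguebci` re-creates, on synthetic data, the computational protocol of a
pediatric brain-computer-interface (BCI) fatigue crossover design: children
attend three sessions — a motor-imagery (MI) BCI, a visual P300 BCI, and a
video control — each bracketed by 2-minute eyes-open resting-state EEG, with
self-reported fatigue (VASF, 0–10 visual analog scale) and resting alpha-band
power as the primary outcomes. This note records the models, the parameters
that matter, the numerical choices, and what the synthetic experiments do and
do not demonstrate.

## Signal model of the synthetic EEG

Recordings are 19-channel (DSI-24 dry-electrode montage, 10–20 names
including Pz) at 300 Hz, in µV.

* **Background.** Independent per-channel 1/f ("pink") noise: white Gaussian
  noise whose amplitude spectrum is shaped by f^(−1/2) (power slope −1) and
  renormalized to a per-channel standard deviation `noise_sd` (default 4 µV).
  The DC component is zeroed.
* **Alpha rhythm.** A single sinusoid at `alpha_freq` (default 10 Hz, bounded
  to 8–12 Hz) with a fixed occipital-dominant topography (weight 1.0 at
  O1/O2, decaying to 0.1 frontally) and random phase. The occipital peak
  amplitude defaults to 14 µV: with the topography's mean squared weight
  (~0.29) and the A²/2 sinusoid power law, the channel-mean 8–12 Hz band
  power lands near 29 µV², the scale of the study conditions being emulated.
* **Sensorimotor mu rhythm.** Sinusoids of amplitude `mu_amp` (6 µV) at the
  alpha frequency on C3 and C4 with independent phases. During imagery the
  envelope on the channel *contralateral* to the imagined hand is multiplied
  by (1 − `erd_depth`), the event-related desynchronization. Power therefore
  attenuates by (1 − d)², which the spectral tests verify directly.
* **P300.** Target flashes add a half-sine deflection of 300 ms width whose
  peak sits `p3_latency` (300 ms) after flash onset, with amplitude `p3_amp`
  (5 µV) at Pz and a parieto-central topography.

Protocol timing is hard-wired to the emulated design: MI calibration is 18
alternating left/right selections (12 s imagery + 6 s break; alternation
starts left), P300 calibration is 9 selections (each grid box once as
target), each a schedule of 15 random permutation rounds over the 9 boxes at
175 ms stimulus-onset asynchrony (100 ms flash + 75 ms pause) followed by a
2 s pause. All generators are bit-reproducible: every operation draws from
`default_rng([seed, stream...])` with a fixed stream id.

The simulator does **not** model blinks, cable or movement artifacts, channel
dropout, visual evoked responses to the game animation, inter-channel
coherence structure beyond the rank-1 sources, or non-stationarity. Passing
pipelines here demonstrates correctness of the computational chain and
recoverability of planted effects — not expected performance on recorded
children's EEG, which is dominated by exactly the nuisance structure the
simulator omits.

## Decoding pipelines

**MI.** Causal 5th-order Butterworth band-pass 5–30 Hz; each 12 s trial cut
into six non-overlapping 2 s windows (108 training windows); per-window
spatial covariance (mean-centered sample estimate with a 1e-8-of-trace
diagonal loading floor to guarantee SPD); tangent-space mapping at the
Riemannian (Karcher) mean of the training covariances; L2-regularized
logistic regression (deterministic lbfgs, tol 1e-8, C = 1). The online
feedback classifier is refit from scratch after every two selections; the
interim models are exposed as a feedback trace while the final decoder uses
all selections. Filtering is forward-only so offline behavior matches what an
online decoder would see.

**P300.** Causal Butterworth 0.1–15 Hz applied to the continuous recording
*before* epoching (epoch-wise filtering of 600 ms windows with a 0.1 Hz
corner is dominated by edge transients, so the order of operations was
flipped); 600 ms post-onset windows per flash (windows overlap since
600 ms > 175 ms SOA); the 15 windows per box per selection ensemble-averaged
to one window (81 windows, 9 targets); XDawn spatial filters (top 4
generalized eigenvectors of evoked vs total energy); each window row-stacked
with the filtered evoked template and summarized by its covariance;
tangent-space mapping; shrinkage LDA (pooled covariance shrunk toward the
scaled identity, analytic Ledoit–Wolf intensity by default, overridable).
Posteriors use a logistic link on the LDA score.

The XDawn-augmented covariance is estimated with Ledoit–Wolf shrinkage
rather than the raw sample estimate: a 600 ms window band-limited to 15 Hz
holds roughly 18 effective temporal degrees of freedom against 23 augmented
channels, so the sample covariance is rank-deficient and its near-null
eigenvalues are noise; shrinkage keeps the matrices well-conditioned and the
manifold spread bounded. This is the standard covariance treatment in
ERP-covariance pipelines.

**Karcher mean.** The tangent-mean fixed point is iterated with an Armijo
backtracking line search on the Karcher cost (sum of squared affine-invariant
distances). The cost is geodesically convex, so enforced descent makes the
iteration globally convergent; the classical unit step was observed to enter
limit cycles on widely spread inputs. Convergence is declared when the mean
log-map norm falls below 1e-8 (`spd_mean` default; the tangent-space
transformer uses 1e-6 for its reference, far below feature noise), and
non-convergence raises an error naming the iteration budget (300).

**Selection logic.** MI: classifier outputs on consecutive 2 s windows feed a
signed accumulator (+1 right / −1 left); a selection requires |net| = 4, so
opposite outputs must be compensated; an exhausted stream (default timeout 60
windows) is an explicit *no-selection* outcome counted as incorrect in game
performance. P300: the nine ensemble-averaged windows are scored by the
binary classifier and a softmax over the nine target scores yields the
posterior vector; the argmax wins, ties break to the lowest box index. Game
performance is correct/total; chance is 50% for MI and 1/9 (~11%) for the
grid.

**Cross-validated metrics.** Stratified 5-fold (seeded) accuracy, precision
(TP/(TP+FP)), recall (TP/(TP+FN)), and a pooled validation confusion matrix;
the P300 positive class is "target".

## Fatigue biomarker

Channels with impedance strictly above 5 MΩ are dropped. The resting PSD is
Welch's method with 10 s Hann windows, 5 s overlap, per-segment mean
detrending, one-sided density scaling; band power is the trapezoidal 8–12 Hz
integral per channel (band edges interpolated, making the integral additive
over sub-bands). The session aggregate is the mean over retained channels
(configurable to a posterior subset — T5/P3/Pz/P4/T6/O1/O2 — since the
emulated protocol does not pin down the channel set). Aggregates above 99 are
excluded at the session level with reason `alpha>99`; an excluded phase makes
the pre/post change missing (NaN), never zero. A single-segment full-window
periodogram is also exposed: over 120 s its grid spacing is 1/120 ≈ 0.0083 Hz,
below the 0.01 Hz resolution figure the Welch default cannot reach (a 10 s
segment gives 0.1 Hz); Welch remains the primary band-power estimator.

A note on units: integrating a µV²/Hz density over a band yields µV², but
band power is conventionally *reported* under the density's µV²/Hz label;
the code computes the true integral and carries the reporting label.

## Statistics

* **Reliability.** Difference-score method: SEM = SD(test − retest)/√2,
  MDC95 = 1.96·√2·SEM (≈ 2.77·SEM). An SEM of 5.0 gives MDC95 ≈ 13.86.
* **Repeated-measures correlation.** ANCOVA formulation (participant factor,
  shared slope) computed from within-participant centered sums of squares;
  r carries the slope sign, dof = N_obs − N_participants − 1; verified to
  1e-8 against a dummy-coded least-squares oracle and cross-checked against
  an independent implementation. Participants with fewer than two complete
  pairs are dropped with a logged warning.
* **Mixed models.** REML linear mixed models (statsmodels MixedLM) with
  participant random intercepts; primary model session × time (pre/post),
  with pre/post anchored at "pre" so the time coefficient is the pre-to-post
  shift. Omnibus F per fixed term is the Wald chi-square over its
  coefficients divided by its numerator dof, referred to an
  F(q, N − rank − groups + 1) distribution; estimated marginal means are
  model predictions per factor cell averaged over the reference grid, with
  normal-theory 95% CIs; pairwise cell contrasts are Holm-corrected. AIC is
  −2·llf + 2·(fixed + 2 variance parameters) from the REML likelihood. The
  optimizer retries lbfgs → cg → powell before declaring a singular design.
* **Composites.** Motivation (0–50) split lower/higher at 36 (the 26–35 vs
  36–45 grouping); workload (0–100, performance item excluded upstream) into
  quartile bins 0–24/25–49/50–74/75–100; discomfort 0–2 vs 3–5; age split at
  the cohort's median date of birth.

## Cohort generator and the end-to-end study

`gen_cohort` draws, per participant, random intercepts for VASF
(SD 1.5) and alpha power (SD 12), session-level residuals (SD 0.8 and 6),
pre means 3.4 (VASF) and 29.4 (alpha), and common pre-to-post shifts of 1.2
VASF points and 2.8 µV² — the cell means of the emulated conditions. VASF is
truncated to [0, 10] and rounded to 0.1 (the scale's granularity is a design
choice); session order follows a cycled Latin square.

`run_study` plays the whole protocol per participant: pre-rest → calibration
→ game trials → post-rest for the two BCI sessions, rest-only for video.
Each session's resting alpha amplitude is scaled to the cohort draw
(√ of the power ratio), so measured band powers inherit the intercepts and
shift; this is what makes the downstream alpha mixed model identifiable.
Default game-trial counts per session (10 MI, 6 P300) keep a full simulated
study at desk scale; they are configuration knobs, not protocol constants.

Parameter-recovery experiments (the ±0.1 recovery of a 1.2-point shift at 200
participants) use reduced VASF spread (between-SD 0.8, residual SD 0.4):
with the default spread ~2% of pre-task scores hit the scale floor and the
truncation attenuates the recovered shift by about 0.1. The generator's
defaults are unchanged; the low-noise setting is the stated condition of the
recovery check.

## Known limitations

* The Karcher-mean tolerance is bounded below by floating-point error on
  badly conditioned covariance stacks (~1e-9 observed); requesting tighter
  tolerances on such inputs raises the non-convergence error by design.
* EDF storage is 16-bit with per-channel symmetric physical ranges, so
  round-trips are exact only to one quantization step (range/65535).
* The mixed-model denominator dof is a residual-style approximation, not a
  Satterthwaite/Kenward–Roger correction; F statistics on small cohorts are
  accordingly approximate.
* Binary classifiers only (left/right, target/non-target); the 9-way P300
  decision is a comparison of binary scores, matching the emulated design.
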