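# Methods

This note documents the models and procedures implemented in `oculocog`,
the defaults they use, and what the synthetic data can and cannot show.

## Scope and data model

The pipeline targets a three-group design — young adults (reference),
healthy elderly controls, and MCI patients — measured with four oculomotor
paradigms (60 Hz monocular gaze in degrees of visual angle, screen-centre
origin) and two cognitive tests.  Every analysis consumes the canonical
participant representation: a 39-vector of 31 eye-movement features
followed by 8 behavioral features, in a fixed documented order.  The order
matters because the CNN's kernel-2 convolution couples adjacent entries;
it is part of the model definition, not a presentation choice.

## Synthetic cohorts

The generator (`simulate.py`, parameters in `profiles.py`) emulates:

* **Saccades** as minimum-jerk displacements whose duration follows a
  main-sequence rule, duration ≈ 20 ms + 2 ms/deg × amplitude, floored at
  two samples.  Latencies are Gaussian per trial (group mean ± SD).
  Anti-saccade errors (probability `anti_error_rate`) first go to the cue
  and are corrected ~120 ms later.
* **Smooth pursuit** as the target sinusoid delayed by `pursuit_delay`
  and scaled by `pursuit_gain`, plus Poisson catch-up saccades (rate
  `catchup_rate`) that close the instantaneous positional error whenever
  it exceeds 0.3°.  Injected catch-up amplitudes are retained as ground
  truth.
* **Memory-guided saccades** launched after the central cross disappears,
  scaled by a per-trial memory gain; a fraction `memory_fail_rate` of
  trials produce no response.
* **Predictive saccades**: each step after the first is anticipated with
  probability `predictive_anticipation` (latency = −|N(lead, sd)|,
  lead defaulting to 120–150 ms) and reactive otherwise.  The first step
  of a trial is always reactive, since its direction is unknowable.
* **Fixational noise** as white Gaussian position noise (SD
  `fixation_noise_sd`), and **blinks** as Poisson-scheduled invalid gaps
  of 0.1–0.2 s.
* **Behavior**: span-task success at list length L follows a logistic in
  (ability − L) with scale 0.6, thinned by a lapse rate; Stroop RT is a
  base plus an interference term on incongruent trials plus half-normal
  noise.

Group defaults encode the intended contrast structure: young adults beat
elderly participants by ≥ 1 between-subject SD on latency-, gain- and
variability-type parameters; the MCI profile differs from controls by a
*small correlated* oculomotor shift — a single latent severity factor
(lognormal, σ = 0.35 per individual) scales a fixed vector of per-parameter
deltas, each ≈ 0.2 between-subject SD — plus a working-memory deficit
concentrated on the backward digit span (≈ 0.7 SD).  Between-subject
jitter is ~10% CV on scale parameters.  The correlated-shift construction
is deliberate: it makes each eye feature individually weak but the
multivariate pattern informative, which is the regime in which fusing
modalities helps.  `scaled_mci_profile(severity)` scales the whole delta
vector for effect-size experiments.

These defaults are documented simulation assumptions, not estimates of any
real cohort.  The generator does not emulate pupil dynamics,
microsaccades, instrument-specific noise spectra, calibration drift, or
MCI subtypes; conclusions from passing tests are about the pipeline's
correctness and the qualitative group structure, not about clinical
performance.

## Event detection and features

Preprocessing interpolates invalid gaps ≤ 75 ms linearly (flagged),
excludes longer gaps, and marks trials with < 50% valid samples unusable.
A Savitzky–Golay filter (window 5, order 2) smooths the positions used for
spatial summaries.  **Event timing deliberately bypasses the smoother**:
at 60 Hz its side-lobes spread saccade energy ~3 samples backwards, which
biases latencies early; detection velocity is therefore the central
difference of the unsmoothed (gap-interpolated) trace.  Samples within
±1 sample of an excluded region get no velocity.

Saccades are maximal runs of speed > 30°/s lasting ≥ 2 samples.  The
onset is the first suprathreshold sample — the central difference reacts
one sample ahead of motion, which cancels the half-sample quantisation of
the true onset, so onsets are unbiased to within ~±⅓ sample — and the
offset is refined forward to the local velocity minimum above a floor of
threshold/3.  Displacements are measured across one flanking sample on
each side so the sub-threshold minimum-jerk tails are not clipped;
without this, gains read ~3% low.  Fixation epochs are the ≥ 100 ms
complements; dispersion is the RMS distance from the centroid.

Feature definitions follow the conventional readings: latency relative to
target (or cross-offset / step) onset; gain as displacement projected on
the instructed axis over eccentricity (20° full step for the predictive
task); pursuit delay as the correlation-maximising lag on a one-sample
grid in [0, 0.5] s; pursuit "variance" as the variance of the
delay-compensated positional error along the motion axis (deg²);
predictive "variance" as the variance of step latencies (s²); saccade
compensation as summed catch-up amplitude along the motion axis over the
target path length.  A 2° amplitude floor separates response saccades from
fixational noise.  Trials without a scorable response are dropped from
their averages; a feature with no usable trials is missing (NaN) and is
median-imputed within training folds downstream.

The adaptive span run starts at length 3, repeats the length after an
error, increments after a success, and stops at three consecutive errors
or a success at the ceiling (8 visuospatial / 9 digit); the score is one
point per correct trial.  Stroop accuracy uses all trials, RT only correct
trials, per congruency.

## Classifier and training

The CNN is conv(1→16) → ReLU → pool → conv(16→32) → ReLU → pool → flatten
→ FC(4096) → ReLU → dropout(0.5) → FC(256) → ReLU → dropout(0.5) →
FC(n_classes).  Kernel 2 with stride 1 and one zero padded *at the end*
keeps the sequence length; pooling is non-overlapping max with size 2 and
floor length.  Under these choices 39 → 19 → 9, flattened width 288.
Training: softmax cross-entropy, Adam (lr 10⁻³, β₁ 0.9, β₂ 0.999),
batch 16, 100 epochs by default, learning rate ×0.9 after every 10 epochs
("reduced by 10%" read literally as a 0.9 multiplier, not a reset to 10%).
Dropout rate, epoch count, batch size and pooling size are package
defaults where the protocol leaves them open.  Initialisation is
uniform ±1/√fan_in; parameters train in float32; all randomness
(init, shuffling, dropout) comes from one seeded generator, so runs are
bit-reproducible on a platform.  Backprop is validated against central
finite differences (rel. tol. 10⁻⁴) in the tests.  The FCNN ablation is
the identical FC head applied directly to the input; SVM (RBF, with
probability estimates) and Random Forest baselines run at scikit-learn
defaults.

## Evaluation protocol

Ten repeated stratified 8:2 holdout splits per task (stratification avoids
losing the 40-of-128 MCI class from small folds; it can be disabled).
Per split: fit the normaliser (training-fold median imputation + z-score
with a 10⁻⁸ scale floor) on the training rows, train the model with a
split-specific seed, and score the test fold.  Accuracy satisfies
accuracy = Σ_c hit_rate_c · n_c / N on every fold by construction, and the
tests assert it.  Binary AUC is reported both pooled across the ten test
folds (headline) and as the per-repeat mean; pooling is the default
because per-fold AUCs at n ≈ 20 are noisy.  The Welch screen reports raw
p-values by default (Benjamini–Hochberg available) for young vs pooled
elderly and control vs MCI, per feature.  Chance levels in the tests are
binomial bands around the majority-class rate rather than a fixed 1/k, to
respect class imbalance.

## Problem sizes used in the checks

The test suite and acceptance script favour fixed, documented problem
sizes: the full default cohort (31/57/40) for group-structure and
classification checks; 10 CNN training repeats at 100 epochs in the
acceptance script; reduced 25-epoch trainings, 16–24 participants per
group, 3 seeds × 3 severity levels for the effect-size monotonicity check,
and 20 single-split schemes for the modality-fusion check.  These sizes
give stable qualitative outcomes while keeping the whole suite
desk-runnable; rerunning with larger cohorts or more repeats only
sharpens the same comparisons.

## Known limitations

* 60 Hz sampling makes saccade kinematics coarse: durations of small
  saccades span 2–3 samples, so peak velocities are underestimated and
  catch-up saccades below ~0.7° can escape detection; saccade
  compensation is accordingly a lower bound.
* The pursuit delay estimator returns non-negative lags on a one-sample
  (16.7 ms) grid; true delays below half a sample round to zero.
* Pursuit "variance" conflates gain shortfall with tracking noise; this
  matches the feature's role as an overall tracking-quality index but
  does not isolate either cause.
* The adaptive span design implements one trial per length with
  repeat-on-error; other clinically used designs (two trials per length,
  length decrements) would shift the score scale.
* Synthetic cohorts cannot validate clinical accuracy; they validate the
  machinery and the qualitative claim that fused modalities dominate
  single ones when both carry independent signal.
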