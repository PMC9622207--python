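# Methods

`crisispredict` turns high-resolution bedside neuromonitoring of severe
traumatic brain injury — intracranial pressure (ICP) and brain tissue oxygen
tension (PbtO2), both in mmHg — into an early-warning problem: estimate, at
each monitored moment, the probability that a crisis *begins* within the next
30 minutes. This note records the model, its assumptions, the tunable
parameters, and the design choices made where more than one reading was
defensible.

## Crisis definitions and event states

A crisis is a sustained threshold violation:

* **ICP crisis** — ICP >= 20 mmHg for strictly more than 5 min;
* **PbtO2 crisis** — PbtO2 <= 20 mmHg for strictly more than 5 min.

Comparisons are inclusive at the threshold and the duration rule is strict: a
run lasting exactly 5 min is not an event. Each sample stands for its
following sampling interval, so a run of *n* samples at interval *dt* lasts
*n·dt* minutes. Missing samples and timestamp gaps break a run — a gap is
never assumed supra-threshold, and no imputation is performed anywhere.

Each sample carries one of four states: **A** (no crisis), **B** (ICP crisis
only), **C** (PbtO2 crisis only), **D** (both). For the ICP prediction task
the at-risk states are A and C — a sample already inside an ICP crisis cannot
begin a new one, so B/D samples are discarded as predictor rows; for the
PbtO2 task the at-risk states are A and B. We read the discard rule as
removing only in-crisis spans: after a crisis ends the patient re-enters the
at-risk pool with the episode number (the 1-based count of at-risk intervals)
incremented. The stricter alternative — censoring the whole record after the
first transition — is available via `censor_after_first_event=True`; under
that reading episode numbers could never grow, which is why resumption is the
default.

## Discrete-time survival structure

Training records are tiled into 30-min blocks anchored at each record's first
timestamp (no wall-clock alignment is assumed). The *last observation* of a
block is its representative; the block contributes a training row iff that
observation is retained by the at-risk filter, and the label says whether a
crisis of the task's type starts within the next block. The final block, and
any block whose successor holds neither data nor an onset, is right-censored
and contributes nothing. Test records are not blocked: every retained sample
with a full 30-min history and an observable 30-min outcome window is an
evaluation row. Using the block's last observation (rather than the last
*retained* observation) as representative makes the training label exactly a
30-min-horizon label at the representative time, which is what the test-time
rows use too; it also means a block whose tail is in-crisis is dropped
entirely, matching the at-risk semantics.

The 70/30 train/test split is at the patient level, stratified on an
ever-event indicator, so no patient contributes rows to both sides. An
observation-level split would mix a patient's own future into training;
patient-level is the conservative default.

## Features

Three nested tiers over the task's own signal (ICP features for the ICP
task), computed on the half-open 30-min window ending at, and including, the
observation:

1. **tier 1** — last value (mmHg) and episode number;
2. **tier 2** — adds mean, median, sample SD (n−1), min, max, last−first,
   last−second-to-last, and trapezoidal AUC on actual timestamps (mmHg·min);
3. **tier 3** — adds the log10–log10 OLS slope of the plain (boxcar,
   mean-removed) periodogram over positive-power non-zero frequencies, the
   spectral-spread variance (variance of frequency under the unit-normalized
   spectrum, in (cycles/min)²), and approximate entropy
   ApEn(m=2, r=0.2·SD(window)).

Choices worth stating:

* 30 samples leave no room for Welch segment averaging, hence the plain
  periodogram. Its per-window log-log slope has a small negative
  finite-sample bias (the log of a chi-square is skewed, and the one-sided
  Nyquist bin carries half the density); the tests therefore check flatness
  of the *averaged* white-noise spectrum and check the per-window estimator
  against an independent direct-summation DFT oracle rather than against 0.
* "Variance of the power-spectrum distribution" is implemented as spectral
  spread; `variance_mode="power"` (variance of the raw power values) is the
  documented alternative.
* ApEn uses the Pincus definition with self-matches, Chebyshev distance, and
  a relative tolerance on the *sample* SD (matching the tier-2 SD
  definition); a constant window has ApEn 0 by convention.
* Trend features tolerate windows with interior gaps (>= 2 usable samples);
  frequency features require a gap-free, evenly sampled window and are
  otherwise missing. Rows whose 30-min history extends past the start of the
  record are dropped for tiers 2–3.

## Models

`CrisisRiskClassifier` wraps three families behind one sklearn-style
estimator: plain logistic regression (`lr`), elastic-net logistic regression
(`en`, saga solver), and a random forest (`rf`). Hyperparameters are chosen
by cross-validated AUROC with `StratifiedGroupKFold` folds grouped by patient
(5 by default, reduced automatically when fewer patients are available;
folds whose training part lacks a class are dropped; a single-class
validation fold scores the chance value 0.5). The winner is refit on all
training rows. LR/EN features are standardized on the training set inside
the fitted pipeline; the forest sees raw features. No class reweighting is
applied by default (`class_weight` is exposed).

Default grids: EN mixes l1_ratio ∈ {0.1, …, 0.9} with penalty strength
C ∈ {0.01, 0.1, 1, 10}; RF searches n_estimators ∈ {200, 500} and
max_depth ∈ {3, 5, None} with the standard `sqrt` features-per-split default
(adding `None` to the feature grid roughly quadruples search cost on a
desk-scale cohort and rarely wins with ~10 correlated features; it remains
one `param_grid` line away).

Variable importance: absolute standardized coefficients for LR/EN;
permutation importance (mean AUROC drop over 10 seeded shuffles, negatives
clipped) for RF; both sum-normalized to 1.

## Evaluation

AUROC is pairwise concordance with ties counted ½. The default confidence
interval is a patient-level bootstrap (B = 1000, percentile limits), which
respects the strong within-patient correlation of dense test rows; the
DeLong asymptotic interval is available, and model comparison uses the
paired DeLong test for correlated ROC curves (implemented from the
structural-components formulas; no pre-installed package provides it).

Decision-curve analysis reports the net benefit NB(t) = TP/N − FP/N·t/(1−t)
of alerting at risk >= t on a grid of thresholds (0.01–0.99, step 0.01, with
the 20–80 % span the clinically discussed range), against alert-all and
no-alert policies. Following the study design the curve is computed on a
sample with equal outcome proportions; balancing sets the prevalence to 0.5
and therefore shifts both the reference curves and the operating region of a
model whose risks are calibrated to the rare-event training distribution —
such a model under-alerts at low thresholds on the balanced sample. The
unbalanced-sample DCA is a flag away and always prints its prevalence.

## Synthetic cohort generator

The restricted trial data cannot be redistributed, so a seeded generator
defines the study conditions end-to-end, with known ground truth.

Per patient: a baseline is drawn (ICP ~ N(14, 3²) mmHg, PbtO2 ~ N(28, 4²)
mmHg) and the ambient signal follows a discretized Ornstein–Uhlenbeck
process around it (reversion 0.1 /min, innovation SD 1.0 mmHg·min^−½,
started from its stationary law; stationary SD ≈ 2.3 mmHg). At every 30-min
block boundary a crisis onset fires per modality with probability

    logistic( −3.0 + 0.25·(level − 20) + 3.0·slope )      [ICP]
    logistic( −3.0 + 0.25·(20 − level) − 3.0·slope )      [PbtO2]

where *level* is the emitted signal at the last pre-boundary sample and
*slope* the (last − first)/duration trend of the preceding 30-min window in
mmHg/min — the same quantities the tier-1/2 features measure, which is what
makes prediction learnable by construction. A fired onset superimposes a
5-min linear ramp to threshold ± 4 mmHg, a plateau of lognormal duration
(median 15 min, σ = 0.5, floored so the violation exceeds 5 min), and a ramp
back; the modality's hazard is suppressed while its excursion is active.
These rates give on the order of one to two crises per patient per day and
roughly 80–90 % of patients at least one crisis over a three-day record —
an event-rich severe-TBI-like cohort.

Ground truth records each injected crisis as the maximal violating run of
the *emitted* signal containing its plateau, so a run detector recovers
onsets exactly; two excursions bridged by ambient noise into one run are
recorded once. Because patient baselines spread 3 mmHg around 14, patients
with high baselines also produce *ambient* sustained crossings that are
genuine crises under the threshold rule but are not governed by the logistic
hazard; they are intentionally left in (heterogeneous event burden is a real
feature of such cohorts) and the recovery tests verify any non-injected
detection against the brute-force run scanner. ICP→PbtO2 coupling and
monitoring-gap injection exist behind config switches and default to off.

The native sampling rate of such archives is not standardized; the canonical
interval here is 1 min (configurable), so a 30-min window is 30 samples.

What the generator does *not* emulate: pulse/respiratory waveform
morphology, artifacts (drain opening, transducer re-zeroing), treatment
feedback (interventions that abort incipient crises), circadian structure,
and informative missingness. Passing tests therefore demonstrate the
pipeline's correctness and the learnability of a hazard of this form — not
clinical performance on trial data.

## Verification experiments and problem sizes

* **Hazard-coefficient recovery.** Tier-1 logistic regression on blocked
  rows is exactly the generative model when the hazard's slope term is
  switched off, so the recovery experiment uses 20 replicates of 500
  patients × 72 h with `hazard_slope_coef = 0`, baseline SD tightened to 1.5
  and innovation SD to 0.3 so ambient crossings (which add level-dependent
  events outside the logistic hazard) stay a negligible fraction; the Wald
  95 % interval for the level coefficient must cover the generating value in
  ≥ 90 % of replicates.
* **Discrimination.** On the canonical 100-patient cohort, tier-2 LR and RF
  reach held-out AUROC ≈ 0.85 with patient-bootstrap CIs excluding 0.5
  (elastic net checked on a 25-patient training subset; dense evaluation on
  15 test patients, ~60k rows — sizes chosen to keep the default test run
  desk-scale).
* **Determinism.** The full pipeline run twice at one seed must produce
  byte-identical metrics JSON; the end-to-end check uses 20 patients × 48 h
  with all tiers and families.
* Event detection, blocking/labeling, every feature, AUROC and the DeLong
  statistic are each checked against independent brute-force oracles
  (exhaustive run scans, double-loop ApEn, direct-summation DFT, explicit
  pairwise concordance and covariance formulas).

## Reproducibility

All randomness flows from explicit seeds. A pipeline run derives four stage
seeds (simulate / split / model / evaluate) from the root seed via
`numpy.random.SeedSequence`, and the generator spawns one independent child
stream per patient, so cohorts are bitwise reproducible and insensitive to
patient order. The run manifest snapshots the configuration, the seeds and a
SHA-256 hash of every artifact.

## Known limitations

* Evaluation rows overlap heavily in time (dense 30-min windows), which is
  why only patient-level resampling is offered for CIs.
* Risk calibration is not modeled; AUROC and net benefit are computed on raw
  predicted probabilities.
* Competing risks (the other modality's crisis, death, monitor removal) are
  treated as simple censoring.
* The balanced-sample DCA inherits the calibration caveat above; both DCA
  variants are reported with their prevalence for that reason.
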