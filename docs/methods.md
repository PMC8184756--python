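# Methods

This note documents the models implemented in `pebga`, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical conventions that matter for reproducing results.

## Behavioral task

A session interleaves 4 pairs of abstract cues — 2 reward pairs (+1€ / 0€)
and 2 punishment pairs (−1€ / 0€) — each presented 24 times (96 trials).
Within a pair the two cues deliver the non-zero outcome with reciprocal
probabilities 0.75/0.25; "correct" means choosing the cue with the better
expected value (more rewarding, or less punishing). Schedules draw both
cues' counterfactual outcomes up front, so replaying an agent against a
schedule is deterministic. A patient performs `n_sessions` (default 3,
range 3–6) sessions with fresh cues each.

## Learning models

**QL.** Values start at 0 € for all cues. After each outcome the chosen
cue's value is updated `Q ← Q + α·δ` with prediction error `δ = R − Q`,
α ∈ [0, 1]. Choice follows a softmax with inverse temperature β.

**QLr.** Adds a repetition bias θ inside the softmax to the cue chosen at
the *previous presentation of the same pair* (per-pair memory, not global
last trial). QL is exactly QLr with θ = 0 — the models are nested, and the
test suite asserts likelihood equality at θ = 0.

**Softmax convention.** The default is multiplicative,
`p(a) ∝ exp(β·(Q_a + θ·rep_a))`, under which β is an inverse temperature and
the published group means (α = 0.26, β = 3.19, θ = 0.44, exposed as
`TABLE1_QLR`) reproduce ~71–75 % correct performance. A divisive variant
`p(a) ∝ exp((Q_a + θ·rep_a)/β)` is available via `convention="divisive"` for
comparison with formulations that treat β as a temperature; with β ≈ 3 it
produces near-random choices and is not the default.

**Fitting.** Bounded multi-start maximum likelihood: `n_starts` (default 20)
uniform draws inside α ∈ [0, 1], β ∈ [0.05, 20], θ ∈ [−2, 2], each refined
with L-BFGS-B; the per-trial likelihood is floored at 1e−12 so the objective
stays finite. BIC = ln(n_trials)·k + 2·NLL (k = 2 for QL, 3 for QLr); model
comparison is a two-sided paired t-test on per-patient BIC differences.

**Identifiability.** At the study's trial counts, α and θ recover well.
β sits on a likelihood ridge whenever choices saturate (a near-deterministic
agent is equally well described by any large β), so individual β estimates
can run to the bound; group medians recover the generating value, but
per-subject linear correlation of β is limited. The recovery test therefore
holds α/θ to a Pearson correlation and β to a rank correlation, at the
task's maximal session count.

**Regressors.** The fitted QLr model is replayed over the observed choices;
per trial it yields PE (δ), outcome R, and pre-update expectation Q of the
chosen cue. PE collapsed across conditions is z-scored across all of a
patient's trials; condition-specific regressors (RPE/PPE, R/P, Q_r/Q_p) are
z-scored within condition — the within-patient normalization scope is not
further specified in the source analysis, and within-condition scaling keeps
the two-regressor decomposition comparable between conditions. A z-scored
within-session trial-index covariate is available for the learning-phase
control.

## Synthetic iEEG generator

Each recording site is a two-contact shaft. Both contacts receive a common
"distant" 1/f source (cancels under bipolar derivation) and independent 1/f
plus white noise; the deeper contact additionally carries local band-limited
noise carriers (γ 50–150 Hz, β 13–33 Hz, θα 4–13 Hz). The γ carrier's
amplitude is multiplied, inside the response window (default 0.25–1.0 s
after outcome onset, 100-ms cosine-smoothed edges, floored at 0.05), by
`1 + gain_R·R_z + gain_Qr·Q_z` on reward trials and the P/Q_p analogue on
punishment trials. An optional pre-outcome gain modulates the carrier by the
expectation regressor in −1.2 to −0.2 s, and an optional (early, late) θα
profile plants low-frequency PE structure; both default to off, so by
default *only* broadband gamma carries PE information — the condition under
which the band model comparison should select the γ-only model.

Default gain table: vmPFC/lOFC get (gain_R, gain_Qr) = (+0.30, −0.30) and
(+0.12, −0.12) for punishment; aINS/dlPFC the mirror image; HPC/lVC/cmVC
weak symmetric PE (±0.15); mITC outcome-only (+0.15, 0). Signs implement the
+outcome/−expectation coding observed empirically. Gain magnitudes and the
noise budget (NoiseConfig: χ = 1 pink background 25 µV per contact, 40 µV
shared, 4 µV white, carriers 7/10/15 µV) were tuned once so that a single
site at ~200 trials yields PE regression |t| of order 3–9, matching the
per-site effect sizes typical of real recordings; they are fixed defaults,
not per-run knobs.

Event timing: the outcome appears 1.25 s after the (lognormal) response —
250 ms choice highlight plus a 1-s delay — and consecutive outcomes are
spaced ≈ 6 s, enough for every outcome-locked epoch and baseline to have
full support. Sampling rate defaults to 512 Hz; rates whose Nyquist falls
below the γ band edge (e.g. 256 Hz) are rejected, mirroring the exclusion of
too-slowly-sampled recordings.

What the generator does **not** emulate: epileptiform transients (beyond
what the 4-SD artifact test injects explicitly), volume conduction across
shafts, cross-site correlation of noise, electrode drift, or behavioral
lapses (the simulated agent is the model itself — its correct rate runs
~2–4 points above the human average, inside the acceptance tolerance).
Passing end-to-end tests therefore demonstrates correctness of the analysis
chain and calibration of its inference, not robustness to every artifact of
clinical data.

## Signal processing

- **Bipolar derivation**: adjacent contacts along each shaft, labelled
  `A1-A2`; single-contact shafts warn and yield nothing.
- **Stepped envelopes**: each band is split into sub-bands (γ: 10 × 10 Hz;
  β: 4 × 5 Hz; θ, α: 1-Hz steps; combined θα 4–13 Hz for the band-comparison
  features), each band-passed (4th-order zero-phase Butterworth — the
  filter family is a package choice), Hilbert-transformed, normalized to
  percent of its session mean, then averaged across sub-bands. The per-sub-
  band normalization undoes the 1/f amplitude tilt that would otherwise let
  the lowest sub-band dominate. The normalization also makes every envelope
  invariant to rescaling the raw signal. A `single` mode (one band-pass over
  the whole range) implements the simpler control variant; on modulated
  broadband input the two correlate > 0.95, on *stationary* noise they are
  two noisy estimators of a constant and correlate only ~0.87.
- **Smoothing/resampling**: 250-ms centered moving average (odd kernel
  length, edge-truncated and renormalized), then decimation to 64 Hz
  (15.625 ms). The boxcar itself is the anti-alias filter: at the 32-Hz
  output Nyquist it attenuates amplitude > 20-fold.
- **Epoching**: −3.0 to +1.5 s around outcome onset on the 64-Hz grid
  (289 samples, t = 0 on-grid; 97 samples in [0, 1.5 s]). Baseline z-scoring
  is per trial over the 6-s window centered on the outcome (−3 to +3 s) —
  implemented literally although it includes post-outcome samples, as
  specified — with a 500-ms pre-cue alternative (`prefix-500ms`).
- **Artifact rule**: a trial is rejected iff any raw sample magnitude
  *strictly* exceeds 4 × the site's full-session SD ("average signal" is
  read as the site's own session signal, not a cross-channel average).
- **Multitaper TFR**: 4–32 Hz with 6-cycle windows and 3 Slepian tapers;
  32–200 Hz with fixed 240-ms windows and a taper count rising linearly
  from 4 to 31 (rounded; the exact schedule is unstated in the source, and
  a ×1.5 half-bandwidth margin keeps all tapers above MNE's concentration
  cutoff).

## Statistics

- **Pointwise OLS** per time point with intercept; t and two-sided p per
  regressor; multi-regressor designs (outcome + expectation) and covariates
  supported. Betas for a z-scored single regressor reduce to x·y/n, which is
  what the permutation engine exploits.
- **Site-level FDR**: Benjamini–Hochberg at q = 0.05 over the 97 p-values in
  [0, 1.5 s] only; significant runs shorter than 100 ms (7 consecutive
  64-Hz samples) are discarded.
- **Parcel screening**: per-trial betas are window-averaged over 0.25–1 s
  *first*, then a one-sample two-sided t across the parcel's pooled sites
  (fixed effect), Bonferroni-corrected across the number of tested parcels;
  a parcel is selected iff corrected-significant *and* its proportion of
  FDR-significant sites strictly exceeds 20 %. Single-site parcels are
  excluded with a warning.
- **Cluster permutation**: observed statistic is the across-site one-sample
  t per time point; clusters are contiguous same-sign runs with two-sided
  pointwise p < 0.05 (ties at the threshold excluded); cluster mass is the
  summed t. The null shuffles the trial/regressor pairing independently per
  site — trials are not aligned across patients, so there is no common
  shuffle to preserve — and records the maximal absolute cluster mass per
  iteration; corrected p_c = (1 + r)/(1 + n_perm), so resolving
  p_c < 1 × 10⁻³ needs n_perm ≥ 999. The default n_perm is 60,000; shrinking
  it can only raise the attainable p_c floor. Positive and negative clusters
  are compared against the shared max-|mass| null, which controls the
  two-sided family-wise rate at the nominal level (verified by null
  simulation in the acceptance suite).
- **Condition contrast**: per-site β_RPE(t) (reward trials) and β_PPE(t)
  (punishment trials); their difference is cluster-tested with within-
  condition shuffles. Swapping condition labels flips the contrast exactly.
- **Outcome-by-phase control**: the model-free non-zero-vs-zero outcome
  contrast, window-averaged, per early/late session half, with a paired t
  for the phase interaction — stationary PE coding predicts no interaction.

## Frequency-band model comparison

Features per site and trial: γ and β power averaged over 0.25–1 s, θα power
over 0–0.5 s (early) and 0.5–1 s (late), each z-scored per site. The model
space is fixed at 8: the γ-only GLM plus γ combined with every non-empty
subset of {β, early θα, late θα} (the source text says "eight alternative
GLMs" but enumerates seven alternatives; the implemented space is the
enumeration plus γ-only, and is documented rather than guessed). Log model
evidence is the BIC approximation −BIC/2 under a Gaussian likelihood —
chosen over a variational linear-model evidence for reproducibility without
the original toolbox; the evidence backend is a single function
(`band_glm_evidence`) and can be swapped. Random-effects BMS uses the
standard variational Dirichlet fixed point (uniform prior α₀ = 1); Ef is the
posterior Dirichlet mean and Xp is estimated from 10⁵ seeded Dirichlet
draws. With ~16 sites the dominant model's Ef saturates at
(n + α₀)/(n + K·α₀) ≈ 0.7–0.9 rather than the ~1 reached with a thousand
sites; Xp still → 1, and Xp is the selection statistic.

## Scales used by the test and acceptance runs

Chosen as package defaults for the validation path: parameter recovery and
behavioral reproduction use 20 patients × 3 sessions; the end-to-end
dissociation run uses 4 patients × 2 sessions × 8 sites (one site per
parcel per patient, pooling 4 sites per parcel) at 512 Hz with 200
permutations and 16 sites entering the band comparison; the
cluster-permutation null calibration uses 100 datasets of 16 sites × 100
trials with 500 permutations. All sizes are configurable (`RunConfig`,
CLI flags), and every threshold and window appears in the emitted manifest.

## Known limitations

- The generator plants effects with a single response window per site;
  region-specific latencies (e.g. earlier insular, later orbitofrontal
  responses) are configurable but not defaulted.
- BIC evidence treats the band GLM residuals as Gaussian i.i.d.; it ranks
  nested linear models well but is not a full variational evidence.
- The divisive softmax variant is provided for completeness; parameter
  values fitted under one convention are not comparable to the other.
- Electrode localization is out of scope: parcel labels are taken as given
  channel metadata, and unmappable parcels are retained but flagged.
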