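# pebga

**P**rediction-**e**rror signals in intracerebral **b**road**b**and-**g**amma
**a**ctivity — a tested, reusable pipeline for model-based analysis of human
iEEG recorded during probabilistic reward/punishment learning, together with
a fully synthetic behavior + iEEG generator used to validate every stage.

## The scientific problem

During instrumental learning, choice values are updated in proportion to the
outcome prediction error (PE) — obtained minus expected outcome value,
δ = R − Q. Whether the brain computes reward PE (R − Q_r, did I get the euro
I expected?) and punishment PE (P − Q_p, did I avoid the loss I feared?) in
the same regions is a long-standing question that fMRI answers poorly, for
reasons of temporal resolution. Intracerebral EEG resolves it: broadband
gamma activity (BGA, 50–150 Hz) tracks local spiking, and trial-wise
regression of BGA on model-derived PE can separate the outcome (+R) and
expectation (−Q) components and compare reward- vs punishment-learning
sensitivity across regions (ventromedial prefrontal and lateral orbitofrontal
cortex vs anterior insula and dorsolateral prefrontal cortex).

`pebga` implements that whole analysis chain for researchers who want to run
it on their own recordings, or to study its statistical behavior on synthetic
data with known ground truth:

1. **Behavior** (`pebga.task`, `pebga.behavior`) — the probabilistic learning
   task (4 cue pairs × 24 presentations = 96 trials/session; reward pairs
   +1€/0, punishment pairs −1€/0, reciprocal 0.75/0.25 contingencies);
   Q-learning (QL) and Q-learning-with-repetition-bias (QLr) agents
   (Q ← Q + α·δ, softmax p ∝ exp(β·(Q + θ·rep))); multi-start
   maximum-likelihood fitting; BIC = ln(n)·k + 2·NLL model comparison; and
   the trial-wise regressors (PE, outcome, expectation, all z-scored).
2. **Synthetic iEEG** (`pebga.synth`, `pebga.edf`) — multichannel 1/f
   recordings whose band-limited amplitudes are modulated trial-by-trial by
   the outcome and expectation regressors with region-specific
   reward/punishment gains; EDF + BIDS-iEEG-style TSV round trip.
3. **Signal processing** (`pebga.preprocessing`) — bipolar re-referencing,
   stepped sub-band Hilbert envelopes (10 × 10 Hz for gamma), 250-ms
   smoothing, 64-Hz resampling (15.625-ms resolution), outcome-locked
   epoching (−3 to +1.5 s) with per-trial 6-s baseline z-scoring, 4-SD
   artifact-trial rejection, multitaper time–frequency maps.
4. **Statistics** (`pebga.glm`) — pointwise OLS of power on regressors;
   Benjamini–Hochberg FDR over the 97 in-window time points with a 100-ms
   minimum-duration rule; parcel-level fixed-effect screening (Bonferroni
   across parcels, >20 % significant-site rule); cluster-based permutation
   inference; reward-vs-punishment contrasts; outcome/expectation
   decomposition.
5. **Band comparison** (`pebga.bands`) — per-site GLMs predicting PE from
   band-power features (γ, β, early/late θα), BIC log evidence, and
   random-effects Bayesian model selection (expected frequencies Ef,
   exceedance probabilities Xp).
6. **Orchestration** (`pebga.pipeline`, `pebga.cli`) — one config, seeded and
   deterministic, with a `pebga` command-line entry point.

## Worked example

Simulate one patient (3 sessions) at the cohort group-mean parameters, fit
both learning models, and compare:

```python
import numpy as np
from pebga import (TABLE1_QLR, TaskConfig, simulate_patient, fit_patient,
                   performance_summary)

cfg = TaskConfig(n_sessions=3)
sessions = simulate_patient(TABLE1_QLR, cfg, np.random.default_rng(0))
perf = performance_summary(sessions)
print("correct rate: reward %.1f%%, punishment %.1f%%" % (
    100 * perf["correct_rate"]["reward"], 100 * perf["correct_rate"]["punishment"]))
ql = fit_patient(sessions, "QL", n_starts=10, rng=0)
qlr = fit_patient(sessions, "QLr", n_starts=10, rng=0)
print("QL : alpha=%.2f beta=%.2f            BIC=%.1f" % (ql.params.alpha, ql.params.beta, ql.bic))
print("QLr: alpha=%.2f beta=%.2f theta=%.2f BIC=%.1f" % (
    qlr.params.alpha, qlr.params.beta, qlr.params.theta, qlr.bic))
```

```
correct rate: reward 68.1%, punishment 72.9%
QL : alpha=0.25 beta=3.85            BIC=295.5
QLr: alpha=0.16 beta=3.85 theta=0.38 BIC=227.4
```

Both conditions are learned at ~70 % correct (chance is 50 %), and the
repetition-bias model wins the BIC comparison — the agent's perseveration is
real structure the plain QL model cannot absorb.

The full synthetic pipeline — continuous recordings, gamma envelopes,
regression, screening, contrasts, band comparison — runs from the shell:

```bash
pebga run-all --out demo --seed 20 --n-patients 4 --n-sites 8 --n-perm 200
```

```
reward-dominant: ['lOFC', 'vmPFC']
punishment-dominant: ['aINS', 'dlPFC']
band model: gamma (Xp=1.000)
```

The planted ground truth (reward gains dominant in vmPFC/lOFC, punishment
gains dominant in aINS/dlPFC, PE information only in the gamma band) is
recovered end to end; `demo/report.json` holds the parcel screening table,
contrast clusters, outcome/expectation decomposition and the BMS posterior.
A staged, file-based flow is also available (`pebga simulate`,
`fit-behavior`, `extract-bga`, `regress`, `contrast`, `band-compare`) so that
real data in the same EDF + TSV layout can enter at any stage boundary.

## Layout

```
src/pebga/        task, behavior, synth, edf, preprocessing, glm, bands,
                  pipeline, cli
tests/            unit + property tests, plus property-based acceptance suite
scripts/          acceptance.py
docs/methods.md   models, parameters, defaults, and known limitations
```
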