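# sacmem

A computational account of when retrieval practice helps — and when it
does not.  The *testing effect* (tested material is retained better than
restudied material) is robust on average, but its dependence on
working-memory (WM) capacity has been contested.  `sacmem` implements a
WM-limited spreading-activation memory model (SAC family) in which a
test trial is two sequential processes — a retrieval attempt and a
post-retrieval re-encoding of the retrieved information — both paid for
out of a limited, quickly-replenishing WM resource pool.  The model
predicts a three-way interaction: testing beats restudy whenever
capacity covers both processes, but for low-capacity learners working
with unfamiliar (low-frequency, WM-expensive) material the attempt
drains the pool, re-encoding is truncated, and testing can fall below
restudy.

The package is organised as an analysis project for researchers in
memory and learning: a library under `src/sacmem/` and narrative
drivers under `analysis/`.

## Model core

Node strengths follow a power law of learning and forgetting,
`B(t) = c (Σ_i Δ_i (t − t_i + 1)^{−d})^b`, calibrated so that three weeks
of 15:1 familiarization yields cue strengths 0.91 (HF) vs 0.46 (LF) at
the practice day.  Operations cost `κ/(1+B)` WM units; a retrieval
attempt additionally costs `WM_extra = w_e (1/B_cue + 1/B_target)`,
which buys no strengthening.  Episode activation `A` maps to accuracy
through `Φ((A − θ)/σ)`.  The free parameters `(w_e, θ, σ)` are fitted by
a 0.01-precision grid search on `w_e` with nested per-participant
`(θ, σ)` RMSE fits over the four frequency × condition cells.  The
behavioral stage scores WM capacity as the mean 2-/3-back
`d′ = Z_Hit − Z_FA` and fits random-intercept logistic mixed models
(in-package Gauss–Hermite estimator, cross-validated against lme4) with
simple slopes at WM mean ± 1 SD.  See `docs/methods.md`.

## Worked example

```sh
python analysis/01_generate_cohort.py --seed 1   # synthetic cohort
python analysis/02_behavioral_stats.py           # d' + mixed models
python analysis/03_simulate_model.py --seed 1    # SAC simulation
python analysis/04_fit_parameters.py --seed 1    # grid-search recovery
```

`03_simulate_model.py` prints, for a 30-participant cohort split at the
median d′:

```
familiarization anchors at practice-day start: HF 0.91, LF 0.46

testing effect (test - restudy), percentage points:
wm_group  frequency
high      HF           3.5
          LF           2.3
low       HF           2.7
          LF          -0.7
```

High-WM participants benefit from testing for both stimulus classes;
low-WM participants benefit only for the familiar (HF) class and show a
slightly negative effect for LF pairs — the signature interaction.
`04_fit_parameters.py` then demonstrates that the estimation machinery
identifies the generating parameters from such a cohort:

```
ground truth: w_e = 0.28, theta = 0.450, sigma = 0.100
recovered:    w_e = 0.28, theta = 0.450, sigma = 0.100
group RMSE at optimum: 1.29e-07 over 25 grid values, n = 30 participants
```

`02_behavioral_stats.py` fits the regression models on the synthetic
behavioral cohort; at n = 30 the LF testing-effect slope is reliably
positive at +1 SD of WM capacity (b ≈ 0.47, p ≈ 0.02) and negative but
non-significant at −1 SD, while the three-way coefficient carries the
generating sign.

A `sacmem` CLI (`generate`, `simulate`, `fit`, `analyze`, `reproduce`)
exposes the same stages for file-based use.

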