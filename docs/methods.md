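# Methods

## The model

`sacmem` implements a localist spreading-activation memory model (the SAC
family) extended with a working-memory (WM) resource economy, built to
explain when retrieval practice (testing) beats restudy and when it does
not.  Concepts (Fribble cues, target words, a session context) and
episodes (one node per learned cue–word–context binding) are nodes whose
base-level strength follows a power law of learning and forgetting:

    B(t) = floor + c · ( Σ_i Δ_i · (t − t_i + 1)^(−d) )^b

with event times `t_i` in hours, increments `Δ_i`, decay exponent
`d = 0.175`, compressive learning exponent `b`, and scale `c`.  The outer
exponent is essential: an additive event sum would force the strength
ratio of two items presented 15:1 to be 15:1, whereas three weeks of
familiarization at that presentation ratio must land on strengths of
roughly 2:1 (0.91 for high-frequency items vs 0.46 for low-frequency
ones).  The two anchors identify the two free constants exactly:
`b = ln(0.91/0.46)/ln 15 ≈ 0.2519` and `c ≈ 0.3384` given the nine-session
schedule (days 0, 2, 4, 7, 9, 11, 14, 16, 18; practice day 22);
`calibrate_strength_constants` recomputes both for any schedule.

Every memory operation draws on a limited per-participant WM pool.
Capacity is the participant's n-back d′ (affine map, identity by
default); the pool refills at 0.5 units/s, so it is always full at trial
onset (10-s trial spacing) and WM constrains processing *within* a trial
only.  Operation costs decrease with the familiarity of the material,

    cost = κ / (1 + familiarity),   κ = 1 by default,

so low-frequency cues are more expensive to encode and retrieve than
high-frequency ones.  A retrieval attempt additionally pays an extra,
non-strengthening cost (failed search paths, maintenance of the
retrieved trace):

    WM_extra = w_e · (1/B_cue + 1/B_target),

with `w_e` a free parameter.  A pool that cannot cover a request grants
what remains (`granted = min(request, available)`), and strengthening is
proportional to the fraction granted: `Δ = λ · granted/request` with a
single learning rate `λ = 1` shared by study encoding, the
activation-driven strengthening of a successful retrieval, and
post-retrieval re-encoding.

A test trial is two sequential processes.  The retrieval attempt charges
the retrieve cost plus `WM_extra` and succeeds with probability
`Φ((A − θ)/σ)`, where `A` is the episode's activation (base strength plus
a share `γ = 0.2` of cue and context activation, the context share
divided by its fan).  Only a successful attempt strengthens: the
retrieval itself (scaled by the attempt's granted fraction) and a
re-encoding of the retrieved information, which requests a fresh encode
cost against whatever the pool still holds.  No feedback is modelled, so
failed attempts strengthen nothing.  This yields the model's central
asymmetry: with ample capacity a successful test trial strengthens twice
as much as a restudy trial, but when attempt + extra costs drain the
pool, re-encoding is truncated and testing can fall below restudy —
which is exactly what happens for low-capacity participants on
low-frequency (expensive) material.

At final test, 24 h later, each pair's predicted accuracy is
`Φ((A − θ)/σ)`.  The three free parameters are `w_e` (group level) and
`(θ, σ)` (participant level).

## Protocol simulation

`familiarize` lays down 135 (HF) or 9 (LF) unit presentation events per
cue over the nine sessions.  Day-1 criterion learning is not simulated;
each episode is created at the practice-day refresh with one baseline
event (`Δ = 1`) plus a normally-charged refresh encoding, mirroring the
fact that all associations reached criterion the day before.  Practice
runs one seeded random permutation of the 64 pairs (16 per
frequency × condition cell).  The target word's familiarity is a fixed
0.91 (well-known vocabulary, comparable to a high-frequency cue); the
context node's strength is fixed at 1 and its spread divided by its fan
of 64, making it a negligible constant shift.

Two execution modes exist.  The stochastic mode samples practice success
Bernoulli-wise from the CDF rule.  The deterministic expected-value mode
("matched-success") carries both counterfactual branches of every test
trial — success and failure activations — and weights them by the success
probability, which may be the model's own CDF value or an observed
per-frequency practice accuracy.  Because the pool refills between
trials and episodes are pair-local, the branches never interact, so the
expectation is exact, and the fitting objective built on it is
deterministic.

## Fitting

Following the estimation design, `fit_group` loops over a `w_e` grid at
0.01 precision.  At each grid value every participant is simulated with
their own capacity and `fit_individual` minimizes the RMSE between
predicted and observed accuracy over the four cells, using Nelder–Mead
on `(θ, log σ)` from three starts spanning the activation range
(tolerance 1e-6).  Per-participant `θ, σ` are averaged; the group RMSE is
recomputed from cohort-mean predicted vs observed cell accuracies at
`(θ̄, σ̄)`; the grid value with the smallest group RMSE wins, ties going
to the smaller `w_e`.  Per-participant seeds are spawned once from the
root seed, so practice orderings are identical across the grid and the
profile is smooth.  Practice success probabilities during fitting come
from the observed practice accuracies (matched mode, default) or from
the model's CDF under Monte-Carlo averaging over seeded replicates
(`mode="mc"`, 20 replicates by default); in either case the optimized
`(θ, σ)` affect only the final-test mapping.

The default operating point — `w_e = 0.28`, `θ = 0.45`, `σ = 0.10` — was
chosen once so that the simulated cohort reproduces the qualitative
phenomenon at fitted-parameter scale: practice accuracies around
0.65–0.9, final accuracies 0.45–0.92, a 3–4 point testing effect for
high-capacity participants in both frequency cells, and a null-to-negative
effect for low-capacity participants on LF pairs.  At this point the LF
test trial costs ≈ 2.3 resource units against a low-capacity pool of
≈ 1.7, so re-encoding is truncated for roughly the lower half of the d′
distribution — the mechanism the model exists to express.

## Behavioral statistics

WM capacity is the mean of the 2-back and 3-back d′ scores
(`d′ = Φ⁻¹(hit rate) − Φ⁻¹(FA rate)`, log-linear correction: +0.5 per
cell, +1 per denominator; 1-back excluded as near-ceiling, with a d′ < 1
exclusion flag).  The regression stage fits random-intercept logistic
mixed models by maximizing the exact marginal likelihood with 21-node
Gauss–Hermite quadrature (Bernoulli rows collapsed to binomial
sufficient statistics per participant × cell; BFGS on `(β, log τ)`;
Wald z and p; SEs from the numerical Hessian).  This in-package
estimator agrees with lme4's `glmer` to ~0.01 on both coefficients and
SEs (cross-checked in the test suite via Rscript).

Factors are treatment-coded — test = 1, HF = 1 — with WM on its raw d′
scale.  This coding is identified by the reported coefficient pattern
itself: the published simple slopes (0.50 at +1 SD, −0.22 at −1 SD)
combined with the LF-stratum condition and condition × WM coefficients
(−1.26, 0.61) solve to slope evaluation at raw WM ≈ 2.89 and 1.71, i.e.
an uncentered moderator with mean ≈ 2.30 and SD ≈ 0.59; the same coding
reproduces the HF-stratum condition effect (≈ 0.35) from the three-way
model's coefficients.  Sum-to-zero ±0.5 coding with centered WM is
available via `coding="sum"`.  Standardized β are obtained by refitting
with all predictors scaled to unit SD.  Simple slopes use the delta
method on the fixed-effect covariance.  The robustness refit adds each
participant's HF/LF practice-accuracy ratio as a covariate (continuity
adjustment when LF accuracy is zero; a ratio constant across
participants is absorbed by the intercept and dropped).

## Synthetic data

`gen_cohort` generates what the analysis consumes: d′ ~ Normal(2.30,
0.59) truncated at 0.2 (the distribution implied by the published
slope-evaluation points, see above), participant intercepts ~ N(0, 0.5)
(a typical magnitude for accuracy data; not reported, chosen once),
trial outcomes Bernoulli from the three-way generating coefficients,
n-back counts from an equal-variance signal-detection model at an
unbiased criterion (4 blocks × 18 trials per frequency × level, 1/3
targets) so that scoring them near-inverts the generating d′, and
practice outcomes with HF ≥ LF accuracy in expectation.  What it does
not emulate: response times, serial-position or item effects,
session-level drift, and any real-data idiosyncrasies beyond the
documented schema — so green tests certify the pipeline's logic and
calibration, not properties of the experimental sample.

`gen_sac_cohort` is the fitting module's ground-truth generator: it runs
the expected-value simulation at known `(w_e*, θ*, σ*)` and emits
observed accuracies either noise-free (exact expected accuracies,
`n_trials_per_cell=None`) or as binomial draws over 16 trials per cell.
Exact grid recovery of `w_e*` is only a well-defined requirement on the
noise-free route, where the objective at truth is ~0; with binomial
observations at 16 trials/cell the argmin moves by sampling noise, which
the recovery analysis reports rather than asserts away.

## Numerical choices and degenerate inputs

- Nelder–Mead with `log σ` keeps `σ > 0` without constraints; three
  starts guard against the shallow valley at large σ.
- All-identical activations make σ non-identifiable: the individual fit
  is flagged `degenerate` and pinned at the boundary start.
- Grid ties break toward smaller `w_e` (strict improvement required).
- `consume` clamps at zero; an exactly-zero grant during re-encoding is
  logged as a `starved` trial.
- Non-causal strength queries (before an event) raise; empty histories
  return the configured floor (0).
- GH quadrature with 21 nodes is accurate for `τ` up to ≈ 2 given the
  binomial collapse; lme4 agreement is the regression test for this.
- Seeds: every stage spawns children from one root via
  `numpy.random.SeedSequence`; identical configs and seeds give
  bit-identical event logs and tables.

## Problem sizes

Simulation-based checks run at the study's scale (30 participants, 64
pairs, 16 trials per cell).  Replicate studies use 50 seeded replicates
of two 8-participant WM groups for the interaction pattern, a 25-point
`w_e` grid for recovery, 200 replicates of n = 300 cohorts for
regression recovery, and 200 null replicates at n = 30 for calibration —
sizes chosen so each stage's Monte-Carlo error is small relative to the
effects being checked.

## Known limitations

- The inherited SAC constants are pinned only through the two printed
  strength anchors; other (c, d, b) triples satisfying them would change
  within-day recency profiles slightly.  The anchors do fix the model's
  behavior at the times that matter (practice + 24 h).
- The retrieval attempt is charged per trial, not per unit search time;
  cue-screen duration is not modelled.
- Link strengths do not decay separately from node strengths, and no
  fan-effect interference beyond the context-fan division is modelled.
- The real-data reproduction path (reading a deposited trial table) is
  implemented but can only be exercised when that table is supplied
  locally; all calibration claims above rest on synthetic cohorts.
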