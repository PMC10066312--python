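"""Synthetic study datasets with the structure the analysis assumes.

``gen_cohort`` emulates the deposited behavioral tables: per-participant
WM capacity (n-back d'), n-back hit/false-alarm counts consistent with
that d', practice-phase outcomes, and 64 final-test trials whose success
probabilities come from a mixed-effects logistic model.  The default
generating fixed effects are the three-way-interaction model's reported
coefficients (treatment coding, raw WM scale), so refitting the same
model on a generated cohort is a ground-truth recovery experiment.

``gen_sac_cohort`` instead runs the SAC simulation with known
(w_e*, theta*, sigma*) and emits observed condition accuracies, the
ground truth for the fitting module's recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .config import SACConfig
from .protocol import CELLS, ProtocolSchedule, simulate_participant

# Reported three-way model coefficients under treatment coding
# (test = 1, HF = 1, WM on the raw d' scale).
DEFAULT_COEFFS: dict[str, float] = {
    "(Intercept)": -0.12,
    "Condition": -1.27,
    "Frequency": -0.71,
    "WM": 0.25,
    "Condition:Frequency": 2.10,
    "Condition:WM": 0.62,
    "Frequency:WM": 0.33,
    "Condition:Frequency:WM": -0.83,
}


@dataclass
class GeneratorSpec:
    """Knobs of the behavioral-cohort generator.

    The d' distribution (mean 2.3, SD 0.59, truncated at 0.2) is the one
    implied by the reported simple-slope evaluation points; see
    docs/methods.md.
    """

    n_participants: int = 30
    dprime_mean: float = 2.3
    dprime_sd: float = 0.59
    dprime_min: float = 0.2
    coeffs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFS))
    random_intercept_sd: float = 0.5
    pairs_per_cell: int = 16
    nback_trials_per_block: int = 18
    nback_blocks_per_condition: int = 4
    nback_target_fraction: float = 1.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        if self.dprime_sd <= 0 or self.pairs_per_cell <= 0:
            raise ValueError("invalid generator spec")
        missing = set(DEFAULT_COEFFS) - set(self.coeffs)
        if missing:
            raise ValueError(f"missing generating coefficients: {missing}")


def _draw_dprime(rng: np.random.Generator, spec: GeneratorSpec,
                 size: int) -> np.ndarray:
    out = rng.normal(spec.dprime_mean, spec.dprime_sd, size=size)
    while True:
        bad = out < spec.dprime_min
        if not bad.any():
            return out
        out[bad] = rng.normal(spec.dprime_mean, spec.dprime_sd,
                              size=int(bad.sum()))


def _linear_predictor(coeffs: dict[str, float], c: float, f: float,
                      w: float) -> float:
    return (coeffs["(Intercept)"] + coeffs["Condition"] * c
            + coeffs["Frequency"] * f + coeffs["WM"] * w
            + coeffs["Condition:Frequency"] * c * f
            + coeffs["Condition:WM"] * c * w
            + coeffs["Frequency:WM"] * f * w
            + coeffs["Condition:Frequency:WM"] * c * f * w)


def _nback_counts(rng: np.random.Generator, dp: float, level: str,
                  spec: GeneratorSpec) -> dict:
    """Hit/false-alarm counts from an equal-variance signal-detection
    model with an unbiased criterion, so scoring them recovers ~dp."""
    n_blocks = 2 * spec.nback_blocks_per_condition  # HF + LF blocks pooled
    n_trials = n_blocks * spec.nback_trials_per_block
    n_targets = int(round(n_trials * spec.nback_target_fraction))
    n_lures = n_trials - n_targets
    hr = norm.cdf(dp / 2.0)
    fr = norm.cdf(-dp / 2.0)
    hits = int(rng.binomial(n_targets, hr))
    fas = int(rng.binomial(n_lures, fr))
    return dict(level=level, hits=hits, misses=n_targets - hits,
                false_alarms=fas, correct_rejections=n_lures - fas,
                n_targets=n_targets, n_lures=n_lures)


def gen_cohort(
    spec: GeneratorSpec, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Generate (trials, nback, practice) tables plus the ground truth.

    Trial outcomes are Bernoulli draws from the logistic linear predictor
    with a participant random intercept; n-back counts invert the d'
    formula; practice accuracies keep HF at least as accurate as LF in
    expectation.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    dps = _draw_dprime(rng, spec, spec.n_participants)
    intercepts = rng.normal(0.0, spec.random_intercept_sd,
                            size=spec.n_participants)
    trial_rows, nback_rows, practice_rows = [], [], []
    for i in range(spec.n_participants):
        pid = f"p{i:03d}"
        w = float(dps[i])
        # n-back: 2- and 3-back share the composite symmetrically; 1-back
        # near ceiling (kept for the exclusion rule)
        delta = float(rng.normal(0.0, 0.15))
        for level, dp_level in (("1-back", w + 1.5), ("2-back", w + delta),
                                ("3-back", w - delta)):
            nback_rows.append(dict(participant=pid,
                                   **_nback_counts(rng, max(dp_level, 0.05),
                                                   level, spec)))
        # practice-phase outcomes for test-condition pairs (HF >= LF)
        p_hf = float(expit(0.9 + 0.5 * (w - spec.dprime_mean)))
        p_lf = float(expit(0.3 + 0.5 * (w - spec.dprime_mean)))
        for freq, p_prac in (("HF", p_hf), ("LF", p_lf)):
            for j in range(spec.pairs_per_cell):
                practice_rows.append(dict(
                    participant=pid, frequency=freq, pair=j,
                    practice_correct=int(rng.random() < p_prac)))
        for freq in ("HF", "LF"):
            for cond in ("test", "restudy"):
                c = 1.0 if cond == "test" else 0.0
                f = 1.0 if freq == "HF" else 0.0
                eta = _linear_predictor(spec.coeffs, c, f, w) + intercepts[i]
                p = expit(eta)
                for j in range(spec.pairs_per_cell):
                    trial_rows.append(dict(
                        participant=pid, frequency=freq, condition=cond,
                        pair=j, final_correct=int(rng.random() < p),
                        wm_capacity=w))
    trials = pd.DataFrame(
        trial_rows, columns=["participant", "frequency", "condition", "pair",
                             "final_correct", "wm_capacity"])
    nback = pd.DataFrame(
        nback_rows, columns=["participant", "level", "hits", "misses",
                             "false_alarms", "correct_rejections",
                             "n_targets", "n_lures"])
    practice = pd.DataFrame(
        practice_rows, columns=["participant", "frequency", "pair",
                                "practice_correct"])
    truth = dict(coeffs=dict(spec.coeffs),
                 random_intercept_sd=spec.random_intercept_sd,
                 dprime=dict(mean=spec.dprime_mean, sd=spec.dprime_sd,
                             min=spec.dprime_min))
    return trials, nback, practice, truth


@dataclass
class DprimeSpec:
    mean: float = 2.3
    sd: float = 0.59
    minimum: float = 0.2


def gen_sac_cohort(
    config: SACConfig,
    schedule: ProtocolSchedule,
    n: int,
    dprime_spec: DprimeSpec | None = None,
    seed: int = 0,
    n_trials_per_cell: int | None = None,
    outdir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Model-generated observed accuracies with known (w_e*, theta*, sigma*).

    Runs the deterministic expected-value simulation per participant (the
    practice success rule is the model's own CDF probability) and converts
    the predicted cell accuracies into observed accuracies: exact
    probabilities when ``n_trials_per_cell`` is None, otherwise binomial
    draws over that many trials.  Returns a tidy observed table (including
    the per-cell practice accuracies the matched-mode fit consumes) and
    the ground-truth parameters.
    """
    dspec = dprime_spec or DprimeSpec()
    rng = np.random.default_rng(seed)
    rows = []
    seeds = np.random.SeedSequence(seed).spawn(max(n, 1))
    for i in range(n):
        pid = f"s{i:03d}"
        dp = float(rng.normal(dspec.mean, dspec.sd))
        while dp < dspec.minimum:
            dp = float(rng.normal(dspec.mean, dspec.sd))
        pseed = int(seeds[i].generate_state(1)[0] % (2**31))
        sim = simulate_participant(dp, schedule, config, pseed,
                                   participant=pid, expected_value=True)
        practice = {
            freq: float(sim.pair_table.loc[
                (sim.pair_table.frequency == freq)
                & (sim.pair_table.condition == "test"), "p_success"].mean())
            for freq in ("HF", "LF")
        }
        for freq, cond in CELLS:
            p_true = sim.condition_accuracy[(freq, cond)]
            if n_trials_per_cell is None:
                observed = p_true
            else:
                observed = rng.binomial(n_trials_per_cell,
                                        p_true) / n_trials_per_cell
            rows.append(dict(
                participant=pid, wm_dprime=dp, frequency=freq,
                condition=cond, observed_accuracy=float(observed),
                true_accuracy=float(p_true),
                practice_accuracy=(practice[freq] if cond == "test"
                                   else np.nan)))
    table = pd.DataFrame(
        rows, columns=["participant", "wm_dprime", "frequency", "condition",
                       "observed_accuracy", "true_accuracy",
                       "practice_accuracy"])
    truth = dict(w_e=config.w_e, theta=config.theta, sigma=config.sigma,
                 dprime=dataclasses.asdict(dspec), n=n,
                 n_trials_per_cell=n_trials_per_cell)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "observed.csv", index=False)
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    return table, truth
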