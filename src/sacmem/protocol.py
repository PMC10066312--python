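"""The experimental protocol driven through the memory engine.

Three weeks of visual-search familiarization (nine sessions, 15:1 HF:LF
presentation ratio) set the Fribble concept strengths; on the practice
day the model refreshes all 64 cue-word associations once, then runs the
randomly intermixed restudy/test practice; after 24 h of decay a cued
recall of every pair yields per-pair predicted accuracies through the
normal-CDF mapping Phi((A - theta) / sigma).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import SACConfig
from .engine import encode_study, re_encode, retrieval_attempt
from .network import (
    MemoryNode,
    NodeKind,
    base_strength,
    episode_activation,
    make_episode,
)
from .wm import WMState, replenish

CELLS = [("HF", "test"), ("HF", "restudy"), ("LF", "test"), ("LF", "restudy")]


@dataclass
class ProtocolSchedule:
    """Timing and counts of the four-week protocol.

    Familiarization sessions sit on ``session_days`` (three per week,
    24-48 h apart); the restudy/test practice runs on ``practice_day``
    and the final cued recall 24 h later.
    """

    n_pairs_per_cell: int = 16
    hf_reps: int = 135
    lf_reps: int = 9
    session_days: tuple[int, ...] = (0, 2, 4, 7, 9, 11, 14, 16, 18)
    practice_day: int = 22
    final_delay_hours: float = 24.0
    trial_spacing_seconds: float = 10.0

    def __post_init__(self) -> None:
        n = len(self.session_days)
        if self.hf_reps % n or self.lf_reps % n:
            raise ValueError("repetitions must divide evenly over sessions")
        if self.lf_reps and self.hf_reps // n < self.lf_reps // n:
            raise ValueError("HF must be presented at least as often as LF")

    @property
    def n_sessions(self) -> int:
        return len(self.session_days)

    @property
    def practice_start_hours(self) -> float:
        return self.practice_day * 24.0

    @property
    def session_times_hours(self) -> tuple[float, ...]:
        return tuple(d * 24.0 for d in self.session_days)


@dataclass
class Network:
    """All nodes for one simulated participant's session."""

    fribbles: dict[str, MemoryNode]
    words: dict[str, MemoryNode]
    context: MemoryNode
    episodes: dict[str, MemoryNode] = field(default_factory=dict)
    pair_frequency: dict[str, str] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.fribbles)


@dataclass
class PairRecord:
    """Per-pair practice outcome, carrying both counterfactual branches.

    For test pairs ``a_success``/``a_fail`` are the final-test activations
    had the retrieval attempt succeeded/failed and ``p_success`` the
    success probability used; restudy pairs have a single branch
    (p_success = 1, both activations equal).
    """

    pair_id: str
    frequency: str
    condition: str
    p_success: float
    events_success: list[tuple[float, float]]
    events_fail: list[tuple[float, float]]
    realized_success: bool | None = None


@dataclass
class SimulatedParticipant:
    participant: str
    wm_dprime: float
    condition_accuracy: dict[tuple[str, str], float]
    pair_table: pd.DataFrame
    trial_log: pd.DataFrame


def familiarize(schedule: ProtocolSchedule, config: SACConfig) -> Network:
    """Build the pre-practice network from the familiarization schedule.

    Each HF fribble receives ``hf_reps`` unit-strength presentation events
    and each LF fribble ``lf_reps``, spread evenly over the nine sessions;
    word and context nodes carry fixed pre-experimental familiarity.
    """
    n_per_freq = 2 * schedule.n_pairs_per_cell
    fribbles: dict[str, MemoryNode] = {}
    words: dict[str, MemoryNode] = {}
    pair_frequency: dict[str, str] = {}
    hf_per_sess = schedule.hf_reps // schedule.n_sessions
    lf_per_sess = schedule.lf_reps // schedule.n_sessions
    for i in range(2 * n_per_freq):
        freq = "HF" if i < n_per_freq else "LF"
        reps = hf_per_sess if freq == "HF" else lf_per_sess
        node = MemoryNode(id=f"fribble_{i:02d}", kind=NodeKind.FRIBBLE)
        for t in schedule.session_times_hours:
            node.events.extend([(t, 1.0)] * reps)
        fribbles[node.id] = node
        words[f"word_{i:02d}"] = MemoryNode(
            id=f"word_{i:02d}", kind=NodeKind.WORD,
            fixed_strength=config.word_strength,
        )
        pair_frequency[f"pair_{i:02d}"] = freq
    context = MemoryNode(id="context", kind=NodeKind.CONTEXT,
                         fixed_strength=config.context_strength)
    return Network(fribbles=fribbles, words=words, context=context,
                   pair_frequency=pair_frequency)


def assign_conditions(
    network: Network, rng: np.random.Generator
) -> dict[str, str]:
    """Randomly split each frequency's pairs 50/50 into test vs restudy."""
    assignment: dict[str, str] = {}
    for freq in ("HF", "LF"):
        pairs = [p for p, f in network.pair_frequency.items() if f == freq]
        pairs = list(rng.permutation(pairs))
        half = len(pairs) // 2
        for p in pairs[:half]:
            assignment[p] = "test"
        for p in pairs[half:]:
            assignment[p] = "restudy"
    return assignment


def _check_assignment(network: Network, assignment: dict[str, str]) -> None:
    counts: dict[tuple[str, str], int] = {c: 0 for c in CELLS}
    for pair, cond in assignment.items():
        counts[(network.pair_frequency[pair], cond)] += 1
    expected = network.n_pairs // 4
    if any(v != expected for v in counts.values()):
        raise ValueError(f"unbalanced condition assignment: {counts}")


def run_practice_day(
    network: Network,
    wm: WMState,
    assignment: dict[str, str],
    config: SACConfig,
    rng: np.random.Generator,
    schedule: ProtocolSchedule,
    practice_acc: dict[str, float] | None = None,
    expected_value: bool = False,
) -> tuple[list[PairRecord], pd.DataFrame]:
    """Refresh every association once, then run the intermixed practice.

    Restudy trials re-encode the pair; test trials run the retrieval
    attempt followed, on success, by post-retrieval re-encoding.  The pool
    refills completely in the inter-trial interval, so WM acts within
    trials only.  ``practice_acc`` (matched-success mode) fixes the test
    success probability per frequency to an observed practice accuracy
    instead of the model's own CDF rule.  With ``expected_value=True`` no
    success is sampled: both branches of every test trial are carried
    forward and weighted by ``p_success`` downstream, which makes the run
    deterministic.
    """
    _check_assignment(network, assignment)
    t0 = schedule.practice_start_hours
    dt_h = schedule.trial_spacing_seconds / 3600.0
    spacing_s = schedule.trial_spacing_seconds
    log_rows: list[dict] = []

    # ---- refresh phase: one study encoding of every pair -----------------
    order = list(rng.permutation(sorted(network.pair_frequency)))
    t = t0
    for i, pair in enumerate(order):
        idx = pair.split("_")[1]
        cue = network.fribbles[f"fribble_{idx}"]
        word = network.words[f"word_{idx}"]
        episode = make_episode(f"episode_{idx}", cue, word, network.context)
        # Day-1 criterion learning collapsed into one baseline event
        episode.events.append((t, config.baseline_increment))
        wm_before = wm.available
        episode, wm, charge = encode_study(episode, cue, wm, t, config)
        network.episodes[pair] = episode
        log_rows.append(dict(
            trial_index=i, pair_id=pair,
            frequency=network.pair_frequency[pair],
            condition=assignment[pair], phase="refresh",
            wm_before=wm_before, charge_attempt=0.0, charge_extra=0.0,
            charge_re_encode=charge, success=True, starved=False,
            strength_after=base_strength(episode, t, config),
        ))
        wm = replenish(wm, spacing_s)
        t += dt_h

    # ---- practice phase: randomly intermixed restudy/test trials ---------
    records: list[PairRecord] = []
    order = list(rng.permutation(sorted(network.pair_frequency)))
    for i, pair in enumerate(order):
        idx = pair.split("_")[1]
        cue = network.fribbles[f"fribble_{idx}"]
        episode = network.episodes[pair]
        freq = network.pair_frequency[pair]
        cond = assignment[pair]
        wm_before = wm.available
        if cond == "restudy":
            episode, wm, charge = encode_study(episode, cue, wm, t, config)
            records.append(PairRecord(
                pair_id=pair, frequency=freq, condition=cond,
                p_success=1.0,
                events_success=list(episode.events),
                events_fail=list(episode.events),
            ))
            log_rows.append(dict(
                trial_index=i, pair_id=pair, frequency=freq, condition=cond,
                phase="practice", wm_before=wm_before, charge_attempt=0.0,
                charge_extra=0.0, charge_re_encode=charge, success=True,
                starved=False,
                strength_after=base_strength(episode, t, config),
            ))
        else:
            override = None
            if practice_acc is not None:
                override = practice_acc[freq]
            attempt, wm = retrieval_attempt(
                cue, network.context, episode, wm, t, config, rng,
                context_fan=network.n_pairs,
                success_prob_override=override,
            )
            events_fail = list(episode.events)
            if expected_value:
                # carry the success branch hypothetically
                attempt.success = True
                episode, wm, charge, starved = re_encode(
                    episode, cue, attempt, wm, t, config)
                events_success = list(episode.events)
                realized: bool | None = None
                # keep the stored node on the expected path: leave events as
                # the success branch; downstream reads branches explicitly
            else:
                episode, wm, charge, starved = re_encode(
                    episode, cue, attempt, wm, t, config)
                events_success = list(episode.events)
                realized = attempt.success
                if not attempt.success:
                    events_success = events_fail
            records.append(PairRecord(
                pair_id=pair, frequency=freq, condition=cond,
                p_success=attempt.success_prob,
                events_success=events_success,
                events_fail=events_fail,
                realized_success=realized,
            ))
            log_rows.append(dict(
                trial_index=i, pair_id=pair, frequency=freq, condition=cond,
                phase="practice", wm_before=wm_before,
                charge_attempt=attempt.charge_attempt,
                charge_extra=attempt.charge_extra,
                charge_re_encode=charge,
                success=attempt.success, starved=starved,
                strength_after=base_strength(episode, t, config),
            ))
        wm = replenish(wm, spacing_s)
        t += dt_h
    return records, pd.DataFrame(log_rows)


def _branch_activation(
    events: list[tuple[float, float]],
    cue: MemoryNode,
    network: Network,
    t: float,
    config: SACConfig,
) -> float:
    ep = MemoryNode(id="tmp", kind=NodeKind.EPISODE, events=list(events))
    ep.link_to(cue.id)
    ep.link_to(network.context.id)
    return episode_activation(ep, cue, network.context, t, config,
                              context_fan=network.n_pairs)


def final_test(
    network: Network,
    records: list[PairRecord],
    config: SACConfig,
    schedule: ProtocolSchedule,
) -> pd.DataFrame:
    """Cued recall of every pair after 24 h of decay.

    Returns one row per pair with the success/failure-branch activations,
    the practice success probability, and the predicted accuracy
    p * Phi((A_s - theta)/sigma) + (1-p) * Phi((A_f - theta)/sigma)
    (for realized stochastic runs the realized branch alone is used).
    """
    if config.sigma <= 0:
        raise ValueError("sigma must be > 0")
    t = schedule.practice_start_hours + schedule.final_delay_hours
    rows = []
    for rec in records:
        idx = rec.pair_id.split("_")[1]
        cue = network.fribbles[f"fribble_{idx}"]
        a_s = _branch_activation(rec.events_success, cue, network, t, config)
        a_f = _branch_activation(rec.events_fail, cue, network, t, config)
        if rec.realized_success is None:
            p = rec.p_success
        else:
            p = 1.0 if rec.realized_success else 0.0
        acc = p * norm.cdf((a_s - config.theta) / config.sigma) + \
            (1.0 - p) * norm.cdf((a_f - config.theta) / config.sigma)
        rows.append(dict(
            pair_id=rec.pair_id, frequency=rec.frequency,
            condition=rec.condition, a_success=a_s, a_fail=a_f,
            p_success=p, predicted_accuracy=float(acc),
        ))
    return pd.DataFrame(rows)


def simulate_participant(
    wm_dprime: float,
    schedule: ProtocolSchedule,
    config: SACConfig,
    seed: int | np.random.Generator,
    participant: str = "sim",
    practice_acc: dict[str, float] | None = None,
    expected_value: bool = False,
) -> SimulatedParticipant:
    """Full pipeline for one participant: familiarize, practice, final test."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    network = familiarize(schedule, config)
    wm = WMState.for_dprime(wm_dprime, config)
    assignment = assign_conditions(network, rng)
    records, log = run_practice_day(
        network, wm, assignment, config, rng, schedule,
        practice_acc=practice_acc, expected_value=expected_value,
    )
    pair_table = final_test(network, records, config, schedule)
    acc = {
        cell: float(pair_table.loc[
            (pair_table.frequency == cell[0])
            & (pair_table.condition == cell[1]),
            "predicted_accuracy"].mean())
        for cell in CELLS
    }
    return SimulatedParticipant(
        participant=participant, wm_dprime=wm_dprime,
        condition_accuracy=acc, pair_table=pair_table, trial_log=log,
    )
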