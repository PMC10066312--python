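"""Trial-level memory operations: study encoding, retrieval, re-encoding.

A restudy trial encodes the association once, paying the encode cost.
A test trial runs two sequential processes: the retrieval attempt (paying
the retrieve cost plus the extra search/maintenance cost) and, only if the
attempt succeeded, a post-retrieval re-encoding paying the encode cost —
no feedback is given, so a failed attempt strengthens nothing.  Each
process strengthens the episode in proportion to the fraction of its
requested resources the pool could grant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .config import SACConfig
from .network import MemoryNode, base_strength, episode_activation, strengthen
from .wm import WMState, consume, wm_extra_cost, wm_operation_cost


@dataclass
class AttemptOutcome:
    """Bookkeeping for one retrieval attempt."""

    activation: float
    success: bool
    success_prob: float
    charge_attempt: float
    charge_extra: float
    attempt_fraction: float  # fraction of the attempt request granted


def encode_study(
    episode: MemoryNode,
    cue: MemoryNode,
    wm: WMState,
    t: float,
    config: SACConfig,
) -> tuple[MemoryNode, WMState, float]:
    """Restudy/refresh encoding of an association.

    Requests the encode cost for material of the cue's familiarity and
    strengthens the episode by the granted fraction.  Returns the episode,
    the depleted pool and the charge.
    """
    b_cue = base_strength(cue, t, config)
    request = wm_operation_cost(b_cue, "encode", config)
    wm, granted = consume(wm, request)
    frac = granted / request if request > 0 else 1.0
    strengthen(episode, t, frac, config)
    return episode, wm, granted


def retrieval_attempt(
    cue: MemoryNode,
    context: MemoryNode,
    episode: MemoryNode,
    wm: WMState,
    t: float,
    config: SACConfig,
    rng: np.random.Generator,
    context_fan: int = 1,
    success_prob_override: float | None = None,
) -> tuple[AttemptOutcome, WMState]:
    """The first process of a test trial.

    Charges the retrieve cost plus the extra search-and-maintenance cost
    (w_e * (1/B_cue + 1/B_target)) against the pool, computes
    the episode's activation (base strength plus spread from cue and
    context), and resolves success.  By default success is Bernoulli with
    p = Phi((A - theta) / sigma), the same normal-CDF mapping used at
    final test; ``success_prob_override`` substitutes a fixed probability
    (matched-success mode).
    """
    if cue.id not in episode.links or context.id not in episode.links:
        raise ValueError(f"episode {episode.id} not linked to cue {cue.id}")
    b_cue = base_strength(cue, t, config)
    # target familiarity: the associated word's pre-experimental strength
    b_target = config.word_strength
    request_attempt = wm_operation_cost(b_cue, "retrieve", config)
    wm, granted_attempt = consume(wm, request_attempt)
    extra = wm_extra_cost(b_cue, b_target, config.w_e)
    wm, granted_extra = consume(wm, extra)

    activation = episode_activation(episode, cue, context, t, config,
                                    context_fan=context_fan)
    if success_prob_override is not None:
        p = float(success_prob_override)
    else:
        p = float(norm.cdf((activation - config.theta) / config.sigma))
    success = bool(rng.random() < p)
    frac = granted_attempt / request_attempt if request_attempt > 0 else 1.0
    out = AttemptOutcome(
        activation=activation,
        success=success,
        success_prob=p,
        charge_attempt=granted_attempt,
        charge_extra=granted_extra,
        attempt_fraction=frac,
    )
    return out, wm


def re_encode(
    episode: MemoryNode,
    cue: MemoryNode,
    attempt: AttemptOutcome,
    wm: WMState,
    t: float,
    config: SACConfig,
) -> tuple[MemoryNode, WMState, float, bool]:
    """The second process of a test trial, gated on attempt success.

    On success the retrieval itself strengthens the episode (the attempt's
    activation boost, scaled by the attempt's granted fraction) and the
    re-encoding of the retrieved information requests a fresh encode cost,
    strengthening by whatever fraction the depleted pool can still grant —
    the truncation that makes retrieval practice costly for low-capacity
    learners on unfamiliar material.  On failure nothing is charged or
    strengthened.  Returns (episode, pool, re-encode charge, starved flag).
    """
    if not attempt.success:
        return episode, wm, 0.0, False
    # activation-driven strengthening from the successful attempt itself
    strengthen(episode, t, attempt.attempt_fraction, config)
    b_cue = base_strength(cue, t, config)
    request = wm_operation_cost(b_cue, "encode", config)
    wm, granted = consume(wm, request)
    frac = granted / request if request > 0 else 1.0
    strengthen(episode, t, frac, config)
    starved = granted == 0.0 and request > 0.0
    return episode, wm, granted, starved
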