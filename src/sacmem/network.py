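"""Localist memory network: nodes, base-level strength, strengthening.

Concept nodes (Fribbles, words, context) and episode nodes carry a history
of strengthening events.  Base-level strength follows a power law of
learning and forgetting:

    B(t) = floor + scale * ( sum_i inc_i * (t - t_i + 1)^-d )^b

with decay exponent d, compressive learning exponent b and all times in
hours.  The compressive outer exponent gives diminishing returns for
massed repetition, which is what lets a 15:1 presentation ratio produce
a roughly 2:1 strength ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .config import SACConfig


class NodeKind(str, Enum):
    FRIBBLE = "fribble_concept"
    WORD = "word_concept"
    CONTEXT = "context"
    EPISODE = "episode"


@dataclass
class MemoryNode:
    """A concept or episode node with a strengthening-event history.

    ``events`` is an ordered list of (time_hours, strength_increment);
    ``links`` maps neighbor node ids to non-negative link strengths.
    """

    id: str
    kind: NodeKind
    events: list[tuple[float, float]] = field(default_factory=list)
    links: dict[str, float] = field(default_factory=dict)
    # pre-experimental familiarity not modelled as events (words, context):
    # when set, base strength is this constant and does not decay
    fixed_strength: float | None = None

    def last_event_time(self) -> float | None:
        return self.events[-1][0] if self.events else None

    def link_to(self, other_id: str, strength: float = 1.0) -> None:
        if strength < 0:
            raise ValueError("link strength must be >= 0")
        self.links[other_id] = strength


def base_strength(node: MemoryNode, t: float, config: SACConfig) -> float:
    """Base-level strength of ``node`` evaluated at time ``t`` (hours).

    Raises if ``t`` precedes any strengthening event (non-causal query).
    An empty history returns the configured floor.
    """
    if node.fixed_strength is not None:
        return node.fixed_strength
    if not node.events:
        return config.strength_floor
    times = np.array([e[0] for e in node.events])
    incs = np.array([e[1] for e in node.events])
    if t < times.max():
        raise ValueError(
            f"non-causal query: t={t} precedes an event at {times.max()}"
        )
    s = float(np.sum(incs * (t - times + 1.0) ** (-config.decay_exponent)))
    if s <= 0.0:
        return config.strength_floor
    return config.strength_floor + config.strength_scale * s ** config.learn_exponent


def strengthen(
    node: MemoryNode, t: float, wm_spent_fraction: float, config: SACConfig
) -> MemoryNode:
    """Append a strengthening event funded by WM resources (in place).

    ``wm_spent_fraction`` is the fraction of the operation's requested WM
    resources actually granted, in [0, 1]; the event increment is
    ``learning_rate * fraction``.  The same rule serves restudy encoding
    and post-retrieval re-encoding (shared learning rate).  A zero spend
    leaves strength unchanged.
    """
    if wm_spent_fraction < 0:
        raise ValueError("wm_spent_fraction must be >= 0")
    last = node.last_event_time()
    if last is not None and t < last:
        raise ValueError(f"event at t={t} precedes last event at {last}")
    inc = config.learning_rate * min(wm_spent_fraction, 1.0)
    if inc > 0:
        node.events.append((t, inc))
    return node


def make_episode(
    episode_id: str,
    fribble: MemoryNode,
    word: MemoryNode,
    context: MemoryNode,
) -> MemoryNode:
    """Create an episode node bound to exactly one fribble, word and context."""
    for n, kind in ((fribble, NodeKind.FRIBBLE), (word, NodeKind.WORD),
                    (context, NodeKind.CONTEXT)):
        if n.kind is not kind:
            raise ValueError(f"node {n.id} has kind {n.kind}, expected {kind}")
    ep = MemoryNode(id=episode_id, kind=NodeKind.EPISODE)
    for n in (fribble, word, context):
        ep.link_to(n.id)
        n.link_to(episode_id)
    return ep


def episode_activation(
    episode: MemoryNode,
    cue: MemoryNode,
    context: MemoryNode,
    t: float,
    config: SACConfig,
    context_fan: int = 1,
) -> float:
    """Activation of an episode node when cued (cue + context present).

    Base strength plus a configured share of the source nodes' activation,
    split by fan: the cue links to a single episode (full share) while the
    context fans out over all episodes in the session.
    """
    if cue.id not in episode.links or context.id not in episode.links:
        raise ValueError(f"episode {episode.id} is not linked to cue/context")
    b_ep = base_strength(episode, t, config)
    b_cue = base_strength(cue, t, config)
    b_ctx = base_strength(context, t, config)
    return b_ep + config.spread_share * (b_cue + b_ctx / max(context_fan, 1))
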