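"""The working-memory resource pool and its cost rules.

Node operations (encoding, retrieval) deplete a limited per-participant
pool that refills within a few seconds, so WM limits act at the trial
level only.  Operation costs decrease with the familiarity (base-level
strength) of the material; retrieval practice additionally pays an extra
cost — memory search and maintenance of the retrieved trace — that is
inversely proportional to cue and target strengths:

    WM_extra = w_e * (1 / B_cue + 1 / B_target)
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import SACConfig


@dataclass
class WMState:
    """A participant's resource pool.

    ``capacity`` is derived from n-back d-prime via the config's affine
    map; ``available`` always lies in [0, capacity]; ``recovery_rate`` is
    in resource units per second.
    """

    capacity: float
    available: float
    recovery_rate: float

    def __post_init__(self) -> None:
        if self.capacity < 0:
            raise ValueError("capacity must be >= 0")
        if not 0 <= self.available <= self.capacity + 1e-12:
            raise ValueError("available must lie in [0, capacity]")

    @classmethod
    def for_dprime(cls, dprime: float, config: SACConfig) -> "WMState":
        cap = config.capacity_for(dprime)
        return cls(capacity=cap, available=cap,
                   recovery_rate=config.recovery_rate)


def consume(wm: WMState, requested: float) -> tuple[WMState, float]:
    """Grant ``min(requested, available)`` resources; never goes negative.

    The clamp is the model's core mechanism: a depleted pool truncates
    whatever operation made the request.
    """
    if requested < 0:
        raise ValueError(f"negative WM request: {requested}")
    granted = min(requested, wm.available)
    new = WMState(wm.capacity, wm.available - granted, wm.recovery_rate)
    return new, granted


def replenish(wm: WMState, dt_seconds: float) -> WMState:
    """Recover ``recovery_rate * dt`` resources, capped at capacity."""
    if dt_seconds < 0:
        raise ValueError(f"negative replenish interval: {dt_seconds}")
    avail = min(wm.capacity, wm.available + wm.recovery_rate * dt_seconds)
    return WMState(wm.capacity, avail, wm.recovery_rate)


def wm_extra_cost(b_cue: float, b_target: float, w_e: float) -> float:
    """Extra WM cost of a retrieval attempt (does not strengthen memory)."""
    if w_e < 0:
        raise ValueError(f"w_e must be >= 0, got {w_e}")
    if w_e == 0.0:
        return 0.0
    if b_cue <= 0 or b_target <= 0:
        raise ValueError(
            "extra retrieval cost undefined for non-positive strength "
            f"(b_cue={b_cue}, b_target={b_target}); an unfamiliarized node "
            "reached retrieval"
        )
    return w_e * (1.0 / b_cue + 1.0 / b_target)


def wm_operation_cost(familiarity: float, kind: str, config: SACConfig) -> float:
    """WM cost of encoding or retrieving material of given familiarity.

    cost = floor + kappa / (1 + familiarity): bounded above by
    floor + kappa at zero familiarity, decreasing toward the floor as
    familiarity grows.
    """
    if familiarity < 0:
        raise ValueError("familiarity must be >= 0")
    if kind == "encode":
        kappa = config.kappa_encode
    elif kind == "retrieve":
        kappa = config.kappa_retrieve
    else:
        raise ValueError(f"unknown operation kind {kind!r}")
    return config.cost_floor + kappa / (1.0 + familiarity)
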