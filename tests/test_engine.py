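"""Trial-level operations: retrieval attempt, re-encoding, resource accounting."""

import numpy as np
import pytest

from sacmem.engine import encode_study, re_encode, retrieval_attempt
from sacmem.network import MemoryNode, NodeKind, base_strength, make_episode
from sacmem.wm import WMState, wm_extra_cost, wm_operation_cost


def make_pair(cue_strength_events=5, cue_id="f"):
    cue = MemoryNode(id=cue_id, kind=NodeKind.FRIBBLE,
                     events=[(0.0, 1.0)] * cue_strength_events)
    word = MemoryNode(id="w", kind=NodeKind.WORD, fixed_strength=0.91)
    ctx = MemoryNode(id="c", kind=NodeKind.CONTEXT, fixed_strength=1.0)
    ep = make_episode("e", cue, word, ctx)
    ep.events.append((10.0, 1.0))
    return cue, word, ctx, ep


def test_zero_we_charges_operation_cost_only(cfg, rng):
    cue, _, ctx, ep = make_pair()
    cfg0 = cfg.replace(w_e=0.0)
    wm = WMState(10.0, 10.0, 0.5)
    out, wm2 = retrieval_attempt(cue, ctx, ep, wm, 10.0, cfg0, rng)
    b_cue = base_strength(cue, 10.0, cfg0)
    assert wm.available - wm2.available == pytest.approx(
        wm_operation_cost(b_cue, "retrieve", cfg0))
    assert out.charge_extra == 0.0


def test_lf_cue_depletes_more_than_hf(cfg, rng):
    wm = WMState(10.0, 10.0, 0.5)
    left = {}
    for label, n_events in (("HF", 40), ("LF", 2)):
        cue, _, ctx, ep = make_pair(cue_strength_events=n_events)
        _, wm2 = retrieval_attempt(cue, ctx, ep, wm, 10.0, cfg, rng)
        left[label] = wm2.available
    assert left["LF"] < left["HF"]


def test_unlinked_episode_raises(cfg, rng):
    cue, _, ctx, ep = make_pair()
    stranger = MemoryNode(id="x", kind=NodeKind.FRIBBLE, events=[(0.0, 1.0)])
    with pytest.raises(ValueError):
        retrieval_attempt(stranger, ctx, ep, WMState(5, 5, 0.5), 10.0, cfg, rng)


def test_success_rate_matches_probability(cfg):
    """Monte-Carlo check of the Bernoulli success rule against its CDF."""
    cue, _, ctx, ep = make_pair()
    rng = np.random.default_rng(7)
    n = 10_000
    hits, p = 0, None
    for _ in range(n):
        out, _ = retrieval_attempt(cue, ctx, ep, WMState(5, 5, 0.5), 10.0,
                                   cfg, rng)
        hits += out.success
        p = out.success_prob
    se = np.sqrt(p * (1 - p) / n)
    assert abs(hits / n - p) < 2 * se + 1e-9


def test_failed_attempt_strengthens_nothing(cfg, rng):
    cue, _, ctx, ep = make_pair()
    out, wm = retrieval_attempt(cue, ctx, ep, WMState(5, 5, 0.5), 10.0, cfg,
                                rng, success_prob_override=0.0)
    events_before = list(ep.events)
    ep2, wm2, charge, starved = re_encode(ep, cue, out, wm, 10.0, cfg)
    assert ep2.events == events_before
    assert charge == 0.0 and not starved
    assert wm2.available == wm.available


def test_starved_re_encode_grants_zero(cfg, rng):
    cue, _, ctx, ep = make_pair()
    out, _ = retrieval_attempt(cue, ctx, ep, WMState(5, 5, 0.5), 10.0, cfg,
                               rng, success_prob_override=1.0)
    drained = WMState(5.0, 0.0, 0.5)
    n_before = len(ep.events)
    ep2, _, charge, starved = re_encode(ep, cue, out, drained, 10.0, cfg)
    assert charge == 0.0 and starved
    # the attempt-driven event lands; the re-encode event carries no strength
    incs = [inc for _, inc in ep2.events[n_before:]]
    assert sum(incs) == pytest.approx(cfg.learning_rate * out.attempt_fraction)


def test_re_encode_equals_full_restudy_increment(cfg, rng):
    """Shared learning rate: ample-resource re-encoding == restudy encoding."""
    cue, _, ctx, ep_test = make_pair()
    out, wm = retrieval_attempt(cue, ctx, ep_test, WMState(20, 20, 0.5), 10.0,
                                cfg, rng, success_prob_override=1.0)
    ep_test, _, _, _ = re_encode(ep_test, cue, out, wm, 10.0, cfg)
    re_encode_inc = ep_test.events[-1][1]

    cue2, _, _, ep_study = make_pair(cue_id="f")
    ep_study, _, _ = encode_study(ep_study, cue2, WMState(20, 20, 0.5), 10.0,
                                  cfg)
    assert re_encode_inc == pytest.approx(ep_study.events[-1][1])


def test_resource_conservation_within_trial(cfg, rng):
    cue, _, ctx, ep = make_pair(cue_strength_events=2)
    wm0 = WMState(1.5, 1.5, 0.5)
    out, wm1 = retrieval_attempt(cue, ctx, ep, wm0, 10.0, cfg, rng,
                                 success_prob_override=1.0)
    _, wm2, charge_re, _ = re_encode(ep, cue, out, wm1, 10.0, cfg)
    spent = out.charge_attempt + out.charge_extra + charge_re
    assert wm0.available - wm2.available == pytest.approx(spent)
    assert wm2.available >= 0.0


def test_successful_test_gain_nondecreasing_in_capacity(cfg, rng):
    """The core mechanism: strength gain from a successful test trial grows
    with capacity and saturates at the full attempt + re-encode gain once
    the pool covers attempt + extra + re-encode costs."""
    def gain_at(capacity):
        cue, _, ctx, ep = make_pair(cue_strength_events=2)
        base = base_strength(ep, 20.0, cfg)
        out, wm = retrieval_attempt(
            cue, ctx, ep, WMState(capacity, capacity, 0.5), 10.0, cfg, rng,
            success_prob_override=1.0)
        ep, _, _, _ = re_encode(ep, cue, out, wm, 10.0, cfg)
        b_cue = base_strength(cue, 10.0, cfg)
        need = (wm_operation_cost(b_cue, "retrieve", cfg)
                + wm_extra_cost(b_cue, cfg.word_strength, cfg.w_e)
                + wm_operation_cost(b_cue, "encode", cfg))
        return base_strength(ep, 20.0, cfg) - base, need

    capacities = [0.6, 0.9, 1.2, 1.5, 2.0, 3.0, 5.0]
    gains, needs = zip(*(gain_at(c) for c in capacities))
    assert all(b >= a - 1e-12 for a, b in zip(gains, gains[1:]))
    full_gain = gains[-1]
    for cap, g in zip(capacities, gains):
        if cap >= needs[0]:
            assert g == pytest.approx(full_gain, rel=1e-9)
        else:
            assert g < full_gain
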