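"""Protocol simulation: familiarization, practice day, final test."""

import numpy as np
import pandas as pd
import pytest

from sacmem.network import base_strength
from sacmem.protocol import (
    CELLS,
    ProtocolSchedule,
    assign_conditions,
    familiarize,
    final_test,
    run_practice_day,
    simulate_participant,
)
from sacmem.wm import WMState


def test_event_counts_match_schedule(network):
    hf = network.fribbles["fribble_00"]
    lf = network.fribbles["fribble_32"]
    assert len(hf.events) == 135
    assert len(lf.events) == 9


def test_familiarization_anchor_strengths(network, cfg, schedule):
    t = schedule.practice_start_hours
    assert base_strength(network.fribbles["fribble_00"], t, cfg) == \
        pytest.approx(0.91, abs=5e-3)
    assert base_strength(network.fribbles["fribble_32"], t, cfg) == \
        pytest.approx(0.46, abs=5e-3)


def test_hf_stronger_than_lf_at_all_times(network, cfg, schedule):
    hf, lf = network.fribbles["fribble_00"], network.fribbles["fribble_32"]
    for day in (19, 20, 22, 23, 30):
        t = day * 24.0
        assert base_strength(hf, t, cfg) > base_strength(lf, t, cfg)


def test_equal_reps_give_equal_strengths(cfg):
    sched = ProtocolSchedule(hf_reps=9, lf_reps=9)
    net = familiarize(sched, cfg)
    t = sched.practice_start_hours
    assert base_strength(net.fribbles["fribble_00"], t, cfg) == \
        pytest.approx(base_strength(net.fribbles["fribble_32"], t, cfg))


def test_uneven_schedule_rejected():
    with pytest.raises(ValueError):
        ProtocolSchedule(hf_reps=100)  # does not divide over 9 sessions


def test_cell_balance_and_unbalanced_assignment_error(cfg, schedule, rng):
    net = familiarize(schedule, cfg)
    assignment = assign_conditions(net, rng)
    counts = pd.Series(
        [(net.pair_frequency[p], c) for p, c in assignment.items()]
    ).value_counts()
    assert all(counts[cell] == 16 for cell in CELLS)
    bad = dict(assignment)
    flip = [p for p, c in bad.items() if c == "test"][0]
    bad[flip] = "restudy"
    with pytest.raises(ValueError, match="unbalanced"):
        run_practice_day(net, WMState(3, 3, 0.5), bad, cfg, rng, schedule)


def test_seeded_determinism_end_to_end(cfg, schedule):
    a = simulate_participant(2.0, schedule, cfg, seed=42)
    b = simulate_participant(2.0, schedule, cfg, seed=42)
    assert a.condition_accuracy == b.condition_accuracy
    pd.testing.assert_frame_equal(a.trial_log, b.trial_log)
    pd.testing.assert_frame_equal(a.pair_table, b.pair_table)


def test_final_test_cdf_properties(cfg, schedule):
    sim = simulate_participant(2.3, schedule, cfg, seed=0,
                               expected_value=True)
    tab = sim.pair_table
    restudy = tab[tab.condition == "restudy"]
    # accuracy strictly increasing in activation within a single branch
    srt = restudy.sort_values("a_success")
    assert srt.predicted_accuracy.is_monotonic_increasing
    assert ((tab.predicted_accuracy >= 0) & (tab.predicted_accuracy <= 1)).all()
    with pytest.raises(ValueError):
        cfg.replace(sigma=0.0)


def test_restudy_cells_invariant_to_we(cfg, schedule):
    """The extra w_e cost applies to retrieval only."""
    sims = [simulate_participant(2.0, schedule, cfg.replace(w_e=w), seed=5,
                                 expected_value=True)
            for w in (0.0, 0.3)]
    for freq in ("HF", "LF"):
        assert sims[0].condition_accuracy[(freq, "restudy")] == \
            pytest.approx(sims[1].condition_accuracy[(freq, "restudy")])
    # ...while a test cell does move
    assert sims[0].condition_accuracy[("LF", "test")] != \
        pytest.approx(sims[1].condition_accuracy[("LF", "test")])


def test_lf_test_accuracy_monotone_in_capacity(cfg, schedule):
    accs = [simulate_participant(d, schedule, cfg, seed=9,
                                 expected_value=True)
            .condition_accuracy[("LF", "test")]
            for d in (0.8, 1.4, 2.0, 2.6, 3.2)]
    assert all(b >= a - 1e-9 for a, b in zip(accs, accs[1:]))


def test_resource_accounting_in_trial_log(cfg, schedule):
    sim = simulate_participant(1.2, schedule, cfg, seed=3)
    log = sim.trial_log
    practice = log[log.phase == "practice"]
    spent = practice[["charge_attempt", "charge_extra",
                      "charge_re_encode"]].sum(axis=1)
    assert (spent <= practice.wm_before + 1e-9).all()
    assert (practice.wm_before <= cfg.capacity_for(1.2) + 1e-9).all()


def test_low_capacity_lf_reencoding_truncated(cfg, schedule):
    """Low-WM participants get less re-encoding on LF than HF test trials."""
    sim = simulate_participant(2.3 - 0.59, schedule, cfg, seed=11)
    log = sim.trial_log
    tests = log[(log.phase == "practice") & (log.condition == "test")
                & log.success]
    if not len(tests[tests.frequency == "LF"]):
        pytest.skip("no successful LF test trials at this seed")
    assert tests[tests.frequency == "LF"].charge_re_encode.mean() < \
        tests[tests.frequency == "HF"].charge_re_encode.mean()


def test_expected_value_mode_is_deterministic_and_carries_branches(
        cfg, schedule):
    a = simulate_participant(2.0, schedule, cfg, seed=1, expected_value=True)
    b = simulate_participant(2.0, schedule, cfg, seed=1, expected_value=True)
    pd.testing.assert_frame_equal(a.pair_table, b.pair_table)
    tests = a.pair_table[a.pair_table.condition == "test"]
    assert (tests.a_success >= tests.a_fail).all()
    assert ((tests.p_success > 0) & (tests.p_success < 1)).all()


def test_matched_mode_uses_given_practice_accuracy(cfg, schedule):
    pa = {"HF": 0.8, "LF": 0.6}
    sim = simulate_participant(2.0, schedule, cfg, seed=1, practice_acc=pa,
                               expected_value=True)
    tests = sim.pair_table[sim.pair_table.condition == "test"]
    for freq, p in pa.items():
        assert (tests[tests.frequency == freq].p_success == p).all()
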