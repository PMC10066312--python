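"""d-prime scoring, regression models, simple slopes, ratio control."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from sacmem.stats import (
    dprime,
    fit_glmm,
    flag_low_1back,
    practice_ratio,
    ratio_controlled_fit,
    simple_slopes,
    wm_capacity_score,
)
from sacmem.stats import testing_effect_slopes as slopes_at_wm_levels
from sacmem.synth import GeneratorSpec, gen_cohort


class TestDprime:
    def test_chance_performance_is_zero(self):
        assert dprime(50, 50, 50, 50, correction="none") == pytest.approx(0.0)

    def test_hand_computed_quantiles(self):
        # hit rate 0.8413 ~ Phi(1), FA 0.1587 ~ Phi(-1): d' ~ 2
        d = dprime(8413, 1587, 1587, 8413, correction="none")
        assert d == pytest.approx(2.0, abs=1e-3)

    def test_loglinear_correction_hand_evaluation(self):
        d = dprime(18, 0, 0, 18)
        expected = norm.ppf(18.5 / 19) - norm.ppf(0.5 / 19)
        assert d == pytest.approx(expected, rel=1e-12)

    def test_extreme_rate_without_correction_raises(self):
        with pytest.raises(ValueError):
            dprime(18, 0, 0, 18, correction="none")

    def test_empty_class_raises(self):
        with pytest.raises(ValueError):
            dprime(0, 0, 3, 15)

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            dprime(-1, 5, 2, 3)


class TestCapacityScore:
    def test_mean_and_order_invariance(self):
        assert wm_capacity_score(2.0, 2.0) == 2.0
        assert wm_capacity_score(1.0, 3.0) == 2.0
        assert wm_capacity_score(3.0, 1.0) == wm_capacity_score(1.0, 3.0)

    def test_sum_aggregate(self):
        assert wm_capacity_score(1.0, 3.0, aggregate="sum") == 4.0

    def test_low_1back_flagged_for_exclusion(self):
        assert flag_low_1back(0.9)
        assert not flag_low_1back(1.2)


@pytest.fixture(scope="module")
def cohort():
    return gen_cohort(GeneratorSpec(n_participants=40, seed=17))


def test_stratified_models_have_expected_terms(cohort):
    trials, *_ = cohort
    hf = fit_glmm(trials, model="two_way", stratum="HF", standardized=False)
    assert list(hf.term) == ["(Intercept)", "Condition", "WM", "Condition:WM"]
    with pytest.raises(ValueError):
        fit_glmm(trials, model="three_way", stratum="HF")


def test_simple_slope_identities(cohort):
    trials, *_ = cohort
    coefs = fit_glmm(trials, model="two_way", stratum="LF",
                     standardized=False)
    fit = coefs.attrs["fit"]
    sl = simple_slopes(fit, {"lo": 1.7, "hi": 2.9})
    b_c = float(coefs.loc[coefs.term == "Condition", "b"].iloc[0])
    b_cw = float(coefs.loc[coefs.term == "Condition:WM", "b"].iloc[0])
    # linear-predictor identity: slope difference = (hi - lo) * interaction
    hi = float(sl.loc[sl["at"] == "hi", "b"].iloc[0])
    lo = float(sl.loc[sl["at"] == "lo", "b"].iloc[0])
    assert hi - lo == pytest.approx((2.9 - 1.7) * b_cw, rel=1e-9)
    assert hi == pytest.approx(b_c + 2.9 * b_cw, rel=1e-9)


def test_zero_interaction_gives_identical_slopes(cohort):
    trials, *_ = cohort
    coefs = fit_glmm(trials, model="two_way", stratum="LF",
                     standardized=False)
    fit = coefs.attrs["fit"]
    j = fit.names.index("Condition:WM")
    fit.beta[j] = 0.0  # no moderation by construction
    sl = simple_slopes(fit, {"-1 SD": 1.7, "+1 SD": 2.9})
    assert sl.b.iloc[0] == pytest.approx(sl.b.iloc[1])


def test_simple_slopes_requires_interaction_term(cohort):
    trials, *_ = cohort
    coefs = fit_glmm(trials, model="main", standardized=False)
    with pytest.raises(ValueError):
        simple_slopes(coefs.attrs["fit"], {"+1 SD": 2.9})


def test_slopes_at_wm_levels_run(cohort):
    trials, *_ = cohort
    sl = slopes_at_wm_levels(trials, stratum="LF")
    assert set(sl["at"]) == {"-1 SD", "+1 SD"}
    # higher WM should show the larger testing effect in LF
    assert float(sl.loc[sl["at"] == "+1 SD", "b"].iloc[0]) > \
        float(sl.loc[sl["at"] == "-1 SD", "b"].iloc[0])


class TestRatioControl:
    def test_constant_ratio_leaves_slopes_unchanged(self, cohort):
        trials, _, practice, _ = cohort
        const = practice.copy()
        # identical practice pattern for everyone: ratio collinear with
        # the intercept, so non-intercept terms match the plain model
        template = const[const.participant == "p000"]
        frames = []
        for pid in const.participant.unique():
            f = template.copy()
            f["participant"] = pid
            frames.append(f)
        const = pd.concat(frames, ignore_index=True)
        plain = fit_glmm(trials, model="three_way", standardized=False)
        controlled = ratio_controlled_fit(trials, const, standardized=False)
        merged = plain.merge(controlled, on="term", suffixes=("_p", "_c"))
        non_int = merged[~merged.term.isin(["(Intercept)"])]
        np.testing.assert_allclose(non_int.b_p, non_int.b_c, atol=1e-3)

    def test_zero_lf_accuracy_adjusted_and_flagged(self):
        practice = pd.DataFrame(dict(
            participant=["a"] * 4, frequency=["HF", "HF", "LF", "LF"],
            pair=[0, 1, 0, 1], practice_correct=[1, 1, 0, 0]))
        r = practice_ratio(practice)
        assert r.ratio_adjusted.iloc[0]
        assert np.isfinite(r.hf_lf_practice_ratio.iloc[0])

    def test_three_way_sign_survives_ratio_control(self, cohort):
        trials, _, practice, truth = cohort
        controlled = ratio_controlled_fit(trials, practice,
                                          standardized=False)
        b3 = float(controlled.loc[
            controlled.term == "Condition:Frequency:WM", "b"].iloc[0])
        assert np.sign(b3) == np.sign(
            truth["coeffs"]["Condition:Frequency:WM"])
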