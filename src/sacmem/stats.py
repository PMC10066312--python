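"""Behavioral analysis: d-prime scoring and the regression stage.

WM capacity is the mean of the 2-back and 3-back d' scores
(d' = Z_Hit - Z_FalseAlarm, log-linear correction for extreme rates).
Final-test accuracy is analyzed with mixed-effects logistic regressions
(random intercept per participant): a main-effect model, a two-way
interaction model, and a three-way interaction model over Condition
(test vs restudy), Frequency (HF vs LF) and WM capacity, plus
frequency-stratified follow-ups, simple slopes of the testing effect at
WM capacity mean +/- 1 SD, and a robustness refit controlling for each
participant's HF/LF practice-accuracy ratio.

Factors are treatment-coded by default (test = 1, HF = 1) with WM entered
on its raw d' scale, which is the coding that reproduces the reported
coefficient pattern; sum-to-zero +/-0.5 coding with centered WM is
available via ``coding="sum"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .glmm import GLMMResult, fit_logistic_glmm

MODELS = ("main", "two_way", "three_way")


# --------------------------------------------------------------------------
# signal-detection scoring
# --------------------------------------------------------------------------

def dprime(
    hits: int,
    misses: int,
    false_alarms: int,
    correct_rejections: int,
    correction: str = "loglinear",
) -> float:
    """d' = Phi^-1(hit rate) - Phi^-1(false-alarm rate) from counts.

    The log-linear correction adds 0.5 to every cell and 1 to each
    denominator, keeping the quantiles finite at perfect or zero rates.
    """
    for v in (hits, misses, false_alarms, correct_rejections):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n_target = hits + misses
    n_lure = false_alarms + correct_rejections
    if n_target == 0 or n_lure == 0:
        raise ValueError("need at least one target and one lure trial")
    if correction == "loglinear":
        hr = (hits + 0.5) / (n_target + 1)
        fr = (false_alarms + 0.5) / (n_lure + 1)
    elif correction == "none":
        hr = hits / n_target
        fr = false_alarms / n_lure
        if hr in (0.0, 1.0) or fr in (0.0, 1.0):
            raise ValueError(
                "extreme rate without correction yields infinite d'")
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return float(norm.ppf(hr) - norm.ppf(fr))


def wm_capacity_score(
    dprime_2back: float, dprime_3back: float, aggregate: str = "mean"
) -> float:
    """Composite WM capacity from the 2- and 3-back d' scores.

    1-back blocks are excluded (near-ceiling accuracy).  The mean is the
    default aggregation; ``aggregate="sum"`` is available.
    """
    if not (np.isfinite(dprime_2back) and np.isfinite(dprime_3back)):
        raise ValueError("d' inputs must be finite")
    if aggregate == "mean":
        return float((dprime_2back + dprime_3back) / 2.0)
    if aggregate == "sum":
        return float(dprime_2back + dprime_3back)
    raise ValueError(f"unknown aggregate {aggregate!r}")


def flag_low_1back(dprime_1back: float, threshold: float = 1.0) -> bool:
    """Exclusion flag: 1-back d' below threshold marks low engagement."""
    return bool(dprime_1back < threshold)


# --------------------------------------------------------------------------
# design construction
# --------------------------------------------------------------------------

def _code_predictors(table: pd.DataFrame, coding: str) -> pd.DataFrame:
    df = table.copy()
    if coding == "treatment":
        df["C"] = (df.condition == "test").astype(float)
        df["F"] = (df.frequency == "HF").astype(float)
        df["W"] = df.wm_capacity.astype(float)
    elif coding == "sum":
        df["C"] = np.where(df.condition == "test", 0.5, -0.5)
        df["F"] = np.where(df.frequency == "HF", 0.5, -0.5)
        df["W"] = df.wm_capacity.astype(float) - df.wm_capacity.mean()
    else:
        raise ValueError(f"unknown coding {coding!r}")
    return df


def _model_terms(model: str, stratum: str) -> list[tuple[str, tuple[str, ...]]]:
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if stratum == "all":
        terms = [("Condition", ("C",)), ("Frequency", ("F",)), ("WM", ("W",))]
        if model in ("two_way", "three_way"):
            terms += [("Condition:Frequency", ("C", "F")),
                      ("Condition:WM", ("C", "W")),
                      ("Frequency:WM", ("F", "W"))]
        if model == "three_way":
            terms += [("Condition:Frequency:WM", ("C", "F", "W"))]
    elif stratum in ("HF", "LF"):
        if model == "three_way":
            raise ValueError("three-way model undefined within a stratum")
        terms = [("Condition", ("C",)), ("WM", ("W",))]
        if model == "two_way":
            terms += [("Condition:WM", ("C", "W"))]
    else:
        raise ValueError(f"unknown stratum {stratum!r}")
    return terms


def build_design(
    table: pd.DataFrame,
    model: str,
    stratum: str = "all",
    coding: str = "treatment",
    extra_covariates: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Design matrix, outcome, groups and term names for one model."""
    required = {"participant", "frequency", "condition", "final_correct",
                "wm_capacity"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = _code_predictors(table, coding)
    if stratum in ("HF", "LF"):
        df = df[df.frequency == stratum]
    terms = _model_terms(model, stratum)
    cols = [np.ones(len(df))]
    names = ["(Intercept)"]
    for name, factors in terms:
        col = np.ones(len(df))
        for f in factors:
            col = col * df[f].to_numpy()
        cols.append(col)
        names.append(name)
    for cov in (extra_covariates or []):
        cols.append(df[cov].to_numpy(dtype=float))
        names.append(cov)
    X = np.column_stack(cols)
    y = df.final_correct.to_numpy(dtype=float)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("final_correct must be binary 0/1")
    groups = df.participant.to_numpy()
    return X, y, groups, names


# --------------------------------------------------------------------------
# regression models
# --------------------------------------------------------------------------

def _standardized_refit(X, y, groups, names, **kwargs) -> GLMMResult:
    """Refit with all non-intercept predictors scaled to unit SD."""
    Xs = X.copy()
    for j in range(1, X.shape[1]):
        sd = X[:, j].std()
        if sd > 0:
            Xs[:, j] = X[:, j] / sd
    return fit_logistic_glmm(Xs, y, groups, names, **kwargs)


def fit_glmm(
    table: pd.DataFrame,
    model: str = "three_way",
    stratum: str = "all",
    coding: str = "treatment",
    standardized: bool = True,
    extra_covariates: list[str] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Fit one mixed-effects logistic regression; return the coefficient table.

    Columns mirror the reporting convention: raw log-odds ``b`` with Wald
    ``z`` and ``p``, standardized ``beta`` (all predictors scaled to unit
    SD in a refit) with its 95% CI.  The fitted :class:`GLMMResult` is
    attached as ``df.attrs["fit"]`` for downstream simple-slope analyses.
    """
    X, y, groups, names = build_design(table, model, stratum, coding,
                                       extra_covariates)
    fit = fit_logistic_glmm(X, y, groups, names, **kwargs)
    out = fit.coef_table().rename(columns={
        "ci_low": "ci_low_b", "ci_high": "ci_high_b"})
    if standardized:
        sfit = _standardized_refit(X, y, groups, names, **kwargs)
        ci = 1.959963984540054 * sfit.se
        out["beta"] = sfit.beta
        out["beta_ci_low"] = sfit.beta - ci
        out["beta_ci_high"] = sfit.beta + ci
    out.attrs["fit"] = fit
    out.attrs["model"] = model
    out.attrs["stratum"] = stratum
    return out


def simple_slopes(
    fit: GLMMResult,
    moderator_values: dict[str, float],
    slope_term: str = "Condition",
    interaction_term: str = "Condition:WM",
) -> pd.DataFrame:
    """Testing-effect slope at fixed moderator values (delta method).

    slope(m) = b_condition + m * b_interaction, with variance from the
    fixed-effect covariance block.
    """
    if slope_term not in fit.names or interaction_term not in fit.names:
        raise ValueError(
            f"model lacks {slope_term!r}/{interaction_term!r} terms")
    i = fit.names.index(slope_term)
    j = fit.names.index(interaction_term)
    rows = []
    for label, m in moderator_values.items():
        slope = fit.beta[i] + m * fit.beta[j]
        var = (fit.vcov[i, i] + m * m * fit.vcov[j, j]
               + 2.0 * m * fit.vcov[i, j])
        se = float(np.sqrt(max(var, 0.0)))
        z = slope / se
        rows.append(dict(at=label, moderator=m, b=float(slope), se=se,
                         z=float(z), p=float(2 * norm.sf(abs(z)))))
    return pd.DataFrame(rows)


def testing_effect_slopes(
    table: pd.DataFrame,
    stratum: str = "LF",
    coding: str = "treatment",
    **kwargs,
) -> pd.DataFrame:
    """Condition-by-WM model in one stratum plus slopes at WM mean +/- 1 SD."""
    coefs = fit_glmm(table, model="two_way", stratum=stratum, coding=coding,
                     standardized=False, **kwargs)
    wm = table.groupby("participant").wm_capacity.first()
    mean, sd = float(wm.mean()), float(wm.std(ddof=1))
    if coding == "sum":
        values = {"-1 SD": -sd, "+1 SD": +sd}
    else:
        values = {"-1 SD": mean - sd, "+1 SD": mean + sd}
    return simple_slopes(coefs.attrs["fit"], values)


def practice_ratio(practice_table: pd.DataFrame,
                   continuity: float = 0.5) -> pd.DataFrame:
    """Per-participant HF/LF practice-accuracy ratio.

    A zero LF accuracy leaves the ratio undefined; it is replaced by the
    continuity-adjusted rate ``continuity / (n_LF + continuity)`` and the
    participant flagged.
    """
    rows = []
    for pid, sub in practice_table.groupby("participant"):
        acc = sub.groupby("frequency").practice_correct.agg(["mean", "count"])
        hf = float(acc.loc["HF", "mean"])
        lf = float(acc.loc["LF", "mean"])
        n_lf = float(acc.loc["LF", "count"])
        flagged = lf == 0.0
        if flagged:
            lf = continuity / (n_lf + continuity)
        rows.append(dict(participant=pid, hf_lf_practice_ratio=hf / lf,
                         ratio_adjusted=flagged))
    return pd.DataFrame(rows)


def ratio_controlled_fit(
    table: pd.DataFrame,
    practice_table: pd.DataFrame,
    coding: str = "treatment",
    **kwargs,
) -> pd.DataFrame:
    """Three-way model controlling for the HF/LF practice-accuracy ratio."""
    ratios = practice_ratio(practice_table)
    merged = table.merge(
        ratios[["participant", "hf_lf_practice_ratio"]], on="participant",
        how="left", validate="many_to_one")
    if merged.hf_lf_practice_ratio.isna().any():
        raise ValueError("practice ratios missing for some participants")
    # a ratio constant across participants is absorbed by the intercept;
    # keep the model full-rank and note the drop
    extra = ["hf_lf_practice_ratio"]
    if float(np.std(merged.hf_lf_practice_ratio)) < 1e-12:
        extra = []
    out = fit_glmm(merged, model="three_way", stratum="all", coding=coding,
                   extra_covariates=extra, **kwargs)
    out.attrs["ratio_dropped_constant"] = not extra
    return out
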