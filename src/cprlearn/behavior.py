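"""Behavioral summaries and posterior predictive checks.

Trials are conditioned on how much the two others (or migration) removed
on the *previous* trial: a moderate decrease of 2-4 fish ("preserve") vs a
sharp decrease of 6 fish ("deplete"); decreases of 5 are excluded from the
classification. The depletion-reaction score contrasts the mean chosen net
size after sharp vs moderate decreases; posterior predictive checks pair
observed conditional choice frequencies with the fitted model's
one-step-ahead probabilities conditioned on the same history.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fitting import FitResult
from .models import ModelParams, ModelSpec, prepare_subject, run_model
from .task import DEFAULT_CONFIG, TaskConfig

__all__ = [
    "session_length_summary",
    "choice_frequency_summary",
    "classify_preceding_decrease",
    "DepletionReactionSummary",
    "depletion_reaction",
    "social_weight_escalation_correlation",
    "PpcReport",
    "posterior_predictive_check",
    "export_rpe_regressors",
]

MODERATE = "moderate"   # previous others/migration decrease of 2-4 fish
LARGE = "large"         # previous decrease of 6 fish


def session_length_summary(dataset: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean and s.d. of trials per session.

    Session lengths are averaged within subject first, then aggregated
    across subjects per condition.
    """
    lengths = (
        dataset.groupby(["condition", "subject_id", "session"], sort=True)
        .size()
        .rename("n_trials")
        .reset_index()
    )
    per_subject = lengths.groupby(["condition", "subject_id"])["n_trials"].mean()
    return (
        per_subject.groupby("condition")
        .agg(mean="mean", sd="std")
        .reset_index()
    )


def choice_frequency_summary(dataset: pd.DataFrame) -> pd.DataFrame:
    """Per-condition relative frequency of each net size (sums to 1)."""
    counts = (
        dataset.groupby(["condition", "own_choice"]).size().rename("count").reset_index()
    )
    counts["frequency"] = counts.groupby("condition")["count"].transform(
        lambda c: c / c.sum()
    )
    return counts


def classify_preceding_decrease(outflow_prev: float) -> str | None:
    """Class of the previous trial's others/migration extraction."""
    if 2 <= outflow_prev <= 4:
        return MODERATE
    if outflow_prev == 6:
        return LARGE
    return None


def _with_preceding_class(dataset: pd.DataFrame) -> pd.DataFrame:
    """Annotate trials with the class of the preceding trial's outflow."""
    df = dataset.sort_values(["subject_id", "session", "trial"]).copy()
    grp = df.groupby(["subject_id", "session"])
    prev_outflow = grp["outflow"].shift(1)
    df["prev_class"] = prev_outflow.map(
        lambda x: None if pd.isna(x) else classify_preceding_decrease(x)
    )
    return df


@dataclass(frozen=True)
class DepletionReactionSummary:
    """Per-subject mean net size after large vs moderate decreases."""

    table: pd.DataFrame  # subject_id, condition, mean_after_large,
                         # mean_after_moderate, difference


def depletion_reaction(dataset: pd.DataFrame) -> DepletionReactionSummary:
    """Mean chosen net size after sharp (6) vs moderate (2-4) decreases.

    The difference (large minus moderate) is positive when subjects
    escalate harvesting after others deplete. Subjects lacking trials in
    one class get a missing value.
    """
    df = _with_preceding_class(dataset)
    df = df[df["prev_class"].notna()]
    means = (
        df.groupby(["subject_id", "condition", "prev_class"])["own_choice"]
        .mean()
        .unstack("prev_class")
        .reindex(columns=[LARGE, MODERATE])
    )
    means.columns = ["mean_after_large", "mean_after_moderate"]
    means["difference"] = means["mean_after_large"] - means["mean_after_moderate"]
    return DepletionReactionSummary(means.reset_index())


def social_weight_escalation_correlation(
    fits: Sequence[FitResult], dataset: pd.DataFrame
) -> float:
    """Pearson correlation of θs with the depletion-reaction difference.

    Returns NaN when fewer than 3 complete subjects or when either
    variable has zero variance.
    """
    summary = depletion_reaction(dataset).table.set_index("subject_id")
    theta = {f.subject_id: f.estimates.theta_s for f in fits}
    rows = [
        (theta[s], summary.loc[s, "difference"])
        for s in summary.index
        if s in theta and np.isfinite(summary.loc[s, "difference"])
    ]
    if len(rows) < 3:
        raise ValueError("need at least 3 subjects with complete data")
    x, y = map(np.asarray, zip(*rows))
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class PpcReport:
    """Observed vs model-predicted conditional choice distributions.

    One row per (condition, preceding-decrease class, net size), with the
    observed choice frequency and the mean one-step-ahead model
    probability over the same trials.
    """

    table: pd.DataFrame


def _per_trial_model_quantities(
    fits: Sequence[FitResult],
    dataset: pd.DataFrame,
    config: TaskConfig,
) -> pd.DataFrame:
    """One-step-ahead probabilities and RPEs for every trial under each
    subject's fitted model."""
    by_subject = {f.subject_id: f for f in fits}
    frames = []
    for sid, sub in dataset.groupby("subject_id", sort=True):
        if sid not in by_subject:
            raise ValueError(f"no fit available for subject {sid}")
        f = by_subject[sid]
        sub = sub.sort_values(["session", "trial"])
        comps, _ = run_model(sub, f.spec, f.estimates, config)
        rec = sub.reset_index(drop=True)
        probs = np.array([c.probs for c in comps])
        rec[["p_net1", "p_net2", "p_net3"]] = probs
        rec["rpe_chosen"] = [c.rpe_chosen for c in comps]
        frames.append(rec)
    return pd.concat(frames, ignore_index=True)


def posterior_predictive_check(
    fits: Sequence[FitResult],
    dataset: pd.DataFrame,
    config: TaskConfig = DEFAULT_CONFIG,
) -> PpcReport:
    """Pair observed conditional choice frequencies with fitted-model
    one-step-ahead probabilities, by preceding-decrease class."""
    df = _with_preceding_class(_per_trial_model_quantities(fits, dataset, config))
    df = df[df["prev_class"].notna()]
    rows = []
    for (cond, cls), g in df.groupby(["condition", "prev_class"], sort=True):
        n = len(g)
        for j, net in enumerate((1, 2, 3)):
            rows.append(
                {
                    "condition": cond,
                    "prev_class": cls,
                    "net_size": net,
                    "observed_frequency": float((g["own_choice"] == net).mean()),
                    "predicted_probability": float(g[f"p_net{net}"].mean()),
                    "n_trials": n,
                }
            )
    return PpcReport(pd.DataFrame(rows))


def export_rpe_regressors(
    fits: Sequence[FitResult],
    dataset: pd.DataFrame,
    config: TaskConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Trial-wise chosen-option prediction errors as a modulator table.

    One row per trial: subject, session, trial, model kind and the RPE of
    the chosen option under the subject's fitted model (the social or
    sustainability variant per condition), usable as a parametric
    modulator column.
    """
    df = _per_trial_model_quantities(fits, dataset, config)
    by_subject = {f.subject_id: f.spec.kind for f in fits}
    out = df[["subject_id", "session", "trial", "rpe_chosen"]].copy()
    out.insert(3, "model", out["subject_id"].map(by_subject))
    return out
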