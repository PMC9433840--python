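"""Model- and parameter-recovery analyses on simulated agents.

Model recovery: simulate agents from each generating model, fit every
candidate model to each simulated run, identify the winner by lowest BIC,
and tabulate the identification fractions as a confusion matrix. Parameter
recovery: simulate-then-refit sweeps reporting per-parameter mean bias and
RMSE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .comparison import bic
from .fitting import DEFAULT_N_STARTS, fit_subject
from .models import ModelParams, ModelSpec, prepare_subject
from .synth import OthersDistribution, generate_agent_dataset, preserving_stream_policy
from .task import DEFAULT_CONFIG, TaskConfig

__all__ = ["ConfusionMatrix", "model_recovery", "parameter_recovery"]

logger = logging.getLogger(__name__)


def _pooled_q0(data: pd.DataFrame, config: TaskConfig) -> np.ndarray:
    """Cohort-pooled initial expectations: first-trial choice frequencies
    over all subjects and sessions, scaled by four.

    Simulated recovery cohorts share one prior by construction, so the
    pooled estimate avoids overfitting the 16 noisy first trials of each
    subject (the per-subject plug-in rule remains the default for fitting
    heterogeneous behavioral data).
    """
    first = data[data["trial"] == 1]["own_choice"]
    counts = first.value_counts().reindex(config.net_sizes, fill_value=0)
    return 4.0 * counts.to_numpy(dtype=float) / len(first)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Generating-model × identified-model fractions; rows sum to one."""

    generating: tuple[str, ...]
    candidates: tuple[str, ...]
    fractions: np.ndarray
    n_runs: dict[str, int]
    n_excluded: dict[str, int]
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.fractions, index=list(self.generating), columns=list(self.candidates)
        )


def _identify(scores: Mapping[str, float], ks: Mapping[str, int]) -> str:
    """Lowest BIC wins; ties break toward the simpler model, then name."""
    return min(scores, key=lambda m: (scores[m], ks[m], m))


def model_recovery(
    specs: Sequence[ModelSpec],
    generating_params: Mapping[str, ModelParams],
    n_runs: int = 50,
    config: TaskConfig = DEFAULT_CONFIG,
    seed: int | None = None,
    condition: str = "social",
    n_starts: int = DEFAULT_N_STARTS,
    dist: OthersDistribution | None = None,
    stream_policy="preserving",
    q0_mode: str = "pooled",
) -> ConfusionMatrix:
    """Confusion matrix of BIC-based model identification.

    For each generating model, ``n_runs`` agents are simulated against
    surrogate streams (stock-conditional by default, the calibrated study
    condition) and every candidate model is fit to each run. ``q0_mode``
    "pooled" estimates the shared initial expectations from the whole
    simulated cohort; "per_subject" applies the individual plug-in rule.
    Runs where any candidate fit fails to converge are excluded and
    counted.
    """
    if stream_policy == "preserving":
        stream_policy = preserving_stream_policy()
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    kinds = tuple(s.kind for s in specs)
    gen_kinds = tuple(generating_params)
    ks = {s.kind: s.k for s in specs}
    ss = np.random.SeedSequence(seed)
    frac = np.zeros((len(gen_kinds), len(kinds)))
    n_used: dict[str, int] = {}
    n_excl: dict[str, int] = {}
    for gi, (gen, gchild) in enumerate(zip(gen_kinds, ss.spawn(len(gen_kinds)))):
        data = generate_agent_dataset(
            ModelSpec(gen),
            generating_params[gen],
            n_subjects=n_runs,
            condition=condition,
            config=config,
            seed=gchild,
            dist=dist,
            subject_prefix=f"{gen[:3].upper()}",
            stream_policy=stream_policy,
        )
        q0 = _pooled_q0(data, config) if q0_mode == "pooled" else None
        fit_seed_root = np.random.SeedSequence(
            int(gchild.generate_state(1)[0] % (2**31))
        )
        wins = np.zeros(len(kinds))
        used = excluded = 0
        subjects = sorted(data["subject_id"].unique())
        for sid, schild in zip(subjects, fit_seed_root.spawn(len(subjects))):
            prep = prepare_subject(data[data["subject_id"] == sid], config, q0=q0)
            fit_seed = int(schild.generate_state(1)[0] % (2**31))
            scores: dict[str, float] = {}
            ok = True
            for spec in specs:
                f = fit_subject(spec, prep, n_starts, fit_seed, config)
                if not f.converged:
                    ok = False
                    break
                scores[spec.kind] = float(bic(f.loglik, spec.k, f.n_obs))
            if not ok:
                excluded += 1
                continue
            wins[kinds.index(_identify(scores, ks))] += 1
            used += 1
        if used == 0:
            raise RuntimeError(f"all runs excluded for generator {gen!r}")
        if excluded:
            logger.warning("%s: excluded %d non-converged runs", gen, excluded)
        frac[gi] = wins / used
        n_used[gen] = used
        n_excl[gen] = excluded
    return ConfusionMatrix(gen_kinds, kinds, frac, n_used, n_excl, seed)


def parameter_recovery(
    spec: ModelSpec,
    param_grid: Sequence[ModelParams],
    n_reps: int = 10,
    config: TaskConfig = DEFAULT_CONFIG,
    seed: int | None = None,
    condition: str = "social",
    n_starts: int = DEFAULT_N_STARTS,
    stream_policy="preserving",
    q0_mode: str = "pooled",
) -> pd.DataFrame:
    """Simulate-then-refit sweep: mean bias and RMSE per free parameter.

    One row per (grid point, parameter) with the generating value, the
    mean fitted value, bias and RMSE over ``n_reps`` simulated agents.
    Stream and Q0 handling as in :func:`model_recovery`.
    """
    if stream_policy == "preserving":
        stream_policy = preserving_stream_policy()
    ss = np.random.SeedSequence(seed)
    rows = []
    for point_idx, (params, child) in enumerate(zip(param_grid, ss.spawn(len(param_grid)))):
        data = generate_agent_dataset(
            spec, params, n_subjects=n_reps, condition=condition,
            config=config, seed=child, stream_policy=stream_policy,
        )
        q0 = _pooled_q0(data, config) if q0_mode == "pooled" else None
        fit_root = np.random.SeedSequence(int(child.generate_state(1)[0] % (2**31)))
        subjects = sorted(data["subject_id"].unique())
        est = {p: [] for p in spec.free_parameter_names}
        for sid, schild in zip(subjects, fit_root.spawn(len(subjects))):
            prep = prepare_subject(data[data["subject_id"] == sid], config, q0=q0)
            f = fit_subject(
                spec, prep,
                n_starts, int(schild.generate_state(1)[0] % (2**31)), config,
            )
            for p in spec.free_parameter_names:
                est[p].append(getattr(f.estimates, p))
        for p in spec.free_parameter_names:
            e = np.asarray(est[p])
            true = getattr(params, p)
            rows.append(
                {
                    "grid_point": point_idx,
                    "parameter": p,
                    "true_value": true,
                    "mean_estimate": e.mean(),
                    "median_estimate": float(np.median(e)),
                    "bias": e.mean() - true,
                    "median_bias": float(np.median(e) - true),
                    "rmse": float(np.sqrt(np.mean((e - true) ** 2))),
                    "n_reps": len(e),
                }
            )
    return pd.DataFrame(rows)
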