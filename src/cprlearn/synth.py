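"""Synthetic inputs: pre-recorded surrogate streams and simulated agents.

The co-players (or the migration outflow, in the nonsocial framing) are
emulated as i.i.d. draws of the per-trial total extraction from the
empirical distribution of the pre-recorded opponents: totals 2-6 with
probabilities 3.4%, 2.7%, 34.9%, 25.3% and 33.7%. Totals are split over
the two opponents uniformly over the valid compositions in {1,2,3}².

Participants are emulated as learning agents: a model from the family in
:mod:`cprlearn.models` equipped with the softmax policy over its learned
values, playing the standard 16 sessions of up to 8 trials against freshly
sampled surrogate streams. The stream semantics are identical in the social
and nonsocial conditions (only the framing differs), mirroring the task.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .models import ModelParams, ModelSpec, softmax_policy
from .task import DEFAULT_CONFIG, TaskConfig, allocate_catch, replenish

__all__ = [
    "OthersDistribution",
    "SurrogateStream",
    "sample_others_total",
    "split_total",
    "sample_stream",
    "preserving_stream_policy",
    "generate_agent_dataset",
    "default_cohort",
    "DATASET_COLUMNS",
]

DATASET_COLUMNS = [
    "subject_id",
    "condition",
    "session",
    "trial",
    "stock_pre",
    "own_choice",
    "own_payoff",
    "other1_catch",
    "other2_catch",
    "outflow",
    "stock_post_catch",
    "stock_next",
    "terminal",
]

# agent default initial expectations: uniform first-trial frequencies
# scaled by four (the Q0 rule applied to an uninformative prior)
_Q0_UNIFORM = np.full(3, 4.0 / 3.0)


@dataclass(frozen=True)
class OthersDistribution:
    """Distribution of the two others' total extraction per trial."""

    support: tuple[int, ...] = (2, 3, 4, 5, 6)
    probabilities: tuple[float, ...] = (0.034, 0.027, 0.349, 0.253, 0.337)

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities)
        if len(self.support) != len(p):
            raise ValueError("support/probability length mismatch")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be non-negative and sum to 1")
        for t in self.support:
            if not any(a + b == t for a in (1, 2, 3) for b in (1, 2, 3)):
                raise ValueError(f"total {t} is not a sum of two net sizes")


@dataclass(frozen=True)
class SurrogateStream:
    """Pre-recorded opponents for one session: per-trial totals and splits."""

    totals: np.ndarray   # (T,)
    splits: np.ndarray   # (T, 2) entries in {1,2,3}, rows sum to totals
    seed: int | None = None


def sample_others_total(
    dist: OthersDistribution, rng: np.random.Generator, size: int | None = None
):
    """Draw i.i.d. per-trial totals from the surrogate distribution."""
    return rng.choice(dist.support, size=size, p=dist.probabilities)


_COMPOSITIONS = {
    t: [(a, t - a) for a in (1, 2, 3) if 1 <= t - a <= 3] for t in range(2, 7)
}


def split_total(total: int, rng: np.random.Generator) -> tuple[int, int]:
    """Split a total over two opponents, uniform over valid compositions."""
    try:
        comps = _COMPOSITIONS[int(total)]
    except KeyError:
        raise ValueError(f"total {total} outside support 2..6") from None
    return comps[rng.integers(len(comps))]


def sample_stream(
    dist: OthersDistribution,
    n_trials: int,
    rng: np.random.Generator,
) -> SurrogateStream:
    """Sample one session's surrogate stream."""
    totals = sample_others_total(dist, rng, size=n_trials)
    splits = np.array([split_total(t, rng) for t in totals])
    return SurrogateStream(totals=np.asarray(totals), splits=splits)


def preserving_stream_policy(reserve: int = 10):
    """Stock-conditional surrogate policy: others hold back at low stock.

    Returns a hook mapping (sampled total, pre-trial stock) to the total
    the pre-recorded others actually extract: ``min(total, max(2,
    stock - reserve))``. At a full lake this never binds, so the marginal
    totals distribution stays the calibrated one; near depletion the
    others leave fish behind, emulating the stock-adaptive play of the
    pre-recorded opponents that keeps sessions alive.
    """
    def policy(total: int, stock_pre: int) -> int:
        return min(int(total), max(2, stock_pre - reserve))

    return policy


def _reinforcements(
    spec: ModelSpec,
    params: ModelParams,
    own_cf: np.ndarray,
    chosen_idx: int,
    own_payoff: int,
    others_payoffs: tuple[int, int],
    sustainable_catch: int,
) -> np.ndarray:
    """Per-option reinforcements for one trial's realized outcome.

    Mirrors :func:`cprlearn.models.reinforcement_matrix`: the social /
    inequity comparison is evaluated on the chosen option's realized
    outcome (unchosen fictive reinforcements anchor at their hypothetical
    payoff), while the sustainability term applies per option.
    """
    outflow = others_payoffs[0] + others_payoffs[1]
    m = outflow / 2.0
    sust = -np.abs(sustainable_catch - own_cf - outflow)
    if spec.kind in ("null", "rw"):
        return own_cf.copy()
    if spec.kind == "nonsocial":
        return (1 - params.theta_n) * own_cf + params.theta_n * sust
    soc_term = own_cf.copy()
    soc_term[chosen_idx] = own_payoff - m
    if spec.kind == "social":
        return (1 - params.theta_s) * own_cf + params.theta_s * soc_term
    if spec.kind == "fs":
        others = np.asarray(others_payoffs, dtype=float)
        c = own_cf.copy()
        c[chosen_idx] = (
            own_payoff
            - params.delta_dis * np.maximum(others - own_payoff, 0.0).sum()
            - params.delta_adv * np.maximum(own_payoff - others, 0.0).sum()
        )
        return (1 - params.theta_s) * own_cf + params.theta_s * c
    if spec.kind == "hybrid":
        comp = (1 - params.xi) * soc_term + params.xi * sust
        return (1 - params.theta) * own_cf + params.theta * comp
    raise ValueError(f"unknown model kind {spec.kind!r}")


def _simulate_subject(
    subject_id: str,
    condition: str,
    spec: ModelSpec,
    params: ModelParams,
    dist: OthersDistribution,
    config: TaskConfig,
    rng: np.random.Generator,
    q0: np.ndarray,
    stream_policy=None,
) -> pd.DataFrame:
    """One agent playing all sessions; returns trial-log rows."""
    net_sizes = np.asarray(config.net_sizes)
    own_cf = net_sizes.astype(float)
    rows = []
    for session in range(1, config.sessions_per_subject + 1):
        stream = sample_stream(dist, config.max_trials_per_session, rng)
        stock = config.capacity
        q = q0.astype(float).copy()
        for t in range(config.max_trials_per_session):
            if spec.kind == "null":
                probs = np.full(3, 1.0 / 3.0)
            else:
                probs = softmax_policy(q, params.beta)
            own = int(rng.choice(net_sizes, p=probs))
            total = int(stream.totals[t])
            if stream_policy is not None:
                adj = int(stream_policy(total, stock))
                if adj != total:
                    total = adj
                    o1, o2 = split_total(total, rng)
                else:
                    o1, o2 = (int(stream.splits[t, 0]), int(stream.splits[t, 1]))
            else:
                o1, o2 = int(stream.splits[t, 0]), int(stream.splits[t, 1])
            payoffs, post_catch = allocate_catch(stock, (own, o1, o2), rng)
            stock_next = replenish(post_catch, config)
            terminal = stock_next == 0 or t + 1 == config.max_trials_per_session
            # fictive delta-rule update from the realized (recorded) outcome
            r = _reinforcements(
                spec, params, own_cf, own - net_sizes[0], payoffs[0],
                (payoffs[1], payoffs[2]), config.sustainable_catch,
            )
            q = q + params.alpha * (r - q)
            rows.append(
                {
                    "subject_id": subject_id,
                    "condition": condition,
                    "session": session,
                    "trial": t + 1,
                    "stock_pre": stock,
                    "own_choice": own,
                    "own_payoff": payoffs[0],
                    "other1_catch": payoffs[1],
                    "other2_catch": payoffs[2],
                    "outflow": payoffs[1] + payoffs[2],
                    "stock_post_catch": post_catch,
                    "stock_next": stock_next,
                    "terminal": terminal,
                }
            )
            if terminal:
                break
            stock = stock_next
    return pd.DataFrame(rows, columns=DATASET_COLUMNS)


def generate_agent_dataset(
    spec: ModelSpec,
    params: ModelParams,
    n_subjects: int,
    condition: str = "social",
    config: TaskConfig = DEFAULT_CONFIG,
    seed: int | None = None,
    dist: OthersDistribution | None = None,
    subject_prefix: str = "S",
    q0: Sequence[float] | None = None,
    stream_policy=None,
) -> pd.DataFrame:
    """Simulate a cohort of identical-parameter agents.

    Each subject plays ``config.sessions_per_subject`` sessions against
    freshly sampled surrogate streams. Totals are i.i.d. unless a
    ``stream_policy`` hook (e.g. :func:`preserving_stream_policy`) makes
    the surrogates stock-conditional. Fully reproducible under ``seed``.
    """
    if condition not in ("social", "nonsocial"):
        raise ValueError(f"unknown condition {condition!r}")
    params.validate(spec)
    rng = np.random.default_rng(seed)
    q0_arr = _Q0_UNIFORM if q0 is None else np.asarray(q0, dtype=float)
    frames = [
        _simulate_subject(
            f"{subject_prefix}{i + 1:03d}", condition, spec, params, dist
            or OthersDistribution(), config, rng, q0_arr, stream_policy,
        )
        for i in range(n_subjects)
    ]
    return pd.concat(frames, ignore_index=True)


def default_cohort(
    seed: int | None = None,
    config: TaskConfig = DEFAULT_CONFIG,
    n_social: int = 22,
    n_nonsocial: int = 24,
    beta: float = 1.5,
    alpha: float = 0.2,
    weight: float = 0.6,
    stream_policy="preserving",
) -> pd.DataFrame:
    """The default synthetic cohort mirroring the analyzed sample.

    22 social-condition agents generated by the social model and 24
    nonsocial-condition agents generated by the sustainable nonsocial
    model, with homogeneous β=1.5 and moderate learning rate and
    comparison weight. The surrogates use the stock-conditional
    preserving policy, which is what keeps mean session length near the
    study's ~6.5 trials; pass ``stream_policy=None`` for purely i.i.d.
    streams.
    """
    if stream_policy == "preserving":
        stream_policy = preserving_stream_policy()
    ss = np.random.SeedSequence(seed)
    s1, s2 = ss.spawn(2)
    soc = generate_agent_dataset(
        ModelSpec("social"),
        ModelParams(alpha=alpha, beta=beta, theta_s=weight),
        n_social,
        condition="social",
        config=config,
        seed=s1,
        subject_prefix="SOC",
        stream_policy=stream_policy,
    )
    non = generate_agent_dataset(
        ModelSpec("nonsocial"),
        ModelParams(alpha=alpha, beta=beta, theta_n=weight),
        n_nonsocial,
        condition="nonsocial",
        config=config,
        seed=s2,
        subject_prefix="NON",
        stream_policy=stream_policy,
    )
    return pd.concat([soc, non], ignore_index=True)
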