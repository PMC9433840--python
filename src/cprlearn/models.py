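"""Reinforcement-learning models of harvesting behavior.

All learning models share a delta-rule value update with fictive
(counterfactual) updating of every net size each trial, and a softmax
policy. They differ only in how the reinforcement of each option is
constructed from the trial's outcome:

- ``rw``        R_i = OwnPayoff_i  (plain Rescorla-Wagner)
- ``social``    R = (1-θs)·OwnPayoff + θs·SocComp, where SocComp is own
                payoff minus the opponents' mean payoff
- ``nonsocial`` R_i = (1-θn)·OwnPayoff_i + θn·SustComp_i, where SustComp_i
                = -|SustainableCatch - OwnPayoff_i - Outflow| penalizes any
                total extraction away from the stock-preserving level
- ``fs``        like ``social`` but the comparison term follows the
                Fehr-Schmidt inequity-aversion form with advantageous (δ+)
                and disadvantageous (δ-) coefficients
- ``hybrid``    comparison term is (1-ξ)·SocComp + ξ·SustComp, so ξ=0
                recovers the social model and ξ=1 the nonsocial model
- ``null``      uniform choice probability 1/3, no learning

Counterfactual own payoffs equal the net sizes themselves (scarcity
truncation only occurs on a session's terminal trial). Initial values Q0
are a per-subject constant: four times the frequency of each net size in
the first trials of the subject's sessions.

Scope of the comparison terms. A linear per-option social comparison
(i - m for every hypothetical net size i against the others' mean m) would
shift all options' reinforcements equally and cancel in the softmax,
collapsing the social model onto RW for every θs. The social-comparison
and inequity terms are therefore evaluated on the chosen option's realized
outcome only; the unchosen options' fictive reinforcement is their
hypothetical direct payoff (equivalently, their comparison term anchors at
the payoff itself, since (1-θ)i + θi = i). The sustainability term, which
is genuinely option-dependent, applies to all options. All nesting
identities (θ=0 or δ=0 reductions to RW, hybrid ξ∈{0,1} degenerations)
hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .task import DEFAULT_CONFIG, TaskConfig

__all__ = [
    "MODEL_KINDS",
    "ModelSpec",
    "ModelParams",
    "TrialComputation",
    "softmax_policy",
    "initial_values",
    "social_comparison",
    "reinforcement_social",
    "sustainability_component",
    "reinforcement_sustain",
    "fs_comparison",
    "hybrid_reinforcement",
    "update_values",
    "counterfactual_payoffs",
    "PreparedSubject",
    "prepare_subject",
    "run_model",
]

# free parameters per model kind, in canonical order
_FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "null": (),
    "rw": ("alpha", "beta"),
    "social": ("alpha", "beta", "theta_s"),
    "nonsocial": ("alpha", "beta", "theta_n"),
    "fs": ("alpha", "beta", "theta_s", "delta_adv", "delta_dis"),
    "hybrid": ("alpha", "beta", "theta", "xi"),
}
MODEL_KINDS = tuple(_FREE_PARAMS)

# [lo, hi] box constraints; beta's upper bound is a practical cap for
# numerical stability (conceptually it is unbounded above)
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (0.0, 1.0),
    "beta": (0.0, 50.0),
    "theta_s": (0.0, 1.0),
    "theta_n": (0.0, 1.0),
    "theta": (0.0, 1.0),
    "delta_adv": (0.0, 1.0),
    "delta_dis": (0.0, 1.0),
    "xi": (0.0, 1.0),
}


@dataclass(frozen=True)
class ModelSpec:
    """A model family member: its kind and free-parameter bookkeeping.

    ``k`` is the per-subject parameter count used in the BIC penalty; the
    uniform baseline counts one parameter per subject.
    """

    kind: str

    def __post_init__(self) -> None:
        if self.kind not in _FREE_PARAMS:
            raise ValueError(f"unknown model kind {self.kind!r}")

    @property
    def free_parameter_names(self) -> tuple[str, ...]:
        return _FREE_PARAMS[self.kind]

    @property
    def k(self) -> int:
        return max(len(self.free_parameter_names), 1)

    @property
    def bounds(self) -> tuple[tuple[float, float], ...]:
        return tuple(PARAM_BOUNDS[p] for p in self.free_parameter_names)


@dataclass(frozen=True)
class ModelParams:
    """Parameter container shared by all model kinds (unused ones ignored)."""

    alpha: float = 0.0
    beta: float = 0.0
    theta_s: float = 0.0
    theta_n: float = 0.0
    theta: float = 0.0
    delta_adv: float = 0.0
    delta_dis: float = 0.0
    xi: float = 0.0

    def vector(self, spec: ModelSpec) -> np.ndarray:
        return np.array([getattr(self, p) for p in spec.free_parameter_names])

    @classmethod
    def from_vector(cls, spec: ModelSpec, x: Sequence[float]) -> "ModelParams":
        names = spec.free_parameter_names
        if len(x) != len(names):
            raise ValueError("parameter vector length mismatch")
        return cls(**dict(zip(names, map(float, x))))

    def validate(self, spec: ModelSpec) -> None:
        for p in spec.free_parameter_names:
            lo, hi = PARAM_BOUNDS[p]
            v = getattr(self, p)
            if not lo <= v <= hi:
                raise ValueError(f"{p}={v} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class TrialComputation:
    """Per-trial model quantities: pre-choice probabilities, reinforcements
    for all options, the chosen option's prediction error, and the raw
    comparison components."""

    probs: tuple[float, float, float]
    reinforcements: tuple[float, float, float]
    rpe_chosen: float
    soc_comp: tuple[float, float, float]
    sust_comp: tuple[float, float, float]


# ---------------------------------------------------------------------------
# elementary operations


def softmax_policy(q: Sequence[float], beta: float) -> np.ndarray:
    """Softmax choice probabilities p(i) ∝ exp(β·Q(i)), max-shifted."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    z = beta * np.asarray(q, dtype=float)
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def initial_values(
    first_trial_choice_counts: Sequence[int], n_sessions: int
) -> np.ndarray:
    """Initial expectations: first-trial choice frequencies scaled by four.

    The factor four maps frequencies onto the task's payoff range; the
    components therefore always sum to four.
    """
    if n_sessions <= 0:
        raise ValueError("n_sessions must be positive")
    counts = np.asarray(first_trial_choice_counts, dtype=float)
    if counts.sum() != n_sessions:
        raise ValueError("first-trial counts must sum to the session count")
    return 4.0 * counts / n_sessions


def social_comparison(
    own_payoff_per_option: Sequence[float], others_mean_payoff: float
) -> np.ndarray:
    """SocComp(i): own payoff under option i minus the others' mean payoff."""
    return np.asarray(own_payoff_per_option, dtype=float) - others_mean_payoff


def reinforcement_social(own, soc_comp, theta_s):
    """R = (1-θs)·own + θs·SocComp."""
    return (1.0 - theta_s) * np.asarray(own, float) + theta_s * np.asarray(soc_comp, float)


def sustainability_component(own, outflow, sustainable_catch: int = 6):
    """SustComp = -|SustainableCatch - own - outflow|; zero only when total
    extraction hits the stock-preserving level, negative for 'too many' and
    'too few' alike."""
    return -np.abs(sustainable_catch - np.asarray(own, float) - outflow)

def reinforcement_sustain(own, sust_comp, theta_n):
    """R = (1-θn)·own + θn·SustComp."""
    return (1.0 - theta_n) * np.asarray(own, float) + theta_n * np.asarray(sust_comp, float)


def fs_comparison(
    own, others_payoffs: Sequence[float], delta_adv: float, delta_dis: float
):
    """Fehr-Schmidt comparison: own payoff penalized by disadvantageous
    inequity (others ahead, weight δ-) and advantageous inequity (self
    ahead, weight δ+), summed over the two opponents."""
    own = np.asarray(own, dtype=float)
    others = np.asarray(others_payoffs, dtype=float)
    dis = np.maximum(others - own[..., None], 0.0).sum(axis=-1)
    adv = np.maximum(own[..., None] - others, 0.0).sum(axis=-1)
    return own - delta_dis * dis - delta_adv * adv


def hybrid_reinforcement(own, soc_comp, sust_comp, theta, xi):
    """R = (1-θ)·own + θ·[(1-ξ)·SocComp + ξ·SustComp]."""
    comp = (1.0 - xi) * np.asarray(soc_comp, float) + xi * np.asarray(sust_comp, float)
    return (1.0 - theta) * np.asarray(own, float) + theta * comp


def update_values(q, reinforcements, alpha):
    """Delta-rule update of every option (fictive updating)."""
    q = np.asarray(q, dtype=float)
    r = np.asarray(reinforcements, dtype=float)
    return q + alpha * (r - q)


def counterfactual_payoffs(net_sizes: Sequence[int] = (1, 2, 3)) -> np.ndarray:
    """Hypothetical own payoff for each option: the net size itself."""
    return np.asarray(net_sizes, dtype=float)


# ---------------------------------------------------------------------------
# trial-by-trial model evaluation on a subject's data


@dataclass(frozen=True)
class PreparedSubject:
    """A subject's log reshaped for fast likelihood evaluation.

    Arrays are padded to (n_sessions, max_trials, ...) with ``valid``
    masking real trials. ``own_cf`` holds counterfactual own payoffs (the
    net sizes); comparison components are precomputed per option so the
    reinforcement matrix is an affine function of the model parameters.
    """

    subject_id: str
    condition: str
    n_sessions: int
    valid: np.ndarray           # (S, T) bool
    choice_idx: np.ndarray      # (S, T) int, option index 0..2 (-1 invalid)
    own_cf: np.ndarray          # (3,) counterfactual payoffs
    own_payoff: np.ndarray      # (S, T) realized own payoff
    others_mean: np.ndarray     # (S, T) opponents' mean realized payoff
    soc_comp: np.ndarray        # (S, T, 3) printed per-option SocComp
    sust_comp: np.ndarray       # (S, T, 3)
    fs_dis_chosen: np.ndarray   # (S, T) Σ max(other_j - own, 0), realized
    fs_adv_chosen: np.ndarray   # (S, T) Σ max(own - other_j, 0), realized
    q0: np.ndarray              # (3,)
    session_ids: np.ndarray     # (S,)
    trial_numbers: np.ndarray   # (S, T) original trial numbers (-1 invalid)

    @property
    def n_obs(self) -> int:
        return int(self.valid.sum())


def prepare_subject(
    df: pd.DataFrame,
    config: TaskConfig = DEFAULT_CONFIG,
    drop_last_trial: bool = False,
    q0: Sequence[float] | None = None,
) -> PreparedSubject:
    """Precompute per-option reinforcement components for one subject.

    In the nonsocial condition the two "opponents" of the social-family
    models are given outflow/2 each, making social and Fehr-Schmidt models
    computable on migration data (cross-fitting). Q0 defaults to the
    subject's own first-trial choice frequencies scaled by four.
    """
    if df["subject_id"].nunique() != 1:
        raise ValueError("prepare_subject expects a single subject")
    condition = str(df["condition"].iloc[0])
    net_sizes = np.asarray(config.net_sizes)
    df = df.sort_values(["session", "trial"])
    if not df["own_choice"].isin(net_sizes).all():
        bad = df.loc[~df["own_choice"].isin(net_sizes), "own_choice"].iloc[0]
        raise ValueError(f"invalid choice code {bad}")

    sessions = [g for _, g in df.groupby("session", sort=True)]
    n_s = len(sessions)
    max_t = max(len(g) for g in sessions)
    valid = np.zeros((n_s, max_t), dtype=bool)
    choice_idx = np.full((n_s, max_t), -1, dtype=int)
    trial_numbers = np.full((n_s, max_t), -1, dtype=int)
    others = np.zeros((n_s, max_t, 2))
    outflow = np.zeros((n_s, max_t))
    own_payoff = np.zeros((n_s, max_t))
    session_ids = np.array([g["session"].iloc[0] for g in sessions])
    for s, g in enumerate(sessions):
        n_t = len(g)
        valid[s, :n_t] = True
        choice_idx[s, :n_t] = g["own_choice"].to_numpy() - net_sizes[0]
        trial_numbers[s, :n_t] = g["trial"].to_numpy()
        own_payoff[s, :n_t] = g["own_payoff"].to_numpy(dtype=float)
        out = g["outflow"].to_numpy(dtype=float)
        outflow[s, :n_t] = out
        if condition == "social":
            others[s, :n_t, 0] = g["other1_catch"].to_numpy(dtype=float)
            others[s, :n_t, 1] = g["other2_catch"].to_numpy(dtype=float)
        else:
            # migration split evenly over two notional opponents
            others[s, :n_t, :] = out[:, None] / 2.0
        if drop_last_trial and n_t > 1:
            valid[s, n_t - 1] = False

    own_cf = counterfactual_payoffs(net_sizes)
    others_mean = others.mean(axis=-1)
    soc = own_cf[None, None, :] - others_mean[..., None]
    sust = -np.abs(
        config.sustainable_catch - own_cf[None, None, :] - outflow[..., None]
    )
    diff = others - own_payoff[..., None]  # (S,T,2)
    fs_dis_chosen = np.maximum(diff, 0.0).sum(axis=-1)
    fs_adv_chosen = np.maximum(-diff, 0.0).sum(axis=-1)

    if q0 is None:
        first = choice_idx[:, 0]
        counts = np.bincount(first, minlength=len(net_sizes)).astype(float)
        q0_arr = 4.0 * counts / n_s
    else:
        q0_arr = np.asarray(q0, dtype=float)

    return PreparedSubject(
        subject_id=str(df["subject_id"].iloc[0]),
        condition=condition,
        n_sessions=n_s,
        valid=valid,
        choice_idx=choice_idx,
        own_cf=own_cf,
        own_payoff=own_payoff,
        others_mean=others_mean,
        soc_comp=soc,
        sust_comp=sust,
        fs_dis_chosen=fs_dis_chosen,
        fs_adv_chosen=fs_adv_chosen,
        q0=q0_arr,
        session_ids=session_ids,
        trial_numbers=trial_numbers,
    )


def _scatter_chosen(base: np.ndarray, prep: PreparedSubject, values: np.ndarray) -> np.ndarray:
    """Overwrite each trial's chosen-option entry of (S,T,3) ``base``."""
    out = base.copy()
    idx = np.where(prep.valid, prep.choice_idx, 0)
    np.put_along_axis(out, idx[..., None], values[..., None], axis=-1)
    return out


def _social_term(prep: PreparedSubject) -> np.ndarray:
    """Comparison term of the social model, (S,T,3): chosen option carries
    the realized SocComp, unchosen anchor at their hypothetical payoff."""
    base = np.broadcast_to(prep.own_cf, prep.soc_comp.shape).astype(float)
    return _scatter_chosen(base, prep, prep.own_payoff - prep.others_mean)


def reinforcement_matrix(
    prep: PreparedSubject, spec: ModelSpec, params: ModelParams
) -> np.ndarray:
    """Per-trial, per-option reinforcements R (S, T, 3) for a model."""
    own = np.broadcast_to(prep.own_cf, prep.soc_comp.shape).astype(float)
    kind = spec.kind
    if kind in ("null", "rw"):
        return own
    if kind == "social":
        return (1 - params.theta_s) * own + params.theta_s * _social_term(prep)
    if kind == "nonsocial":
        return (1 - params.theta_n) * own + params.theta_n * prep.sust_comp
    if kind == "fs":
        c_chosen = (
            prep.own_payoff
            - params.delta_dis * prep.fs_dis_chosen
            - params.delta_adv * prep.fs_adv_chosen
        )
        c = _scatter_chosen(own, prep, c_chosen)
        return (1 - params.theta_s) * own + params.theta_s * c
    if kind == "hybrid":
        comp = (1 - params.xi) * _social_term(prep) + params.xi * prep.sust_comp
        return (1 - params.theta) * own + params.theta * comp
    raise ValueError(f"unknown model kind {kind!r}")


def _value_trajectory(
    r: np.ndarray, q0: np.ndarray, alpha: float
) -> np.ndarray:
    """Pre-choice values Q_{t-1} per trial, resetting to Q0 each session.

    The fictive delta rule makes reinforcements independent of the value
    state, so the update is the linear recursion
    Q_t = (1-α)·Q_{t-1} + α·R_t, evaluated as an IIR filter per session.
    """
    n_s, n_t, n_opt = r.shape
    if alpha == 0.0:
        return np.broadcast_to(q0, r.shape).copy()
    # y_t = alpha*r_t + (1-alpha)*y_{t-1}, y_0 = q0
    zi = ((1 - alpha) * np.broadcast_to(q0, (n_s, 1, n_opt))).copy()
    post, _ = lfilter([alpha], [1.0, -(1.0 - alpha)], r, axis=1, zi=zi)
    q_prev = np.empty_like(post)
    q_prev[:, 0, :] = q0
    q_prev[:, 1:, :] = post[:, :-1, :]
    return q_prev


def log_likelihood(
    prep: PreparedSubject, spec: ModelSpec, params: ModelParams
) -> float:
    """Total log-likelihood of the subject's choices under the model."""
    if spec.kind == "null":
        return -prep.n_obs * np.log(3.0)
    r = reinforcement_matrix(prep, spec, params)
    q_prev = _value_trajectory(r, prep.q0, params.alpha)
    z = params.beta * q_prev
    z = z - z.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    idx = np.where(prep.valid, prep.choice_idx, 0)
    chosen_logp = np.take_along_axis(logp, idx[..., None], axis=-1)[..., 0]
    return float(chosen_logp[prep.valid].sum())


def run_model(
    prep: PreparedSubject | pd.DataFrame,
    spec: ModelSpec,
    params: ModelParams,
    config: TaskConfig = DEFAULT_CONFIG,
) -> tuple[list[TrialComputation], float]:
    """Trial-by-trial model pass: pre-choice probabilities, reinforcements,
    and the chosen option's prediction error, plus the total log-likelihood.

    Values are re-initialized to Q0 at every session start (each session is
    a fresh environment).
    """
    if isinstance(prep, pd.DataFrame):
        prep = prepare_subject(prep, config)
    params.validate(spec)
    if spec.kind == "null":
        r = reinforcement_matrix(prep, spec, params)
        q_prev = np.broadcast_to(prep.q0, r.shape)
        probs = np.full(r.shape, 1.0 / 3.0)
    else:
        r = reinforcement_matrix(prep, spec, params)
        q_prev = _value_trajectory(r, prep.q0, params.alpha)
        z = params.beta * q_prev
        z = z - z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=-1, keepdims=True)
    out: list[TrialComputation] = []
    loglik = 0.0
    for s, t in zip(*np.nonzero(prep.valid)):
        c = prep.choice_idx[s, t]
        out.append(
            TrialComputation(
                probs=tuple(probs[s, t]),
                reinforcements=tuple(r[s, t]),
                rpe_chosen=float(r[s, t, c] - q_prev[s, t, c]),
                soc_comp=tuple(prep.soc_comp[s, t]),
                sust_comp=tuple(prep.sust_comp[s, t]),
            )
        )
        loglik += np.log(probs[s, t, c])
    return out, float(loglik)
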