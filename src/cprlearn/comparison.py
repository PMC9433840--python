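"""Model-evaluation metrics and random-effects Bayesian model selection.

Per-subject goodness of fit is summarized by the Bayesian Information
Criterion, BIC = -2·loglik + k·ln(n); -BIC/2 approximates the log model
evidence and feeds a variational random-effects scheme that estimates
group-level model frequencies (expected multinomial parameters) and
exceedance probabilities (probability that each model is the most
prevalent), with a uniform Dirichlet prior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma

from .fitting import FitResult

__all__ = [
    "bic",
    "bayes_factor_category",
    "mcfadden_r2",
    "EvidenceMatrix",
    "evidence_from_fits",
    "balanced_accuracy",
    "BmsResult",
    "bms_random_effects",
]


def bic(loglik: float, k: int, n_obs: int):
    """BIC = -2·loglik + k·ln(n). Lower is better."""
    n = np.asarray(n_obs)
    if (n < 1).any():
        raise ValueError("n_obs must be >= 1")
    if np.any(np.asarray(k) < 0):
        raise ValueError("k must be >= 0")
    return -2.0 * np.asarray(loglik) + np.asarray(k) * np.log(n)


def bayes_factor_category(delta_bic: float) -> str:
    """Evidence category for a BIC difference: |Δ| ≤ 2 inconclusive,
    2 < |Δ| ≤ 10 positive, |Δ| > 10 very strong."""
    a = abs(delta_bic)
    if a <= 2:
        return "inconclusive"
    if a <= 10:
        return "positive"
    return "very strong"


def mcfadden_r2(loglik_model: float, loglik_null: float) -> float:
    """McFadden pseudo-R² = 1 - loglik_model/loglik_null."""
    if loglik_null == 0:
        raise ValueError("degenerate null log-likelihood of 0")
    if loglik_null > 0:
        raise ValueError("null log-likelihood must be negative")
    return 1.0 - loglik_model / loglik_null


@dataclass(frozen=True)
class EvidenceMatrix:
    """Subjects × models grid of fit summaries.

    ``log_evidence`` is the -BIC/2 approximation used for model selection.
    """

    subject_ids: tuple[str, ...]
    model_kinds: tuple[str, ...]
    loglik: np.ndarray      # (N, M)
    bic: np.ndarray         # (N, M)
    n_obs: np.ndarray       # (N,)
    k: np.ndarray           # (M,)
    conditions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.bic.shape != (len(self.subject_ids), len(self.model_kinds)):
            raise ValueError("evidence matrix must be rectangular")
        if not np.isfinite(self.bic).all():
            raise ValueError("non-finite evidence entries")

    @property
    def log_evidence(self) -> np.ndarray:
        return -self.bic / 2.0

    def aggregate_bic(self) -> pd.Series:
        """Summed per-subject BIC per model."""
        return pd.Series(self.bic.sum(axis=0), index=list(self.model_kinds))


def evidence_from_fits(fit_lists: Mapping[str, Sequence[FitResult]]) -> EvidenceMatrix:
    """Assemble an evidence matrix from per-model fit-result lists."""
    kinds = tuple(fit_lists)
    by_model = {
        m: {f.subject_id: f for f in fits} for m, fits in fit_lists.items()
    }
    subjects = sorted(set.intersection(*(set(d) for d in by_model.values())))
    if not subjects:
        raise ValueError("no subject fitted under every model")
    ll = np.array([[by_model[m][s].loglik for m in kinds] for s in subjects])
    n = np.array([by_model[kinds[0]][s].n_obs for s in subjects])
    k = np.array([by_model[m][subjects[0]].spec.k for m in kinds])
    scores = bic(ll, k[None, :], n[:, None])
    conds = tuple(by_model[kinds[0]][s].condition for s in subjects)
    return EvidenceMatrix(tuple(subjects), kinds, ll, scores, n, k, conds)


DEFAULT_CLASS_MAP = {
    "social": "social",
    "fs": "social",
    "nonsocial": "nonsocial",
    "rw": "nonsocial",
}
# each model's opposite-class counterpart in the pairwise decision rule
_COUNTERPART = {"social": "nonsocial", "nonsocial": "social", "fs": "rw", "rw": "fs"}


def balanced_accuracy(
    evidence: EvidenceMatrix,
    subject_conditions: Sequence[str] | None = None,
    model_class_map: Mapping[str, str] = DEFAULT_CLASS_MAP,
    counterparts: Mapping[str, str] = _COUNTERPART,
) -> dict[str, float]:
    """Condition-classification balanced accuracy per model.

    Model M of class c predicts that a subject is in condition c iff
    BIC(M) < BIC(M's opposite-class counterpart). Balanced accuracy is the
    mean of the two per-condition correct rates, insensitive to the
    social/nonsocial group-size imbalance.
    """
    conds = np.asarray(subject_conditions if subject_conditions is not None
                       else evidence.conditions)
    if len(conds) != len(evidence.subject_ids):
        raise ValueError("one condition per subject required")
    out: dict[str, float] = {}
    cols = {m: j for j, m in enumerate(evidence.model_kinds)}
    for m in evidence.model_kinds:
        if m not in model_class_map:
            if m == "null":
                continue
            raise ValueError(f"model {m!r} has no class mapping")
        other = counterparts[m]
        if other not in cols:
            continue
        cls = model_class_map[m]
        opp = "nonsocial" if cls == "social" else "social"
        predicts_cls = evidence.bic[:, cols[m]] < evidence.bic[:, cols[other]]
        rates = []
        for cond, want in ((cls, True), (opp, False)):
            mask = conds == cond
            if mask.sum() == 0:
                raise ValueError(f"no subjects in condition {cond!r}")
            rates.append(np.mean(predicts_cls[mask] == want))
        out[m] = float(np.mean(rates))
    return out


@dataclass(frozen=True)
class BmsResult:
    model_kinds: tuple[str, ...]
    model_frequencies: np.ndarray
    exceedance_probabilities: np.ndarray
    dirichlet_concentrations: np.ndarray
    n_mc_samples: int
    seed: int | None
    converged: bool
    n_iterations: int


def bms_random_effects(
    evidence: EvidenceMatrix | np.ndarray,
    n_mc_samples: int = 1_000_000,
    seed: int | None = None,
    prior_concentration: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> BmsResult:
    """Random-effects (variational Dirichlet) model selection.

    Treats the model generating each subject's data as a random effect
    drawn from a population multinomial with Dirichlet-distributed
    frequencies. Iterates posterior subject-model assignment weights
    u_nk ∝ exp(log-evidence_nk + ψ(α_k) - ψ(Σα)) against concentration
    updates α = α0 + Σ_n u_n until the concentrations move less than
    ``tol``. Exceedance probabilities come from Monte-Carlo draws of the
    fitted Dirichlet.
    """
    if isinstance(evidence, EvidenceMatrix):
        kinds = evidence.model_kinds
        lev = evidence.log_evidence
    else:
        lev = np.asarray(evidence, dtype=float)
        kinds = tuple(f"m{j}" for j in range(lev.shape[1]))
    n_sub, n_mod = lev.shape
    if n_mod < 2:
        raise ValueError("need at least two models")
    lev = lev - lev.max(axis=1, keepdims=True)  # row shifts cancel

    alpha = np.full(n_mod, prior_concentration, dtype=float)
    converged = False
    for it in range(1, max_iter + 1):
        w = lev + digamma(alpha) - digamma(alpha.sum())
        w = w - w.max(axis=1, keepdims=True)
        u = np.exp(w)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = prior_concentration + u.sum(axis=0)
        if np.abs(alpha_new - alpha).max() < tol:
            alpha = alpha_new
            converged = True
            break
        alpha = alpha_new

    freqs = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_mc_samples)
    winners = np.argmax(draws, axis=1)
    xp = np.bincount(winners, minlength=n_mod) / n_mc_samples
    return BmsResult(
        model_kinds=kinds,
        model_frequencies=freqs,
        exceedance_probabilities=xp,
        dirichlet_concentrations=alpha,
        n_mc_samples=n_mc_samples,
        seed=seed,
        converged=converged,
        n_iterations=it,
    )
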