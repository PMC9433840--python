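# cprlearn

Reinforcement-learning models of how people harvest a shared, depletable
resource — and why they over-exploit it when the resource is framed as
common rather than private.

`cprlearn` is a research toolkit for a three-player lake-fishing game: each
trial a player removes 1, 2 or 3 fish while two co-players (or, in a
"private" framing, natural migration) remove 2–6 more; the surviving stock
then grows by ×1.5 (floored) up to a capacity of 16 fish, and a session ends
when the lake is fished out or after 8 trials. A total extraction of 6 fish
per trial keeps the stock stable, so every choice trades personal profit
against sustainability.

The package provides, end to end:

- a deterministic **task engine** for the lake game;
- a **synthetic-data generator**: pre-recorded "opponent"/migration streams
  calibrated to an empirical totals distribution (2–6 fish with frequencies
  3.4 / 2.7 / 34.9 / 25.3 / 33.7 %), and simulated participants as learning
  agents (16 sessions each);
- a family of **trial-by-trial learning models** sharing a softmax policy,
  p_t(i) ∝ exp(β·Q_{t−1}(i)), and a fictive delta rule,
  Q_t(i) = Q_{t−1}(i) + α(R_{i,t} − Q_{t−1}(i)), applied to all three net
  sizes each trial. The models differ in the reinforcement R:
  - **RW** — own payoff only;
  - **social** — R = (1−θs)·OwnPayoff + θs·SocComp, with the social
    comparison SocComp = own payoff − opponents' mean payoff;
  - **nonsocial (sustainable)** — R = (1−θn)·OwnPayoff + θn·SustComp, with
    SustComp = −|6 − own − outflow| penalizing unsustainable *and*
    wasteful totals alike;
  - **FS** — inequity aversion with advantageous/disadvantageous
    coefficients δ⁺, δ⁻;
  - **hybrid** — mixes SocComp and SustComp with a weight ξ ∈ [0,1]
    (ξ=0 ≡ social, ξ=1 ≡ nonsocial);
  - **null** — uniform 1/3 baseline.

  Initial expectations are Q₀(i) = 4·(first-trial frequency of net size i).
- **per-subject maximum-likelihood fitting** (20 seeded starts, bounded
  L-BFGS-B), and trial-wise reward-prediction-error export for use as
  parametric regressors;
- **model comparison**: BIC (−2·logL + k·ln n), Bayes-factor evidence
  categories, McFadden pseudo-R², condition-classification balanced
  accuracy, and random-effects Bayesian model selection (variational
  Dirichlet scheme) with model frequencies and exceedance probabilities;
- **model- and parameter-recovery** harnesses (confusion matrices,
  bias/RMSE sweeps) and **posterior predictive checks** conditioned on how
  much the others removed on the previous trial.

## Worked example

```python
from cprlearn import (default_cohort, fit_population, evidence_from_fits,
                      bms_random_effects, balanced_accuracy, ModelSpec,
                      session_length_summary)

data = default_cohort(seed=7)          # 22 social + 24 nonsocial agents
print(session_length_summary(data))
fits = {k: fit_population(ModelSpec(k), data, n_starts=10, seed=42)
        for k in ("null", "social", "nonsocial", "rw")}
ev = evidence_from_fits(fits)
print((ev.bic / ev.n_obs[:, None]).mean(axis=0))      # BIC per observation
print(bms_random_effects(ev, seed=1).exceedance_probabilities)
print(balanced_accuracy(ev))
```

Output (abridged):

```
condition     mean       sd
nonsocial 6.882812 0.266004
   social 6.534091 0.312635

mean BIC per observation:
  null       2.241
  social     2.092
  nonsocial  2.078
  rw         2.069

balanced accuracy: {'social': 0.712, 'nonsocial': 0.714}
```

Sessions last ≈6.5–6.9 trials (the social-condition lake dies faster), the
uniform baseline costs ≈2.24 BIC per choice while every learning model
improves on it by ≈0.15, and the social/nonsocial model pair classifies a
subject's condition from fit quality alone at ≈71% balanced accuracy. On
this pooled cohort the two-parameter RW model takes the largest share of
the random-effects comparison — parsimony competes hard with the
condition-specific models when evidence is aggregated across both framings.

A command-line interface mirrors the library
(`cprlearn simulate | fit | compare | recover | ppc | export-regressors`);
every output file carries the configuration hash and seed that produced it.

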