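# Methods

## Task model

The environment is a common-pool-resource game: an integer fish stock with
capacity 16 shared by one modeled player and two co-players. Each trial all
three simultaneously demand fish (nets of size 1–3 for the player; the two
others jointly remove 2–6). The surviving stock is multiplied by 1.5,
rounded down, and capped at capacity; a session starts at a full lake and
ends at depletion (post-replenishment stock 0) or after 8 trials. With a
total extraction of 6 per trial the stock is approximately stable; because
of the floor in the growth rule even an exactly-6 total eventually depletes
the lake from capacity, so "6 keeps the stock constant" is treated as a
participant-facing approximation, not an engine invariant.

When the stock cannot cover the total demand, demands are granted in a
seeded random player order, each taking `min(demand, remaining)` until the
lake is empty. The allocation rule matters only on a session's final trial,
so no downstream quantity is sensitive to it; it was chosen because it
conserves fish and is reproducible under a fixed seed.

## Surrogate streams

The two co-players (or, in the private framing, "migration") are emulated
as a pre-recorded stream: per-trial totals drawn i.i.d. from the empirical
distribution (2:3.4%, 3:2.7%, 4:34.9%, 5:25.3%, 6:33.7%), split over the
two opponents uniformly at random over the valid compositions in {1,2,3}²
(the marginal totals distribution does not pin down the per-opponent split;
uniform is the maximum-entropy choice). Social and nonsocial conditions use
identical stream semantics — only the framing differs.

A purely i.i.d. stream, however, cannot reproduce the study-scale session
lengths: its mean total (≈4.83) plus any own choice (≥1) keeps total
extraction near or above 6, and the floor dynamics then kill the lake in
≤5 trials for every agent parameterization we examined. Real pre-recorded
opponents were stock-adaptive. The generator therefore exposes a
stock-conditional hook, `preserving_stream_policy(reserve=10)`: the others'
total is `min(sampled_total, max(2, stock − reserve))`. At a full lake the
cap never binds, so the marginal distribution stays the calibrated one;
near depletion the others hold back, as adaptive opponents do. With
`reserve=10` and the default cohort agents, mean session length is ≈6.5
trials (social ≈6.4 < nonsocial ≈6.8, reproducing the ordering seen with
human players) and each subject contributes ≈105 choices. `reserve` was
calibrated once against the ≈6.5-trial design target and then frozen.
`generate_agent_dataset` keeps the hook off by default; `default_cohort`
(the study-conditions constructor: 22 social-model + 24 nonsocial-model
agents, α=0.2, β=1.5, comparison weight 0.6) turns it on.

## Learning models

All models share the softmax policy p_t(i) ∝ exp(β·Q_{t−1}(i)) (computed
max-shifted for stability) and the delta rule applied *fictively* to all
three options each trial, with values reset to the constant Q₀ at every
session start. Q₀(i) is four times the frequency of net size i among the
subject's first trials (one per session); the factor four scales
frequencies onto the payoff range. Counterfactual own payoffs equal the net
sizes themselves; scarcity truncation is ignored because it can only occur
on a terminal trial, whose update never influences a later choice.

### Scope of the comparison terms

A consequential design point: with a *linear per-option* social comparison,
SocComp(i) = i − m for every hypothetical net size i against the others'
mean m, the θs-weighted term is a common shift across options. Fictive
updating applies the same learning rate to all options and the softmax
depends only on value differences, so the social model would be *exactly*
likelihood-equivalent to RW at every θs — the weight would be
unidentifiable and the model family's social/asocial distinction empty (we
verified the flat likelihood numerically). The package therefore evaluates
the social-comparison and inequity terms on the **chosen option's realized
outcome**: the chosen option's reinforcement is
(1−θs)·OwnPayoff + θs·(OwnPayoff − m), while unchosen options' fictive
reinforcement is their hypothetical direct payoff (equivalently, their
comparison term anchors at the payoff itself, since (1−θ)i + θi = i). The
sustainability term −|6 − i − outflow| is genuinely option-dependent (a
V-shape over net sizes) and applies per option, which is also what makes
the nonsocial model predict preservation after large outflows.

All nesting identities hold exactly as likelihood equalities:
social(θs=0) ≡ RW ≡ nonsocial(θn=0); FS(δ⁺=δ⁻=0) ≡ RW at any θs (with
both coefficients zero the inequity comparison collapses onto the payoff
itself); hybrid(ξ=0) ≡ social and hybrid(ξ=1) ≡ nonsocial. Note that the
social model is *not* nested in FS: matching its comparison inside the FS
form would need a negative advantageous coefficient (being ahead is
rewarding in the social model, penalized in FS), and the δ's are bounded in
[0,1].

The Fehr–Schmidt convention follows the standard assignment: δ⁻ weights
disadvantageous inequity (others ahead), δ⁺ advantageous inequity (self
ahead). The hybrid model uses one free comparison weight θ together with
the mixing weight ξ (k=4): R = (1−θ)·own + θ·[(1−ξ)·SocComp + ξ·SustComp].
The uniform baseline is counted with k=1 per subject in BIC.

### Parameters

| parameter | meaning | range | typical |
|---|---|---|---|
| α | learning rate | [0,1] | 0.2–0.5 |
| β | inverse temperature (per fish-unit value) | [0,50] | ≈1.5 |
| θs / θn / θ | comparison weight | [0,1] | ≈0.6 |
| δ⁺, δ⁻ | advantageous / disadvantageous inequity | [0,1] | 0–0.5 |
| ξ | sustainability mixing weight | [0,1] | condition-dependent |

β's upper bound of 50 is a numerical-stability cap, not a substantive
constraint. Simulated agents use the uniform-prior initialization
Q₀ = (4/3, 4/3, 4/3) — the Q₀ rule applied to an uninformative prior —
because the data-driven rule is circular at generation time.

## Fitting

Each subject is fit independently by maximum likelihood: 20 uniform-random
starting points inside the parameter box (seeded), bounded L-BFGS-B with
finite-difference gradients (ftol 1e-6) from each, best optimum kept, ties
broken by earliest start. All trials with a recorded choice enter the
likelihood, including each session's last trial; `drop_last_trial`
reproduces the exclusion used when the trial-end incentive is absent. A
likelihood evaluation is vectorized across a subject's sessions: because
fictive reinforcements do not depend on the value state, the delta rule is
a linear recursion evaluated as an IIR filter, making a 46-subject,
20-start fit a matter of seconds.

## Recovery harnesses

Model recovery simulates agents from each generating model, fits every
candidate to every run, identifies the winner by lowest BIC (ties toward
the simpler model), and tabulates a confusion matrix. Parameter recovery
reports per-parameter median/mean bias and RMSE over simulate-then-refit
sweeps.

Two harness defaults matter. First, recovery runs on the calibrated
(stock-conditional) streams — the study condition, ≈105 choices per
subject; with i.i.d.-only streams (~62 choices) β's recovery error roughly
doubles for informational, not algorithmic, reasons. Second, the harness
estimates Q₀ from the *pooled* cohort's first trials rather than each
subject's 16: recovery cohorts share one prior by construction, and the
per-subject plug-in rule overfits its 16 observations badly enough to bias
α upward and β downward by several tenths. The per-subject rule remains
the default in `fit_subject`/`fit_population`, where heterogeneous real
subjects are the use case.

At the reference point (α=0.4, β=2, θs=0.6; 46 agents × 16 sessions) the
median bias of every parameter is below 0.05, and social- vs
nonsocial-model agents at strong weights (θ=0.8, β=5) are identified
perfectly. The hybrid weight recovers direction: median ξ≈0 on
social-generated data and ≈0.9 on nonsocial-generated data.

## Model comparison

Per-subject evidence is approximated by −BIC/2. The random-effects scheme
treats each subject's generating model as a draw from a population
multinomial with Dirichlet prior (concentration 1 per model) and iterates
posterior assignment weights u_nk ∝ exp(log-evidence + ψ(α_k) − ψ(Σα))
against concentration updates to a 1e-8 fixed point; exceedance
probabilities are estimated from 10⁶ seeded Dirichlet draws. The scheme is
invariant to per-subject evidence shifts. Bayes-factor categories for
aggregate BIC differences: ≤2 inconclusive, 2–10 positive, >10 very
strong.

Balanced accuracy is a reconstruction (no published definition exists):
model M of class c predicts a subject is in condition c iff BIC(M) beats
M's opposite-class counterpart (pairs social↔nonsocial and FS↔RW); the
score is the mean of the two per-condition correct rates. Real-cohort
values of this statistic are not asserted anywhere.

## Behavioral summaries and predictive checks

Trials are conditioned on the previous trial's others/migration removal:
moderate (2–4 fish), large (6), with 5 excluded. The depletion-reaction
score is the within-subject mean chosen net size after large minus after
moderate decreases. Posterior predictive checks use one-step-ahead
probabilities conditioned on the observed history (not free-running
simulation) and pair them with observed conditional frequencies; on
self-simulated-and-refit cohorts the two agree within Monte-Carlo error.
Trial-wise chosen-option prediction errors R_chosen − Q_{t−1}(chosen) are
exportable as a parametric-modulator table.

What synthetic agents do *not* reproduce: an unconditionally positive
escalation-after-depletion difference. For value-maximizing agents the
modal choice is already the largest net, so the social comparison's
post-depletion devaluation of the chosen option lowers the score, and
post-depletion observations are additionally selected toward early,
high-stock trials (depletion usually ends the session). Escalation in
human groups reflects motives beyond this value model; the fitted models
track the observed *conditional* choice frequencies (the predictive
check), which is the claim the package tests.

## Numerical choices and limitations

- Softmax computed with max-shift; log-likelihoods stay finite for β ≤ 50.
- Optimizer tie-breaks: lowest negative log-likelihood, then earliest
  start index; identification tie-breaks: smaller k, then name.
- Degenerate inputs are contracts, not silent NaNs: zero sessions, empty
  datasets, out-of-range choices and stock-inconsistent logs raise with
  the offending location.
- Synthetic cohorts are i.i.d. agents with homogeneous parameters per
  condition; no hierarchical priors, eligibility traces, choice kernels or
  forgetting are modeled.
- The totals distribution is sampled marginally (or with the preserving
  hook); real pre-recorded opponents had richer temporal structure.
- All randomness flows through explicit integer seeds; identical seeds
  give byte-identical outputs.
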