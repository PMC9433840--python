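"""Learning-model operations, nesting identities, and a brute-force trace oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cprlearn import (
    ModelParams,
    ModelSpec,
    fs_comparison,
    hybrid_reinforcement,
    initial_values,
    prepare_subject,
    reinforcement_social,
    reinforcement_sustain,
    run_model,
    social_comparison,
    softmax_policy,
    sustainability_component,
    update_values,
)
from cprlearn.models import log_likelihood


class TestSoftmax:
    def test_symmetry_and_zero_beta(self):
        assert np.allclose(softmax_policy((5, 5, 5), 3.0), [1 / 3] * 3)
        assert np.allclose(softmax_policy((1, 9, -4), 0.0), [1 / 3] * 3)

    def test_direct_evaluation(self):
        p = softmax_policy((1, 2, 3), 1.0)
        assert np.allclose(p, [0.09003057, 0.24472847, 0.66524096], atol=1e-6)

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            softmax_policy((1, 2, 3), -0.1)

    def test_numerically_stable_at_large_beta(self):
        p = softmax_policy((100.0, 200.0, 300.0), 50.0)
        assert np.isfinite(p).all() and abs(p.sum() - 1) < 1e-12

    @given(
        q=st.tuples(*[st.floats(-5, 5) for _ in range(3)]),
        b1=st.floats(0, 10),
        b2=st.floats(0, 10),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_normalizes_and_beta_sharpens_argmax(self, q, b1, b2):
        lo, hi = sorted([b1, b2])
        p_lo, p_hi = softmax_policy(q, lo), softmax_policy(q, hi)
        assert abs(p_lo.sum() - 1) < 1e-12
        best = int(np.argmax(q))
        assert p_hi[best] >= p_lo[best] - 1e-12


class TestInitialValues:
    @pytest.mark.parametrize(
        "counts,expected",
        [((4, 8, 4), (1, 2, 1)), ((0, 16, 0), (0, 4, 0)), ((16, 0, 0), (4, 0, 0))],
    )
    def test_scaled_first_trial_frequencies(self, counts, expected):
        assert np.allclose(initial_values(counts, 16), expected)

    @given(
        counts=st.tuples(st.integers(0, 16), st.integers(0, 16), st.integers(0, 16))
    )
    @settings(deadline=None, derandomize=True)
    def test_components_sum_to_four(self, counts):
        n = sum(counts)
        if n == 0:
            return
        assert abs(initial_values(counts, n).sum() - 4.0) < 1e-12

    def test_zero_sessions_rejected(self):
        with pytest.raises(ValueError):
            initial_values((0, 0, 0), 0)


class TestReinforcementComponents:
    def test_social_comparison_arithmetic(self):
        assert social_comparison([3], 2)[0] == 1
        assert social_comparison([2], 2)[0] == 0
        assert social_comparison([1], 3)[0] == -2
        assert np.allclose(social_comparison((1, 2, 3), 2), (-1, 0, 1))

    def test_reinforcement_social_blend(self):
        assert reinforcement_social(2, -1, 0.0) == 2
        assert reinforcement_social(2, -1, 1.0) == -1
        assert reinforcement_social(2, -1, 0.5) == 0.5

    @pytest.mark.parametrize(
        "own,outflow,expected", [(2, 4, 0), (3, 6, -3), (1, 2, -3), (3, 3, 0)]
    )
    def test_sustainability_zero_point_and_penalty(self, own, outflow, expected):
        assert sustainability_component(own, outflow) == expected

    def test_sustainability_never_positive(self, rng):
        for _ in range(100):
            own = rng.integers(1, 4)
            out = rng.integers(2, 7)
            assert sustainability_component(own, out) <= 0

    def test_reinforcement_sustain_blend(self):
        assert reinforcement_sustain(2, 0, 1.0) == 0
        assert reinforcement_sustain(3, -3, 0.5) == 0
        assert reinforcement_sustain(3, -3, 0.0) == 3

    def test_fs_comparison(self):
        assert fs_comparison(2, (2, 2), 0.7, 0.3) == 2
        assert fs_comparison(3, (1, 2), delta_adv=0.5, delta_dis=0) == 1.5
        assert fs_comparison(1, (2, 3), delta_adv=0, delta_dis=0.5) == 1 - 0.5 * 3
        assert fs_comparison(5, (1, 1), 0.0, 0.0) == 5

    def test_hybrid_degenerations(self):
        assert hybrid_reinforcement(2, 1, -3, theta=0.5, xi=0) == reinforcement_social(2, 1, 0.5)
        assert hybrid_reinforcement(2, 1, -3, theta=0.5, xi=1) == reinforcement_sustain(2, -3, 0.5)
        assert hybrid_reinforcement(0, 1, -3, theta=1.0, xi=0.5) == -1

    def test_update_values(self):
        assert np.allclose(update_values((1, 2, 3), (3, 3, 3), 0.0), (1, 2, 3))
        assert np.allclose(update_values((1, 2, 3), (3, 3, 3), 1.0), (3, 3, 3))
        assert np.allclose(update_values((1, 2, 3), (3, 3, 3), 0.5), (2, 2.5, 3))


def _toy_subject(condition="social"):
    """Two sessions, three trials each, hand-specified outcomes."""
    rows = []
    catches = {
        1: [(2, (1, 2)), (3, (3, 3)), (1, (2, 2))],
        2: [(1, (1, 1)), (2, (2, 3)), (3, (1, 2))],
    }
    for sess, trials in catches.items():
        stock = 16
        for t, (own, (o1, o2)) in enumerate(trials, start=1):
            post = stock - own - o1 - o2
            nxt = min(math.floor(1.5 * post), 16)
            rows.append(
                dict(
                    subject_id="T1", condition=condition, session=sess, trial=t,
                    stock_pre=stock, own_choice=own, own_payoff=own,
                    other1_catch=o1, other2_catch=o2, outflow=o1 + o2,
                    stock_post_catch=post, stock_next=nxt, terminal=t == 3,
                )
            )
            stock = nxt
    return pd.DataFrame(rows)


def _trace_social_loglik(df, alpha, beta, theta_s, q0):
    """Independent spreadsheet-style trace of the social model.

    Pure-python delta-rule walk: softmax of beta*Q before each choice,
    chosen option reinforced with (1-th)*payoff + th*(payoff - others
    mean), unchosen options fictively reinforced with their hypothetical
    payoff, all options updated with learning rate alpha; values reset to
    q0 at each session start.
    """
    ll = 0.0
    for _, sess in df.groupby("session"):
        q = list(q0)
        for _, row in sess.iterrows():
            exps = [math.exp(beta * (qi - max(q))) for qi in q]
            probs = [e / sum(exps) for e in exps]
            c = int(row.own_choice) - 1
            ll += math.log(probs[c])
            m = (row.other1_catch + row.other2_catch) / 2
            r = [1.0, 2.0, 3.0]
            r[c] = (1 - theta_s) * row.own_payoff + theta_s * (row.own_payoff - m)
            q = [qi + alpha * (ri - qi) for qi, ri in zip(q, r)]
    return ll


class TestRunModel:
    def test_null_loglik_is_uniform(self, social_dataset):
        sub = social_dataset[social_dataset.subject_id == "S001"]
        _, ll = run_model(sub, ModelSpec("null"), ModelParams())
        assert np.isclose(ll, -len(sub) * np.log(3), atol=1e-12)

    def test_three_trial_trace_matches_brute_force_oracle(self):
        df = _toy_subject()
        alpha, beta, th = 0.37, 1.8, 0.44
        q0 = (1.0, 2.0, 1.0)
        prep = prepare_subject(df, q0=q0)
        ll = log_likelihood(prep, ModelSpec("social"), ModelParams(alpha=alpha, beta=beta, theta_s=th))
        oracle = _trace_social_loglik(df, alpha, beta, th, q0)
        assert abs(ll - oracle) < 1e-10

    def test_trace_oracle_across_parameters(self):
        df = _toy_subject()
        for alpha, beta, th in [(0, 1, 0.5), (1, 0.5, 0.9), (0.5, 0, 0.1), (0.8, 3, 0)]:
            prep = prepare_subject(df, q0=(4 / 3, 4 / 3, 4 / 3))
            ll = log_likelihood(
                prep, ModelSpec("social"), ModelParams(alpha=alpha, beta=beta, theta_s=th)
            )
            oracle = _trace_social_loglik(df, alpha, beta, th, (4 / 3, 4 / 3, 4 / 3))
            assert abs(ll - oracle) < 1e-10

    def test_probs_normalize_and_rpe_consistency(self, social_dataset):
        sub = social_dataset[social_dataset.subject_id == "S002"]
        comps, ll = run_model(
            sub, ModelSpec("social"), ModelParams(alpha=0.4, beta=2, theta_s=0.6)
        )
        assert len(comps) == len(sub)
        for c in comps:
            assert abs(sum(c.probs) - 1) < 1e-12
            assert all(p >= 0 for p in c.probs)
            assert np.isfinite(c.rpe_chosen)
        assert np.isfinite(ll) and ll < 0

    def test_invalid_choice_rejected(self):
        df = _toy_subject()
        df.loc[df.index[0], "own_choice"] = 4
        with pytest.raises(ValueError, match="choice"):
            prepare_subject(df)


class TestNestingIdentities:
    """Exact likelihood equalities between nested family members."""

    def _prep(self, dataset, sid="S001"):
        return prepare_subject(dataset[dataset.subject_id == sid])

    @pytest.mark.parametrize("dataset_fixture", ["social_dataset", "nonsocial_dataset"])
    def test_rw_equals_zero_weight_models(self, dataset_fixture, request):
        prep = self._prep(request.getfixturevalue(dataset_fixture))
        base = dict(alpha=0.35, beta=2.2)
        ll_rw = log_likelihood(prep, ModelSpec("rw"), ModelParams(**base))
        assert ll_rw == log_likelihood(
            prep, ModelSpec("social"), ModelParams(**base, theta_s=0.0)
        )
        assert ll_rw == log_likelihood(
            prep, ModelSpec("nonsocial"), ModelParams(**base, theta_n=0.0)
        )
        # both inequity coefficients zero: comparison collapses onto the
        # payoff itself, so FS reduces to RW at any theta_s
        for th in (0.0, 0.4, 1.0):
            assert ll_rw == pytest.approx(
                log_likelihood(
                    prep,
                    ModelSpec("fs"),
                    ModelParams(**base, theta_s=th, delta_adv=0, delta_dis=0),
                ),
                abs=1e-12,
            )

    def test_hybrid_degenerates_into_social_and_nonsocial(self, social_dataset):
        prep = self._prep(social_dataset)
        base = dict(alpha=0.5, beta=1.7)
        for w in (0.2, 0.8):
            assert log_likelihood(
                prep, ModelSpec("hybrid"), ModelParams(**base, theta=w, xi=0.0)
            ) == pytest.approx(
                log_likelihood(prep, ModelSpec("social"), ModelParams(**base, theta_s=w)),
                abs=1e-12,
            )
            assert log_likelihood(
                prep, ModelSpec("hybrid"), ModelParams(**base, theta=w, xi=1.0)
            ) == pytest.approx(
                log_likelihood(prep, ModelSpec("nonsocial"), ModelParams(**base, theta_n=w)),
                abs=1e-12,
            )

    def test_social_weight_is_identifiable(self, social_dataset):
        """The social weight changes the likelihood (no degeneracy with RW)."""
        prep = self._prep(social_dataset)
        lls = {
            th: log_likelihood(
                prep, ModelSpec("social"), ModelParams(alpha=0.3, beta=2, theta_s=th)
            )
            for th in (0.0, 0.5, 0.9)
        }
        assert len({round(v, 6) for v in lls.values()}) == 3


class TestValueBounds:
    def test_values_stay_in_reinforcement_hull(self, social_dataset):
        """Delta-rule contraction keeps Q inside the hull of Q0 and the
        attainable reinforcements."""
        from cprlearn.models import _value_trajectory, reinforcement_matrix

        prep = prepare_subject(social_dataset[social_dataset.subject_id == "S003"])
        params = ModelParams(alpha=0.7, beta=2, theta_s=0.8)
        r = reinforcement_matrix(prep, ModelSpec("social"), params)
        q = _value_trajectory(r, prep.q0, params.alpha)
        lo = min(prep.q0.min(), r.min()) - 1e-12
        hi = max(prep.q0.max(), r.max()) + 1e-12
        assert (q[prep.valid] >= lo).all() and (q[prep.valid] <= hi).all()


class TestModelSpec:
    @pytest.mark.parametrize(
        "kind,k", [("null", 1), ("rw", 2), ("social", 3), ("nonsocial", 3), ("fs", 5), ("hybrid", 4)]
    )
    def test_parameter_counts(self, kind, k):
        assert ModelSpec(kind).k == k

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("bandit")

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            ModelParams(alpha=1.2).validate(ModelSpec("rw"))
        with pytest.raises(ValueError):
            ModelParams(beta=-1).validate(ModelSpec("rw"))
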