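import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igtrl.models import (
    EVLParams,
    PVLParams,
    choice_probabilities,
    choice_sensitivity_evl,
    choice_sensitivity_pvl,
    decay_update,
    delta_update,
    evl_valence,
    prospect_utility,
    session_loglik,
    simulate_agent,
)
from igtrl.task import DECKS, Session, Trial

from conftest import random_pvl_params
from oracle import naive_session_loglik


class TestProspectUtility:
    def test_hand_checked_values(self):
        assert prospect_utility(0, 0.5, 2) == 0
        assert prospect_utility(100, 0.5, 2) == pytest.approx(10.0)
        assert prospect_utility(-100, 0.5, 2) == pytest.approx(-20.0)

    @given(
        x=st.floats(-2000, 2000),
        alpha=st.floats(0.05, 0.95),
        lam=st.floats(0.05, 4.95),
    )
    def test_sign_matches_outcome(self, x, alpha, lam):
        u = prospect_utility(x, alpha, lam)
        assert np.sign(u) == np.sign(x)

    @given(
        alpha=st.floats(0.05, 0.95),
        lam=st.floats(0.05, 4.95),
        x=st.floats(-1000, 1000),
        dx=st.floats(0.5, 100),
    )
    def test_strictly_increasing_in_outcome(self, alpha, lam, x, dx):
        assert prospect_utility(x + dx, alpha, lam) > prospect_utility(x, alpha, lam)

    @given(x=st.floats(-1000, -1), alpha=st.floats(0.05, 0.95))
    def test_loss_utility_decreases_with_loss_aversion(self, x, alpha):
        assert prospect_utility(x, alpha, 3.0) < prospect_utility(x, alpha, 0.5)

    def test_alpha_one_is_linear(self):
        for x in (-300.0, -7.0, 5.0, 250.0):
            lam = 2.0
            expected = x if x >= 0 else lam * x
            assert prospect_utility(x, 1.0 - 1e-12, lam) == pytest.approx(expected, rel=1e-9)


class TestEVLValence:
    def test_hand_checked(self):
        assert evl_valence(100, -250, 0.5) == pytest.approx(-75.0)

    def test_limits(self):
        assert evl_valence(100, -250, 0.0) == 100
        assert evl_valence(100, -250, 1.0) == -250


class TestLearningRules:
    def test_decay_from_zero(self):
        E = decay_update(np.zeros(4), "B", 10.0, 0.5)
        assert E.tolist() == [0, 10, 0, 0]

    def test_decay_hand_checked(self):
        E = decay_update(np.ones(4), "A", 2.0, 0.5)
        assert E.tolist() == [2.5, 0.5, 0.5, 0.5]

    def test_decay_limit_A_zero(self):
        E = decay_update(np.array([3.0, 1.0, 2.0, 5.0]), "C", 7.0, 0.0)
        assert E.tolist() == [0, 0, 7.0, 0]

    def test_delta_only_chosen_moves(self):
        E0 = np.array([1.0, 2.0, 3.0, 4.0])
        E = delta_update(E0, "C", 10.0, 0.1)
        assert E[2] == pytest.approx(3.0 + 0.1 * 7.0)
        assert E[[0, 1, 3]].tolist() == [1.0, 2.0, 4.0]

    def test_delta_from_zero(self):
        assert delta_update(np.zeros(4), "C", 10.0, 0.1).tolist() == [0, 0, 1.0, 0]

    def test_delta_limits(self):
        E0 = np.array([1.0, 2.0, 3.0, 4.0])
        assert delta_update(E0, "A", 9.0, 1.0)[0] == 9.0
        assert delta_update(E0, "A", 9.0, 0.0).tolist() == E0.tolist()

    def test_invalid_deck_rejected(self):
        with pytest.raises((ValueError, KeyError)):
            decay_update(np.zeros(4), "E", 1.0, 0.5)


class TestChoiceSensitivity:
    def test_pvl_mapping(self):
        assert choice_sensitivity_pvl(0) == 0
        assert choice_sensitivity_pvl(1) == pytest.approx(2.0)
        assert choice_sensitivity_pvl(3) == pytest.approx(26.0)

    @given(c=st.floats(0.01, 4.99), dc=st.floats(0.01, 1.0))
    def test_pvl_strictly_increasing(self, c, dc):
        assert choice_sensitivity_pvl(min(c + dc, 5.0)) > choice_sensitivity_pvl(c)

    def test_evl_mapping(self):
        assert choice_sensitivity_evl(0.0, 57) == 1.0
        assert choice_sensitivity_evl(1.7, 10) == pytest.approx(1.0)
        assert choice_sensitivity_evl(1.0, 100) == pytest.approx(10.0)


class TestChoiceProbabilities:
    def test_uniform_cases(self):
        np.testing.assert_allclose(choice_probabilities(np.zeros(4), 3.0), 0.25)
        np.testing.assert_allclose(choice_probabilities(np.array([5.0, -2, 1, 0]), 0.0), 0.25)

    def test_hand_checked_softmax(self):
        p = choice_probabilities(np.array([1.0, 0, 0, 0]), math.log(3))
        np.testing.assert_allclose(p, [0.5, 1 / 6, 1 / 6, 1 / 6], atol=1e-12)

    @given(
        E=st.lists(st.floats(-50, 50), min_size=4, max_size=4),
        theta=st.floats(0, 10),
        shift=st.floats(-100, 100),
    )
    def test_normalization_and_shift_invariance(self, E, theta, shift):
        E = np.asarray(E)
        p = choice_probabilities(E, theta)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        p2 = choice_probabilities(E + shift, theta)
        np.testing.assert_allclose(p, p2, atol=1e-9)

    def test_extreme_scale_is_stable(self):
        p = choice_probabilities(np.array([700.0, -700.0, 0.0, 0.0]), 1.0)
        assert np.isfinite(p).all() and p.sum() == pytest.approx(1.0)

    def test_unavailable_decks_get_zero(self):
        p = choice_probabilities(np.zeros(4), 1.0, available=("A", "C"))
        assert p[1] == p[3] == 0
        assert p[0] == p[2] == pytest.approx(0.5)

    def test_empty_available_rejected(self):
        with pytest.raises(ValueError):
            choice_probabilities(np.zeros(4), 1.0, available=())


def _random_session(rng, n_trials=80, subject="r"):
    trials = []
    counts = np.zeros(4, int)
    for t in range(1, n_trials + 1):
        avail = [j for j in range(4) if counts[j] < 60]
        j = int(rng.choice(avail))
        counts[j] += 1
        win = int(rng.integers(0, 150))
        loss = -int(rng.integers(0, 300)) if rng.uniform() < 0.4 else 0
        from igtrl.task import Outcome

        trials.append(Trial(subject, t, DECKS[j], Outcome(win, loss)))
    return Session(subject_id=subject, group="g", trials=trials)


class TestSessionLoglik:
    @pytest.mark.parametrize("model", ["evl", "pvl_delta", "pvl_decay"])
    def test_matches_naive_oracle_on_random_cases(self, model):
        rng = np.random.default_rng(1234)
        for _ in range(40):  # 40 cases x 3 models = 120 random cases
            sess = _random_session(rng, n_trials=int(rng.integers(20, 100)))
            if model == "evl":
                params = EVLParams(
                    w=float(rng.uniform(0.05, 0.95)),
                    phi=float(rng.uniform(0.05, 0.95)),
                    c_evl=float(rng.uniform(-3, 3)),
                )
                pdict = {"w": params.w, "phi": params.phi, "c_evl": params.c_evl}
            else:
                params = random_pvl_params(rng)
                pdict = {"alpha": params.alpha, "lam": params.lam, "A": params.A, "c": params.c}
            fast = session_loglik(params, sess, model)
            slow = naive_session_loglik(pdict, sess, model)
            assert fast == pytest.approx(slow, abs=1e-10)
            assert fast <= 0

    def test_closed_form_at_zero_consistency(self, example_session):
        # c -> 0 makes theta -> 0: every choice uniform over 4 decks
        params = PVLParams(alpha=0.5, lam=1.0, A=0.5, c=1e-12)
        ll = session_loglik(params, example_session, "pvl_decay")
        assert ll == pytest.approx(example_session.modeling_horizon * math.log(0.25), abs=1e-6)

    def test_single_trial_is_uniform(self, schedule):
        from igtrl.task import Outcome

        sess = Session("s", "g", [Trial("s", 1, "B", Outcome(100, 0))])
        params = PVLParams(alpha=0.3, lam=2.0, A=0.7, c=2.0)
        assert session_loglik(params, sess, "pvl_decay") == pytest.approx(math.log(0.25))

    def test_label_equivariance(self):
        # permuting deck labels consistently leaves the likelihood unchanged
        rng = np.random.default_rng(9)
        sess = _random_session(rng)
        perm = {"A": "C", "B": "D", "C": "B", "D": "A"}
        permuted = Session(
            subject_id=sess.subject_id,
            group=sess.group,
            trials=[
                Trial(t.subject_id, t.trial_index, perm[t.deck], t.outcome)
                for t in sess.trials
            ],
        )
        params = PVLParams(alpha=0.4, lam=1.5, A=0.6, c=1.2)
        assert session_loglik(params, sess, "pvl_decay") == pytest.approx(
            session_loglik(params, permuted, "pvl_decay"), abs=1e-12
        )

    def test_truncated_session_only_counts_horizon(self):
        seq = ["B"] * 59 + ["A", "C", "D"] * 8 + ["A", "B"] + ["C"] * 14
        from igtrl.task import Outcome

        trials = [Trial("s", i + 1, d, Outcome(50, 0)) for i, d in enumerate(seq)]
        sess = Session("s", "g", trials)
        assert sess.modeling_horizon == 85
        params = PVLParams(alpha=0.5, lam=1.0, A=0.5, c=1e-12)
        assert session_loglik(params, sess, "pvl_decay") == pytest.approx(
            85 * math.log(0.25), abs=1e-6
        )

    def test_unknown_model_rejected(self, example_session):
        with pytest.raises(ValueError, match="unknown model"):
            session_loglik(PVLParams(0.5, 1, 0.5, 1), example_session, "pvl_nope")


class TestSimulateAgent:
    def test_same_seed_identical_session(self, schedule):
        p = PVLParams(alpha=0.4, lam=1.0, A=0.5, c=1.5)
        s1 = simulate_agent(p, schedule, "pvl_decay", seed=77)
        s2 = simulate_agent(p, schedule, "pvl_decay", seed=77)
        assert [(t.deck, t.outcome) for t in s1.trials] == [
            (t.deck, t.outcome) for t in s2.trials
        ]

    def test_random_agent_uniform_deck_frequencies(self, schedule):
        # c ~ 0 => theta ~ 0 => uniform choice; pooled frequencies within 3 SE
        p = PVLParams(alpha=0.5, lam=1.0, A=0.5, c=1e-9)
        counts = np.zeros(4)
        n_total = 0
        for seed in range(100):
            s = simulate_agent(p, schedule, "pvl_decay", n_trials=100, seed=seed)
            counts += s.deck_counts()
            n_total += 100
        freq = counts / n_total
        se = math.sqrt(0.25 * 0.75 / n_total)
        assert (np.abs(freq - 0.25) < 3 * se).all()

    def test_loss_aversion_reduces_bad_deck_choices(self, schedule):
        # higher lambda -> fewer picks from the loss-heavy decks A/B
        def mean_bad(lam):
            props = []
            for seed in range(60):
                p = PVLParams(alpha=0.3, lam=lam, A=0.5, c=1.0)
                s = simulate_agent(p, schedule, "pvl_decay", n_trials=100, seed=1000 + seed)
                counts = s.deck_counts()
                props.append((counts[0] + counts[1]) / counts.sum())
            return np.mean(props)

        assert mean_bad(4.5) < mean_bad(0.06)

    def test_never_overdraws_a_deck(self, schedule):
        p = PVLParams(alpha=0.3, lam=0.1, A=0.9, c=3.0)  # near-deterministic chooser
        s = simulate_agent(p, schedule, "pvl_decay", n_trials=240, seed=3)
        assert (s.deck_counts() <= 60).all()
        assert len(s) == 240

    def test_too_many_trials_rejected(self, schedule):
        p = PVLParams(alpha=0.3, lam=1.0, A=0.5, c=1.0)
        with pytest.raises(ValueError, match="exceeds"):
            simulate_agent(p, schedule, "pvl_decay", n_trials=241)


class TestParamBounds:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(alpha=0.0, lam=1, A=0.5, c=1),
            dict(alpha=0.5, lam=5.0, A=0.5, c=1),
            dict(alpha=0.5, lam=1, A=1.0, c=1),
            dict(alpha=0.5, lam=1, A=0.5, c=-0.1),
        ],
    )
    def test_pvl_bounds_enforced(self, kwargs):
        with pytest.raises(ValueError):
            PVLParams(**kwargs)

    def test_evl_bounds_enforced(self):
        with pytest.raises(ValueError):
            EVLParams(w=0.5, phi=0.5, c_evl=5.0)
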