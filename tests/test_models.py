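import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from igtrl import (
    DECKS,
    MODELS,
    ModelParameters,
    PayoffSchedule,
    choice_probabilities,
    preference_ratio,
    prospect_utility,
    simulate_agent,
    subject_log_likelihood,
)
from igtrl.models import (
    log_choice_probabilities,
    cohort_arrays,
    cohort_log_likelihood,
    _cohort_log_likelihood_numpy,
    sensitivity,
    update_decay,
    update_delta,
    update_perseverance,
)
from igtrl.task import ValidationError

from conftest import make_subject


# ---------------------------------------------------------------------------
# independent straight-line oracle: re-derives the sequential likelihood with
# explicit scalar loops and no shared code path
# ---------------------------------------------------------------------------

def oracle_loglik(model, p: ModelParameters, choices, nets):
    ev = [0.0, 0.0, 0.0, 0.0]
    ps = [0.0, 0.0, 0.0, 0.0]
    theta = 3.0**p.c - 1.0
    total = 0.0
    for ch, x in zip(choices, nets):
        j = "ABCD".index(ch)
        if model == "vpp":
            v = [p.w * ev[d] + (1 - p.w) * ps[d] for d in range(4)]
        else:
            v = list(ev)
        denom = sum(math.exp(theta * v[d] - theta * max(v)) for d in range(4))
        total += theta * v[j] - theta * max(v) - math.log(denom)
        u = abs(x) ** p.alpha if x >= 0 else -p.lam * abs(x) ** p.alpha
        if model == "pvl_decay":
            ev = [p.A * e for e in ev]
            ev[j] += u
        else:
            ev[j] = ev[j] + p.A * (u - ev[j])
        if model == "vpp":
            ps = [p.k * q for q in ps]
            ps[j] += p.ep if x >= 0 else p.en
    return total


def random_params(rng, model) -> ModelParameters:
    kw = dict(
        A=rng.uniform(0, 1),
        alpha=rng.uniform(0, 2),
        c=rng.uniform(0, 5),
        lam=rng.uniform(0, 10),
    )
    if model == "vpp":
        kw.update(
            ep=rng.normal(0, 2), en=rng.normal(0, 2),
            k=rng.uniform(0, 1), w=rng.uniform(0, 1),
        )
    return ModelParameters(**kw)


def random_sequence(rng, max_len=5):
    n = rng.integers(1, max_len + 1)
    choices = [DECKS[i] for i in rng.integers(0, 4, n)]
    nets = [int(x) for x in rng.choice([-260, -250, -50, 90, 100, 200, 210], n)]
    return choices, nets


class TestProspectUtility:
    @pytest.mark.parametrize(
        "x,alpha,lam,expected",
        [(100, 1.0, 1.0, 100.0), (-50, 1.0, 2.0, -100.0), (100, 0.5, 1.0, 10.0), (0, 0.7, 3.0, 0.0)],
    )
    def test_known_values(self, x, alpha, lam, expected):
        assert prospect_utility(x, alpha, lam) == pytest.approx(expected)

    @given(st.floats(-300, 300), st.floats(0.05, 2), st.floats(0, 10))
    def test_sign_and_loss_aversion(self, x, alpha, lam):
        u = prospect_utility(x, alpha, lam)
        if x > 0:
            assert u > 0
        elif x < 0:
            assert u <= 0
            assert abs(u) == pytest.approx(lam * abs(prospect_utility(-x, alpha, 1.0)))


class TestUpdateRules:
    def test_decay_discounts_all_then_adds(self):
        out = update_decay(np.array([1.0, 1, 1, 1]), 0, 2.0, 0.5)
        assert out.tolist() == [2.5, 0.5, 0.5, 0.5]

    def test_decay_zero_rate_erases_history(self):
        out = update_decay(np.array([3.0, 4, 5, 6]), 2, 7.0, 0.0)
        assert out.tolist() == [0, 0, 7.0, 0]

    def test_delta_full_and_zero_learning(self):
        ev = np.array([1.0, 2, 3, 4])
        assert update_delta(ev, 1, 10.0, 1.0)[1] == 10.0
        assert update_delta(ev, 1, 10.0, 0.0).tolist() == ev.tolist()

    def test_delta_leaves_unchosen_untouched(self):
        ev = np.array([1.0, 2, 3, 4])
        out = update_delta(ev, 0, 9.0, 0.3)
        assert out[1:].tolist() == ev[1:].tolist()

    def test_perseverance_full_decay_and_increment(self):
        out = update_perseverance(np.array([5.0, 5, 5, 5]), 1, +100, 0.0, 1.0, -1.0)
        assert out.tolist() == [0, 1.0, 0, 0]

    def test_perseverance_decays_unchosen_decks(self):
        out = update_perseverance(np.array([2.0, 2, 2, 2]), 0, -50, 0.5, 1.0, -1.0)
        assert out.tolist() == [0.0, 1.0, 1.0, 1.0]

    def test_perseverance_degenerate_identity(self):
        p = np.array([1.0, -2, 3, 0.5])
        out = update_perseverance(p, 3, +10, 1.0, 0.0, 0.0)
        assert out.tolist() == p.tolist()

    def test_tie_net_zero_takes_positive_branch(self):
        out = update_perseverance(np.zeros(4), 0, 0, 0.5, 2.0, -9.0)
        assert out[0] == 2.0


class TestChoiceProbabilities:
    def test_zero_consistency_is_uniform(self):
        probs = choice_probabilities(np.array([9.0, -3, 0.5, 100]), c=0.0)
        assert probs.tolist() == [0.25] * 4

    def test_equal_values_uniform_any_c(self):
        probs = choice_probabilities(np.full(4, 2.3), c=3.7)
        np.testing.assert_allclose(probs, 0.25, atol=1e-12)

    def test_hand_computed_half(self):
        # sensitivity ln 3 on values [1,0,0,0]: p_A = 3 / (3 + 3) = 0.5
        c = math.log(1 + math.log(3)) / math.log(3)
        assert sensitivity(c) == pytest.approx(math.log(3))
        probs = choice_probabilities(np.array([1.0, 0, 0, 0]), c=c)
        assert probs[0] == pytest.approx(0.5, abs=1e-12)

    @given(st.lists(st.floats(-50, 50), min_size=4, max_size=4), st.floats(0, 5))
    def test_simplex_and_log_probs_finite(self, values, c):
        probs = choice_probabilities(np.array(values), c)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert (probs >= 0).all()
        logp = log_choice_probabilities(np.array(values), c)
        assert np.isfinite(logp).all() and (logp <= 0).all()

    @given(st.lists(st.floats(-1, 1), min_size=4, max_size=4), st.floats(0, 5))
    def test_strict_positivity_in_representable_range(self, values, c):
        assert (choice_probabilities(np.array(values), c) > 0).all()

    def test_extreme_values_stable(self):
        probs = choice_probabilities(np.array([1e4, 0, 0, 0]), c=5.0)
        assert np.isfinite(probs).all() and probs.sum() == pytest.approx(1.0)


class TestSubjectLogLikelihood:
    def test_uniform_policy_exact(self):
        subj = make_subject(["A"] * 80)
        p = ModelParameters(A=0.5, alpha=0.5, c=0.0, lam=1.0)
        for model in MODELS:
            assert subject_log_likelihood(model, p, subj) == pytest.approx(
                80 * math.log(0.25), abs=1e-12
            )

    def test_two_trial_hand_computation(self):
        # PVL-Delta, A=1, alpha=1, lam=1, c=1 (theta=2); A chosen twice,
        # win 200 then loss 250. Trial 1: EV all zero -> p = 1/4; then
        # EV_A = 200. Trial 2: p_A = e^{400} / (e^{400} + 3).
        subj = make_subject(["A", "A"], nets=[200, -250])
        p = ModelParameters(A=1.0, alpha=1.0, c=1.0, lam=1.0)
        expected = math.log(0.25) + (400 - np.logaddexp(400, math.log(3)))
        got = subject_log_likelihood("pvl_delta", p, subj)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_matches_straight_line_oracle(self):
        rng = np.random.default_rng(12345)
        for _ in range(100):
            choices, nets = random_sequence(rng)
            for model in MODELS:
                p = random_params(rng, model)
                subj = make_subject(choices, nets=nets)
                assert subject_log_likelihood(model, p, subj) == pytest.approx(
                    oracle_loglik(model, p, choices, nets), abs=1e-10
                )

    def test_invalid_trials_skip_likelihood_and_state(self):
        # premature trial in the middle: same result as if it never happened
        clean = make_subject(["A", "B"], nets=[200, -250])
        with_bad = make_subject(["A", "C", "B"], nets=[200, 100, -250],
                                rts=[500.0, 100.0, 500.0])
        p = ModelParameters(A=0.7, alpha=0.6, c=1.2, lam=2.0, ep=0.4, en=-0.3, k=0.5, w=0.6)
        for model in MODELS:
            assert subject_log_likelihood(model, p, with_bad) == pytest.approx(
                subject_log_likelihood(model, p, clean), abs=1e-12
            )

    def test_update_on_invalid_flag_changes_result(self):
        with_bad = make_subject(["A", "A"], nets=[200, -250], rts=[100.0, 500.0])
        p = ModelParameters(A=1.0, alpha=1.0, c=1.0, lam=1.0)
        skip = subject_log_likelihood("pvl_delta", p, with_bad)
        carry = subject_log_likelihood("pvl_delta", p, with_bad, update_on_invalid=True)
        assert skip != carry

    def test_zero_valid_trials_error(self):
        subj = make_subject(["A"], rts=[100.0])
        with pytest.raises(ValidationError):
            subject_log_likelihood("pvl_delta", ModelParameters(0.5, 0.5, 1, 1), subj)

    def test_vpp_nests_pvl_delta(self):
        rng = np.random.default_rng(999)
        for _ in range(50):
            choices, nets = random_sequence(rng, max_len=10)
            subj = make_subject(choices, nets=nets)
            base = random_params(rng, "vpp")
            p = ModelParameters(A=base.A, alpha=base.alpha, c=base.c, lam=base.lam,
                                ep=base.ep, en=base.en, k=base.k, w=1.0)
            assert subject_log_likelihood("vpp", p, subj) == pytest.approx(
                subject_log_likelihood("pvl_delta", p, subj), abs=1e-10
            )

    def test_deck_relabeling_invariance(self):
        rng = np.random.default_rng(4242)
        perm = {"A": "C", "B": "D", "C": "B", "D": "A"}
        choices, nets = random_sequence(rng, max_len=8)
        relabeled = [perm[c] for c in choices]
        for model in MODELS:
            p = random_params(rng, model)
            assert subject_log_likelihood(model, p, make_subject(choices, nets=nets)) == (
                pytest.approx(
                    subject_log_likelihood(model, p, make_subject(relabeled, nets=nets)),
                    abs=1e-12,
                )
            )


class TestCohortLikelihood:
    def test_matches_per_subject_reference(self):
        rng = np.random.default_rng(55)
        subjects, thetas = [], []
        for i in range(7):
            choices, nets = random_sequence(rng, max_len=30)
            rts = [100.0 if rng.random() < 0.1 else 500.0 for _ in choices]
            subjects.append(make_subject(choices, nets=nets, rts=rts, subject_id=f"s{i}"))
            thetas.append(random_params(rng, "vpp").as_array())
        theta = np.array(thetas)
        choices_arr, nets_arr = cohort_arrays(subjects)
        for model in MODELS:
            got = cohort_log_likelihood(model, theta, choices_arr, nets_arr)
            for i, subj in enumerate(subjects):
                if not subj.valid_trials:
                    continue
                want = subject_log_likelihood(
                    model, ModelParameters(*theta[i][:4], *(theta[i][4:] if model == "vpp" else (0, 0, 0, 1))),
                    subj,
                )
                assert got[i] == pytest.approx(want, abs=1e-9)

    def test_numba_and_numpy_paths_agree(self):
        rng = np.random.default_rng(66)
        subjects = [make_subject(*random_sequence(rng, max_len=20), subject_id=f"s{i}")
                    for i in range(4)]
        theta = np.array([random_params(rng, "vpp").as_array() for _ in range(4)])
        choices_arr, nets_arr = cohort_arrays(subjects)
        for model in MODELS:
            np.testing.assert_allclose(
                cohort_log_likelihood(model, theta, choices_arr, nets_arr),
                _cohort_log_likelihood_numpy(model, theta, choices_arr, nets_arr),
                atol=1e-9,
            )


class TestSimulateAgent:
    def test_trial_count_and_validity(self, schedule):
        p = ModelParameters(A=0.3, alpha=0.5, c=1.0, lam=2.0)
        subj = simulate_agent("pvl_delta", p, schedule, np.random.default_rng(3))
        assert len(subj.trials) == 80
        assert all(t.is_valid for t in subj.trials)
        assert all((t.gain > 0) != (t.loss > 0) for t in subj.trials)

    def test_choice_frequencies_match_probabilities(self, schedule):
        # c=0 agent chooses uniformly regardless of state
        p = ModelParameters(A=0.5, alpha=0.5, c=0.0, lam=1.0)
        rng = np.random.default_rng(11)
        counts = np.zeros(4)
        for _ in range(30):
            subj = simulate_agent("pvl_decay", p, schedule, rng)
            for t in subj.trials:
                counts[DECKS.index(t.choice)] += 1
        freqs = counts / counts.sum()
        assert np.abs(freqs - 0.25).max() < 3 * np.sqrt(0.25 * 0.75 / counts.sum())

    def test_loss_averse_learner_prefers_safe_decks(self, schedule):
        p = ModelParameters(A=0.2, alpha=0.5, c=2.0, lam=5.0, w=1.0)
        rng = np.random.default_rng(21)
        ratios = [
            preference_ratio(simulate_agent("vpp", p, schedule, rng)) for _ in range(60)
        ]
        assert np.mean(ratios) > 0.5


def test_parameter_bounds_enforced():
    with pytest.raises(ValidationError):
        ModelParameters(A=1.2, alpha=0.5, c=1.0, lam=1.0)
    with pytest.raises(ValidationError):
        ModelParameters(A=0.5, alpha=0.5, c=6.0, lam=1.0)
    ModelParameters(A=0.5, alpha=0.5, c=1.0, lam=1.0, ep=-30.0, en=40.0)  # eps unbounded
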