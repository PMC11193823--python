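import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rlexpect.agents import (
    choice_prob_ck,
    choice_prob_inverse_gain,
    choice_prob_noisy,
    choice_prob_softmax,
    ck_update,
    dual_rate_update,
    forget_decay,
    pack_trials,
    sequence_loglik,
    simulate_choices,
    trialwise_logprob,
)
from rlexpect.params import DualRateParams
from rlexpect.task import build_schedule, default_design

from .conftest import trials_frame
from . import oracles

unit = st.floats(0.0, 1.0)


class TestElementaryUpdates:
    def test_dual_rate_arithmetic(self):
        assert dual_rate_update(0.5, 1, 0.3, 0.9) == pytest.approx(0.65)
        assert dual_rate_update(0.5, 0, 0.9, 0.1) == pytest.approx(0.45)
        assert dual_rate_update(1.0, 1, 0.7, 0.2) == 1.0  # zero prediction error

    def test_dual_rate_bounds_enforced(self):
        with pytest.raises(ValueError):
            dual_rate_update(1.2, 1, 0.5, 0.5)
        with pytest.raises(ValueError):
            dual_rate_update(0.5, 2, 0.5, 0.5)

    def test_forget_decay(self):
        assert forget_decay([0.8], 0.25)[0] == pytest.approx(0.6)
        np.testing.assert_allclose(forget_decay([0.3, 0.9], 0.0), [0.3, 0.9])
        assert forget_decay([0.3, 0.9], 1.0).sum() == 0.0
        with pytest.raises(ValueError):
            forget_decay([0.5], 1.5)

    def test_ck_update(self):
        np.testing.assert_allclose(ck_update([0.0, 0.0], 0, 0.5), [0.5, 0.0])
        np.testing.assert_allclose(ck_update([0.4, 0.7], 1, 0.0), [0.4, 0.7])
        ck = np.array([0.0, 0.9])
        for _ in range(50):
            prev = ck.copy()
            ck = ck_update(ck, 0, 0.3)
            assert ck[0] > prev[0] and ck[1] < prev[1]
        assert ck[0] > 0.99 and ck[1] < 0.01

    @given(q=unit, phi=unit, a=unit, r=st.sampled_from([0, 1]))
    @settings(max_examples=50, deadline=None)
    def test_values_stay_in_unit_interval(self, q, phi, a, r):
        q2 = dual_rate_update(q, r, a, a)
        assert 0.0 <= q2 <= 1.0
        assert 0.0 <= forget_decay([q2], phi)[0] <= 1.0
        ck = ck_update([q, 1 - q], 0, a)
        assert np.all((0 <= ck) & (ck <= 1))


class TestResponseRules:
    def test_inverse_gain(self):
        assert choice_prob_inverse_gain(0.3, 0.3, 0.0) == 0.5  # exact tie at any beta
        assert choice_prob_inverse_gain(1.0, 0.0, 1.0) == pytest.approx(
            1 / (1 + np.exp(-1)), abs=1e-9
        )
        assert choice_prob_inverse_gain(1.0, 0.0, 1e9) == pytest.approx(0.5, abs=1e-6)

    def test_noisy_rule(self):
        assert choice_prob_noisy(0.9, 0.1, 5.0, 1.0) == 0.5  # pure noise
        assert choice_prob_noisy(1.0, 0.0, 2.0, 0.0) == pytest.approx(
            1 / (1 + np.exp(-2)), abs=1e-9
        )
        assert choice_prob_noisy(0.4, 0.4, 3.0, 0.3) == 0.5
        # noise bounds the attainable probabilities
        assert choice_prob_noisy(1.0, 0.0, 20.0, 0.2) <= 0.9

    def test_kernel_rule(self):
        assert choice_prob_ck(0.2, 0.2, 0.5, 0.5, 0.0, 0.0) == 0.5
        assert choice_prob_ck(1.0, 0.0, 0.7, 0.7, 2.0, 1.0) == pytest.approx(
            1 / (1 + np.exp(-2)), abs=1e-9
        )
        assert choice_prob_ck(0.5, 0.5, 1.0, 0.0, 2.0, -5.0) == pytest.approx(
            1 / (1 + np.exp(5)), abs=1e-9
        )

    def test_reduction_to_plain_softmax(self):
        # xi = 0 and tau = 0 both collapse onto the inverse-temperature rule
        base = choice_prob_softmax(0.8, 0.3, 4.0)
        assert choice_prob_noisy(0.8, 0.3, 4.0, 0.0) == pytest.approx(base)
        assert choice_prob_ck(0.8, 0.3, 0.9, 0.2, 4.0, 0.0) == pytest.approx(base)

    def test_convention_agreement(self):
        # inverse gain beta_g and inverse temperature 1/beta_g give equal rules
        for bg in (0.1, 0.5, 2.0):
            assert choice_prob_inverse_gain(0.9, 0.2, bg) == pytest.approx(
                choice_prob_softmax(0.9, 0.2, 1.0 / bg), abs=1e-12
            )


def _random_theta(model_id, rng):
    if model_id in ("SWo", "SSo"):
        return {
            "alpha_gain": rng.uniform(0, 1),
            "alpha_loss": rng.uniform(0, 1),
            "beta": rng.uniform(0.05, 2.0),
        }
    if model_id in ("SSh", "SWh"):
        return {
            "alpha_gain": rng.uniform(0, 1),
            "alpha_loss": rng.uniform(0, 1),
            "beta": rng.uniform(0, 15.0),
        }
    if model_id == "ES":
        return {
            "alpha_gain": rng.uniform(0, 1),
            "alpha_loss": rng.uniform(0, 1),
            "beta": rng.uniform(0, 15.0),
            "phi": rng.uniform(0, 1),
            "xi": rng.uniform(0, 1),
            "q0": rng.uniform(0, 1),
        }
    return {
        "alpha": rng.uniform(0, 1),
        "phi": rng.uniform(0, 1),
        "beta": rng.uniform(0, 15.0),
        "alpha_ck": rng.uniform(0, 1),
        "tau": rng.uniform(-5, 5),
    }


def _enumeration_trials(design, rng, T=8):
    pair_seq = [1, 2, 1, 3, 2, 1, 3, 2][:T]
    trials = []
    for pid in pair_seq:
        p = design.pair(pid)
        a, b = (p.stim_better, p.stim_worse) if rng.random() < 0.5 else (
            p.stim_worse,
            p.stim_better,
        )
        trials.append(
            {
                "pair": pid,
                "stim_a": a,
                "stim_b": b,
                "reward_if": {a: int(rng.random() < 0.5), b: int(rng.random() < 0.5)},
            }
        )
    return trials


class TestSequenceLikelihood:
    @pytest.mark.parametrize("model_id", ["SWo", "SSh", "ES", "RLfCK"])
    def test_matches_enumeration_oracle(self, design, model_id):
        """Enumerated probabilities of all 2^T sequences sum to 1 and agree
        with exp(sequence_loglik), for random parameter draws."""
        rng = np.random.default_rng(sum(ord(c) for c in model_id))
        for _ in range(3):
            theta = _random_theta(model_id, rng)
            trials = _enumeration_trials(design, rng)
            enum = oracles.enumerate_sequences(model_id, theta, trials)
            assert sum(enum.values()) == pytest.approx(1.0, abs=1e-10)
            for choices, prob in list(enum.items())[::17]:
                rows = [
                    (
                        t["pair"],
                        t["stim_a"] if c == 0 else t["stim_b"],
                        t["reward_if"][t["stim_a"] if c == 0 else t["stim_b"]],
                    )
                    for t, c in zip(trials, choices)
                ]
                from rlexpect.families import get_family

                fam = get_family(model_id)
                vec = np.array([theta[n] for n in fam.param_names])
                ll = sequence_loglik(trials_frame(rows), vec, model_id, design)
                assert np.exp(ll) == pytest.approx(prob, abs=1e-10)

    def test_equal_value_trial_is_chance(self, design):
        table = trials_frame([(1, 1, 1)])
        params = DualRateParams(0.5, 0.5, 1.0)
        assert sequence_loglik(table, params, "SWo", design) == pytest.approx(
            np.log(0.5)
        )

    def test_additivity_over_independent_pairs(self, design):
        rows1 = [(1, 1, 1), (1, 1, 0), (1, 2, 1)]
        rows2 = [(2, 3, 1), (2, 4, 0)]
        params = DualRateParams(0.4, 0.2, 0.3)
        ll_both = sequence_loglik(trials_frame(rows1 + rows2), params, "SWo", design)
        ll1 = sequence_loglik(trials_frame(rows1), params, "SWo", design)
        ll2 = sequence_loglik(trials_frame(rows2), params, "SWo", design)
        assert ll_both == pytest.approx(ll1 + ll2, abs=1e-10)

    def test_two_trial_forward_recursion(self, design):
        # Hand-rolled: trial 1 choose stim 1 (Q=0 both, p=.5), reward 1 ->
        # Q1 = 0.5; trial 2 choose stim 1 again, p = sigmoid((0.5-0)/1).
        table = trials_frame([(1, 1, 1), (1, 1, 0)])
        params = DualRateParams(0.5, 0.1, 1.0)
        expected = np.log(0.5) + np.log(1 / (1 + np.exp(-0.5)))
        assert sequence_loglik(table, params, "SWo", design) == pytest.approx(
            expected, abs=1e-12
        )

    def test_unordered_trials_rejected(self, design):
        table = trials_frame([(1, 1, 1), (1, 1, 0)])
        table.loc[1, "trial"] = 1
        with pytest.raises(ValueError, match="increasing"):
            sequence_loglik(table, DualRateParams(0.5, 0.5, 1.0), "SWo", design)

    def test_foreign_choice_rejected(self, design):
        table = trials_frame([(1, 5, 1)])
        with pytest.raises(ValueError, match="not in pair"):
            sequence_loglik(table, DualRateParams(0.5, 0.5, 1.0), "SWo", design)


class TestSimulation:
    def test_deterministic_given_seed(self, design):
        sched = build_schedule(design, seed=3)
        params = DualRateParams(0.3, 0.1, 0.2)
        a = simulate_choices(params, sched, design, "SWo", seed=11)
        b = simulate_choices(params, sched, design, "SWo", seed=11)
        assert a.equals(b)

    def test_no_learning_is_chance(self, design):
        sched = build_schedule(design, seed=3)
        params = DualRateParams(0.0, 0.0, 0.2)
        sims = [
            simulate_choices(params, sched, design, "SWo", seed=s)["optimal"].mean()
            for s in range(30)
        ]
        rate = np.mean(sims)
        se = np.sqrt(0.25 / (len(sims) * 120))
        assert abs(rate - 0.5) < 4 * se

    def test_learner_beats_chance(self, design):
        from scipy.stats import binomtest

        params = DualRateParams(0.3, 0.1, 0.2)
        rng = np.random.default_rng(99)
        hits, total = 0, 0
        for _ in range(50):
            sched = build_schedule(design, rng)
            sim = simulate_choices(params, sched, design, "SWo", rng)
            hits += int(sim["optimal"].sum())
            total += len(sim)
        assert binomtest(hits, total, 0.5, alternative="greater").pvalue < 1e-3

    def test_recorded_probabilities_match_likelihood(self, design):
        """The generative probabilities equal the likelihood the core assigns
        to the simulated trajectory — simulation and fitting share the model."""
        for model_id, theta in [
            ("SWo", np.array([0.4, 0.2, 0.3])),
            ("ES", np.array([0.4, 0.2, 5.0, 0.1, 0.05, 0.3])),
            ("RLfCK", np.array([0.3, 0.1, 5.0, 0.4, 1.5])),
        ]:
            sched = build_schedule(design, seed=5)
            sim = simulate_choices(theta, sched, design, model_id, seed=6, return_probs=True)
            sim["subject_id"] = 1
            packed = pack_trials(sim, design)
            lp = trialwise_logprob(packed, theta, model_id)
            np.testing.assert_allclose(
                np.exp(lp[0]), sim["p_choice"].to_numpy(), atol=1e-10
            )
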