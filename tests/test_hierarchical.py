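import numpy as np
import pandas as pd
import pytest

import rlexpect as rx
from rlexpect.families import get_family
from rlexpect.hierarchical import (
    GroupLevelState,
    OFFSET_LABELS,
    log_joint,
    sample_posterior,
    subject_posterior_means,
)
from rlexpect.priors import PriorConfig, SamplerConfig

from .conftest import trials_frame
from . import oracles


def _tiny_state(k, seed=0):
    rng = np.random.default_rng(seed)
    return GroupLevelState(
        mu=rng.normal(0, 1, k),
        delta=rng.normal(0, 1, (k, 4)),
        sigma=rng.uniform(0.5, 2.0, k),
    )


class TestLogJoint:
    def test_empty_dataset_is_prior_only(self):
        state = _tiny_state(3)
        priors = PriorConfig.narrow()
        val = log_joint(pd.DataFrame(), state, {}, priors, "SSo")
        expected = 0.0
        for p in range(3):
            expected += priors.mu_logpdf(state.mu[p])
            expected += priors.sigma_logpdf(state.sigma[p])
            for j in range(4):
                expected += priors.delta_logpdf(state.delta[p, j])
        assert val == pytest.approx(expected, abs=1e-10)

    def test_nonpositive_sigma_rejected(self):
        state = _tiny_state(3)
        state.sigma[1] = 0.0
        assert log_joint(pd.DataFrame(), state, {}, PriorConfig.wide(), "SWo") == -np.inf

    def test_matches_density_oracle(self, design):
        """Tiny configuration (2 subjects, few trials) against a hand-rolled
        hierarchical density."""
        fam = get_family("SWo")
        priors = PriorConfig.wide()
        state = _tiny_state(3, seed=4)
        t1 = trials_frame([(1, 1, 1), (1, 1, 0)], subject_id=1, group=0)
        t2 = trials_frame([(2, 3, 1), (2, 4, 0), (2, 3, 1)], subject_id=2, group=50)
        dataset = pd.concat([t1, t2], ignore_index=True)
        xs = {1: np.array([-0.5, -1.0, -2.0]), 2: np.array([0.3, -2.5, -1.0])}

        val = log_joint(dataset, state, xs, priors, "SWo", design)

        def to_oracle(frame):
            out = []
            for r in frame.itertuples():
                p = design.pair(r.pair)
                out.append(
                    {
                        "pair": r.pair,
                        "stim_a": p.stim_better,
                        "stim_b": p.stim_worse,
                        "chosen": r.choice,
                        "reward": r.reward,
                    }
                )
            return out

        expected = oracles.joint_density_oracle(
            "SWo",
            {1: to_oracle(t1), 2: to_oracle(t2)},
            {1: 0, 2: 50},
            xs,
            state.mu,
            {lab: state.delta[:, j] for j, lab in enumerate(OFFSET_LABELS)},
            state.sigma,
            priors.mu_sd,
            priors.delta_sd,
            priors.sigma_logpdf,
            fam.param_names,
            fam.constrain,
        )
        assert val == pytest.approx(expected, abs=1e-8)

    def test_invariant_to_subject_order(self, design):
        priors = PriorConfig.narrow()
        state = _tiny_state(3, seed=5)
        t1 = trials_frame([(1, 1, 1), (1, 2, 0)], subject_id=1, group=25)
        t2 = trials_frame([(3, 5, 1), (3, 6, 0)], subject_id=2, group=100)
        xs = {1: np.array([0.1, 0.2, -1.0]), 2: np.array([-0.3, 0.4, -0.5])}
        a = log_joint(pd.concat([t1, t2]), state, xs, priors, "SSo", design)
        b = log_joint(pd.concat([t2, t1]), state, xs, priors, "SSo", design)
        assert a == pytest.approx(b, abs=1e-10)

    def test_additivity_over_subjects(self, design):
        priors = PriorConfig.narrow()
        state = _tiny_state(3, seed=6)
        t1 = trials_frame([(1, 1, 1)], subject_id=1, group=0)
        t2 = trials_frame([(2, 3, 0)], subject_id=2, group=0)
        xs = {1: np.array([0.1, 0.2, -1.0]), 2: np.array([-0.3, 0.4, -0.5])}
        both = log_joint(pd.concat([t1, t2]), state, xs, priors, "SSo", design)
        only1 = log_joint(t1, state, {1: xs[1]}, priors, "SSo", design)
        only2 = log_joint(t2, state, {2: xs[2]}, priors, "SSo", design)
        prior_only = log_joint(pd.DataFrame(), state, {}, priors, "SSo", design)
        assert both == pytest.approx(only1 + only2 - prior_only, abs=1e-8)


class TestSampler:
    def test_retained_draw_bookkeeping(self):
        cfg = SamplerConfig(n_chains=3, n_warmup=20, n_sampling=40, seed=1)
        draws = sample_posterior(pd.DataFrame(), "SSo", config=cfg)
        assert draws.n_retained == cfg.n_retained == 120
        assert draws.mu.shape == (3, 40, 3)
        assert draws.delta.shape == (3, 40, 3, 4)

    def test_prior_only_moments_narrow(self):
        """With no likelihood the sampler reproduces the prior: mu ~ N(0, 1)
        and sigma ~ half-Normal(0, 0.2) under the narrow variant."""
        cfg = SamplerConfig(n_chains=2, n_warmup=50, n_sampling=1000, seed=2)
        draws = sample_posterior(pd.DataFrame(), "SSo", config=cfg)
        mu = draws.mu[:, :, 0].ravel()
        n = mu.size
        assert abs(mu.mean()) < 4 / np.sqrt(n)
        assert abs(mu.std(ddof=1) - 1.0) < 0.08
        sig = draws.sigma[:, :, 0].ravel()
        halfnormal_mean = 0.2 * np.sqrt(2 / np.pi)
        assert abs(sig.mean() - halfnormal_mean) < 0.02

    def test_deterministic_given_seed(self, small_cohort_table):
        _, table = small_cohort_table
        sub = table[table["subject_id"] <= 4]
        cfg = SamplerConfig(n_chains=2, n_warmup=30, n_sampling=30, seed=3)
        a = sample_posterior(sub, "SWo", config=cfg)
        b = sample_posterior(sub, "SWo", config=cfg)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.subject_x, b.subject_x)
        c = sample_posterior(sub, "SWo", config=SamplerConfig(2, 30, 30, seed=4))
        assert not np.array_equal(a.mu, c.mu)

    def test_group_mean_draw_construction(self):
        cfg = SamplerConfig(n_chains=2, n_warmup=20, n_sampling=25, seed=5)
        draws = sample_posterior(pd.DataFrame(), "SSo", config=cfg)
        gm = draws.group_mean_draws("alpha_gain")
        assert gm.shape == (50, 5)
        np.testing.assert_array_equal(gm[:, 0], draws.mu[:, :, 0].reshape(-1))
        np.testing.assert_allclose(
            gm[:, 2] - gm[:, 0], draws.delta[:, :, 0, 1].reshape(-1), atol=1e-12
        )
        with pytest.raises(ValueError, match="unknown parameter"):
            draws.group_mean_draws("nonexistent")


class TestDiagnostics:
    def _draws_from_chains(self, chains):
        k = 1
        n_c, n_d = chains.shape
        return rx.PosteriorDraws(
            model_id="SWo",
            param_names=("alpha_gain",),
            mu=chains[:, :, None],
            delta=np.zeros((n_c, n_d, k, 4)),
            sigma=np.ones((n_c, n_d, k)),
            subject_x=None,
            subject_ids=np.array([]),
            subject_groups=np.array([], dtype=int),
            prior_variant="wide",
            seed=0,
        )

    def test_stationary_chains_pass(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(4, 800))
        diag = rx.convergence_diagnostics(self._draws_from_chains(chains))
        entry = diag["per_parameter"]["mu[alpha_gain]"]
        assert entry["rhat"] == pytest.approx(1.0, abs=0.01)
        assert entry["ess_bulk"] <= 4 * 800 * 1.25

    def test_shifted_chain_flagged(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(4, 400))
        chains[0] += 5.0
        diag = rx.convergence_diagnostics(self._draws_from_chains(chains))
        assert diag["per_parameter"]["mu[alpha_gain]"]["rhat"] > 1.1
        assert "mu[alpha_gain]" in diag["non_converged"]

    def test_single_chain_warns(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(1, 400))
        with pytest.warns(UserWarning, match="two chains"):
            diag = rx.convergence_diagnostics(self._draws_from_chains(chains))
        assert diag["per_parameter"]["mu[alpha_gain]"]["rhat"] is None


class TestSubjectPosteriorMeans:
    def test_constant_draws(self):
        k = 3
        sub_x = np.full((2, 10, 1, k), 0.0)
        draws = rx.PosteriorDraws(
            model_id="SWo",
            param_names=("alpha_gain", "alpha_loss", "beta"),
            mu=np.zeros((2, 10, k)),
            delta=np.zeros((2, 10, k, 4)),
            sigma=np.ones((2, 10, k)),
            subject_x=sub_x,
            subject_ids=np.array([7]),
            subject_groups=np.array([50]),
            prior_variant="wide",
            seed=0,
        )
        means = subject_posterior_means(draws)
        assert means.loc[0, "x_alpha_gain"] == 0.0
        # logit-scale mean 0 maps to 0.5 under both reported conventions
        assert means.loc[0, "alpha_gain"] == pytest.approx(0.5)
        assert means.loc[0, "alpha_gain_mean_of_transform"] == pytest.approx(0.5)

    def test_monotone_ordering_preserved(self, small_cohort_table):
        _, table = small_cohort_table
        sub = table[table["subject_id"] <= 5]
        cfg = SamplerConfig(n_chains=2, n_warmup=30, n_sampling=40, seed=8)
        draws = sample_posterior(sub, "SWo", config=cfg)
        means = subject_posterior_means(draws)
        order_x = means.sort_values("x_alpha_gain")["subject_id"].tolist()
        order_c = means.sort_values("alpha_gain")["subject_id"].tolist()
        assert order_x == order_c


class TestMLE:
    def test_recovers_strong_simulated_subject(self, design):
        """A long simulated series pins down the generating parameters."""
        from rlexpect.agents import simulate_choices
        from rlexpect.task import TaskDesign, build_schedule

        long_design = TaskDesign(pairs=design.pairs, trials_per_pair=600)
        params = rx.DualRateParams(0.8, 0.1, 0.1)
        sched = build_schedule(long_design, seed=1)
        sim = simulate_choices(params, sched, long_design, "SWo", seed=2)
        res = rx.fit_mle(sim, "SWo", design=long_design, seed=3, n_starts=2)
        assert res.params.alpha_gain == pytest.approx(0.8, abs=0.1)
        assert res.params.alpha_loss == pytest.approx(0.1, abs=0.1)
        assert res.params.beta == pytest.approx(0.1, abs=0.1)
        from rlexpect.agents import sequence_loglik

        truth_ll = sequence_loglik(sim, params, "SWo", long_design)
        assert res.loglik >= truth_ll - 1e-6

    def test_single_trial_returns_interior_point(self, design):
        table = trials_frame([(1, 1, 1)])
        res = rx.fit_mle(table, "SWo", design=design, n_starts=2)
        assert 0.0 < res.params.alpha_gain < 1.0
        assert np.isfinite(res.loglik)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rx.fit_mle(pd.DataFrame(), "SWo")
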