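"""Partial likelihood, Bayes factor quadrature, and sequential monitoring."""

import math

import numpy as np
import pytest
from lifelines import CoxPHFitter

from conftest import random_small_dataset
from coxprior.cox import (
    BFTrajectory,
    MonotoneLikelihoodError,
    SurvivalDataset,
    _PartialLik,
    bf10,
    cox_mle,
    cox_partial_loglik,
    first_exit,
    hazard_ratio,
    sensitivity_grid,
    sequential_bf,
)
from coxprior.pooling import PriorSpec
from coxprior.simulate import TrialConfig, gen_survival


class TestPartialLoglik:
    def test_single_risk_set_hand_value(self, two_subject_data):
        assert cox_partial_loglik(two_subject_data, 0.0) == pytest.approx(
            math.log(0.5), rel=1e-12
        )

    def test_all_censored_is_zero(self):
        data = SurvivalDataset(time=[1.0, 2.0, 3.0], event=[0, 0, 0], arm=[1, 0, 1])
        for beta in (-3.0, 0.0, 5.0):
            assert cox_partial_loglik(data, beta) == 0.0

    def test_arm_flip_leaves_maximum_value_and_negates_maximizer(self, effect_trial):
        beta_hat, se = cox_mle(effect_trial)
        beta_flip, se_flip = cox_mle(effect_trial.flip_arms())
        assert beta_flip == pytest.approx(-beta_hat, abs=1e-8)
        assert se_flip == pytest.approx(se, rel=1e-10)
        assert cox_partial_loglik(effect_trial, beta_hat) == pytest.approx(
            cox_partial_loglik(effect_trial.flip_arms(), beta_flip), rel=1e-12
        )

    def test_overflow_guarded_for_extreme_beta(self, effect_trial):
        assert np.isfinite(cox_partial_loglik(effect_trial, 600.0))
        assert np.isfinite(cox_partial_loglik(effect_trial, -600.0))

    def test_efron_tied_times_match_lifelines(self):
        # heavy ties: integer-rounded event times
        rng = np.random.default_rng(4)
        arm = rng.integers(0, 2, 60)
        time = np.ceil(rng.exponential(3.0 / np.exp(0.5 * arm)))
        event = (rng.random(60) < 0.85).astype(int)
        data = SurvivalDataset(time=time, event=event, arm=arm)
        cph = CoxPHFitter().fit(data.to_dataframe(), "time", "event")
        beta_hat, se = cox_mle(data)
        assert beta_hat == pytest.approx(cph.params_["arm"], abs=2e-4)
        assert se == pytest.approx(cph.standard_errors_["arm"], rel=1e-3)


class TestCoxMLE:
    def test_recovers_null_and_effect(self):
        null = gen_survival(TrialConfig(n_per_arm=1000, true_beta=0.0, seed=11))
        beta_hat, se = cox_mle(null)
        assert abs(beta_hat) < 3 * se
        eff = gen_survival(TrialConfig(n_per_arm=1000, true_beta=0.7, seed=11))
        beta_hat, se = cox_mle(eff)
        assert abs(beta_hat - 0.7) < 3 * se

    def test_matches_lifelines(self, effect_trial):
        cph = CoxPHFitter().fit(
            effect_trial.to_dataframe()[["time", "event", "arm"]], "time", "event"
        )
        beta_hat, se = cox_mle(effect_trial)
        assert beta_hat == pytest.approx(cph.params_["arm"], abs=1e-4)
        assert se == pytest.approx(cph.standard_errors_["arm"], rel=1e-4)

    def test_monotone_likelihood_reported(self, two_subject_data):
        with pytest.raises(MonotoneLikelihoodError):
            cox_mle(two_subject_data)

    def test_hazard_ratio_round_trip(self):
        assert hazard_ratio(0.0) == 1.0
        assert math.log(hazard_ratio(0.37)) == pytest.approx(0.37, rel=1e-14)


class TestBF10:
    def test_zero_events_gives_unity(self, std_normal_prior):
        data = SurvivalDataset(time=[1.0, 2.0], event=[0, 0], arm=[1, 0])
        assert bf10(data, std_normal_prior) == 1.0

    def test_two_subject_symmetric_prior_is_exactly_one(
        self, two_subject_data, std_normal_prior
    ):
        # the partial likelihood is the logistic sigmoid; its mean under any
        # symmetric prior equals its value at 0
        assert bf10(two_subject_data, std_normal_prior) == pytest.approx(1.0, abs=1e-6)
        assert bf10(two_subject_data, PriorSpec(0.0, 0.4)) == pytest.approx(1.0, abs=1e-6)

    def test_one_sided_positive_exceeds_one_on_positive_effect(
        self, two_subject_data, std_normal_prior
    ):
        assert bf10(two_subject_data, std_normal_prior, side="positive") > 1.0

    def test_quadrature_matches_monte_carlo_prior_average(self, std_normal_prior):
        rng = np.random.default_rng(20)
        for side in ("two_sided", "positive"):
            for _ in range(3):
                data = random_small_dataset(rng)
                lik = _PartialLik(data)
                draws = std_normal_prior.truncate(
                    "positive" if side == "positive" else "none"
                ).rvs(200_000, rng)
                ratios = np.exp(lik.loglik_many(draws) - lik.loglik(0.0))
                mc, mc_se = ratios.mean(), ratios.std() / math.sqrt(len(ratios))
                assert abs(bf10(data, std_normal_prior, side=side) - mc) <= 3 * mc_se

    def test_arm_flip_symmetries(self, std_normal_prior):
        data = random_small_dataset(np.random.default_rng(21))
        flipped = data.flip_arms()
        assert bf10(data, std_normal_prior) == pytest.approx(
            bf10(flipped, std_normal_prior), rel=1e-6
        )
        assert bf10(data, std_normal_prior, side="positive") == pytest.approx(
            bf10(flipped, std_normal_prior, side="negative"), rel=1e-6
        )


class TestSequential:
    def test_first_exit_injected_sequence(self):
        assert first_exit([2, 25, 30], (1 / 20, 20)) == 1
        assert first_exit([2, 0.5, 3], (1 / 20, 20)) is None
        assert first_exit([0.01], (1 / 20, 20)) == 0

    def test_trajectory_structure_and_stop(self, effect_trial, std_normal_prior):
        traj = sequential_bf(
            effect_trial, std_normal_prior, side="positive", order_seed=42
        )
        cases = [k for k, _ in traj.steps]
        assert cases == sorted(set(cases))
        assert traj.stopped_at == len(traj.steps) - 1
        assert traj.steps[traj.stopped_at][1] >= 20
        assert traj.decision == "accept_h1"
        for k, bf in traj.steps[:-1]:
            assert 1 / 20 < bf < 20

    def test_no_event_prefix_yields_unity_and_no_stop(self, std_normal_prior):
        data = SurvivalDataset(
            time=np.arange(1.0, 13.0), event=[0] * 12, arm=[0, 1] * 6
        )
        traj = sequential_bf(data, std_normal_prior, step=4, order_seed=0)
        assert all(bf == 1.0 for _, bf in traj.steps)
        assert traj.stopped_at is None and traj.decision == "inconclusive"

    def test_honors_recorded_entry_order(self, std_normal_prior):
        data = gen_survival(TrialConfig(n_per_arm=30, seed=5))
        a = sequential_bf(data, std_normal_prior, side="positive", thresholds=(1e-9, 1e9))
        b = sequential_bf(data, std_normal_prior, side="positive", thresholds=(1e-9, 1e9))
        assert a.steps == b.steps  # deterministic without an order seed

    def test_evidence_accumulates_under_h1(self, std_normal_prior):
        # median BF10 over seeds increases with the data prefix
        medians = []
        for size in (60, 150, 300):
            bfs = []
            for seed in range(12):
                data = gen_survival(
                    TrialConfig(n_per_arm=size // 2, true_beta=0.7, seed=seed)
                )
                bfs.append(bf10(data, std_normal_prior, side="positive"))
            medians.append(np.median(bfs))
        assert medians[0] < medians[1] < medians[2]

    def test_thresholds_validated(self, effect_trial, std_normal_prior):
        with pytest.raises(ValueError):
            sequential_bf(effect_trial, std_normal_prior, thresholds=(2.0, 20.0))


class TestSensitivityGrid:
    def test_grid_size_and_singleton_equivalence(self, std_normal_prior):
        data = gen_survival(TrialConfig(n_per_arm=40, seed=6))
        sigmas = [round(0.3 + 0.1 * i, 1) for i in range(15)]
        assert sigmas[-1] == 1.7
        trajectories = sensitivity_grid(
            data, sigmas, side="positive", order_seed=3, step=20
        )
        assert len(trajectories) == 15
        single = sensitivity_grid(data, [1.0], side="positive", order_seed=3, step=20)[0]
        direct = sequential_bf(
            data, PriorSpec(0.0, 1.0), side="positive", step=20,
            _order=np.random.default_rng(3).permutation(len(data)),
        )
        assert single.steps == direct.steps

    def test_zero_event_data_constant_unity(self):
        data = SurvivalDataset(time=[1.0, 2.0, 3.0, 4.0], event=[0] * 4, arm=[0, 1, 0, 1])
        for traj in sensitivity_grid(data, [0.3, 1.0], order_seed=0, step=2):
            assert all(bf == 1.0 for _, bf in traj.steps)

    def test_log_bf_ordering_stable_in_sigma_on_strong_effect(self, effect_trial):
        # on fixed strong-effect data the full-sample BF varies smoothly in
        # sigma with no ordering flips across the grid
        sigmas = [0.3 + 0.2 * i for i in range(8)]
        bfs = [
            bf10(effect_trial, PriorSpec(0.0, s), side="positive") for s in sigmas
        ]
        diffs = np.diff(np.log(bfs))
        sign_changes = np.sum(np.sign(diffs[1:]) != np.sign(diffs[:-1]))
        assert sign_changes <= 1  # smooth, unimodal in sigma: one turning point
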