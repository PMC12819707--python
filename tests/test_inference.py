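"""Bayesian grid inference: likelihoods, posteriors, sampling, adaptive selection."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from cuecombo.inference import (
    DEFAULT_MU_GRID,
    DEFAULT_SIGMA_GRID,
    ConditionData,
    JointPosterior,
    SigmaPosterior,
    condition_likelihood,
    condition_log_likelihood,
    expected_information_gain,
    joint_posterior,
    pse_estimate,
    psychometric_prob,
    sample_sigmas,
    select_next_stimulus,
    sigma_posterior,
)
from cuecombo.models import CueSigmas, Model, combined_sigma, pse_slope
from cuecombo.simulate import Condition, Simulant, mcs_design, run_experiment

ROOT2 = np.sqrt(2.0)


def _point_mass(value, grid=None):
    grid = DEFAULT_SIGMA_GRID if grid is None else np.asarray(grid, float)
    p = np.zeros(grid.size)
    p[int(np.argmin(np.abs(grid - value)))] = 1.0
    return SigmaPosterior(grid, p)


def _quadrature_prob(delta, sigma, mu=0.0):
    """Independent oracle: numerically integrate the Gaussian density of the
    internal difference measurement from 0 to infinity."""
    def integrand(dm):
        return math.exp(-((dm - (delta - mu)) ** 2) / (2 * sigma**2)) / (
            sigma * math.sqrt(2 * math.pi))
    val, _ = quad(integrand, 0, np.inf, epsabs=1e-12, epsrel=1e-12)
    return val


class TestPsychometricProb:
    def test_half_at_pse(self):
        assert psychometric_prob(1.5, 2.0, mu=1.5) == pytest.approx(0.5)

    def test_limits(self):
        assert psychometric_prob(1e9, 2.0) == pytest.approx(1.0)
        assert psychometric_prob(-1e9, 2.0) == pytest.approx(0.0)

    def test_standard_normal_value(self):
        assert psychometric_prob(2.0, 2.0, mu=0.0) == pytest.approx(0.8413, abs=1e-4)

    def test_matches_quadrature(self):
        for delta in (-3.0, -0.5, 0.0, 1.0, 4.0):
            for sigma in (0.5, 2.0, 11.0):
                for mu in (-1.0, 0.0, 2.5):
                    assert psychometric_prob(delta, sigma, mu) == pytest.approx(
                        _quadrature_prob(delta, sigma, mu), abs=1e-8)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            psychometric_prob(1.0, 0.0)


class TestConditionLikelihood:
    def test_single_bernoulli_trial(self):
        data = ConditionData.from_dict({1.0: (1, 1)})
        assert condition_likelihood(data, 2.0) == pytest.approx(
            psychometric_prob(1.0, 2.0))

    def test_empty_product_is_one(self):
        data = ConditionData(np.array([]), np.array([]), np.array([]))
        assert condition_likelihood(data, 2.0) == pytest.approx(1.0)

    def test_matches_brute_force_product(self):
        data = ConditionData.from_dict({1.0: (15, 20), -1.0: (5, 20)})
        sigma, mu = 2.0, 0.0
        expected = 1.0
        for d, (k, n) in data.as_dict().items():
            psi = _quadrature_prob(d, sigma, mu)
            expected *= psi**k * (1 - psi) ** (n - k)
        assert condition_likelihood(data, sigma, mu) == pytest.approx(
            expected, rel=1e-8)

    def test_invariant_under_positive_scaling_in_posterior(self):
        """Adding a constant to the log-likelihood (scaling the likelihood)
        leaves the normalised posterior untouched."""
        data = ConditionData.from_dict({1.0: (15, 20), -1.0: (5, 20)})
        post = sigma_posterior(data)
        grid = post.grid
        ll = condition_log_likelihood(data, ROOT2 * grid)
        w = np.exp(ll + 123.0 - (ll + 123.0).max())
        np.testing.assert_allclose(w / w.sum(), post.p, rtol=1e-10)

    def test_counts_validation(self):
        with pytest.raises(ValueError):
            ConditionData.from_dict({1.0: (5, 4)})


class TestSigmaPosterior:
    def test_no_evidence_returns_prior(self):
        data = ConditionData.from_dict({1.0: (0, 0), -1.0: (0, 0)})
        post = sigma_posterior(data)
        np.testing.assert_allclose(post.p, 1.0 / post.grid.size)

    def test_mass_sums_to_one(self, rng):
        sim = Simulant("s", CueSigmas(7, 6, 3), Model.OPT)
        res = run_experiment(sim, mcs_design(), rng, keep_trials=False)
        for data in res.condition_data.values():
            assert sigma_posterior(data).p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_mode_recovers_generating_sigma(self, rng):
        sim = Simulant("s", CueSigmas(3, 3, 3), Model.OPT)
        modes = []
        for _ in range(40):
            res = run_experiment(sim, mcs_design(), rng, keep_trials=False)
            modes.append(sigma_posterior(res.condition_data["Thumb"]).mode())
        assert np.mean(modes) == pytest.approx(3.0, abs=0.35)

    def test_single_cue_modes_ordered_by_true_sigma(self, rng):
        """With varied sigmas (7, 6, 3), heavy-trial single-cue posteriors
        order their modes thumb > index > config."""
        sim = Simulant("s", CueSigmas(7, 6, 3), Model.OPT)
        design = mcs_design(trials_per_level=400)
        res = run_experiment(sim, design, rng, keep_trials=False)
        modes = {c: sigma_posterior(d).mode()
                 for c, d in res.single_cue_data().items()}
        assert modes["thumb"] > modes["index"] > modes["config"]


class TestSampleSigmas:
    def test_point_mass_posterior_constant_draws(self, rng):
        post = _point_mass(3.01)
        draws = sample_sigmas(post, 500, rng)
        assert np.all(draws == post.mode())

    def test_uniform_posterior_mean(self, rng):
        grid = DEFAULT_SIGMA_GRID
        post = SigmaPosterior(grid, np.full(grid.size, 1 / grid.size))
        draws = sample_sigmas(post, 100_000, rng)
        assert draws.mean() == pytest.approx(20.01, abs=0.15)

    def test_ks_distance_to_posterior_cdf(self, rng):
        sim = Simulant("s", CueSigmas(4, 4, 4), Model.OPT)
        res = run_experiment(sim, mcs_design(), rng, keep_trials=False)
        post = sigma_posterior(res.condition_data["Config"])
        draws = np.sort(sample_sigmas(post, 10_000, rng))
        cdf_at_draws = np.interp(draws, post.grid, post.cdf())
        emp = np.arange(1, draws.size + 1) / draws.size
        assert np.max(np.abs(emp - cdf_at_draws)) < 0.02


class TestJointPosterior:
    def _conflict_data(self, rng, mu_true=0.0, sigma_true=2.5, t=20):
        deltas = np.array([-5, -2, -1, -0.5, 0.5, 1, 2, 5], dtype=float)
        p = psychometric_prob(deltas, ROOT2 * sigma_true, mu_true)
        k = rng.binomial(t, p)
        return ConditionData(deltas, k.astype(float), np.full(8, float(t)))

    def test_unbiased_mu_in_large_trial_limit(self, rng):
        data = self._conflict_data(rng, mu_true=0.0, t=4000)
        joint = joint_posterior(data)
        assert abs(pse_estimate(joint)) <= 0.2

    def test_label_swap_reflects_mu_marginal(self, rng):
        data = self._conflict_data(rng, mu_true=1.3, t=50)
        flipped = ConditionData(-data.deltas, data.n - data.k, data.n)
        m1 = joint_posterior(data).mu_marginal()
        m2 = joint_posterior(flipped).mu_marginal()
        np.testing.assert_allclose(m1, m2[::-1], atol=1e-10)

    def test_opt_conflict_mu_mode_matches_slope_prediction(self, rng):
        """For an OPT observer at +3 conflict with sigmas (7, 6, 3), the mu
        mode concentrates near slope x 3 = +1.185 mm across replicates."""
        sig = CueSigmas(7, 6, 3)
        mu_true = pse_slope(Model.OPT, sig) * 3.0
        sigma_true = combined_sigma(Model.OPT, sig)
        modes = [pse_estimate(joint_posterior(
            self._conflict_data(rng, mu_true, sigma_true, t=20)))
            for _ in range(60)]
        se = np.std(modes, ddof=1) / np.sqrt(len(modes))
        assert abs(np.mean(modes) - mu_true) < 3 * se + 0.05  # + grid step/2

    def test_marginals_recover_by_summation(self, rng):
        joint = joint_posterior(self._conflict_data(rng))
        assert joint.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert joint.mu_marginal().sum() == pytest.approx(1.0, abs=1e-12)
        assert joint.sigma_marginal().sum() == pytest.approx(1.0, abs=1e-12)


class TestPseEstimate:
    def test_point_mass(self):
        p = np.zeros((DEFAULT_MU_GRID.size, 3))
        p[np.argmin(np.abs(DEFAULT_MU_GRID - 1.5)), 1] = 1.0
        joint = JointPosterior(DEFAULT_MU_GRID, np.array([1.0, 2.0, 3.0]), p)
        assert pse_estimate(joint) == pytest.approx(1.5)

    def test_uniform_marginal_tie_breaks_to_zero(self):
        p = np.full((DEFAULT_MU_GRID.size, 2), 1.0 / (DEFAULT_MU_GRID.size * 2))
        joint = JointPosterior(DEFAULT_MU_GRID, np.array([1.0, 2.0]), p)
        assert pse_estimate(joint) == 0.0


class TestAdaptiveSelection:
    def test_point_mass_posterior_returns_first_candidate(self):
        post = _point_mass(2.01)
        assert select_next_stimulus(post, [0.5, -0.5, 5.0]) == 0.5

    def test_symmetric_tie_breaks_to_first_listed(self):
        grid = DEFAULT_SIGMA_GRID
        post = SigmaPosterior(grid, np.full(grid.size, 1 / grid.size))
        assert select_next_stimulus(post, [-1.0, 1.0]) == -1.0
        assert select_next_stimulus(post, [1.0, -1.0]) == 1.0

    def test_matches_brute_force_entropy_computation(self):
        """Exhaustive oracle: enumerate both responses at every candidate and
        recompute expected posterior entropy with explicit loops."""
        grid = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        p = np.array([0.1, 0.25, 0.3, 0.25, 0.1])
        post = SigmaPosterior(grid, p)
        candidates = [-0.5, 0.5, -5.0, 5.0]

        def entropy(q):
            q = q[q > 0]
            return -(q * np.log(q)).sum()

        gains = []
        for c in candidates:
            psi = np.array([psychometric_prob(c, ROOT2 * s) for s in grid])
            eh = 0.0
            for resp in (1, 0):
                like = psi if resp else 1 - psi
                w = like * p
                if w.sum() > 0:
                    eh += w.sum() * entropy(w / w.sum())
            gains.append(entropy(p) - eh)
        best = candidates[int(np.argmax(np.round(gains, 12)))]
        assert select_next_stimulus(post, candidates) == best
        np.testing.assert_allclose(
            expected_information_gain(
                p, np.array([[psychometric_prob(c, ROOT2 * s) for s in grid]
                             for c in candidates])),
            gains, rtol=1e-10)

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError):
            select_next_stimulus(_point_mass(2.0), [])

    def test_adaptive_beats_mcs_on_posterior_entropy(self, rng):
        """With matched trial budgets the greedy information-gain schedule
        yields, on average, a lower-entropy sigma posterior than constant
        stimuli (the efficiency rationale for adaptive testing)."""
        from cuecombo.simulate import ExperimentDesign

        sim = Simulant("s", CueSigmas(4, 4, 4), Model.OPT)
        radii = (5.0, 8.0, 9.0, 9.5, 10.5, 11.0, 12.0, 15.0)
        n_rep, diffs = 200, []
        for _ in range(n_rep):
            ent = {}
            for schedule in ("adaptive", "MCS"):
                design = ExperimentDesign(10.0, radii, 5,
                                          (Condition("Thumb"),), schedule)
                res = run_experiment(sim, design, rng, keep_trials=False)
                post = sigma_posterior(res.condition_data["Thumb"])
                ent[schedule] = post.entropy()
            diffs.append(ent["adaptive"] - ent["MCS"])
        assert np.mean(diffs) < 0


class TestRecoveryConsistency:
    def test_mu_rmse_decreases_with_trials(self, rng):
        """PSE estimates are consistent: RMSE shrinks as trials per level grow."""
        deltas = np.array([-5, -2, -1, -0.5, 0.5, 1, 2, 5], dtype=float)
        mu_true, sigma_true = 1.0, 2.5
        p = psychometric_prob(deltas, ROOT2 * sigma_true, mu_true)
        rmse = []
        for t in (5, 20, 80):
            errs = []
            for _ in range(40):
                k = rng.binomial(t, p)
                data = ConditionData(deltas, k.astype(float), np.full(8, float(t)))
                errs.append(pse_estimate(joint_posterior(data)) - mu_true)
            rmse.append(np.sqrt(np.mean(np.square(errs))))
        assert rmse[2] < rmse[0]
        assert rmse[1] < rmse[0] * 1.25  # monotone within simulation error
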