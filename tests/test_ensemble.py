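"""Prior, posterior, and the Bayesian-averaged ensemble."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voxelbma import (
    aggregate_run_coefficients,
    build_cost_grid,
    ensemble_predict,
    fit_ensemble,
    posterior_weights,
    prior_weights,
    with_point_mass_prior,
)
from voxelbma.ensemble import SubjectPrediction


class TestPriorWeights:
    def test_center_weight_by_direct_normalization(self):
        grid = build_cost_grid(10.0, 19.0)
        w = prior_weights(grid)
        i = np.arange(-9, 10)
        direct = np.exp(-2.0 * (i / 9.0) ** 2)
        direct /= direct.sum()
        np.testing.assert_allclose(w, direct, rtol=1e-12)
        assert w[9] == w.max() == pytest.approx(0.0918, abs=5e-4)

    def test_symmetric_and_invariant_to_grid_scale(self):
        w1 = prior_weights(build_cost_grid(10.0, 19.0))
        w2 = prior_weights(build_cost_grid(0.01, 5000.0))
        np.testing.assert_allclose(w1, w2)
        np.testing.assert_allclose(w1, w1[::-1])
        assert w1.sum() == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_grid_uniform_with_warning(self):
        grid = build_cost_grid(5.0, 5.0)
        with pytest.warns(UserWarning, match="degenerate"):
            w = prior_weights(grid)
        np.testing.assert_allclose(w, np.full(19, 1 / 19))


class TestPosteriorWeights:
    def test_two_component_direct_formula(self):
        post, ev, shift = posterior_weights([0.5, 0.5], np.log([0.2, 0.8]))
        np.testing.assert_allclose(post, [0.2, 0.8], rtol=1e-12)

    def test_three_component_direct_formula(self):
        prior = np.array([0.2, 0.3, 0.5])
        L = np.array([0.1, 0.5, 0.2])
        expected = prior * L / (prior * L).sum()
        post, _, _ = posterior_weights(prior, np.log(L))
        np.testing.assert_allclose(post, expected, rtol=1e-12)

    def test_uniform_ll_gives_prior_back(self):
        prior = np.array([0.1, 0.6, 0.3])
        post, _, _ = posterior_weights(prior, np.array([-7.0, -7.0, -7.0]))
        np.testing.assert_allclose(post, prior, rtol=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(
        lls=st.lists(st.floats(-50, 0), min_size=3, max_size=19),
        shift=st.floats(-500, 500),
    )
    def test_invariant_to_uniform_ll_shift(self, lls, shift):
        ll = np.array(lls)
        prior = np.full(len(ll), 1.0 / len(ll))
        base, _, _ = posterior_weights(prior, ll)
        shifted, _, _ = posterior_weights(prior, ll + shift)
        np.testing.assert_allclose(base, shifted, rtol=1e-9, atol=1e-15)

    def test_evidence_is_prior_likelihood_dot_product(self):
        prior = np.array([0.25, 0.75])
        ll = np.log([0.4, 0.1])
        post, ev, shift = posterior_weights(prior, ll)
        L_shifted = np.exp(ll - shift)
        assert ev == pytest.approx(float(L_shifted @ prior))

    def test_all_neginf_rejected(self):
        with pytest.raises(ValueError, match="likelihood"):
            posterior_weights([0.5, 0.5], np.array([-np.inf, -np.inf]))


@pytest.fixture
def fitted(tiny_separable):
    table, _ = tiny_separable
    train = table.subset(np.arange(0, table.n_subjects, 2))
    test = table.subset(np.arange(1, table.n_subjects, 2))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        ens = fit_ensemble(train)
    return ens, train, test


class TestFitEnsemble:
    def test_normalization_and_aggregation_identity(self, fitted):
        ens, _, _ = fitted
        assert ens.prior.sum() == pytest.approx(1.0, abs=1e-12)
        assert ens.posterior.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(
            ens.run_coefficients, aggregate_run_coefficients(ens), rtol=1e-12
        )

    def test_posterior_proportional_to_likelihood_times_prior(self, fitted):
        ens, _, _ = fitted
        unnorm = ens.likelihood * ens.prior
        np.testing.assert_allclose(ens.posterior, unnorm / unnorm.sum(), rtol=1e-12)
        assert ens.evidence == pytest.approx(float(unnorm.sum()))

    def test_prior_regularizes_high_cost_models(self, fitted):
        """Relative to a uniform prior, the Gaussian prior strictly reduces
        the posterior weight of the strongly-fitting top-of-grid models."""
        ens, _, _ = fitted
        uniform, _, _ = posterior_weights(np.full(19, 1 / 19), ens.log_likelihoods)
        assert np.all(ens.posterior[-3:] <= uniform[-3:] + 1e-15)
        # and the damping is strict at the very top whenever it carries mass
        if uniform[-1] > 1e-12:
            assert ens.posterior[-1] < uniform[-1]

    def test_duplicated_training_set_predicts_identically(self, fitted):
        ens, train, test = fitted
        doubled = train.subset(np.r_[np.arange(train.n_subjects), np.arange(train.n_subjects)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            ens2 = fit_ensemble(doubled)
        p1 = [p.predicted_label for p in ensemble_predict(ens, test)]
        p2 = [p.predicted_label for p in ensemble_predict(ens2, test)]
        assert p1 == p2


class TestEnsemblePredict:
    def test_hand_weighted_average(self):
        """Two-model reduction: weights (0.3, 0.7), probabilities (0.9, 0.4)."""
        H = np.array([0.3, 0.7]) @ np.array([0.9, 0.4])
        assert H == pytest.approx(0.55)
        assert int(H > 0.5) == 1  # patient

    def test_exact_half_predicts_control(self):
        pred = SubjectPrediction("s0", 0.5, int(0.5 > 0.5), 1)
        assert pred.predicted_label == 0

    def test_convexity_bounds(self, fitted):
        from voxelbma.svm import predict_probability

        ens, _, test = fitted
        probs = np.stack([predict_probability(m, test.matrix) for m in ens.models])
        H = np.array([p.ensemble_probability for p in ensemble_predict(ens, test)])
        assert np.all(H >= probs.min(axis=0) - 1e-12)
        assert np.all(H <= probs.max(axis=0) + 1e-12)

    def test_column_mismatch_rejected(self, fitted):
        ens, _, test = fitted
        bad = test.subset(np.arange(test.n_subjects))
        bad.matrix = bad.matrix[:, :-1]
        bad.voxel_index_map = bad.voxel_index_map[:-1]
        with pytest.raises(ValueError, match="voxel columns"):
            ensemble_predict(ens, bad)

    def test_point_mass_prior_reduces_to_single_model(self, fitted):
        ens, _, test = fitted
        for idx in (0, 9, 18):
            focused = with_point_mass_prior(ens, idx)
            np.testing.assert_allclose(focused.posterior, np.eye(19)[idx])
            single_scores = ens.models[idx].score(test.matrix)
            expected = (single_scores > 0).astype(int)
            got = [p.predicted_label for p in ensemble_predict(focused, test)]
            np.testing.assert_array_equal(got, expected)


class TestAggregateCoefficients:
    def test_mean_of_two_models(self):
        betas = np.array([[1.0, -1.0], [3.0, 1.0]])
        np.testing.assert_allclose(np.array([0.5, 0.5]) @ betas, [2.0, 0.0])

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_weighted_average_within_elementwise_envelope(self, seed):
        rng = np.random.default_rng(seed)
        betas = rng.normal(size=(5, 7))
        w = rng.dirichlet(np.ones(5))
        agg = w @ betas
        assert np.all(agg >= betas.min(axis=0) - 1e-12)
        assert np.all(agg <= betas.max(axis=0) + 1e-12)

    def test_point_mass_posterior_returns_member_beta(self, fitted):
        ens, _, _ = fitted
        focused = with_point_mass_prior(ens, 3)
        np.testing.assert_allclose(
            aggregate_run_coefficients(focused), ens.models[3].coefficients, rtol=1e-12
        )
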