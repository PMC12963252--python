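"""Correlation-informed PCA: fitting, projection, selection, surveys."""

import numpy as np
import pytest

from neurostate import (
    InputError,
    NoEligibleComponentsError,
    ParameterError,
    StateLabels,
    correlate_projections,
    fit_pca,
    loading_rate_regression,
    project,
    select_components,
    survey_per_trial_correlations,
)
from neurostate.preprocess import RateMatrix


def as_rates(X):
    return RateMatrix(np.abs(X), np.arange(X.shape[0], dtype=float))


class TestFitPCA:
    def test_collinear_data_has_one_component(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=500)
        X = np.column_stack([2 * t, -t])  # exactly on a line in channel space
        model = fit_pca(X)
        assert model.explained_variance[0] > 0
        assert model.explained_variance[1] == pytest.approx(0.0, abs=1e-10)
        direction = np.array([2.0, -1.0]) / np.sqrt(5)
        assert abs(model.loadings[:, 0] @ direction) == pytest.approx(1.0, abs=1e-8)

    def test_isotropic_white_data_equal_variances(self):
        rng = np.random.default_rng(1)
        model = fit_pca(rng.normal(size=(10_000, 4)))
        ev = model.explained_variance
        assert ev.max() / ev.min() < 1.1

    def test_reconstruction_and_variance_conservation(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 6)) * rng.uniform(0.5, 3.0, 6)
        model = fit_pca(X)
        np.testing.assert_allclose(model.loadings.T @ model.loadings,
                                   np.eye(6), atol=1e-8)
        feats = project(X, model)
        recon = feats @ model.loadings.T + model.channel_means
        np.testing.assert_allclose(recon, X, atol=1e-8)
        assert model.explained_variance.sum() == pytest.approx(
            X.var(axis=0, ddof=1).sum(), abs=1e-8)

    def test_too_few_samples(self):
        with pytest.raises(InputError):
            fit_pca(np.ones((1, 3)))


class TestProject:
    def test_projection_variance_equals_explained_variance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(400, 5))
        model = fit_pca(X)
        feats = project(X, model)
        np.testing.assert_allclose(feats.var(axis=0, ddof=1),
                                   model.explained_variance, atol=1e-8)

    def test_empty_and_out_of_range_indices(self):
        model = fit_pca(np.random.default_rng(4).normal(size=(50, 3)))
        X = np.zeros((10, 3))
        with pytest.raises(ParameterError):
            project(X, model, indices=[])
        with pytest.raises(ParameterError):
            project(X, model, indices=[5])

    def test_channel_mismatch(self):
        model = fit_pca(np.random.default_rng(5).normal(size=(50, 3)))
        with pytest.raises(InputError):
            project(np.zeros((10, 4)), model)

    def test_single_channel_projection_is_centered_data(self):
        x = np.random.default_rng(6).normal(size=(100, 1))
        model = fit_pca(x)
        feats = project(x, model)
        np.testing.assert_allclose(np.abs(feats[:, 0]),
                                   np.abs(x[:, 0] - x.mean()), atol=1e-10)


class TestCorrelate:
    def test_projection_equal_to_labels(self):
        y = np.tile([0, 1], 50)
        r, p = correlate_projections(y.astype(float)[:, None], StateLabels(y))
        assert r[0] == pytest.approx(1.0)
        assert p[0] < 1e-10

    def test_negated_labels_give_minus_one(self):
        y = np.tile([0, 1], 50)
        r, _ = correlate_projections((-y + 5.0)[:, None], StateLabels(y))
        assert r[0] == pytest.approx(-1.0)

    def test_orthogonalized_projection_is_uncorrelated(self):
        rng = np.random.default_rng(7)
        y = (rng.uniform(size=200) < 0.4).astype(int)
        yc = y - y.mean()
        f = rng.normal(size=200)
        f = f - (f @ yc) / (yc @ yc) * yc  # Gram-Schmidt against labels
        r, _ = correlate_projections(f[:, None], StateLabels(y))
        assert abs(r[0]) < 1e-10

    def test_single_class_labels_warn_nan(self):
        with pytest.warns(UserWarning):
            r, p = correlate_projections(np.random.default_rng(8).normal(size=(50, 2)),
                                         StateLabels(np.zeros(50, dtype=int)))
        assert np.isnan(r).all() and np.isnan(p).all()


class TestSelect:
    def test_benchmark_example(self):
        sel = select_components(np.array([0.5, 0.19, -0.3, 0.05]), benchmark=0.2)
        assert sel.selected == [0, 2]

    def test_zero_benchmark_keeps_all(self):
        sel = select_components(np.array([0.5, 0.19, -0.3, 0.05]), benchmark=0.0)
        assert sel.selected == [0, 1, 2, 3]

    def test_boundary_is_inclusive(self):
        sel = select_components(np.array([0.2, 0.1999]), benchmark=0.2)
        assert sel.selected == [0]

    def test_no_survivor_raises_with_max_r(self):
        with pytest.raises(NoEligibleComponentsError) as err:
            select_components(np.array([0.05, -0.12]), benchmark=0.2)
        assert err.value.max_abs_r == pytest.approx(0.12)


class TestInvariances:
    def test_sign_flip_of_loading_column(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(300, 4))
        y = (rng.uniform(size=300) < 0.5).astype(int)
        model = fit_pca(X)
        r0, _ = correlate_projections(project(X, model), y)
        model.loadings[:, 1] *= -1
        r1, _ = correlate_projections(project(X, model), y)
        np.testing.assert_allclose(np.abs(r1), np.abs(r0), atol=1e-12)

    def test_rate_scale_equivariance(self):
        rng = np.random.default_rng(10)
        X = np.abs(rng.normal(size=(300, 4))) + 1.0
        y = (rng.uniform(size=300) < 0.5).astype(int)
        r0, _ = correlate_projections(project(X, fit_pca(X)), y)
        Xs = 7.3 * X
        r1, _ = correlate_projections(project(Xs, fit_pca(Xs)), y)
        np.testing.assert_allclose(np.abs(r1), np.abs(r0), atol=1e-10)


class TestSurvey:
    def _locked_trials(self, rng, n_trials=6, n=400, n_ch=5):
        trials = []
        for _ in range(n_trials):
            y = np.zeros(n, dtype=int)
            y[n // 3 : 2 * n // 3] = 1
            X = rng.normal(size=(n, n_ch))
            X[:, 0] += 4.0 * y  # one strongly label-locked channel
            trials.append((X, StateLabels(y)))
        return trials

    def test_locked_channel_yields_eligible_pc_each_trial(self):
        trials = self._locked_trials(np.random.default_rng(11))
        survey = survey_per_trial_correlations(trials)
        assert np.all(survey.eligible_per_trial >= 1)

    def test_shuffled_labels_lower_median(self):
        rng = np.random.default_rng(12)
        trials = self._locked_trials(rng)
        survey = survey_per_trial_correlations(trials)
        shuffled = [(X, StateLabels(rng.permutation(lab.labels)))
                    for X, lab in trials]
        survey_sh = survey_per_trial_correlations(shuffled)
        assert survey_sh.median_restricted < survey.median_restricted

    def test_pooling_invariance_under_duplication(self):
        trials = self._locked_trials(np.random.default_rng(13), n_trials=1)
        s1 = survey_per_trial_correlations(trials)
        s3 = survey_per_trial_correlations(trials * 3)
        assert s3.median_restricted == pytest.approx(s1.median_restricted)
        np.testing.assert_array_equal(s3.histogram_counts, 3 * s1.histogram_counts)

    def test_empty_trial_list(self):
        with pytest.raises(InputError):
            survey_per_trial_correlations([])


class TestLoadingRegression:
    def test_perfectly_proportional_loadings(self):
        x = np.linspace(1.0, 10.0, 20)
        sel, uns = loading_rate_regression(0.3 * x, np.full(20, 0.05), x)
        assert sel.r_squared == pytest.approx(1.0)
        assert sel.theta_deg == pytest.approx(np.degrees(np.arctan(0.3)))
        assert uns.slope == pytest.approx(0.0, abs=1e-12)

    def test_independent_loadings_have_low_r2(self):
        rng = np.random.default_rng(14)
        x = rng.uniform(1, 10, 192)
        sel, _ = loading_rate_regression(rng.normal(size=192), rng.normal(size=192), x)
        assert sel.r_squared < 0.1

    def test_insufficient_channels(self):
        with pytest.raises(InputError):
            loading_rate_regression(np.ones(2), np.ones(2), np.ones(2))
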