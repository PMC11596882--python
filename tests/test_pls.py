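import numpy as np
import pytest

from nirpls import pls
from tests._oracles import ols_coefficients, simpls_coefficients


def random_problem(rng, n=10, p=20):
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    return X, y


class TestFit:
    def test_rank_one_structure_recovered_exactly(self, rng):
        """X = y v' is a noiseless one-factor problem; one component
        reproduces the response to machine precision."""
        y = rng.uniform(0, 100, 12)
        v = rng.normal(size=30)
        X = np.outer(y, v)
        model = pls.fit_pls(X, y, 1)
        np.testing.assert_allclose(pls.predict(model, X), y, atol=1e-9)

    def test_full_rank_fit_equals_ols(self, rng):
        X, y = random_problem(rng, n=12, p=5)
        model = pls.fit_pls(X, y, 5)
        b_ols = ols_coefficients(X, y)
        np.testing.assert_allclose(model.coefficients, b_ols, atol=1e-8)

    def test_excess_components_rejected(self, rng):
        y = rng.uniform(0, 1, 8)
        X = np.outer(y, rng.normal(size=10))  # rank 1 after centering
        with pytest.raises(ValueError, match="rank"):
            pls.fit_pls(X, y, 3)

    def test_zero_variance_response_rejected(self, rng):
        X = rng.normal(size=(6, 4))
        with pytest.raises(ValueError, match="zero-variance"):
            pls.fit_pls(X, np.full(6, 7.0), 2)

    def test_scores_orthogonal(self, rng):
        X, y = random_problem(rng)
        model = pls.fit_pls(X, y, 4)
        gram = model.scores.T @ model.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_loading_reconstruction(self, rng):
        """X_centered = T P' + residual exactly (deflation bookkeeping)."""
        X, y = random_problem(rng)
        model = pls.fit_pls(X, y, 3)
        Xc = X - model.x_mean
        resid = Xc - model.scores @ model.x_loadings.T
        # residual must be what 3 deflation steps leave behind
        explained = 100.0 * (1.0 - (resid**2).sum() / (Xc**2).sum())
        assert explained == pytest.approx(
            model.explained_x_variance.sum(), abs=1e-8)


class TestAgainstSimpls:
    def test_nipals_equals_simpls_univariate(self, rng):
        for _ in range(10):
            X, y = random_problem(rng)
            model = pls.fit_pls(X, y, 3)
            b = simpls_coefficients(X, y, 3)
            np.testing.assert_allclose(model.coefficients, b, atol=1e-8)


class TestPredict:
    def test_prediction_at_x_mean_is_y_mean(self, rng):
        X, y = random_problem(rng)
        model = pls.fit_pls(X, y, 2)
        assert pls.predict(model, model.x_mean)[0] == pytest.approx(
            model.y_mean, abs=1e-10)

    def test_row_permutation_equivariance(self, rng):
        X, y = random_problem(rng)
        model = pls.fit_pls(X, y, 2)
        perm = rng.permutation(len(y))
        np.testing.assert_allclose(pls.predict(model, X[perm]),
                                   pls.predict(model, X)[perm])

    def test_dimension_mismatch_rejected(self, rng):
        X, y = random_problem(rng)
        model = pls.fit_pls(X, y, 2)
        with pytest.raises(ValueError, match="channels"):
            pls.predict(model, X[:, :-1])

    def test_rmsec_never_increases_with_components(self, rng):
        X, y = random_problem(rng, n=14, p=8)
        model = pls.fit_pls(X, y, 6)
        rmsecs = [
            np.sqrt(((y - pls.predict(model, X, k)) ** 2).mean())
            for k in range(1, 7)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(rmsecs, rmsecs[1:]))


class TestVarianceContributions:
    def test_rank_one_single_component_explains_everything(self, rng):
        y = rng.uniform(0, 100, 10)
        X = np.outer(y, rng.normal(size=15))
        model = pls.fit_pls(X, y, 1)
        assert pls.variance_contributions(model)[0] == pytest.approx(100.0)

    def test_contributions_bounded_and_cumulative(self, rng):
        X, y = random_problem(rng)
        model = pls.fit_pls(X, y, 5)
        ev = pls.variance_contributions(model)
        assert np.all(ev >= 0)
        assert ev.sum() <= 100 + 1e-8
        np.testing.assert_allclose(pls.cumulative_variance(model),
                                   np.cumsum(ev))


class TestCrossValidation:
    def test_noiseless_two_component_mixture(self, rng):
        """Spectra lying exactly in a 2-D subspace linear in y are
        predicted perfectly with 2 components."""
        y = np.linspace(0, 100, 9)
        s1, s2 = rng.normal(size=(2, 40))
        X = np.outer(y / 100, s1) + np.outer(1 - y / 100, s2)
        curve = pls.cross_validate(X, y, 3)
        assert curve[1] < 1e-6

    def test_loo_matches_bruteforce_refit(self, rng):
        X, y = random_problem(rng, n=6, p=3)
        curve = pls.cross_validate(X, y, 3)
        for k in range(1, 4):
            sq = []
            for i in range(6):
                mask = np.arange(6) != i
                m = pls.fit_pls(X[mask], y[mask], k)
                sq.append((y[i] - pls.predict(m, X[i])[0]) ** 2)
            assert curve[k - 1] == pytest.approx(np.sqrt(np.mean(sq)),
                                                 abs=1e-10)

    def test_mean_model_rmsecv_closed_form(self):
        """Constant spectra carry no information, so every held-out
        prediction is the training mean; on y = [0, 50, 100] that gives
        sqrt((75^2 + 0 + 75^2)/3)."""
        X = np.ones((3, 5)) + np.arange(5)  # constant rows
        y = np.array([0.0, 50.0, 100.0])
        curve = pls.cross_validate(X, y, 1)
        assert curve[0] == pytest.approx(np.sqrt(2 * 75.0**2 / 3))

    def test_group_cv_keeps_replicates_together(self, rng):
        """With duplicated rows, plain LOO leaks the twin into training;
        grouped CV must not (so its error is strictly larger here)."""
        y0 = rng.uniform(0, 100, 6)
        X0 = np.outer(y0, rng.normal(size=12)) + rng.normal(0, 5, (6, 12))
        X = np.repeat(X0, 2, axis=0)
        y = np.repeat(y0, 2)
        groups = np.repeat(np.arange(6), 2)
        loo = pls.cross_validate(X, y, 2)
        grouped = pls.cross_validate(X, y, 2, groups=groups)
        assert grouped[1] > loo[1]

    def test_too_few_groups_rejected(self, rng):
        X, y = random_problem(rng, n=4, p=3)
        with pytest.raises(ValueError, match="groups"):
            pls.cross_validate(X, y, 2, groups=np.zeros(4))


class TestComponentSelection:
    @pytest.mark.parametrize("curve,expected", [
        ([5.0, 1.0, 0.99, 0.99], 2),
        ([3.0, 3.0, 3.0], 1),
        ([5.0, 4.0, 3.0, 2.0], 4),
        ([2.0, 2.03, 5.0], 1),
    ])
    def test_parsimony_rule(self, curve, expected):
        assert pls.select_n_components(np.array(curve)) == expected

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            pls.select_n_components(np.array([]))


def test_model_serialization_roundtrip(rng):
    X, y = random_problem(rng)
    model = pls.fit_pls(X, y, 3)
    back = pls.model_from_dict(pls.model_to_dict(model))
    np.testing.assert_allclose(back.coefficients, model.coefficients)
    np.testing.assert_allclose(pls.predict(back, X), pls.predict(model, X))
    with pytest.raises(ValueError, match="format"):
        pls.model_from_dict({"format_version": 99})
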