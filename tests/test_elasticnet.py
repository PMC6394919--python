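import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genopred import elasticnet as en
from genopred import synthio
from genopred.exceptions import InvalidParameterError


def lasso_oracle(Zs, yc, lam):
    """Exhaustive active-set/sign enumeration for the standardized LASSO.

    Minimizes (1/2n)||y - Zb||^2 + lam*||b||_1 by solving the stationarity
    system for every (active set, sign) combination and keeping the unique
    KKT-consistent solution. Only feasible for a handful of predictors.
    """
    n, m = Zs.shape
    G = Zs.T @ Zs / n
    c = Zs.T @ yc / n
    best = None
    for r in range(m + 1):
        for active in itertools.combinations(range(m), r):
            A = list(active)
            for signs in itertools.product([-1.0, 1.0], repeat=r):
                s = np.array(signs)
                if r == 0:
                    b = np.zeros(m)
                else:
                    try:
                        bA = np.linalg.solve(G[np.ix_(A, A)], c[A] - lam * s)
                    except np.linalg.LinAlgError:
                        continue
                    if np.any(np.sign(bA) != s):
                        continue
                    b = np.zeros(m)
                    b[A] = bA
                grad = c - G @ b
                inactive = [j for j in range(m) if j not in A]
                if inactive and np.abs(grad[inactive]).max() > lam + 1e-10:
                    continue
                obj = en.en_objective(Zs, yc, b, lam, 1.0)
                if best is None or obj < best[0]:
                    best = (obj, b)
    return best[1]


def _standardized_toy(n, m, seed, h2_like=0.7):
    rng = np.random.default_rng(seed)
    Z = rng.normal(size=(n, m))
    beta = rng.normal(size=m) * (rng.random(m) < 0.6)
    y = Z @ beta + rng.normal(scale=0.5, size=n)
    Zs = (Z - Z.mean(0)) / Z.std(0)
    yc = y - y.mean()
    return Zs, yc


class TestSoftThreshold:
    def test_examples(self):
        assert en.soft_threshold(3, 1) == 2
        assert en.soft_threshold(-0.5, 1) == 0
        assert en.soft_threshold(-3, 1) == -2

    @given(st.floats(-100, 100, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_identity_at_zero(self, z):
        assert en.soft_threshold(z, 0) == pytest.approx(z)

    @given(
        st.floats(-100, 100, allow_nan=False),
        st.floats(0, 100, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_shrinks_toward_zero(self, z, t):
        out = en.soft_threshold(z, t)
        assert abs(out) <= abs(z) + 1e-12
        assert out * z >= 0

    def test_negative_threshold(self):
        with pytest.raises(InvalidParameterError):
            en.soft_threshold(1.0, -0.5)


class TestPenaltySpec:
    def test_alpha_domain(self):
        with pytest.raises(InvalidParameterError):
            en.PenaltySpec(alpha=1.2)

    def test_grid_must_decrease(self):
        with pytest.raises(InvalidParameterError):
            en.PenaltySpec(lambda_grid=[1.0, 2.0])
        with pytest.raises(InvalidParameterError):
            en.PenaltySpec(lambda_grid=[1.0, -1.0])

    def test_alpha_zero_needs_grid(self):
        Zs, yc = _standardized_toy(30, 5, 0)
        with pytest.raises(InvalidParameterError, match="lambda_grid"):
            en.en_fit_path(Zs, yc, en.PenaltySpec(alpha=0.0))
        # explicit grid works
        path = en.en_fit_path(Zs, yc, en.PenaltySpec(alpha=0.0, lambda_grid=[1.0, 0.5]))
        assert path.coefs.shape == (2, 5)


class TestFitPath:
    def test_all_zero_at_lambda_max(self):
        Zs, yc = _standardized_toy(40, 8, 1)
        lam_max = np.abs(Zs.T @ yc).max() / len(yc)
        path = en.en_fit_path(Zs, yc, en.PenaltySpec(alpha=1.0), lambdas=np.array([lam_max * 1.001]))
        np.testing.assert_allclose(path.coefs[0], 0.0)

    def test_single_predictor_closed_form(self):
        # z'y/n = 2 on a standardized predictor; lambda=1, alpha=0.5 -> S(2,.5)/1.5 = 1
        n = 50
        rng = np.random.default_rng(2)
        z = rng.normal(size=n)
        z = (z - z.mean()) / z.std()
        y = 2.0 * z  # => z'y/n = 2 exactly
        path = en.en_fit_path(
            z[:, None], y, en.PenaltySpec(alpha=0.5, standardize=False), lambdas=np.array([1.0])
        )
        assert path.coefs[0, 0] == pytest.approx(1.0, abs=1e-7)

    def test_kkt_at_alpha_1(self):
        Zs, yc = _standardized_toy(60, 5, 3)
        n = len(yc)
        for lam in (0.05, 0.2, 0.5):
            path = en.en_fit_path(Zs, yc, en.PenaltySpec(alpha=1.0, standardize=False), lambdas=np.array([lam]))
            b = path.coefs[0]
            grad = Zs.T @ (yc - Zs @ b) / n
            active = b != 0
            assert np.all(np.abs(grad[~active]) <= lam + 1e-6)
            if active.any():
                np.testing.assert_allclose(grad[active], lam * np.sign(b[active]), atol=1e-6)

    def test_matches_exhaustive_lasso_oracle(self):
        for seed in range(3):
            Zs, yc = _standardized_toy(40, 5, seed)
            for lam in (0.1, 0.3):
                path = en.en_fit_path(
                    Zs, yc, en.PenaltySpec(alpha=1.0, standardize=False), lambdas=np.array([lam])
                )
                oracle = lasso_oracle(Zs, yc, lam)
                np.testing.assert_allclose(path.coefs[0], oracle, atol=1e-6)

    def test_objective_monotone_per_sweep(self):
        Zs, yc = _standardized_toy(50, 20, 4)
        for alpha, lam in ((1.0, 0.1), (0.5, 0.3), (0.001, 0.05)):
            trace = en.cd_objective_trace(Zs, yc, lam, alpha, n_sweeps=30, standardize=False)
            assert np.all(np.diff(trace) <= 1e-12)

    def test_alpha_continuity_near_ridge(self):
        study = synthio.simulate_study(
            150, 80, synthio.TraitArchitecture(kind="polygenic", h2=0.5), seed=5
        )
        Z = study.genotypes.values
        y = study.true_breeding_values + study.noise
        grid = np.geomspace(10.0, 0.01, 30)
        p3 = en.en_fit_path(Z, y, en.PenaltySpec(alpha=1e-3, lambda_grid=grid))
        p4 = en.en_fit_path(Z, y, en.PenaltySpec(alpha=1e-4, lambda_grid=grid))
        pred3 = Z @ p3.coefs[-1] + p3.intercepts[-1]
        pred4 = Z @ p4.coefs[-1] + p4.intercepts[-1]
        denom = np.linalg.norm(pred3 - pred3.mean())
        assert np.linalg.norm(pred3 - pred4) / denom < 0.01

    def test_back_transform_consistency(self):
        # standardized and raw fits must agree in prediction at the same solution
        rng = np.random.default_rng(6)
        Z = rng.normal(loc=3.0, scale=2.0, size=(80, 10))
        y = Z[:, 0] * 0.5 + rng.normal(size=80)
        path = en.en_fit_path(Z, y, en.PenaltySpec(alpha=1.0), lambdas=np.array([1e-4]))
        pred = Z @ path.coefs[0] + path.intercepts[0]
        # near-unpenalized solution approximates OLS predictions
        X = np.column_stack([np.ones(80), Z])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(pred, X @ beta, atol=1e-2)


class TestCvSelect:
    def test_pure_noise_selects_sparse_model(self):
        rng = np.random.default_rng(7)
        Z = synthio.simulate_genotypes(300, 500, seed=7).values
        y = rng.normal(size=300)
        spec = en.PenaltySpec(alpha=1.0, n_lambda=50, seed=7)
        path = en.en_cv_select(Z, y, spec)
        assert (path.effects.effects == 0).mean() >= 0.95

    def test_signal_beats_intercept_only(self):
        study = synthio.simulate_study(
            500, 1000, synthio.TraitArchitecture(kind="sparse", pi_null=0.99, h2=0.5), seed=8
        )
        Z = study.genotypes.values
        y = study.true_breeding_values + study.noise
        spec = en.PenaltySpec(alpha=1.0, n_lambda=50, seed=8)
        path = en.en_cv_select(Z, y, spec)
        assert path.cv_mse[path.chosen_index] < path.cv_mse[0]

    def test_one_se_rule_selects_larger_lambda(self):
        study = synthio.simulate_study(
            200, 100, synthio.TraitArchitecture(kind="polygenic", h2=0.5), seed=9
        )
        Z = study.genotypes.values
        y = study.true_breeding_values + study.noise
        base = dict(alpha=1.0, n_lambda=40, seed=9)
        p_min = en.en_cv_select(Z, y, en.PenaltySpec(criterion="minMSE", **base))
        p_1se = en.en_cv_select(Z, y, en.PenaltySpec(criterion="minMSE_1SE", **base))
        assert p_1se.chosen_lambda >= p_min.chosen_lambda

    def test_cv_outputs_aligned(self):
        Zs, yc = _standardized_toy(60, 10, 10)
        path = en.en_cv_select(Zs, yc, en.PenaltySpec(alpha=0.5, n_lambda=25, seed=1))
        assert path.cv_mse.shape == path.lambdas.shape == path.cv_se.shape
        assert path.coefs.shape == (25, 10)

    def test_too_few_individuals(self):
        with pytest.raises(InvalidParameterError):
            en.en_cv_select(np.zeros((3, 2)), np.zeros(3), en.PenaltySpec(cv_folds=5))
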