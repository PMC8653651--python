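"""PLS1 core: metrics, NIPALS fits, cross-validation against brute-force oracles."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from ftirquant import (
    MixtureDesign,
    NoiseModel,
    WavenumberAxis,
    cross_validate,
    evaluate,
    fit_pls,
    planted_profiles,
    r_squared,
    rmse,
    simulate_dataset,
    split_train_test,
)
from ftirquant.pls import coefficient_path
from ftirquant.preprocessing import fit_chain, spec_by_name


class TestMetrics:
    def test_rmse_hand_value(self):
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_rmse_scale_equivariance(self, rng):
        y, yh = rng.normal(size=20), rng.normal(size=20)
        assert rmse(2 * y, 2 * yh) == pytest.approx(2 * rmse(y, yh))

    def test_rmse_errors(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            rmse([], [])

    def test_r_squared_trivials(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert r_squared(y, y) == pytest.approx(1.0)
        assert r_squared(y, np.full(4, y.mean())) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            r_squared(np.ones(4), y)

    def test_pearson_definition_matches_sse_for_ls_fit(self, rng):
        """For least-squares fitted values the two R^2 definitions coincide;
        squared Pearson is never below 1 - SSE/SST there."""
        x = rng.normal(size=50)
        y = 2.0 * x + rng.normal(size=50)
        X = np.column_stack([x, np.ones(50)])
        yhat = X @ np.linalg.lstsq(X, y, rcond=None)[0]
        sse = r_squared(y, yhat)
        pearson = r_squared(y, yhat, definition="squared_pearson")
        assert pearson >= sse - 1e-12
        assert pearson == pytest.approx(sse, abs=1e-10)


class TestFitPLS:
    def test_rank_one_problem_solved_with_one_lv(self, rng):
        t = rng.normal(size=20)
        p = rng.normal(size=15)
        X = np.outer(t, p)
        model = fit_pls(X, t, nlvs=1)
        assert rmse(t, model.predict(X)) < 1e-8

    def test_max_nlvs_matches_ols(self, rng):
        """On a tall full-rank problem, PLS with all components equals
        ordinary least squares — the closed-form oracle."""
        X = rng.normal(size=(40, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=40) * 0.1
        model = fit_pls(X, y, nlvs=8)
        Xc = np.column_stack([X, np.ones(40)])
        ols_pred = Xc @ np.linalg.lstsq(Xc, y, rcond=None)[0]
        np.testing.assert_allclose(model.predict(X), ols_pred, atol=1e-6)

    def test_matches_sklearn_pls_coefficients(self, rng):
        """Independent cross-check: sklearn's NIPALS PLS (scale=False)
        must give the same regression coefficients."""
        X = rng.normal(size=(30, 12))
        y = X[:, 0] - 2 * X[:, 3] + rng.normal(size=30) * 0.2
        for nlv in (1, 3, 6):
            ours = fit_pls(X, y, nlvs=nlv)
            ref = PLSRegression(n_components=nlv, scale=False).fit(X, y)
            np.testing.assert_allclose(ours.b, ref.coef_.ravel(), atol=1e-8)

    def test_permutation_invariance(self, rng):
        X = rng.normal(size=(25, 10))
        y = X @ rng.normal(size=10)
        perm = rng.permutation(25)
        b1 = fit_pls(X, y, nlvs=4).b
        b2 = fit_pls(X[perm], y[perm], nlvs=4).b
        np.testing.assert_allclose(b1, b2, atol=1e-10)

    def test_invalid_inputs(self, rng):
        X = rng.normal(size=(10, 5))
        with pytest.raises(ValueError):
            fit_pls(X, np.ones(10), nlvs=2)  # constant y
        with pytest.raises(ValueError):
            fit_pls(X, rng.normal(size=10), nlvs=10)  # nlvs > n - 1

    def test_coefficient_path_consistent_with_single_fits(self, rng):
        X = rng.normal(size=(20, 9))
        y = X @ rng.normal(size=9) + rng.normal(size=20) * 0.1
        B, y_mean, x_mean = coefficient_path(X, y, 5)
        for k in (1, 3, 5):
            np.testing.assert_allclose(B[:, k - 1], fit_pls(X, y, k).b, atol=1e-10)


class TestCrossValidate:
    def test_loo_equals_brute_force_refits(self, rng):
        """LOO RMSECV must equal an independent loop that refits a PLS
        model from scratch for each left-out sample."""
        X = rng.normal(size=(30, 50))
        y = X[:, :3] @ np.array([1.0, -2.0, 0.5]) + rng.normal(size=30) * 0.3
        max_nlvs = 5
        result = cross_validate(X, y, max_nlvs, "loo")
        for nlv in range(1, max_nlvs + 1):
            preds = np.empty(30)
            for i in range(30):
                keep = np.arange(30) != i
                model = fit_pls(X[keep], y[keep], nlv)
                preds[i] = model.predict(X[i : i + 1])[0]
            np.testing.assert_allclose(
                result.rmsecv_by_nlv[nlv - 1], rmse(y, preds), atol=1e-10
            )

    def test_tie_breaks_toward_fewer_latent_variables(self):
        from ftirquant.pls import CVResult

        rmsecv = np.array([5.0, 3.0, 3.0, 4.0])
        assert int(np.argmin(rmsecv)) + 1 == 2  # argmin takes the first minimum
        res = CVResult("leave_one_out", rmsecv, int(np.argmin(rmsecv)) + 1, 0.9)
        assert res.chosen_nlvs == 2 and res.rmsecv == 3.0

    def test_noise_free_two_component_mixtures_need_two_lvs(self, axis):
        target, adulterant = planted_profiles(axis, (1500.0, 1700.0))
        design = MixtureDesign(tuple(range(10, 100, 10)), 2, 2, 2)
        ds = simulate_dataset(design, target, adulterant, NoiseModel.silent(), axis)
        result = cross_validate(ds.absorbance, ds.labels, 3, "loo")
        assert result.rmsecv_by_nlv[1] < 1e-6

    def test_kfold_deterministic_and_feasibility_checked(self, rng):
        X = rng.normal(size=(24, 10))
        y = X @ rng.normal(size=10) + rng.normal(size=24)
        a = cross_validate(X, y, 3, 4, seed=9)
        b = cross_validate(X, y, 3, 4, seed=9)
        np.testing.assert_array_equal(a.rmsecv_by_nlv, b.rmsecv_by_nlv)
        with pytest.raises(ValueError):
            cross_validate(X, y, 3, 25)  # k > n
        with pytest.raises(ValueError):
            cross_validate(X, y, 30, 4)  # max_nlvs infeasible


@pytest.fixture(scope="module")
def fitted(axis):
    target, adulterant = planted_profiles(axis, (1500.0, 1700.0))
    from ftirquant import default_design

    ds = simulate_dataset(default_design(), target, adulterant, NoiseModel(seed=21), axis)
    cal, test = split_train_test(ds, seed=22)
    chain = fit_chain(spec_by_name("SNV"), axis, cal.absorbance)
    X = chain.transform(cal.absorbance)
    cv = cross_validate(X, cal.labels, 8, 7, seed=0)
    model = fit_pls(X, cal.labels, cv.chosen_nlvs)
    return model, chain, cal, test, cv


class TestEvaluate:
    def test_test_set_identical_to_calibration_gives_rmsep_equal_rmsec(self, fitted):
        model, chain, cal, _, _ = fitted
        report = evaluate(model, chain, cal, cal)
        assert report.rmsep == pytest.approx(report.rmsec)

    def test_empty_test_set_rejected(self, fitted):
        model, chain, cal, test, _ = fitted
        with pytest.raises(ValueError, match="empty"):
            evaluate(model, chain, cal, test.take([]))

    def test_generalization_comparable_to_cv(self, fitted):
        """On a held-out split of the same simulated population, RMSEP
        should stay within a factor two of RMSECV."""
        model, chain, cal, test, cv = fitted
        report = evaluate(model, chain, cal, test)
        assert report.rmsep < 2 * cv.rmsecv
        assert report.r2_test > 0.9
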