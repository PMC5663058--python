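"""Imputation, autoscaling, PLS/VIP against independent oracles, CV, PCA."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from thermetab import chemometrics as chem


def orthonormal_predictors(n, p, rng):
    """Random matrix with mutually orthogonal, mean-zero, unit-SD columns."""
    A = rng.standard_normal((n, p + 1))
    A[:, 0] = 1.0  # force orthogonality to the constant => exact zero means
    q, _ = np.linalg.qr(A)
    X = q[:, 1:] * np.sqrt(n - 1)
    return pd.DataFrame(X, columns=[f"m{j}" for j in range(p)])


def small_matrix(rng, n=12, p=6, missing=0):
    values = pd.DataFrame(
        rng.uniform(5, 15, size=(n, p)),
        index=[f"pl{i}" for i in range(n)],
        columns=[f"m{j}" for j in range(p)],
    )
    if missing:
        idx = rng.choice(n * p, size=missing, replace=False)
        flat = values.to_numpy().ravel()
        flat[idx] = np.nan
        values[:] = flat.reshape(n, p)
    treatments = pd.Series(["W", "C", "D"] * (n // 3), index=values.index)
    return chem.MetaboliteMatrix(values=values, treatments=treatments)


class TestMetaboliteMatrix:
    def test_duplicate_names_rejected(self, rng):
        values = pd.DataFrame(np.ones((4, 2)), columns=["a", "a"])
        with pytest.raises(ValueError, match="duplicate"):
            chem.MetaboliteMatrix(values=values, treatments=pd.Series(["W", "W", "D", "D"]))

    def test_small_treatment_rejected(self):
        values = pd.DataFrame(np.ones((3, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="< 2 plants"):
            chem.MetaboliteMatrix(values=values, treatments=pd.Series(["W", "W", "D"]))

    def test_csv_round_trip_with_missing(self, tmp_path, rng):
        mat = small_matrix(rng, missing=5)
        mat.to_csv(tmp_path / "m.csv")
        back = chem.MetaboliteMatrix.from_csv(tmp_path / "m.csv")
        pd.testing.assert_frame_equal(back.values, mat.values, check_names=False)
        assert back.n_missing == 5
        assert (back.treatments == mat.treatments).all()


class TestImputation:
    def test_complete_matrix_returned_identical(self, rng):
        mat = small_matrix(rng)
        out = chem.impute_missing(mat)
        pd.testing.assert_frame_equal(out.values, mat.values)

    def test_mean_imputation_definition(self, rng):
        mat = small_matrix(rng, missing=0)
        mat.values.iloc[0, 0] = np.nan
        out = chem.impute_missing(mat, method="mean")
        assert out.values.iloc[0, 0] == pytest.approx(mat.values.iloc[1:, 0].mean())

    def test_fully_missing_column_named(self, rng):
        mat = small_matrix(rng)
        mat.values["m3"] = np.nan
        with pytest.raises(ValueError, match="m3"):
            chem.impute_missing(mat)

    @pytest.mark.parametrize("method", ["mean", "knn", "iterative"])
    def test_observed_cells_untouched_and_deterministic(self, rng, method):
        mat = small_matrix(rng, missing=8)
        out1 = chem.impute_missing(mat, method=method, seed=11)
        out2 = chem.impute_missing(mat, method=method, seed=11)
        pd.testing.assert_frame_equal(out1.values, out2.values)
        obs = (~mat.missing_mask).to_numpy()
        assert np.array_equal(
            out1.values.to_numpy()[obs], mat.values.to_numpy()[obs]
        )
        assert out1.n_missing == 0

    def test_iterative_beats_mean_under_correlation(self):
        """With strongly correlated metabolites (rho = 0.8) the chained
        imputer should beat column means on masked ground truth."""
        rng = np.random.default_rng(5)
        n, p, rho = 24, 8, 0.8
        factor = rng.standard_normal(n)
        X = 10 + np.sqrt(rho) * factor[:, None] + np.sqrt(1 - rho) * rng.standard_normal((n, p))
        truth = pd.DataFrame(X, columns=[f"m{j}" for j in range(p)])
        mask = rng.random(truth.shape) < 0.05
        masked = truth.mask(mask)
        treatments = pd.Series(["W", "C", "D"] * (n // 3), index=truth.index)
        mat = chem.MetaboliteMatrix(values=masked, treatments=treatments)
        errs = {}
        for method in ("mean", "iterative"):
            out = chem.impute_missing(mat, method=method, seed=1)
            errs[method] = np.sqrt(np.mean((out.values.to_numpy() - X)[mask] ** 2))
        assert errs["iterative"] < errs["mean"]


class TestAutoscale:
    def test_scaled_moments_and_round_trip(self, rng):
        X = pd.DataFrame(rng.uniform(0, 50, (15, 5)))
        Xs, centers, scales = chem.autoscale(X)
        assert np.allclose(Xs.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(Xs.std(axis=0, ddof=1), 1.0, atol=1e-12)
        pd.testing.assert_frame_equal(Xs * scales + centers, X)

    def test_zero_variance_dropped_with_warning(self, rng):
        X = pd.DataFrame(rng.standard_normal((10, 3)), columns=["a", "b", "c"])
        X["b"] = 7.0
        with pytest.warns(UserWarning, match="b"):
            Xs, _, _ = chem.autoscale(X)
        assert list(Xs.columns) == ["a", "c"]


class TestPLSFit:
    def test_perfect_single_predictor(self, rng):
        X = orthonormal_predictors(12, 5, rng)
        y = X["m0"].to_numpy()
        model = chem.pls_fit(X, y, n_comp=1)
        coef = model.coefficients()
        assert coef["m0"] == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(coef.drop("m0"), 0.0, atol=1e-10)
        assert np.allclose(model.predict(X), y, atol=1e-10)

    def test_matches_reference_implementation(self, rng):
        """Coefficients, predictions and scores agree with an independent
        NIPALS PLS implementation on 20 random problems."""
        for _ in range(20):
            X = pd.DataFrame(rng.standard_normal((12, 8)))
            y = rng.standard_normal(12)
            A = int(rng.integers(1, 7))
            mine = chem.pls_fit(X, y, n_comp=A, scale=False)
            ref = PLSRegression(n_components=A, scale=False).fit(X.to_numpy(), y)
            assert np.allclose(
                mine.coefficients().to_numpy(), ref.coef_.ravel(), atol=1e-8
            )
            assert np.allclose(
                mine.predict(X), ref.predict(X.to_numpy()).ravel(), atol=1e-8
            )
            # scores agree up to the per-component sign convention
            for a in range(A):
                t_mine, t_ref = mine.T[:, a], ref.x_scores_[:, a]
                sign = np.sign(t_mine @ t_ref)
                assert np.allclose(t_mine, sign * t_ref, atol=1e-8)

    def test_full_rank_equals_least_squares(self, rng):
        X = pd.DataFrame(rng.standard_normal((12, 8)))
        y = rng.standard_normal(12)
        model = chem.pls_fit(X, y, n_comp=8, scale=False)
        Xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc.to_numpy(), y - y.mean(), rcond=None)
        pred_ols = y.mean() + Xc.to_numpy() @ beta
        assert np.allclose(model.predict(X), pred_ols, atol=1e-8)

    def test_score_orthogonality_and_unit_weights(self, rng):
        X = pd.DataFrame(rng.standard_normal((18, 10)))
        y = rng.standard_normal(18)
        model = chem.pls_fit(X, y, n_comp=5)
        G = model.T.T @ model.T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-10
        assert np.allclose(np.linalg.norm(model.W, axis=0), 1.0, atol=1e-12)

    def test_invalid_component_count(self, rng):
        X = pd.DataFrame(rng.standard_normal((6, 4)))
        with pytest.raises(ValueError):
            chem.pls_fit(X, rng.standard_normal(6), n_comp=6)


class TestVIP:
    def test_one_component_closed_form(self, rng):
        """Single component: VIP_j = sqrt(p) |w_j|; perfectly aligned
        predictor with an orthogonal partner gives (sqrt(2), 0)."""
        X = orthonormal_predictors(10, 2, rng)
        y = X["m0"].to_numpy()
        model = chem.pls_fit(X, y, n_comp=1)
        vip = chem.vip_scores(model).vip
        assert vip["m0"] == pytest.approx(np.sqrt(2.0), abs=1e-10)
        assert vip["m1"] == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(vip.to_numpy(), np.sqrt(2) * np.abs(model.W[:, 0]), atol=1e-10)

    def test_vip_normalisation(self, rng):
        for _ in range(5):
            X = pd.DataFrame(rng.standard_normal((15, 9)))
            y = rng.standard_normal(15)
            model = chem.pls_fit(X, y, n_comp=int(rng.integers(1, 6)))
            vip = chem.vip_scores(model).vip
            assert np.sum(vip**2) == pytest.approx(9.0, rel=1e-10)

    def test_noise_predictor_ranks_below_threshold(self):
        """A pure-noise predictor added to informative ones stays below the
        mean-VIP selection threshold in nearly all seeded runs."""
        hits = 0
        n_runs = 100
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            signal = rng.standard_normal(18)
            X = pd.DataFrame(
                {
                    "s1": signal + 0.2 * rng.standard_normal(18),
                    "s2": -signal + 0.2 * rng.standard_normal(18),
                    "s3": signal + 0.2 * rng.standard_normal(18),
                    "noise": rng.standard_normal(18),
                }
            )
            model = chem.pls_fit(X, signal, n_comp=2)
            res = chem.vip_scores(model)
            hits += not res.above_mean["noise"]
        assert hits >= 95


class TestCrossValidation:
    def test_intercept_baseline_closed_form(self, rng):
        """LOO 0-component RMSEP equals the closed-form leave-one-out mean
        error sqrt(mean((y_i - ybar)^2)) * n/(n-1)."""
        y = rng.standard_normal(14)
        X = pd.DataFrame(rng.standard_normal((14, 5)))
        cv = chem.cross_validate(X, y, max_comp=3)
        n = len(y)
        expected = np.sqrt(np.mean((y - y.mean()) ** 2)) * n / (n - 1)
        assert cv.rmsep_cv[0] == pytest.approx(expected, rel=1e-12)

    def test_noise_free_recovery_within_k_components(self, rng):
        """y built from k orthogonal predictors: k components capture
        essentially all predictable variation (>95% RMSEP reduction)."""
        k = 3
        X = orthonormal_predictors(16, 8, rng)
        y = X.iloc[:, :k].sum(axis=1).to_numpy()
        cv = chem.cross_validate(X, y, max_comp=6)
        assert cv.rmsep_adj[k] < 0.05 * cv.rmsep_adj[0]
        assert cv.r2_train[k] == pytest.approx(1.0, abs=1e-10)

    def test_permutation_destroys_structure(self, rng):
        X = orthonormal_predictors(18, 10, rng)
        y = X.iloc[:, 0].to_numpy() + 0.3 * rng.standard_normal(18)
        r2s = []
        for _ in range(20):
            yp = rng.permutation(y)
            cv = chem.cross_validate(X, yp, max_comp=5)
            r2s.append(cv.r2_cv[cv.n_comp])
        assert np.mean(r2s) <= 0.2

    def test_kfold_seeded_deterministic(self, rng):
        X = pd.DataFrame(rng.standard_normal((15, 6)))
        y = rng.standard_normal(15)
        a = chem.cross_validate(X, y, max_comp=3, scheme="kfold", n_folds=5, seed=4)
        b = chem.cross_validate(X, y, max_comp=3, scheme="kfold", n_folds=5, seed=4)
        assert np.array_equal(a.rmsep_cv, b.rmsep_cv)


class TestSelectComponents:
    def _cv(self, curve):
        z = np.zeros(len(curve))
        return chem.CVResult(
            rmsep_cv=np.asarray(curve, float), rmsep_adj=np.asarray(curve, float),
            r2_cv=z, r2_train=z,
        )

    def test_valley(self):
        assert chem.select_components(self._cv([5, 4, 3, 2, 3, 4])) == 3

    def test_tie_toward_fewer(self):
        assert chem.select_components(self._cv([5, 4, 2, 3, 2, 4])) == 2

    def test_monotone_increasing(self):
        assert chem.select_components(self._cv([1, 2, 3, 4])) == 1


class TestPCA:
    def test_collinear_data_single_component(self):
        t = np.linspace(-1, 1, 10)
        X = pd.DataFrame({"a": 2 * t, "b": -3 * t})
        _, var = chem.pca_overview(X, n_comp=1)
        assert var[0] == pytest.approx(1.0)

    def test_fractions_non_increasing_and_bounded(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 8)))
        _, var = chem.pca_overview(X, n_comp=6)
        assert np.all(np.diff(var) <= 1e-12)
        assert var.sum() <= 1.0 + 1e-12

    def test_agrees_with_svd_oracle(self, rng):
        X = pd.DataFrame(rng.standard_normal((15, 6)))
        scores, var = chem.pca_overview(X, n_comp=4)
        Xc = (X - X.mean(axis=0)).to_numpy()
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        oracle_scores = U[:, :4] * S[:4]
        for a in range(4):
            sign = np.sign(scores.iloc[:, a].to_numpy() @ oracle_scores[:, a])
            assert np.allclose(scores.iloc[:, a], sign * oracle_scores[:, a], atol=1e-10)
        assert np.allclose(var, (S**2 / (S**2).sum())[:4], atol=1e-10)
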