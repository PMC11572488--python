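"""Elastic Net fitting, LOOCV protocol, covariate CIs, and prediction."""

import numpy as np
import pandas as pd
import pytest

from bsclock.clock_model import (
    ClockModel,
    _standardize,
    covariate_ci,
    encode_covariates,
    feature_overlap,
    fit_elastic_net,
    loocv_predict,
    penalized_objective,
    predict_ages,
)


def _toy(rng, n=40, p=5, q=2, gamma=(4.0, -2.0), noise=1.0):
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"g{j}" for j in range(p)])
    D = pd.DataFrame(
        rng.integers(0, 2, size=(n, q)).astype(float), columns=["lymphoma", "als"][:q]
    )
    b = rng.normal(size=p) * 3
    y = 30 + X.to_numpy() @ b + D.to_numpy() @ np.asarray(gamma) + rng.normal(0, noise, n)
    return X, D, y


class TestEncodeCovariates:
    def test_one_hot_with_reference_dropped(self, sample_table_4):
        D = encode_covariates(sample_table_4.set_index("sample", drop=False))
        assert D.shape == (4, 2)
        assert list(D.columns) == ["leukemia", "lymphoma"]
        assert D.loc["s1"].sum() == 0  # reference samples all-zero

    def test_all_normal_gives_empty_matrix(self, sample_table_4):
        t = sample_table_4.copy()
        t["disease"] = "normal"
        D = encode_covariates(t.set_index("sample", drop=False))
        assert D.shape == (4, 0)

    def test_unseen_label_rejected_with_known_levels(self, sample_table_4):
        t = sample_table_4.set_index("sample", drop=False)
        with pytest.raises(ValueError, match="known levels"):
            encode_covariates(t, vocabulary=["normal", "leukemia"])


class TestFitElasticNet:
    def test_unpenalized_matches_normal_equations(self, rng):
        """lam1 = lam2 = 0, p < n, no covariates -> OLS closed form."""
        X, _, y = _toy(rng, q=0, gamma=())
        model = fit_elastic_net(X, y, 0.0, 0.0, include_covariates=False)
        Xs, _, _ = _standardize(X.to_numpy())
        M = np.column_stack([np.ones(len(y)), Xs])
        expected = np.linalg.solve(M.T @ M, M.T @ y)
        assert model.intercept == pytest.approx(expected[0], abs=1e-6)
        np.testing.assert_allclose(model.coef.to_numpy(), expected[1:], atol=1e-6)

    def test_full_shrinkage_leaves_intercept_and_covariates(self, rng):
        X, D, y = _toy(rng)
        model = fit_elastic_net(X, y, 1e9, 0.0, D=D)
        assert (model.coef == 0.0).all()
        # prediction reduces to beta0 + D @ gamma, the unpenalized block's OLS
        Z = np.column_stack([np.ones(len(y)), D.to_numpy()])
        expected_block = np.linalg.lstsq(Z, y, rcond=None)[0]
        assert model.intercept == pytest.approx(expected_block[0], abs=1e-6)
        np.testing.assert_allclose(
            model.covariate_coef.to_numpy(), expected_block[1:], atol=1e-6
        )

    def test_model2_equals_model1_without_covariates(self, rng):
        X, D, y = _toy(rng)
        m1 = fit_elastic_net(X, y, 0.4, 0.2, D=D.iloc[:, :0], include_covariates=True)
        m2 = fit_elastic_net(X, y, 0.4, 0.2, include_covariates=False)
        np.testing.assert_allclose(m1.coef.to_numpy(), m2.coef.to_numpy(), atol=1e-10)
        assert m1.intercept == pytest.approx(m2.intercept, abs=1e-10)

    @pytest.mark.parametrize("lam1,lam2", [(0.5, 0.3), (1.0, 0.0), (0.0, 0.7)])
    def test_kkt_optimality_with_covariates(self, rng, lam1, lam2):
        """Stationarity of the penalized objective: the site block satisfies
        the Elastic Net subgradient conditions and the unpenalized
        intercept/covariate block has zero gradient."""
        X, D, y = _toy(rng)
        m = fit_elastic_net(X, y, lam1, lam2, D=D)
        Xs, _, _ = _standardize(X.to_numpy())
        beta, gamma = m.coef.to_numpy(), m.covariate_coef.to_numpy()
        resid = y - m.intercept - Xs @ beta - D.to_numpy() @ gamma
        n = len(y)
        grad_sites = Xs.T @ resid / n  # = lam1*sign(b) + 2*lam2*b at optimum
        for g, b in zip(grad_sites, beta):
            if b != 0.0:
                assert g == pytest.approx(lam1 * np.sign(b) + 2 * lam2 * b, abs=1e-6)
            else:
                assert abs(g) <= lam1 + 1e-6
        Z = np.column_stack([np.ones(n), D.to_numpy()])
        np.testing.assert_allclose(Z.T @ resid / n, 0.0, atol=1e-6)

    def test_objective_never_exceeds_null_model(self, rng):
        X, D, y = _toy(rng)
        for lam1, lam2 in [(0.1, 0.0), (0.0, 0.5), (2.0, 2.0)]:
            m = fit_elastic_net(X, y, lam1, lam2, D=D)
            Xs, _, _ = _standardize(X.to_numpy())
            fitted = penalized_objective(
                Xs, y, D.to_numpy(), m.intercept, m.coef.to_numpy(),
                m.covariate_coef.to_numpy(), lam1, lam2,
            )
            null = penalized_objective(
                Xs, y, D.to_numpy(), float(np.mean(y)), np.zeros(X.shape[1]),
                np.zeros(D.shape[1]), lam1, lam2,
            )
            assert fitted <= null + 1e-12

    def test_prediction_invariant_to_column_rescaling(self, rng):
        X, D, y = _toy(rng)
        m1 = fit_elastic_net(X, y, 0.3, 0.2, D=D)
        X2 = X.copy()
        X2["g0"] = X2["g0"] * 37.0 + 4.2
        m2 = fit_elastic_net(X2, y, 0.3, 0.2, D=D)
        p1 = predict_ages(m1, X, sample_table=None)
        p2 = predict_ages(m2, X2, sample_table=None)
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-6)

    def test_underdetermined_unpenalized_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 10)))
        with pytest.raises(ValueError, match="underdetermined"):
            fit_elastic_net(X, np.arange(5.0) + 1, 0.0, 0.0, include_covariates=False)

    def test_nonfinite_inputs_rejected(self, rng):
        X, _, y = _toy(rng, q=0, gamma=())
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_elastic_net(X, y, 0.1, 0.1, include_covariates=False)


def test_model_json_roundtrip(tmp_path, rng):
    X, D, y = _toy(rng)
    m = fit_elastic_net(X, y, 0.3, 0.2, D=D)
    m.to_json(tmp_path / "model.json")
    back = ClockModel.from_json(tmp_path / "model.json")
    pd.testing.assert_series_equal(m.coef, back.coef)
    pd.testing.assert_series_equal(m.covariate_coef, back.covariate_coef)
    assert back.lam1 == m.lam1 and back.intercept == pytest.approx(m.intercept)
    X_pred = X.copy()
    np.testing.assert_allclose(
        predict_ages(m, X_pred, None).to_numpy(),
        predict_ages(back, X_pred, None).to_numpy(),
        atol=1e-12,
    )


def _linear_cohort(rng, n=12, p=3, noise=0.05):
    """Ages an exact linear function of p sites, tiny noise."""
    X = pd.DataFrame(
        rng.uniform(0.1, 0.9, size=(n, p)),
        columns=[f"chr1:{100 * (j + 1)}" for j in range(p)],
        index=[f"s{i:02d}" for i in range(n)],
    )
    w = np.array([60.0, -40.0, 30.0])[:p]
    y = 40 + (X.to_numpy() - 0.5) @ w + rng.normal(0, noise, n)
    samples = pd.DataFrame(
        {
            "sample": X.index,
            "age": np.clip(y, 1, None),
            "sex": "unknown",
            "disease": "normal",
        }
    ).set_index("sample", drop=False)
    return X, samples


class TestLoocv:
    def test_recovers_linear_structure(self, rng):
        X, samples = _linear_cohort(rng)
        run = loocv_predict(
            X, samples, include_covariates=False,
            grid=[(0.01, 0.0), (0.1, 0.01)], seed=1,
        )
        err = np.abs(run.table["predicted"] - run.table["age"])
        assert err.max() < 1.0

    def test_order_invariance(self, rng):
        X, samples = _linear_cohort(rng, n=14)
        run1 = loocv_predict(X, samples, include_covariates=False,
                             grid=[(0.01, 0.0), (0.2, 0.1)], seed=3)
        perm = rng.permutation(len(X))
        run2 = loocv_predict(X.iloc[perm], samples.iloc[perm],
                             include_covariates=False,
                             grid=[(0.01, 0.0), (0.2, 0.1)], seed=3)
        merged = run1.table.merge(run2.table, on="sample", suffixes=("_a", "_b"))
        np.testing.assert_allclose(
            merged["predicted_a"], merged["predicted_b"], atol=1e-12
        )

    def test_duplicated_samples_predicted_alike(self, rng):
        X, samples = _linear_cohort(rng, n=10)
        X2 = pd.concat([X, X.set_axis([f"t{i:02d}" for i in range(10)])])
        s2 = pd.concat(
            [samples, samples.assign(sample=[f"t{i:02d}" for i in range(10)])
                          .set_index("sample", drop=False)]
        )
        run = loocv_predict(X2, s2, include_covariates=False, grid=[(0.05, 0.01)], seed=0)
        t = run.table.set_index("sample")
        for i in range(10):
            assert t.loc[f"s{i:02d}", "predicted"] == pytest.approx(
                t.loc[f"t{i:02d}", "predicted"], abs=1e-6
            )

    def test_too_small_cohort_rejected(self, rng):
        X, samples = _linear_cohort(rng, n=5)
        with pytest.raises(ValueError, match="too small"):
            loocv_predict(X, samples, inner_k=5, grid=[(0.1, 0.0)])


class TestCovariateCI:
    def _run_with_coefs(self, coefs: np.ndarray, level_name="leukemia"):
        n = len(coefs)
        table = pd.DataFrame(
            {"sample": [f"s{i}" for i in range(n)], "age": 50.0,
             "predicted": 50.0, "lam1": 0.1, "lam2": 0.0}
        )
        from bsclock.clock_model import LoocvRun

        return LoocvRun(
            table=table,
            covariate_coefs=pd.DataFrame({level_name: coefs}, index=table["sample"]),
            include_covariates=True,
            covariate_levels=["normal", level_name],
            seed=0,
        )

    def test_constant_coefficient_degenerate_interval(self):
        ci = covariate_ci(self._run_with_coefs(np.full(20, 2.5)))
        row = ci.loc["leukemia"]
        assert row["lower"] == row["upper"] == row["coefficient"] == 2.5

    def test_percentile_bounds_linear_interpolation(self):
        """Coefficients 1..100 -> 2.5th/97.5th percentiles 3.475 / 97.525."""
        ci = covariate_ci(self._run_with_coefs(np.arange(1.0, 101.0)))
        row = ci.loc["leukemia"]
        assert row["lower"] == pytest.approx(3.475, abs=1e-12)
        assert row["upper"] == pytest.approx(97.525, abs=1e-12)
        assert row["coefficient"] == pytest.approx(50.5)
        # age_effect view is the negated coefficient with flipped bounds
        assert row["age_effect"] == pytest.approx(-50.5)
        assert row["age_effect_lower"] == pytest.approx(-97.525, abs=1e-12)

    def test_no_covariates_warns_and_returns_empty(self, rng):
        X, samples = _linear_cohort(rng, n=10)
        run = loocv_predict(X, samples, include_covariates=False, grid=[(0.05, 0.0)])
        with pytest.warns(UserWarning, match="no covariates"):
            ci = covariate_ci(run)
        assert ci.empty

    def test_normal_method_symmetric(self):
        ci = covariate_ci(self._run_with_coefs(np.arange(1.0, 101.0)), method="normal")
        row = ci.loc["leukemia"]
        assert row["upper"] - row["coefficient"] == pytest.approx(
            row["coefficient"] - row["lower"], abs=1e-9
        )


class TestPredictAges:
    def test_training_matrix_reproduces_fitted_values(self, rng):
        X, D, y = _toy(rng)
        m = fit_elastic_net(X, y, 0.2, 0.1, D=D)
        Xs, _, _ = _standardize(X.to_numpy())
        fitted = m.intercept + Xs @ m.coef.to_numpy() + D.to_numpy() @ m.covariate_coef.to_numpy()
        samples = pd.DataFrame(
            {"sample": X.index.astype(str), "age": np.clip(y, 1, None),
             "sex": "unknown",
             "disease": np.where(D["lymphoma"] == 1, "lymphoma",
                                 np.where(D["als"] == 1, "als", "normal"))}
        ).set_index("sample", drop=False)
        # rows where both indicators fire cannot be expressed as one label
        clean = (D.sum(axis=1) <= 1).to_numpy()
        got = predict_ages(m, X[clean].set_index(samples.index[clean]),
                           sample_table=samples[clean])
        np.testing.assert_allclose(got.to_numpy(), fitted[clean], atol=1e-9)

    def test_all_sites_missing_gives_intercept_plus_covariates(self, rng):
        X, D, y = _toy(rng)
        m = fit_elastic_net(X, y, 0.2, 0.1, D=D.iloc[:, :0], include_covariates=False)
        other = pd.DataFrame({"zz:1": [0.5, 0.2]}, index=["a", "b"])
        pred = predict_ages(m, other, max_missing=1.0)
        np.testing.assert_allclose(pred.to_numpy(), m.intercept)

    def test_missingness_cap_enforced(self, rng):
        X, _, y = _toy(rng, q=0, gamma=())
        m = fit_elastic_net(X, y, 0.2, 0.1, include_covariates=False)
        partial = X[["g0", "g1"]]
        with pytest.raises(ValueError, match="refusing to predict"):
            predict_ages(m, partial, max_missing=0.5)

    def test_covariate_model_without_metadata_warns(self, rng):
        X, D, y = _toy(rng)
        m = fit_elastic_net(X, y, 0.2, 0.1, D=D)
        with pytest.warns(UserWarning, match="reference class"):
            predict_ages(m, X, sample_table=None)


class TestFeatureOverlap:
    def _model(self, rng, sites):
        X = pd.DataFrame(rng.uniform(size=(30, len(sites))), columns=sites)
        y = 10 + 50 * X.mean(axis=1).to_numpy() + rng.normal(0, 0.1, 30)
        return fit_elastic_net(X, y, 0.001, 0.001, include_covariates=False)

    def test_identical_and_disjoint(self, rng):
        a = self._model(rng, ["s1", "s2", "s3"])
        b = self._model(rng, ["s4", "s5"])
        overlap, unique = feature_overlap({"A": a, "A2": a, "B": b})
        p = len(a.selected_sites)
        assert overlap.loc["A", "A2"] == p
        assert overlap.loc["A", "B"] == 0
        assert unique["A"] == 0 and unique["B"] == len(b.selected_sites)
        assert (overlap.to_numpy() == overlap.to_numpy().T).all()

    def test_overlap_bounded_by_smaller_model(self, rng):
        a = self._model(rng, ["s1", "s2", "s3"])
        b = self._model(rng, ["s2", "s3", "s4", "s5"])
        overlap, _ = feature_overlap({"A": a, "B": b})
        assert 0 <= overlap.loc["A", "B"] <= min(overlap.loc["A", "A"], overlap.loc["B", "B"])

    def test_single_model_rejected(self, rng):
        a = self._model(rng, ["s1"])
        with pytest.raises(ValueError, match="at least 2"):
            feature_overlap({"A": a})
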