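"""MPLS calibration: estimator, CV/LV selection, outliers, domain flags."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from colosig import mpls
from colosig.preprocess import PretreatmentSpec


def toy_problem(seed=0, n=20, p=50, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p) * 0.2
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


class TestStratifiedSplit:
    def test_single_stratum_rounding(self):
        assign = mpls.stratified_split(np.zeros(100), 0.28, seed=0)
        assert (assign == "calibration").sum() == 28

    def test_proportions_kept_within_one_sample(self):
        rng = np.random.default_rng(5)
        strata = rng.choice(
            ["1", "2", "3", "4", "5-8"], size=693,
            p=[0.289, 0.297, 0.184, 0.121, 0.109],
        )
        assign = mpls.stratified_split(strata, 0.28, seed=1)
        for lev in np.unique(strata):
            n_s = (strata == lev).sum()
            n_cal = ((strata == lev) & (assign == "calibration")).sum()
            assert abs(n_cal - 0.28 * n_s) <= 1.0

    def test_seed_reproducibility(self):
        strata = np.repeat(["a", "b"], 50)
        a = mpls.stratified_split(strata, 0.28, seed=3)
        b = mpls.stratified_split(strata, 0.28, seed=3)
        assert np.array_equal(a, b)


class TestMPLSRegressor:
    def test_equals_pls1_without_residual_scaling(self):
        """With residual SDs forced to one, MPLS is textbook PLS1."""
        X, y = toy_problem(0)
        for k in (1, 3, 5):
            ours = mpls.MPLSRegressor(k, scale_residuals=False).fit(X, y)
            sk = PLSRegression(n_components=k, scale=False).fit(X, y[:, None])
            assert np.allclose(
                ours.predict(X), sk.predict(X).ravel(), atol=1e-8
            )

    def test_rank_one_noiseless_fits_exactly(self):
        rng = np.random.default_rng(1)
        direction = rng.normal(size=40)
        t = rng.normal(size=15)
        X = np.outer(t, direction)
        y = 3.0 * t + 1.0
        m = mpls.MPLSRegressor(1).fit(X, y)
        assert np.allclose(m.predict(X), y, atol=1e-10)

    def test_rmse_c_nonincreasing_in_lv(self):
        X, y = toy_problem(2, noise=0.5)
        rmses = [
            np.sqrt(np.mean((y - mpls.MPLSRegressor(k).fit(X, y).predict(X)) ** 2))
            for k in range(1, 8)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(rmses, rmses[1:]))

    def test_rank_deficiency_reports_achievable_rank(self):
        X = np.outer(np.arange(10.0), np.ones(5))
        y = np.arange(10.0)
        with pytest.raises(mpls.MplsError, match="rank"):
            mpls.MPLSRegressor(4).fit(X, y)

    def test_domain_statistics_scaling(self):
        X, y = toy_problem(3, n=40)
        m = mpls.MPLSRegressor(5).fit(X, y)
        h = m.spectral_h(X)
        # mean calibration H is (n-1)/n under the chosen scaling
        assert h.mean() == pytest.approx((40 - 1) / 40, rel=1e-6)
        # the calibration centroid has H (= GH) of zero
        assert m.spectral_h(m.x_mean_[None, :])[0] == pytest.approx(0.0, abs=1e-10)
        # a calibration spectrum is its own nearest neighbour
        assert m.neighbourhood_h(X).min() == pytest.approx(0.0, abs=1e-10)


class TestCrossValidation:
    def test_noiseless_rank_one_rmse_cv_near_zero(self):
        rng = np.random.default_rng(4)
        t = rng.normal(size=60)
        X = np.outer(t, rng.normal(size=30))
        y = 2.0 * t
        curve = mpls.cross_validate(X, y, PretreatmentSpec(), max_lv=3, seed=0)
        assert curve[0] < 1e-8

    def test_invariant_to_sample_order_given_seed(self):
        X, y = toy_problem(5, n=60, noise=0.3)
        c1 = mpls.cross_validate(X, y, PretreatmentSpec(), 4, seed=7)
        c2 = mpls.cross_validate(X, y, PretreatmentSpec(), 4, seed=7)
        assert np.array_equal(c1, c2)

    def test_max_lv_reduced_with_warning(self):
        X, y = toy_problem(6, n=22)
        with pytest.warns(UserWarning, match="reduced"):
            curve = mpls.cross_validate(X, y, PretreatmentSpec(), 30, seed=0)
        assert len(curve) < 30


class TestSelectLv:
    def test_flat_curve_picks_one(self):
        assert mpls.select_lv([5.0, 5.0, 5.0], 50) == 1

    def test_f_rule_example(self):
        # (4.0/3.85)^2 = 1.079 below the alpha=0.25 critical value at n=100
        assert mpls.select_lv([10.0, 4.0, 3.9, 3.85], 100) == 2

    def test_minimum_at_first_lv(self):
        assert mpls.select_lv([1.0, 2.0, 3.0], 100) == 1


class TestOutlierPasses:
    def test_clean_data_zero_removals(self, noiseless_dataset):
        """A clean (noise- and scatter-free) calibration set loses nothing."""
        X, y = noiseless_dataset["X"], noiseless_dataset["y"]
        retained, log = mpls.calibration_outlier_passes(
            X, y, PretreatmentSpec(), n_lv=5
        )
        assert len(log) == 0
        assert retained.size == X.shape[0]

    def test_leverage_outlier_removed_by_h(self, clean_dataset):
        X = clean_dataset["X"].copy()
        y = clean_dataset["y"]
        X[7] = X[7] * 100.0
        retained, log = mpls.calibration_outlier_passes(
            X, y, PretreatmentSpec(), n_lv=5
        )
        assert 7 not in retained
        row = log[log["row"] == 7].iloc[0]
        assert row["pass_no"] == 1 and "H" in row["rule"]

    def test_residual_outlier_removed_by_t(self, clean_dataset):
        X, y = clean_dataset["X"], clean_dataset["y"].copy()
        base = mpls.MPLSRegressor(5).fit(X, y)
        y[11] += 10.0 * base.sec_
        retained, log = mpls.calibration_outlier_passes(
            X, y, PretreatmentSpec(), n_lv=5
        )
        assert 11 not in retained
        assert "T" in log[log["row"] == 11].iloc[0]["rule"]


class TestDevelopModel:
    def test_grid_of_one(self, clean_dataset):
        X, y = clean_dataset["X"], clean_dataset["y"]
        model, board = mpls.develop_model(
            X, y, grid=[PretreatmentSpec()], max_lv=6, seed=0
        )
        assert len(board) == 1
        assert model.spec.scatter == "none"

    def test_scatter_correction_wins_under_scatter(self, scattered_dataset):
        """With multiplicative scatter, SNV or MSC beats raw spectra."""
        X, y = scattered_dataset["X"], scattered_dataset["y"]
        grid = [
            PretreatmentSpec("none"),
            PretreatmentSpec("snv"),
            PretreatmentSpec("msc"),
        ]
        model, board = mpls.develop_model(X, y, grid=grid, max_lv=8, seed=0)
        assert model.spec.scatter in ("snv", "msc")
        none_rmse = board.loc[board["scatter"] == "none", "rmse_cv"].iloc[0]
        assert model.rmse_cv < none_rmse


@pytest.fixture(scope="module")
def fitted(clean_dataset):
    X, y = clean_dataset["X"], clean_dataset["y"]
    model, _ = mpls.develop_model(
        X, y, grid=[PretreatmentSpec("none")], max_lv=6, seed=0
    )
    return model, X, y


class TestPrediction:
    def test_calibration_spectra_inside_domain(self, fitted):
        model, X, _ = fitted
        pred = model.predict(X[model.retained_rows])
        # calibration spectra are their own nearest neighbours (NH = 0)
        # and essentially none sit outside the GH/NH domain
        assert pred["NH"].min() == pytest.approx(0.0, abs=1e-10)
        assert (pred["NH"] <= model.nh_max).all()
        assert pred["excluded"].mean() < 0.05

    def test_extrapolation_flagged_by_gh(self, fitted):
        model, X, _ = fitted
        pred = model.predict(X[:5] * 100.0)
        assert pred["excluded"].all()
        assert (pred["GH"] > model.gh_max).all()

    def test_flags_do_not_alter_predictions(self, fitted):
        model, X, _ = fitted
        wild = np.vstack([X[:5], X[:5] * 100.0])
        pred = model.predict(wild)
        assert pred["excluded"].tolist() == [False] * 5 + [True] * 5
        again = model.predict(X[:5] * 100.0)
        assert np.allclose(pred["prediction"].iloc[5:], again["prediction"])

    def test_serialisation_roundtrip(self, fitted, tmp_path):
        model, X, _ = fitted
        path = tmp_path / "model.json"
        path.write_text(model.to_json())
        back = mpls.CalibrationModel.from_json(path.read_text())
        a, b = model.predict(X[:10]), back.predict(X[:10])
        assert np.allclose(a["prediction"], b["prediction"])
        assert np.allclose(a["GH"], b["GH"])


class TestFitStatistics:
    def test_perfect_predictions(self):
        y = np.arange(10.0) + 1
        s = mpls.fit_statistics(y, y)
        assert s.rmse == 0.0 and s.r2 == pytest.approx(1.0)

    def test_relative_rmse_is_rmse_over_reference_mean(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(90, 30, 50)
        pred = ref + rng.normal(0, 5, 50)
        s = mpls.fit_statistics(pred, ref)
        assert s.relative_rmse == pytest.approx(s.rmse / ref.mean())

    def test_too_few_pairs(self):
        with pytest.raises(mpls.MplsError):
            mpls.fit_statistics([1.0, 2.0], [1.0, 2.0])
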