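"""Modified partial least squares (MPLS) calibration.

MPLS is the Shenk-Westerhaus variant of univariate PLS used by NIR
calibration software: after each latent variable (LV) is extracted, the
spectral residual at every wavelength is divided by that wavelength's
residual SD before the next LV is computed, down-weighting wavelengths
that are already well modelled.  With the residual SDs forced to one the
algorithm reduces exactly to textbook NIPALS PLS1.

The module covers the full calibration workflow:

* parity-stratified calibration/validation splitting (28% calibration),
* cross-validated LV selection (20 random groups; the chosen LV is the
  smallest whose RMSE_CV is not significantly different from the curve
  minimum by a one-sided F test at alpha = 0.25),
* three-pass calibration outlier elimination on the H (spectral
  leverage, > 10), T (standardised residual, > 3) and X (relative
  unmodelled spectral variance, > 10) statistics,
* treatment-grid model development (5 scatter x 5 derivative codes = 25
  candidate models, ranked by RMSE_CV),
* applicability-domain filtering of predictions: GH (Mahalanobis
  distance from the calibration score centroid over LV, > 3.5) and NH
  (distance to the nearest calibration spectrum in the same metric,
  > 2.0) flag extrapolations without altering the predicted values,
* summary fit statistics including the relative RMSE of validation
  (RMSE_V divided by the validation-set reference mean).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from colosig.preprocess import Pretreatment, PretreatmentSpec, default_grid


class MplsError(ValueError):
    pass


class MplsRankError(MplsError):
    """Requested more latent variables than the data can support."""

    def __init__(self, achievable_rank: int):
        self.achievable_rank = achievable_rank
        super().__init__(
            f"rank deficiency: only {achievable_rank} informative latent "
            "variables available"
        )


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def stratified_split(
    strata, fraction: float = 0.28, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Assign samples to 'calibration'/'validation' within strata.

    Within each stratum, ``round(fraction * n_stratum)`` samples are
    drawn uniformly at random into the calibration set, so strata keep
    their proportions (to +/- 1 sample) in both subsets.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    strata = np.asarray(strata)
    if strata.size == 0:
        raise MplsError("empty sample set")
    out = np.full(strata.shape, "validation", dtype=object)
    for level in pd.unique(strata):
        idx = np.flatnonzero(strata == level)
        n_cal = int(np.rint(fraction * idx.size))
        chosen = rng.choice(idx, size=n_cal, replace=False)
        out[chosen] = "calibration"
    return out.astype(str)


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------


class MPLSRegressor(RegressorMixin, BaseEstimator):
    """Modified PLS1 regression on pretreated spectra.

    Parameters
    ----------
    n_components : int
        Number of latent variables.
    scale_residuals : bool
        Apply the per-wavelength residual standardisation between
        factors (the "modified" step).  ``False`` gives standard PLS1.

    Fitted attributes (trailing underscore) store everything needed to
    replay the pipeline on new spectra: centres, per-factor weights,
    loadings and regression coefficients in each factor's working scale,
    the residual-SD vectors, calibration scores and their covariance
    (for the H/GH/NH statistics) and the mean unmodelled spectral
    sum-of-squares (for the X statistic).
    """

    def __init__(self, n_components: int = 10, scale_residuals: bool = True):
        self.n_components = n_components
        self.scale_residuals = scale_residuals

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if y.shape[0] != n:
            raise MplsError("X and y disagree on sample count")
        if self.n_components < 1:
            raise MplsError("need at least one latent variable")
        if n < self.n_components + 2:
            raise MplsError(
                f"n = {n} too small for {self.n_components} latent variables"
            )
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xk = X - self.x_mean_
        yk = y - self.y_mean_
        W, P, Q, SDs, T = [], [], [], [], []
        for k in range(self.n_components):
            w = Xk.T @ yk
            norm = np.linalg.norm(w)
            if norm <= 1e-12 * max(1.0, np.abs(yk).max()):
                raise MplsRankError(k)
            w = w / norm
            t = Xk @ w
            tt = float(t @ t)
            if tt <= 0:
                raise MplsError(f"degenerate score at factor {k + 1}")
            pl = Xk.T @ t / tt
            q = float(yk @ t / tt)
            Xk = Xk - np.outer(t, pl)
            yk = yk - q * t
            W.append(w)
            P.append(pl)
            Q.append(q)
            T.append(t)
            if k < self.n_components - 1:
                if self.scale_residuals:
                    sd = Xk.std(axis=0, ddof=1)
                    sd = np.where(sd < 1e-12, 1.0, sd)
                else:
                    sd = np.ones(p)
                Xk = Xk / sd
                SDs.append(sd)
        self.weights_ = np.column_stack(W)
        self.loadings_ = np.column_stack(P)
        self.q_ = np.asarray(Q)
        self.resid_sd_ = SDs
        self.scores_ = np.column_stack(T)
        cov = np.cov(self.scores_, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        # tiny ridge keeps the Mahalanobis metric defined for collinear scores
        cov = cov + 1e-10 * np.trace(cov) / cov.shape[0] * np.eye(cov.shape[0])
        self.score_cov_inv_ = np.linalg.inv(cov)
        resid_ss = (Xk**2).sum(axis=1)
        self.resid_ss_mean_ = float(resid_ss.mean())
        self.x_total_ss_mean_ = float(((X - self.x_mean_) ** 2).sum(axis=1).mean())
        fitted = self._predict_from_scores(self.scores_)
        self.sec_ = float(
            np.sqrt(((y - fitted) ** 2).sum() / max(n - self.n_components - 1, 1))
        )
        self.y_sd_ = float(y.std(ddof=1))
        self.n_samples_ = n
        return self

    # -- internal plumbing --------------------------------------------------

    def _transform(self, X, n_components: int | None = None):
        """Scores and final working-space residual for new spectra."""
        ncomp = self.n_components if n_components is None else n_components
        if not 1 <= ncomp <= self.n_components:
            raise MplsError("n_components out of fitted range")
        Xk = np.asarray(X, dtype=float) - self.x_mean_
        if Xk.shape[1] != self.x_mean_.shape[0]:
            raise MplsError("spectra are not on the calibration grid")
        T = np.empty((Xk.shape[0], ncomp))
        for k in range(ncomp):
            t = Xk @ self.weights_[:, k]
            T[:, k] = t
            Xk = Xk - np.outer(t, self.loadings_[:, k])
            if k < ncomp - 1:
                Xk = Xk / self.resid_sd_[k]
        return T, Xk

    def _predict_from_scores(self, T):
        return self.y_mean_ + T @ self.q_[: T.shape[1]]

    # -- public surface -----------------------------------------------------

    def predict(self, X, n_components: int | None = None):
        T, _ = self._transform(X, n_components)
        return self._predict_from_scores(T)

    def spectral_h(self, X):
        """H = D^2 / LV, Mahalanobis leverage in score space.

        Scaled so the calibration-set mean H is ~1 (exactly (n-1)/n);
        the calibration centroid has H = 0.
        """
        T, _ = self._transform(X)
        d2 = np.einsum("ij,jk,ik->i", T, self.score_cov_inv_, T)
        return d2 / self.n_components

    def neighbourhood_h(self, X):
        """NH: distance to the nearest calibration spectrum, same metric."""
        T, _ = self._transform(X)
        diff = T[:, None, :] - self.scores_[None, :, :]
        d2 = np.einsum("nij,jk,nik->ni", diff, self.score_cov_inv_, diff)
        return d2.min(axis=1) / self.n_components

    def x_statistic(self, X):
        """Relative unmodelled spectral variance (sample SS / mean SS).

        When the calibration residual is numerically zero (a perfect
        fit), the ratio is undefined on round-off noise and all samples
        report 0 by convention.
        """
        if self.resid_ss_mean_ <= 1e-12 * max(self.x_total_ss_mean_, 1e-300):
            return np.zeros(np.asarray(X).shape[0])
        _, resid = self._transform(X)
        return (resid**2).sum(axis=1) / self.resid_ss_mean_

    def t_statistic(self, X, y):
        """Standardised prediction residual |y - yhat| / SEC.

        A numerically perfect calibration (SEC at round-off level) has
        no residual outliers: the statistic is 0 by convention.
        """
        if self.sec_ <= 1e-8 * max(self.y_sd_, 1e-300):
            return np.zeros(np.asarray(X).shape[0])
        return np.abs(np.asarray(y, dtype=float) - self.predict(X)) / self.sec_


# ---------------------------------------------------------------------------
# cross-validation and LV selection
# ---------------------------------------------------------------------------


def cross_validate(
    X,
    y,
    spec: PretreatmentSpec,
    max_lv: int,
    n_groups: int = 20,
    seed: int | np.random.Generator = 0,
    scale_residuals: bool = True,
) -> np.ndarray:
    """RMSE_CV per LV count, pooled over ``n_groups`` random groups.

    ``X`` holds raw spectra: the pretreatment (including the MSC
    reference mean) is refitted on each training fold so no held-out
    information leaks into the fold models.  Returns ``rmse[l - 1]`` for
    ``l = 1..max_lv`` (``max_lv`` is reduced with a warning when folds
    are too small).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < n_groups:
        raise MplsError(f"n = {n} smaller than the number of CV groups")
    order = rng.permutation(n)
    folds = np.array_split(order, n_groups)
    min_train = n - max(len(f) for f in folds)
    eff_lv = min(max_lv, min_train - 2)
    if eff_lv < max_lv:
        warnings.warn(
            f"max_lv reduced from {max_lv} to {eff_lv} for fold size", stacklevel=2
        )
    if eff_lv < 1:
        raise MplsError("folds too small for any latent variable")
    sq_err = np.zeros(eff_lv)
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        pt = Pretreatment(spec).fit(X[mask])
        Xtr, Xte = pt.transform(X[mask]), pt.transform(X[fold])
        fold_lv = eff_lv
        while True:
            try:
                model = MPLSRegressor(fold_lv, scale_residuals).fit(Xtr, y[mask])
                break
            except MplsRankError as err:
                # rank-deficient fold: fit what is achievable; higher LV
                # re-use the deepest model's predictions
                if err.achievable_rank < 1:
                    raise
                fold_lv = err.achievable_rank
        for l in range(1, eff_lv + 1):
            pred = model.predict(Xte, n_components=min(l, fold_lv))
            sq_err[l - 1] += float(((y[fold] - pred) ** 2).sum())
    return np.sqrt(sq_err / n)


def select_lv(rmse_cv, n: int, alpha: float = 0.25) -> int:
    """Smallest LV whose RMSE_CV is not significantly above the minimum.

    One-sided F rule (Haaland-Thomas): with ``l* = argmin`` (ties to
    fewer LV), choose the smallest ``l`` with
    ``(RMSE_CV(l)/RMSE_CV(l*))^2 < F_crit(alpha; n, n)``.
    """
    rmse_cv = np.asarray(rmse_cv, dtype=float)
    if rmse_cv.size == 0:
        raise MplsError("empty RMSE_CV curve")
    l_star = int(np.argmin(rmse_cv))  # argmin takes the first = fewest LV
    best = rmse_cv[l_star]
    if best == 0:
        return l_star + 1
    crit = stats.f.isf(alpha, n, n)
    for l in range(l_star + 1):
        if (rmse_cv[l] / best) ** 2 < crit:
            return l + 1
    return l_star + 1


# ---------------------------------------------------------------------------
# outlier elimination
# ---------------------------------------------------------------------------


@dataclass
class OutlierThresholds:
    h_max: float = 10.0
    t_max: float = 3.0
    x_max: float = 10.0


def calibration_outlier_passes(
    X,
    y,
    spec: PretreatmentSpec,
    n_lv: int,
    n_passes: int = 3,
    thresholds: OutlierThresholds | None = None,
    scale_residuals: bool = True,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Iterative calibration clean-up (up to ``n_passes`` refits).

    Each pass refits the pretreatment and the MPLS model on the samples
    retained so far, computes the H, T and X statistics, and drops any
    sample exceeding a threshold; passes stop early once nothing is
    removed.  Returns the retained index array (into the original rows)
    and a per-removal log.
    """
    thr = thresholds or OutlierThresholds()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    retained = np.arange(X.shape[0])
    log_rows = []
    for pass_no in range(1, n_passes + 1):
        if retained.size < n_lv + 2:
            raise MplsError("outlier removal left too few calibration samples")
        pt = Pretreatment(spec).fit(X[retained])
        Xt = pt.transform(X[retained])
        model = MPLSRegressor(n_lv, scale_residuals).fit(Xt, y[retained])
        h = model.spectral_h(Xt)
        t = model.t_statistic(Xt, y[retained])
        x = model.x_statistic(Xt)
        bad = (h > thr.h_max) | (t > thr.t_max) | (x > thr.x_max)
        if not bad.any():
            break
        for i in np.flatnonzero(bad):
            reasons = []
            if h[i] > thr.h_max:
                reasons.append("H")
            if t[i] > thr.t_max:
                reasons.append("T")
            if x[i] > thr.x_max:
                reasons.append("X")
            log_rows.append(
                dict(pass_no=pass_no, row=int(retained[i]), h=float(h[i]),
                     t=float(t[i]), x=float(x[i]), rule="+".join(reasons))
            )
        retained = retained[~bad]
    log = pd.DataFrame(log_rows, columns=["pass_no", "row", "h", "t", "x", "rule"])
    return retained, log


# ---------------------------------------------------------------------------
# model development over the treatment grid
# ---------------------------------------------------------------------------


@dataclass
class CalibrationModel:
    """A fitted pretreatment + MPLS pipeline with its development record."""

    spec: PretreatmentSpec
    pretreatment: Pretreatment
    mpls: MPLSRegressor
    n_lv: int
    rmse_cv: float
    rmse_cv_curve: np.ndarray
    retained_rows: np.ndarray
    removal_log: pd.DataFrame = field(repr=False)
    gh_max: float = 3.5
    nh_max: float = 2.0

    def predict(self, X) -> pd.DataFrame:
        """Predictions with applicability-domain flags.

        GH and NH exceedances only flag rows as ``excluded``; the
        predicted values themselves are returned for every sample.
        """
        X = np.asarray(X, dtype=float)
        Xt = self.pretreatment.transform(X)
        pred = self.mpls.predict(Xt)
        gh = self.mpls.spectral_h(Xt)
        nh = self.mpls.neighbourhood_h(Xt)
        return pd.DataFrame(
            {
                "prediction": pred,
                "GH": gh,
                "NH": nh,
                "excluded": (gh > self.gh_max) | (nh > self.nh_max),
            }
        )

    def to_json(self) -> str:
        m = self.mpls
        payload = {
            "format": "colosig-mpls-v1",
            "scatter": self.spec.scatter,
            "derivative": list(self.spec.derivative),
            "n_lv": self.n_lv,
            "rmse_cv": self.rmse_cv,
            "gh_max": self.gh_max,
            "nh_max": self.nh_max,
            "x_mean": m.x_mean_.tolist(),
            "y_mean": m.y_mean_,
            "weights": m.weights_.tolist(),
            "loadings": m.loadings_.tolist(),
            "q": m.q_.tolist(),
            "resid_sd": [s.tolist() for s in m.resid_sd_],
            "scores": m.scores_.tolist(),
            "score_cov_inv": m.score_cov_inv_.tolist(),
            "resid_ss_mean": m.resid_ss_mean_,
            "x_total_ss_mean": m.x_total_ss_mean_,
            "sec": m.sec_,
            "y_sd": m.y_sd_,
            "n_samples": m.n_samples_,
            "msc_reference": (
                None
                if self.spec.scatter != "msc"
                else self.pretreatment.steps_[0].reference_.tolist()
            ),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        d = json.loads(text)
        if d.get("format") != "colosig-mpls-v1":
            raise MplsError("unrecognised model format")
        spec = PretreatmentSpec(d["scatter"], tuple(d["derivative"]))
        pt = Pretreatment(spec)
        pt.steps_ = pt._scatter_steps()
        if spec.scatter == "msc":
            pt.steps_[0].reference_ = np.asarray(d["msc_reference"])
        from colosig.preprocess import GapSegmentDerivative

        pt.derivative_ = GapSegmentDerivative(spec.derivative)
        m = MPLSRegressor(d["n_lv"])
        m.x_mean_ = np.asarray(d["x_mean"])
        m.y_mean_ = d["y_mean"]
        m.weights_ = np.asarray(d["weights"])
        m.loadings_ = np.asarray(d["loadings"])
        m.q_ = np.asarray(d["q"])
        m.resid_sd_ = [np.asarray(s) for s in d["resid_sd"]]
        m.scores_ = np.asarray(d["scores"])
        m.score_cov_inv_ = np.asarray(d["score_cov_inv"])
        m.resid_ss_mean_ = d["resid_ss_mean"]
        m.x_total_ss_mean_ = d["x_total_ss_mean"]
        m.sec_ = d["sec"]
        m.y_sd_ = d["y_sd"]
        m.n_samples_ = d["n_samples"]
        return cls(
            spec, pt, m, d["n_lv"], d["rmse_cv"], np.array([]),
            np.array([]), pd.DataFrame(), d["gh_max"], d["nh_max"],
        )


def develop_model(
    X,
    y,
    grid: list[PretreatmentSpec] | None = None,
    max_lv: int = 16,
    n_groups: int = 20,
    seed: int = 0,
    n_passes: int = 3,
    thresholds: OutlierThresholds | None = None,
    scale_residuals: bool = True,
) -> tuple[CalibrationModel, pd.DataFrame]:
    """Develop one model per pretreatment and keep the best.

    For each grid cell: outlier passes, cross-validated LV selection,
    then the final model on the cleaned calibration set; the winning
    treatment is the one with the lowest RMSE_CV at its selected LV.
    Returns the winner and the full leaderboard (one row per treatment).
    """
    grid = default_grid() if grid is None else grid
    if not grid:
        raise MplsError("empty treatment grid")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rows, fitted = [], []
    for j, spec in enumerate(grid):
        eff_lv = min(max_lv, X.shape[0] - 3)
        retained, removal_log = calibration_outlier_passes(
            X, y, spec, eff_lv, n_passes, thresholds, scale_residuals
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curve = cross_validate(
                X[retained], y[retained], spec, eff_lv, n_groups,
                np.random.default_rng(seed), scale_residuals,
            )
        n_lv = select_lv(curve, retained.size)
        pt = Pretreatment(spec).fit(X[retained])
        mpls = MPLSRegressor(n_lv, scale_residuals).fit(
            pt.transform(X[retained]), y[retained]
        )
        model = CalibrationModel(
            spec, pt, mpls, n_lv, float(curve[n_lv - 1]), curve, retained, removal_log
        )
        fitted.append(model)
        rows.append(
            dict(
                treatment=spec.label, scatter=spec.scatter,
                derivative=",".join(map(str, spec.derivative)), n_lv=n_lv,
                rmse_cv=float(curve[n_lv - 1]), n_retained=int(retained.size),
                n_removed=int(X.shape[0] - retained.size),
            )
        )
    leaderboard = pd.DataFrame(rows)
    best = int(leaderboard["rmse_cv"].idxmin())
    return fitted[best], leaderboard


# ---------------------------------------------------------------------------
# fit statistics
# ---------------------------------------------------------------------------


@dataclass
class FitStats:
    n: int
    mean: float
    sd: float
    rmse: float
    r2: float
    relative_rmse: float


def fit_statistics(predictions, references) -> FitStats:
    """RMSE, squared Pearson R2 and the RMSE/reference-mean ratio.

    ``relative_rmse`` is the validation-context statistic: RMSE divided
    by the mean of the reference values in the same context.
    """
    pred = np.asarray(predictions, dtype=float)
    ref = np.asarray(references, dtype=float)
    ok = np.isfinite(pred) & np.isfinite(ref)
    pred, ref = pred[ok], ref[ok]
    if pred.size < 3:
        raise MplsError("need at least 3 paired values for fit statistics")
    rmse = float(np.sqrt(np.mean((pred - ref) ** 2)))
    r2 = float(np.corrcoef(pred, ref)[0, 1] ** 2)
    mean = float(ref.mean())
    return FitStats(
        n=int(pred.size), mean=mean, sd=float(ref.std(ddof=1)),
        rmse=rmse, r2=r2, relative_rmse=rmse / mean,
    )
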