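"""Pedigree-based variance-component estimation.

The central tool is a bivariate *animal model*: for each trait,

``y_t = X_t b_t + Z_t a_t + e_t``

with fixed effects ``b`` (parity, calving season, herd), additive
genetic effects ``a`` with ``var(a) = G0 (x) A`` (``A`` the numerator
relationship matrix) and residuals with ``var(e) = R0 (x) I``.  The
residual covariance between traits applies only to animals recorded for
both; animals missing one trait are handled by exact Gaussian
marginalisation (their missing row simply never enters the observed-data
covariance).  Restricted maximum likelihood is maximised by
average-information (AI) iterations with step halving and projection of
``G0``/``R0`` back to the positive-semidefinite cone, which keeps the
restricted log-likelihood non-decreasing.  Standard errors come from the
inverse AI matrix, and heritabilities and genetic/phenotypic
correlations (with delta-method SEs) from the estimated components:

``h2 = s2_a / (s2_a + s2_e)``,
``r_a = cov_a / sqrt(s2_a1 s2_a2)``,
``r_p = cov_p / sqrt(s2_p1 s2_p2)`` with ``s2_p = s2_a + s2_e`` and
``cov_p = cov_a + cov_e``.

Low-variance traits (IgA, IgM) may be rescaled (x100) before fitting;
REML estimates are invariant to such rescaling up to the obvious ``c^2``
factor on variances, so ratios are unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator
from statsmodels.stats.anova import anova_lm

from colosig.pedigree import Pedigree, build_a_matrix


class RemlError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# derived ratios
# ---------------------------------------------------------------------------


def derive_ratios(G0, R0) -> dict:
    """Heritabilities and correlations from 2x2 (or 1x1) G0 and R0."""
    G0 = np.atleast_2d(np.asarray(G0, dtype=float))
    R0 = np.atleast_2d(np.asarray(R0, dtype=float))
    P0 = G0 + R0
    k = G0.shape[0]
    h2 = np.array([G0[t, t] / P0[t, t] if P0[t, t] > 0 else np.nan for t in range(k)])
    out = {"h2": h2}
    if k == 2:
        denom_a = np.sqrt(G0[0, 0] * G0[1, 1])
        denom_p = np.sqrt(P0[0, 0] * P0[1, 1])
        out["r_a"] = G0[0, 1] / denom_a if denom_a > 0 else np.nan
        out["r_p"] = P0[0, 1] / denom_p if denom_p > 0 else np.nan
    return out


# ---------------------------------------------------------------------------
# univariate least-squares means
# ---------------------------------------------------------------------------


def fit_univariate_lsmeans(
    phenotypes: pd.DataFrame,
    response: str,
    factors: tuple[str, ...] = ("parity", "season", "herd"),
):
    """OLS least-squares means and type-III F tests per fixed effect.

    LS means are marginal means: model predictions averaged over the
    levels of the other factors with equal weights.  Returns
    ``(lsmeans, anova)`` where ``lsmeans`` maps each factor to a
    DataFrame of ``level``, ``lsmean``, ``se``.
    """
    data = phenotypes.dropna(subset=[response, *factors]).copy()
    terms = " + ".join(f"C({f}, Sum)" for f in factors)
    res = smf.ols(f"Q('{response}') ~ {terms}", data=data).fit()
    design_info = res.model.data.design_info
    levels = {f: sorted(data[f].unique(), key=str) for f in factors}
    lsmeans: dict[str, pd.DataFrame] = {}
    for f in factors:
        rows = []
        for lev in levels[f]:
            grid = {g: [lev] if g == f else levels[g] for g in factors}
            grid_df = pd.DataFrame(
                [dict(zip(grid.keys(), vals)) for vals in _cartesian(grid)]
            )
            (exog,) = build_design_matrices([design_info], grid_df)
            L = np.asarray(exog).mean(axis=0)
            est = float(L @ res.params)
            se = float(np.sqrt(L @ res.cov_params() @ L))
            rows.append(dict(level=lev, lsmean=est, se=se))
        lsmeans[f] = pd.DataFrame(rows)
    anova = anova_lm(res, typ=3)
    return lsmeans, anova


def _cartesian(grid: dict):
    keys = list(grid)

    def rec(i):
        if i == len(keys):
            yield ()
            return
        for v in grid[keys[i]]:
            for rest in rec(i + 1):
                yield (v, *rest)

    return rec(0)


# ---------------------------------------------------------------------------
# AI-REML animal model
# ---------------------------------------------------------------------------


def _vech_index(k: int):
    """(row, col) pairs for the lower triangle, diagonal first order."""
    return [(i, j) for i in range(k) for j in range(i + 1)]


def _project_psd(M: np.ndarray, floor: float) -> np.ndarray:
    w, V = np.linalg.eigh(M)
    if w.min() >= floor:
        return M
    return (V * np.clip(w, floor, None)) @ V.T


class AnimalModelREML(BaseEstimator):
    """Bivariate (or univariate) animal-model REML estimator.

    Parameters
    ----------
    traits : tuple of str
        One or two phenotype columns in the records table.
    fixed_effects : tuple of str
        Categorical fixed-effect columns (fitted per trait with separate
        design matrices, i.e. block-diagonal X).
    rescale : dict or None
        Per-trait multiplier applied before fitting (e.g. ``{"IgA":
        100}`` for low-variance traits).  Reported (co)variances stay on
        the rescaled scale; ratios are scale-free.
    max_iter, tol_loglik, tol_param : convergence control.

    ``fit(records, pedigree)`` expects one row per animal with NaN for a
    missing trait; every animal must appear in the pedigree.
    """

    def __init__(
        self,
        traits: tuple[str, ...] = ("trait1", "trait2"),
        fixed_effects: tuple[str, ...] = ("parity", "season", "herd"),
        rescale: dict | None = None,
        max_iter: int = 200,
        tol_loglik: float = 1e-8,
        tol_param: float = 1e-6,
        verbose: bool = False,
    ):
        self.traits = traits
        self.fixed_effects = fixed_effects
        self.rescale = rescale
        self.max_iter = max_iter
        self.tol_loglik = tol_loglik
        self.tol_param = tol_param
        self.verbose = verbose

    # -- model assembly -----------------------------------------------------

    def _assemble(self, records: pd.DataFrame, A: np.ndarray, ped_index):
        T = len(self.traits)
        ys, trs, ans, Xblocks = [], [], [], []
        for t, trait in enumerate(self.traits):
            sub = records.dropna(subset=[trait])
            scale = (self.rescale or {}).get(trait, 1.0)
            ys.append(sub[trait].to_numpy(dtype=float) * scale)
            trs.append(np.full(len(sub), t))
            ans.append(ped_index(sub["animal"].to_numpy()))
            X = np.ones((len(sub), 1))
            for f in self.fixed_effects:
                if f not in sub.columns:
                    continue
                d = pd.get_dummies(sub[f].astype(str), drop_first=True)
                X = np.column_stack([X, d.to_numpy(dtype=float)])
            Xblocks.append(X)
        y = np.concatenate(ys)
        tr = np.concatenate(trs)
        an = np.concatenate(ans)
        q = sum(b.shape[1] for b in Xblocks)
        X = np.zeros((len(y), q))
        r0 = c0 = 0
        for b in Xblocks:
            X[r0 : r0 + b.shape[0], c0 : c0 + b.shape[1]] = b
            r0 += b.shape[0]
            c0 += b.shape[1]
        # drop collinear fixed-effect columns
        _, R = np.linalg.qr(X)
        keep = np.abs(np.diag(R)) > 1e-9 * np.abs(np.diag(R)).max()
        if not keep.all():
            X = X[:, keep]
        Abig = A[np.ix_(an, an)]
        Same = (an[:, None] == an[None, :]).astype(float)
        return y, tr, X, Abig, Same, T

    def _basis(self, tr, Abig, Same, T):
        """dV/dtheta for each parameter (V is linear in theta)."""
        basis = []
        grid = (tr[:, None], tr[None, :])
        for which, M in (("G", Abig), ("R", Same)):
            for i, j in _vech_index(T):
                E = np.zeros((T, T))
                E[i, j] = E[j, i] = 1.0
                basis.append(E[grid] * M)
        return basis

    @staticmethod
    def _unpack(theta, T):
        m = len(_vech_index(T))
        G0 = np.zeros((T, T))
        R0 = np.zeros((T, T))
        for k, (i, j) in enumerate(_vech_index(T)):
            G0[i, j] = G0[j, i] = theta[k]
            R0[i, j] = R0[j, i] = theta[m + k]
        return G0, R0

    @staticmethod
    def _pack(G0, R0):
        T = G0.shape[0]
        idx = _vech_index(T)
        return np.array([G0[i, j] for i, j in idx] + [R0[i, j] for i, j in idx])

    def _loglik(self, theta, basis, X, y):
        V = sum(t * B for t, B in zip(theta, basis))
        try:
            cho = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return None
        logdetV = 2.0 * np.sum(np.log(np.diag(cho[0])))
        Vinv = cho_solve(cho, np.eye(len(y)))
        VinvX = Vinv @ X
        XtVinvX = X.T @ VinvX
        sign, logdetX = np.linalg.slogdet(XtVinvX)
        if sign <= 0:
            return None
        C = np.linalg.inv(XtVinvX)
        P = Vinv - VinvX @ C @ VinvX.T
        Py = P @ y
        ll = -0.5 * (logdetV + logdetX + float(y @ Py))
        return ll, P, Py

    # -- fitting ------------------------------------------------------------

    def fit(self, records: pd.DataFrame, pedigree: Pedigree | np.ndarray, ped_ids=None):
        if isinstance(pedigree, Pedigree):
            A = build_a_matrix(pedigree)
            ped_index = pedigree.index_of
        else:
            A = np.asarray(pedigree, dtype=float)
            lookup = {a: i for i, a in enumerate(np.asarray(ped_ids))}
            ped_index = lambda ids: np.array([lookup[a] for a in ids])  # noqa: E731
        y, tr, X, Abig, Same, T = self._assemble(records, A, ped_index)
        if len(y) <= X.shape[1] + 2 * len(_vech_index(T)):
            raise RemlError("too few records for the requested model")
        basis = self._basis(tr, Abig, Same, T)

        # starting values: OLS residual variance split 30/70, mild covariances
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = np.array([resid[tr == t].var(ddof=1) for t in range(T)])
        G0 = np.diag(0.3 * s2)
        R0 = np.diag(0.7 * s2)
        if T == 2:
            G0[0, 1] = G0[1, 0] = 0.1 * np.sqrt(G0[0, 0] * G0[1, 1])
            R0[0, 1] = R0[1, 0] = 0.1 * np.sqrt(R0[0, 0] * R0[1, 1])
        theta = self._pack(G0, R0)
        floor = 1e-8 * s2.mean()

        state = self._loglik(theta, basis, X, y)
        if state is None:
            raise RemlError("starting values give a singular covariance")
        ll, P, Py = state
        path = [ll]
        converged = False
        boundary_flag = False
        for it in range(self.max_iter):
            m = len(theta)
            score = np.empty(m)
            u = []
            for k, B in enumerate(basis):
                BPy = B @ Py
                u.append(BPy)
                score[k] = -0.5 * (np.sum(P * B) - float(Py @ BPy))
            AI = np.empty((m, m))
            Pu = [P @ ui for ui in u]
            for a in range(m):
                for b in range(a, m):
                    AI[a, b] = AI[b, a] = 0.5 * float(u[a] @ Pu[b])
            try:
                delta = np.linalg.solve(AI + 1e-10 * np.eye(m) * np.trace(AI) / m, score)
            except np.linalg.LinAlgError:
                delta = score / (np.trace(AI) / m)
            step = 1.0
            accepted = False
            for _ in range(12):
                cand = theta + step * delta
                Gc, Rc = self._unpack(cand, T)
                Gp, Rp = _project_psd(Gc, floor), _project_psd(Rc, floor)
                if not (np.allclose(Gp, Gc, atol=1e-10) and np.allclose(Rp, Rc, atol=1e-10)):
                    boundary_flag = True
                cand = self._pack(Gp, Rp)
                st = self._loglik(cand, basis, X, y)
                if st is not None and st[0] >= ll - 1e-10:
                    new_ll, P, Py = st
                    rel_param = np.max(
                        np.abs(cand - theta) / np.maximum(np.abs(theta), floor)
                    )
                    theta = cand
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                # cannot improve: treat as converged at the current point
                converged = True
                break
            path.append(new_ll)
            rel_ll = abs(new_ll - ll) / max(abs(ll), 1.0)
            ll = new_ll
            if self.verbose:
                print(f"iter {it + 1}: logL={ll:.6f}")
            if rel_ll < self.tol_loglik and rel_param < self.tol_param:
                converged = True
                break
        if not converged:
            raise RemlError(
                f"REML did not converge in {self.max_iter} iterations "
                f"(logL path: {path[:3]}...{path[-2:]})"
            )

        self.G0_, self.R0_ = self._unpack(theta, T)
        self.loglik_ = ll
        self.loglik_path_ = np.asarray(path)
        self.n_iter_ = len(path) - 1
        self.converged_ = True
        self.boundary_ = boundary_flag
        self.n_records_ = len(y)
        # SEs from the inverse AI matrix + numerical delta method
        m = len(theta)
        score = np.empty(m)
        u = [B @ Py for B in basis]
        Pu = [P @ ui for ui in u]
        AI = np.empty((m, m))
        for a in range(m):
            for b in range(a, m):
                AI[a, b] = AI[b, a] = 0.5 * float(u[a] @ Pu[b])
        try:
            self.theta_cov_ = np.linalg.inv(AI)
        except np.linalg.LinAlgError:
            self.theta_cov_ = np.linalg.pinv(AI)
        self.theta_ = theta
        ratios = derive_ratios(self.G0_, self.R0_)
        self.h2_ = ratios["h2"]
        self.r_a_ = ratios.get("r_a", np.nan)
        self.r_p_ = ratios.get("r_p", np.nan)
        self.se_ = self._delta_method_ses(theta, T)
        return self

    def _delta_method_ses(self, theta, T):
        """Delta-method SEs for h2 and correlations (numeric gradients)."""

        def funcs(th):
            G0, R0 = self._unpack(th, T)
            r = derive_ratios(G0, R0)
            vals = list(r["h2"])
            if T == 2:
                vals += [r["r_a"], r["r_p"]]
            return np.array(vals, dtype=float)

        base = funcs(theta)
        J = np.zeros((len(base), len(theta)))
        for k in range(len(theta)):
            h = max(1e-6 * abs(theta[k]), 1e-10)
            up, dn = theta.copy(), theta.copy()
            up[k] += h
            dn[k] -= h
            J[:, k] = (funcs(up) - funcs(dn)) / (2 * h)
        var = np.einsum("ij,jk,ik->i", J, self.theta_cov_, J)
        se = np.sqrt(np.clip(var, 0.0, None))
        names = [f"h2_{t}" for t in self.traits]
        if T == 2:
            names += ["r_a", "r_p"]
        return dict(zip(names, se))

    # -- reporting ----------------------------------------------------------

    def summary(self) -> pd.DataFrame:
        rows = []
        for t, trait in enumerate(self.traits):
            rows.append(
                dict(
                    quantity=f"h2_{trait}", estimate=self.h2_[t],
                    se=self.se_.get(f"h2_{trait}", np.nan),
                )
            )
        if len(self.traits) == 2:
            rows.append(dict(quantity="r_a", estimate=self.r_a_, se=self.se_.get("r_a")))
            rows.append(dict(quantity="r_p", estimate=self.r_p_, se=self.se_.get("r_p")))
        return pd.DataFrame(rows)


def fit_bivariate_reml(
    records: pd.DataFrame,
    pedigree: Pedigree,
    traits: tuple[str, str],
    fixed_effects: tuple[str, ...] = ("parity", "season", "herd"),
    rescale: dict | None = None,
    **kwargs,
) -> AnimalModelREML:
    """Thin functional wrapper over :class:`AnimalModelREML`."""
    est = AnimalModelREML(
        traits=traits, fixed_effects=fixed_effects, rescale=rescale, **kwargs
    )
    return est.fit(records, pedigree)
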