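"""Shape-constrained additive models for bounded pairwise responses.

A quasi-binomial (logit link) additive model whose smooth terms can be
constrained to be monotone nondecreasing or nonnegative. Monotonicity is
obtained by construction: each smooth is a cubic B-spline whose coefficients
enter through a cumulative-sum-of-exponentials map

    beta_1 = 0,  beta_j = sum_{l<=j} exp(gamma_l)   (j = 2..k),

so the B-spline coefficient sequence is nondecreasing for any real gamma and
the inner optimisation is unconstrained. Nonnegative ("positive constraint")
smooths use the same map on an uncentred basis, anchoring f(min x) = 0 so the
fitted effect is nonnegative over the observed range. Smoothing parameters
are chosen by deviance-based GCV on a log10 grid with cyclic coordinate
descent. Wiggliness is penalised by a second-order difference penalty on the
B-spline coefficients; because a collapsed smooth (all increments -> 0) has a
vanishing Jacobian, its effective degrees of freedom shrink to ~0, which is
what licenses dropping "edf ~ 0" terms from a final model.

The estimator follows the scikit-learn protocol (``fit`` / ``predict`` /
``get_params``); ``fit_scam`` is a thin functional wrapper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import interpolate, special, stats
from sklearn.base import BaseEstimator, RegressorMixin

SMOOTH_KINDS = ("smooth_monotone_increasing", "smooth_nonnegative")
TERM_KINDS = SMOOTH_KINDS + ("linear", "factor")

_GAMMA_CLIP = 18.0  # |gamma| bound: exp() stays finite, increments can hit ~0


@dataclass(frozen=True)
class TermSpec:
    """One model term: a constrained smooth, a linear term or a factor.

    ``k`` is the B-spline basis size for smooths (>= 4); ``ref_level`` names
    the reference level of a factor (defaults to the alphabetically first).
    """
    name: str
    kind: str
    k: int = 10
    penalty_order: int = 2
    ref_level: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in TERM_KINDS:
            raise ValueError(f"unknown term kind {self.kind!r}")
        if self.kind in SMOOTH_KINDS and self.k < 4:
            raise ValueError("smooth basis size k must be >= 4")


@dataclass(frozen=True)
class TermTest:
    term: str
    kind: str
    statistic: float          # F for smooths, t for parametric contrasts
    edf: float                # edf for smooths, 1 for parametric
    p_value: float
    estimate: float | None = None


def build_monotone_basis(x: np.ndarray, k: int = 10):
    """Cubic B-spline design on quantile-spaced knots with the monotone map.

    Returns ``(B, knots, k_eff)`` where ``B`` is the (n, k_eff) design. If x
    has fewer than k distinct values, k is reduced (warning). Constant x is
    an error.
    """
    x = np.asarray(x, dtype=float)
    distinct = np.unique(x)
    if distinct.size < 2:
        raise ValueError("constant covariate: cannot build a smooth basis")
    k_eff = int(min(k, max(distinct.size, 4)))
    if k_eff < k:
        warnings.warn(f"reducing basis size to {k_eff} ({distinct.size} distinct x)")
    degree = 3
    n_interior = k_eff - degree - 1
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(distinct, qs)
        interior = np.unique(interior)
        k_eff = len(interior) + degree + 1
    else:
        interior = np.array([])
        k_eff = degree + 1
    lo, hi = distinct[0], distinct[-1]
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    B = _design(x, knots, degree)
    return B, knots, k_eff


def _design(x, knots, degree=3):
    xc = np.clip(x, knots[0], knots[-1])
    return interpolate.BSpline.design_matrix(xc, knots, degree,
                                             extrapolate=False).toarray()


def _beta_from_gamma(gamma: np.ndarray) -> np.ndarray:
    """beta = (0, cumsum(exp(gamma)))."""
    inc = np.exp(np.clip(gamma, -_GAMMA_CLIP, _GAMMA_CLIP))
    return np.concatenate([[0.0], np.cumsum(inc)])


def _beta_jacobian(gamma: np.ndarray) -> np.ndarray:
    """P[i, l] = d beta_i / d gamma_l = exp(gamma_l) * 1[i >= l+1]."""
    inc = np.exp(np.clip(gamma, -_GAMMA_CLIP, _GAMMA_CLIP))
    k = gamma.size + 1
    P = np.zeros((k, gamma.size))
    for l in range(gamma.size):
        P[l + 1:, l] = inc[l]
    return P


def _diff_penalty(k: int, order: int = 2) -> np.ndarray:
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


class _SmoothBlock:
    """Internal per-smooth state: basis, centering, penalty, parameters."""

    def __init__(self, spec: TermSpec, x: np.ndarray):
        self.spec = spec
        B, self.knots, self.k = build_monotone_basis(x, spec.k)
        self.centered = spec.kind == "smooth_monotone_increasing"
        self.col_means = B.mean(axis=0) if self.centered else np.zeros(self.k)
        self.B = B - self.col_means
        self.x_min, self.x_max = float(np.min(x)), float(np.max(x))
        self.n_par = self.k - 1

    def design_at(self, x: np.ndarray) -> np.ndarray:
        out_of_range = (x < self.x_min) | (x > self.x_max)
        if np.any(out_of_range):
            warnings.warn(f"extrapolating smooth '{self.spec.name}' beyond the "
                          "observed covariate range (values clipped)")
        return _design(np.asarray(x, float), self.knots) - self.col_means


class ScamRegressor(BaseEstimator, RegressorMixin):
    """Shape-constrained additive model (quasi-binomial logit by default).

    Parameters
    ----------
    terms : sequence of TermSpec
        Model terms; columns of the design frame are referenced by name.
    family : {"quasibinomial", "gaussian"}
        Quasi-binomial with logit link (Pearson-estimated dispersion) or an
        ordinary Gaussian/identity model (used e.g. for analytic partition
        checks).
    lam_grid : array-like
        log10 smoothing-parameter grid searched by GCV.
    n_sweeps : int
        Cyclic coordinate-descent sweeps over the smooths.
    max_iter, tol : inner Gauss-Newton controls.

    Attributes (after ``fit``)
    --------------------------
    coef_ : dict mapping term name -> coefficient vector (B-spline scale for
        smooths); ``lambda_`` per-smooth smoothing parameters; ``edf_``
        per-term effective degrees of freedom; ``deviance_``,
        ``null_deviance_``, ``deviance_explained_`` (percent), ``adj_r2_``,
        ``dispersion_``, ``converged_``, ``n_iter_``.
    """

    def __init__(self, terms: Sequence[TermSpec] = (), family: str = "quasibinomial",
                 lam_grid=None, n_sweeps: int = 3, max_iter: int = 200,
                 tol: float = 1e-8, select_lambda: bool = True,
                 fixed_lambda=None, gcv_gamma: float = 1.4):
        self.terms = terms
        self.family = family
        self.lam_grid = lam_grid
        self.n_sweeps = n_sweeps
        self.max_iter = max_iter
        self.tol = tol
        self.select_lambda = select_lambda
        self.fixed_lambda = fixed_lambda
        self.gcv_gamma = gcv_gamma

    # -- family helpers ----------------------------------------------------
    def _mu(self, eta):
        if self.family == "gaussian":
            return eta
        return special.expit(eta)

    def _weights(self, mu):
        if self.family == "gaussian":
            return np.ones_like(mu)
        return np.clip(mu * (1.0 - mu), 1e-10, None)

    def _deviance(self, y, mu):
        if self.family == "gaussian":
            return float(np.sum((y - mu) ** 2))
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        d = special.xlogy(y, y / mu) + special.xlogy(1 - y, (1 - y) / (1 - mu))
        return float(2.0 * np.sum(d))

    # -- assembly ----------------------------------------------------------
    def _setup(self, X: pd.DataFrame):
        self._par_names = ["(Intercept)"]
        self._factor_levels = {}
        self._smooths: dict[str, _SmoothBlock] = {}
        par_cols = [np.ones(len(X))]
        for t in self.terms:
            if t.name not in X.columns:
                raise ValueError(f"term column {t.name!r} not in design frame")
            if t.kind == "linear":
                par_cols.append(np.asarray(X[t.name], float))
                self._par_names.append(t.name)
            elif t.kind == "factor":
                levels = sorted(map(str, pd.unique(X[t.name].astype(str))))
                ref = t.ref_level if t.ref_level is not None else levels[0]
                if ref not in levels:
                    raise ValueError(f"reference level {ref!r} absent for {t.name}")
                others = [l for l in levels if l != ref]
                self._factor_levels[t.name] = (ref, others)
                col = X[t.name].astype(str).to_numpy()
                for l in others:
                    par_cols.append((col == l).astype(float))
                    self._par_names.append(f"{t.name}[{l}]")
            else:
                self._smooths[t.name] = _SmoothBlock(t, np.asarray(X[t.name], float))
        self._X_par = np.column_stack(par_cols)
        self._n_par = self._X_par.shape[1]

    def _unpack(self, theta):
        alpha = theta[: self._n_par]
        gammas = {}
        ofs = self._n_par
        for name, blk in self._smooths.items():
            gammas[name] = theta[ofs: ofs + blk.n_par]
            ofs += blk.n_par
        return alpha, gammas

    def _eta(self, theta):
        alpha, gammas = self._unpack(theta)
        eta = self._X_par @ alpha
        for name, blk in self._smooths.items():
            eta = eta + blk.B @ _beta_from_gamma(gammas[name])
        return eta

    def _penalty(self, theta, lam):
        alpha, gammas = self._unpack(theta)
        pen = 0.0
        for name, blk in self._smooths.items():
            beta = _beta_from_gamma(gammas[name])
            pen += lam[name] * float(beta @ blk.S @ beta)
            pen += lam.get(f"{name}:null", 0.0) * float(beta @ blk.S0 @ beta)
            pen += self._eps_ridge * float(gammas[name] @ gammas[name])
        return pen

    # -- core fixed-lambda fit --------------------------------------------
    def _fit_fixed_lambda(self, y, lam, theta0):
        theta = theta0.copy()
        eta = self._eta(theta)
        mu = self._mu(eta)
        obj = self._deviance(y, mu) + self._penalty(theta, lam)
        n_iter = 0
        converged = False
        for n_iter in range(1, self.max_iter + 1):
            alpha, gammas = self._unpack(theta)
            w = self._weights(mu)
            # Jacobian of eta wrt theta and penalty gradient/Hessian
            J_blocks = [self._X_par]
            grad_pen = [np.zeros(self._n_par)]
            H_pen_blocks = [np.zeros((self._n_par, self._n_par))]
            for name, blk in self._smooths.items():
                g = gammas[name]
                P = _beta_jacobian(g)
                beta = _beta_from_gamma(g)
                Seff = lam[name] * blk.S + lam.get(f"{name}:null", 0.0) * blk.S0
                J_blocks.append(blk.B @ P)
                grad_pen.append(2 * (P.T @ (Seff @ beta))
                                + 2 * self._eps_ridge * g)
                H_pen_blocks.append(2 * (P.T @ Seff @ P)
                                    + 2 * self._eps_ridge * np.eye(blk.n_par))
            J = np.column_stack(J_blocks)
            grad = 2.0 * (J.T @ (mu - y)) + np.concatenate(grad_pen)
            H = 2.0 * (J.T * w) @ J
            p = H.shape[0]
            ofs = 0
            for blk_H in H_pen_blocks:
                m = blk_H.shape[0]
                H[ofs: ofs + m, ofs: ofs + m] += blk_H
                ofs += m
            H[np.diag_indices(p)] += 1e-9
            try:
                step = np.linalg.solve(H, -grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, -grad, rcond=None)[0]
            # backtracking line search on the penalised deviance
            t_step = 1.0
            improved = False
            for _ in range(30):
                cand = theta + t_step * step
                cand[self._n_par:] = np.clip(cand[self._n_par:],
                                             -_GAMMA_CLIP, _GAMMA_CLIP)
                eta_c = self._eta(cand)
                mu_c = self._mu(eta_c)
                obj_c = self._deviance(y, mu_c) + self._penalty(cand, lam)
                if np.isfinite(obj_c) and obj_c <= obj + 1e-14:
                    improved = True
                    break
                t_step *= 0.5
            if not improved:
                converged = True  # no descent direction improves: at optimum
                break
            rel = abs(obj - obj_c) / max(abs(obj_c), 1e-12)
            theta, eta, mu, obj = cand, eta_c, mu_c, obj_c
            if rel < self.tol:
                converged = True
                break
        # edf and covariance at the solution
        alpha, gammas = self._unpack(theta)
        w = self._weights(mu)
        J_blocks = [self._X_par]
        H_pen_blocks = [np.zeros((self._n_par, self._n_par))]
        for name, blk in self._smooths.items():
            P = _beta_jacobian(gammas[name])
            Seff = lam[name] * blk.S + lam.get(f"{name}:null", 0.0) * blk.S0
            J_blocks.append(blk.B @ P)
            H_pen_blocks.append(2 * (P.T @ Seff @ P)
                                + 2 * self._eps_ridge * np.eye(blk.n_par))
        J = np.column_stack(J_blocks)
        A = 2.0 * (J.T * w) @ J
        H = A.copy()
        ofs = 0
        for blk_H in H_pen_blocks:
            m = blk_H.shape[0]
            H[ofs: ofs + m, ofs: ofs + m] += blk_H
            ofs += m
        H[np.diag_indices(H.shape[0])] += 1e-9
        Hinv = np.linalg.inv(H)
        F = Hinv @ A
        edf_diag = np.diag(F)
        dev = self._deviance(y, mu)
        return {"theta": theta, "mu": mu, "eta": eta, "deviance": dev,
                "edf_diag": edf_diag, "edf_total": float(edf_diag.sum()),
                "Hinv": Hinv, "J": J, "w": w, "converged": converged,
                "n_iter": n_iter, "obj": obj}

    # -- public API --------------------------------------------------------
    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        if self.family == "quasibinomial" and ((y < 0).any() or (y > 1).any()):
            raise ValueError("quasi-binomial response must lie in [0, 1]")
        self.terms = list(self.terms)
        self._eps_ridge = 1e-7
        self._setup(X)
        for blk in self._smooths.values():
            blk.S = _diff_penalty(blk.k, blk.spec.penalty_order)
            # null-space shrinkage (mgcv "select"-style): the difference
            # penalty leaves linear coefficient sequences unpenalised, so a
            # spurious slope could survive any lambda; a separately selected
            # shrinkage on that direction lets a null smooth reach edf ~ 0
            u = np.arange(blk.k, dtype=float)
            u -= u.mean()
            u /= np.linalg.norm(u)
            blk.S0 = np.outer(u, u)
        n = len(y)
        n_coef = self._n_par + sum(b.n_par for b in self._smooths.values())
        if n < 2 * n_coef:
            warnings.warn(f"only {n} rows for {n_coef} coefficients")
        theta0 = np.zeros(n_coef)
        if self.family == "quasibinomial":
            ybar = float(np.clip(np.mean(y), 1e-4, 1 - 1e-4))
            theta0[0] = special.logit(ybar)
        else:
            theta0[0] = float(np.mean(y))
        theta0[self._n_par:] = -3.0
        lam = {}
        for name in self._smooths:
            lam[name] = 1.0
            lam[f"{name}:null"] = 1e-3
        if self.fixed_lambda:
            lam.update({k: float(v) for k, v in self.fixed_lambda.items()
                        if k in lam})
        grid = (np.asarray(self.lam_grid, float) if self.lam_grid is not None
                else np.linspace(-4.0, 4.0, 21))
        fit = self._fit_fixed_lambda(y, lam, theta0)
        if self.select_lambda and self._smooths:
            hyper = [k for name in self._smooths
                     for k in (name, f"{name}:null")]
            # wiggliness is tuned with the usual mild GCV inflation; the
            # null-space shrinkage decides whether a smooth keeps its linear
            # trend at all -- a selection decision, where plain GCV is
            # anticonservative, so a BIC-like inflation is used there
            gamma_null = max(self.gcv_gamma, np.log(n))
            for _ in range(self.n_sweeps):
                changed = False
                for name in hyper:
                    g_edf = gamma_null if name.endswith(":null") \
                        else self.gcv_gamma
                    best = (np.inf, lam[name], fit)
                    for lg in grid:
                        lam_try = dict(lam, **{name: 10.0 ** lg})
                        cand = self._fit_fixed_lambda(y, lam_try, fit["theta"])
                        # GCV on the quasi family's Pearson-based scale
                        pearson = float(np.sum(
                            (y - cand["mu"]) ** 2
                            / np.clip(self._variance(cand["mu"]), 1e-10, None)))
                        gcv = (n * pearson
                               / max(n - g_edf * cand["edf_total"],
                                     1e-6) ** 2)
                        if gcv < best[0]:
                            best = (gcv, 10.0 ** lg, cand)
                    if best[1] != lam[name]:
                        changed = True
                    lam[name] = best[1]
                    fit = best[2]
                if not changed:
                    break

            def _sel_gcv(cand):
                pearson = float(np.sum(
                    (y - cand["mu"]) ** 2
                    / np.clip(self._variance(cand["mu"]), 1e-10, None)))
                return (n * pearson
                        / max(n - gamma_null * cand["edf_total"], 1e-6) ** 2)

            # term-collapse pass: for each smooth, compare the fully
            # penalised corner (term effectively removed) with the current
            # configuration under the selection-inflated criterion
            corner = 10.0 ** float(np.max(grid))
            for name in self._smooths:
                if lam[name] >= corner and lam[f"{name}:null"] >= corner:
                    continue
                lam_try = dict(lam, **{name: corner, f"{name}:null": corner})
                cand = self._fit_fixed_lambda(y, lam_try, fit["theta"])
                if _sel_gcv(cand) <= _sel_gcv(fit):
                    lam = lam_try
                    fit = cand
        self.lambda_ = lam
        self._finalize(X, y, fit)
        return self

    def _finalize(self, X, y, fit):
        n = len(y)
        theta = fit["theta"]
        alpha, gammas = self._unpack(theta)
        self.theta_ = theta
        self.coef_ = {}
        self.edf_ = {}
        ofs = 0
        # parametric block: intercept + linear + factor contrasts, edf fixed
        self.coef_["(Intercept)"] = alpha[0]
        par_edf = fit["edf_diag"][: self._n_par]
        idx = 1
        for t in self.terms:
            if t.kind == "linear":
                self.coef_[t.name] = float(alpha[idx])
                self.edf_[t.name] = float(par_edf[idx])
                idx += 1
            elif t.kind == "factor":
                ref, others = self._factor_levels[t.name]
                self.coef_[t.name] = {f"{l}": float(alpha[idx + j])
                                      for j, l in enumerate(others)}
                self.edf_[t.name] = float(par_edf[idx: idx + len(others)].sum())
                idx += len(others)
        ofs = self._n_par
        for name, blk in self._smooths.items():
            self.coef_[name] = _beta_from_gamma(gammas[name])
            self.edf_[name] = float(fit["edf_diag"][ofs: ofs + blk.n_par].sum())
            ofs += blk.n_par
        self.edf_total_ = fit["edf_total"]
        self.mu_ = fit["mu"]
        self.eta_ = fit["eta"]
        self.deviance_ = fit["deviance"]
        mu0 = np.full(n, np.mean(y))
        self.null_deviance_ = self._deviance(y, mu0)
        self.deviance_explained_ = (100.0 * (1.0 - self.deviance_
                                             / self.null_deviance_)
                                    if self.null_deviance_ > 1e-10 * n else 0.0)
        w = fit["w"]
        pearson = float(np.sum((y - self.mu_) ** 2 / np.clip(
            self._variance(self.mu_), 1e-10, None)))
        self.df_residual_ = max(n - self.edf_total_, 1.0)
        self.dispersion_ = pearson / self.df_residual_
        # working-residual adjusted R^2
        z = self.eta_ + (y - self.mu_) / np.clip(w, 1e-10, None)
        zbar = float(np.average(z, weights=w))
        ss_res = float(np.sum(w * (z - self.eta_) ** 2))
        ss_tot = float(np.sum(w * (z - zbar) ** 2))
        r2w = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        self.adj_r2_ = 1.0 - (1.0 - r2w) * (n - 1) / max(n - self.edf_total_, 1.0)
        self.converged_ = fit["converged"]
        self.n_iter_ = fit["n_iter"]
        self._fit_info = fit
        self.n_obs_ = n
        if not self.converged_:
            warnings.warn("SCAM did not converge; fit flagged, inspect n_iter_")
        self._assert_shape_constraints()

    def _variance(self, mu):
        if self.family == "gaussian":
            return np.ones_like(mu)
        return mu * (1.0 - mu)

    def _assert_shape_constraints(self):
        for name, blk in self._smooths.items():
            grid = np.linspace(blk.x_min, blk.x_max, 200)
            f = _design(grid, blk.knots) @ self.coef_[name]
            if np.any(np.diff(f) < -1e-10):
                raise AssertionError(f"monotonicity violated for smooth {name}")
            if blk.spec.kind == "smooth_nonnegative" and np.any(f < -1e-10):
                raise AssertionError(f"nonnegativity violated for smooth {name}")

    def predict(self, X: pd.DataFrame):
        eta = np.full(len(X), self.coef_["(Intercept)"])
        for t in self.terms:
            if t.kind == "linear":
                eta += self.coef_[t.name] * np.asarray(X[t.name], float)
            elif t.kind == "factor":
                ref, others = self._factor_levels[t.name]
                col = X[t.name].astype(str).to_numpy()
                for l in others:
                    eta += self.coef_[t.name][l] * (col == l)
            else:
                blk = self._smooths[t.name]
                eta += blk.design_at(np.asarray(X[t.name], float)) @ self.coef_[t.name]
        return self._mu(eta)

    def partial_effect(self, term: str, grid=None):
        """Centered partial effect of a smooth on the linear-predictor scale.

        Returns (grid, f_hat). Values outside the observed covariate range
        trigger an extrapolation warning and are clipped.
        """
        if term not in self._smooths:
            raise ValueError(f"{term!r} is not a smooth term")
        blk = self._smooths[term]
        if grid is None:
            grid = np.linspace(blk.x_min, blk.x_max, 200)
        grid = np.asarray(grid, float)
        f = blk.design_at(grid) @ self.coef_[term]
        return grid, f

    # -- inference ---------------------------------------------------------
    def term_tests(self) -> list[TermTest]:
        """Wald-type tests: F for smooth blocks, t for parametric terms."""
        fit = self._fit_info
        Vtheta = self.dispersion_ * fit["Hinv"]
        dfres = self.df_residual_
        out = []
        idx = 1
        for t in self.terms:
            if t.kind == "linear":
                est = self.coef_[t.name]
                se = float(np.sqrt(max(Vtheta[idx, idx], 1e-300)))
                tval = est / se
                p = 2.0 * stats.t.sf(abs(tval), dfres)
                out.append(TermTest(t.name, "linear", float(tval), 1.0, float(p),
                                    float(est)))
                idx += 1
            elif t.kind == "factor":
                ref, others = self._factor_levels[t.name]
                for j, l in enumerate(others):
                    est = self.coef_[t.name][l]
                    se = float(np.sqrt(max(Vtheta[idx + j, idx + j], 1e-300)))
                    tval = est / se
                    p = 2.0 * stats.t.sf(abs(tval), dfres)
                    out.append(TermTest(f"{t.name}[{l}]", "factor", float(tval),
                                        1.0, float(p), float(est)))
                idx += len(others)
        ofs = self._n_par
        alpha, gammas = self._unpack(self.theta_)
        for name, blk in self._smooths.items():
            m = blk.n_par
            beta = self.coef_[name]
            P = _beta_jacobian(gammas[name])
            Vb = P @ Vtheta[ofs: ofs + m, ofs: ofs + m] @ P.T
            edf = max(self.edf_[name], 1e-3)
            Vb_pinv = np.linalg.pinv(Vb, rcond=1e-8)
            Fstat = float(beta @ Vb_pinv @ beta) / edf
            p = float(stats.f.sf(Fstat, edf, dfres)) if Fstat > 0 else 1.0
            out.append(TermTest(name, blk.spec.kind, Fstat, float(self.edf_[name]),
                                p))
            ofs += m
        return out


def fit_scam(table: pd.DataFrame, spec: Sequence[TermSpec],
             response: str = "fst", family: str = "quasibinomial",
             **kwargs) -> ScamRegressor:
    """Fit a :class:`ScamRegressor` on a pair table (functional wrapper)."""
    model = ScamRegressor(terms=list(spec), family=family, **kwargs)
    return model.fit(table, np.asarray(table[response], float))


def drop_null_smooths(table: pd.DataFrame, spec: Sequence[TermSpec],
                      response: str = "fst", threshold: float = 0.1,
                      family: str = "quasibinomial", **kwargs):
    """Iteratively remove smooths penalised to edf < ``threshold``.

    Refits after each removal until a fixed point; returns
    (final spec, final fitted model).
    """
    spec = list(spec)
    fit = fit_scam(table, spec, response=response, family=family, **kwargs)
    while True:
        null_terms = [t.name for t in spec if t.kind in SMOOTH_KINDS
                      and fit.edf_[t.name] < threshold]
        if not null_terms:
            return spec, fit
        spec = [t for t in spec if t.name not in null_terms]
        fit = fit_scam(table, spec, response=response, family=family, **kwargs)


def default_model_terms(columns: Sequence[str] | None = None) -> list[TermSpec]:
    """The standard pair-table model: cluster factor, monotone smooths for
    geographic distance and temperature gradients, nonnegative smooths for
    rainfall/moisture gradients, linear distance-to-secondary-site term."""
    terms = [
        TermSpec("clus_type", "factor", ref_level="P1P1"),
        TermSpec("dist_geo_km", "smooth_monotone_increasing"),
        TermSpec("delta_dist_km_CT", "smooth_monotone_increasing"),
        TermSpec("delta_dist_km_SB", "linear"),
        TermSpec("delta_tmean", "smooth_monotone_increasing"),
        TermSpec("delta_tmaxsum", "smooth_monotone_increasing"),
        TermSpec("delta_rmean", "smooth_nonnegative"),
        TermSpec("delta_ndmi16", "smooth_nonnegative"),
    ]
    if columns is not None:
        terms = [t for t in terms if t.name in columns or t.kind == "factor"]
    return terms
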