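"""Random-intercept logistic regression for patients in wards in hospitals.

:class:`MultilevelLogit` fits a binary-outcome logistic model with up to two
strictly nested Gaussian random intercepts on the logit scale,

    logit P(y_ij = 1) = x_ij' beta + u_h(hospital) + u_w(ward),
    u_h ~ N(0, sigma2_h),   u_w ~ N(0, sigma2_w),

by one of two backends behind the same results contract:

``laplace``
    Penalized IRLS for the joint mode of (beta, u) with a Laplace
    approximation to the marginal likelihood, profiled over the two variance
    components (Nelder-Mead on the log-variance scale).  The joint Hessian's
    random-effect block is block-arrow by hospital (wards couple only to
    their own hospital), so each Newton step and the log-determinant are
    O(#wards + #hospitals) via a Schur complement on the hospital diagonal.
    Deterministic; used as the default and as the starting point for MCMC.

``mcmc``
    Metropolis-within-Gibbs: vectorized single-site random-walk updates for
    the ward and hospital intercepts (conditionally independent within an
    update), a joint random-walk update for beta with the Laplace covariance
    as proposal, and conjugate inverse-gamma Gibbs draws for the variances
    (flat prior on beta, Gamma^-1(0.001, 0.001) on each variance).  Reports
    posterior medians with 95% credible intervals and the conditional DIC.

Shrunken (empirical-Bayes) cluster residuals come with posterior standard
errors at both levels; single-level models (no random terms) are delegated
to statsmodels GLM and wrapped in the same results class.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "MultilevelLogit",
    "MultilevelResults",
    "fit_single_level",
    "fit_three_level",
    "shrunken_residuals",
    "ConvergenceError",
    "RankDeficientError",
    "DicUnavailableError",
    "split_rhat",
]

BOUNDARY_TOL = 1e-4  # variance below this is reported as a boundary estimate


class ConvergenceError(RuntimeError):
    """Estimation failed a convergence check; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class RankDeficientError(ValueError):
    """The fixed-effect design matrix is rank deficient."""


class DicUnavailableError(RuntimeError):
    """DIC requested from a non-MCMC fit (use ``aic`` instead)."""


# ---------------------------------------------------------------------------
# design matrix construction
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DesignInfo:
    """Recipe for rebuilding a design matrix on new data."""

    terms: list  # (name, kind, levels, ref); kind in {"numeric", "categorical"}
    names: list  # column names including "intercept"


def build_design(df: pd.DataFrame, terms, ref_levels=None):
    """Build an intercept-led design matrix from named columns.

    Columns of object/categorical/boolean dtype — or any column named in
    ``ref_levels`` — are dummy-coded against the stated (else first sorted)
    reference level; numeric columns enter linearly.

    Returns ``(X, info)`` where ``info`` replays the encoding on new data via
    :func:`design_from_info` (raising on unseen levels).
    """
    ref_levels = ref_levels or {}
    cols = [np.ones(len(df))]
    names = ["intercept"]
    spec = []
    for term in terms:
        if term not in df.columns:
            raise KeyError(f"design term {term!r} not in data")
        col = df[term]
        categorical = (
            term in ref_levels
            or col.dtype == object
            or isinstance(col.dtype, pd.CategoricalDtype)
            or col.dtype == bool
        )
        if categorical:
            levels = sorted(pd.unique(col))
            ref = ref_levels.get(term, levels[0])
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent from {term!r}")
            spec.append((term, "categorical", levels, ref))
            for lv in levels:
                if lv == ref:
                    continue
                cols.append((col == lv).to_numpy(float))
                names.append(f"{term}[{lv}]")
        else:
            spec.append((term, "numeric", None, None))
            cols.append(col.to_numpy(float))
            names.append(term)
    X = np.column_stack(cols)
    return X, DesignInfo(terms=spec, names=names)


def design_from_info(df: pd.DataFrame, info: DesignInfo) -> np.ndarray:
    """Re-apply a stored design recipe; unseen categorical levels error."""
    cols = [np.ones(len(df))]
    for term, kind, levels, ref in info.terms:
        if term not in df.columns:
            raise KeyError(f"design term {term!r} not in data")
        col = df[term]
        if kind == "categorical":
            unseen = set(pd.unique(col)) - set(levels)
            if unseen:
                raise ValueError(f"unseen level(s) {sorted(unseen)} in {term!r}")
            for lv in levels:
                if lv == ref:
                    continue
                cols.append((col == lv).to_numpy(float))
        else:
            cols.append(col.to_numpy(float))
    return np.column_stack(cols)


def _check_rank(X: np.ndarray, names) -> None:
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    bad = diag < 1e-8 * max(1.0, diag.max())
    if bad.any():
        aliased = [names[i] for i in np.flatnonzero(bad)]
        raise RankDeficientError(f"aliased design column(s): {aliased}")


# ---------------------------------------------------------------------------
# arrow-structured solver for the random-effect block
# ---------------------------------------------------------------------------

class _ArrowSolver:
    """Solve and log-det for S = Z'WZ + D^-1 under strict ward-in-hospital nesting.

    Ordering (u_w, u_h): S = [[diag(d_w), C], [C', diag(d_h)]] where C couples
    each ward to its single hospital with weight c_w.  The Schur complement
    onto hospitals stays diagonal: s_h = d_h - sum_{w in h} c_w^2 / d_w.
    """

    def __init__(self, Wt, wi, W, hi, H, hw, s2w, s2h):
        self.W, self.H, self.hw = W, H, hw
        self.d_w = self.c_w = self.d_h = self.s_h = None
        if W:
            self.c_w = np.bincount(wi, weights=Wt, minlength=W)
            self.d_w = self.c_w + 1.0 / s2w
        if H:
            self.d_h = np.bincount(hi, weights=Wt, minlength=H) + 1.0 / s2h
            if W:
                self.s_h = self.d_h - np.bincount(
                    hw, weights=self.c_w**2 / self.d_w, minlength=H
                )
            else:
                self.s_h = self.d_h

    def solve(self, rw, rh):
        """Solve S [xw; xh] = [rw; rh]; vector or (q, k) matrix right sides."""
        if not self.W:
            return None, (rh / _bcast(self.s_h, rh) if self.H else None)
        t = rw / _bcast(self.d_w, rw)
        if not self.H:
            return t, None
        acc = np.zeros_like(rh)
        np.add.at(acc, self.hw, _bcast(self.c_w, rw) * t)
        xh = (rh - acc) / _bcast(self.s_h, rh)
        xw = t - _bcast(self.c_w / self.d_w, rw) * xh[self.hw]
        return xw, xh

    @property
    def logdet(self):
        out = 0.0
        if self.W:
            out += np.log(self.d_w).sum()
        if self.H:
            out += np.log(self.s_h).sum()
        return out

    def posterior_var(self):
        """Diagonal of S^-1: conditional (posterior) variances of (u_w, u_h)."""
        var_w = var_h = None
        if self.H:
            var_h = 1.0 / self.s_h
        if self.W:
            var_w = 1.0 / self.d_w
            if self.H:
                var_w = var_w + (self.c_w / self.d_w) ** 2 * var_h[self.hw]
        return var_w, var_h


def _bcast(v, like):
    return v[:, None] if like.ndim == 2 else v


# ---------------------------------------------------------------------------
# penalized IRLS + Laplace
# ---------------------------------------------------------------------------

def _penalized_ll(y, eta, uw, uh, s2w, s2h):
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    if uw is not None and s2w:
        ll -= 0.5 * float(uw @ uw) / s2w
    if uh is not None and s2h:
        ll -= 0.5 * float(uh @ uh) / s2h
    return ll


def _pirls(y, X, wi, W, hi, H, hw, s2w, s2h, beta, uw, uh, maxiter=100, gtol=1e-6):
    """Joint Newton (penalized IRLS) for (beta, u) at fixed variances.

    Returns the mode, the Laplace profile log-likelihood, the fixed-effect
    covariance (Schur complement inverse) and the posterior variances of u.
    """
    n, p = X.shape
    beta = beta.copy()
    uw = uw.copy() if W else None
    uh = uh.copy() if H else None
    f_prev = -np.inf
    solver = None
    for _ in range(maxiter):
        eta = X @ beta
        if W:
            eta = eta + uw[wi]
        if H:
            eta = eta + uh[hi]
        mu = expit(eta)
        f0 = _penalized_ll(y, eta, uw, uh, s2w, s2h)
        resid = y - mu
        Wt = mu * (1.0 - mu) + 1e-12

        gb = X.T @ resid
        gw = np.bincount(wi, weights=resid, minlength=W) - uw / s2w if W else None
        gh = np.bincount(hi, weights=resid, minlength=H) - uh / s2h if H else None

        gmax = np.abs(gb).max()
        if W:
            gmax = max(gmax, np.abs(gw).max())
        if H:
            gmax = max(gmax, np.abs(gh).max())

        solver = _ArrowSolver(Wt, wi, W, hi, H, hw, s2w, s2h)
        XW = X * Wt[:, None]
        A = X.T @ XW
        Bw = (
            np.column_stack([np.bincount(wi, weights=XW[:, j], minlength=W) for j in range(p)])
            if W
            else None
        )  # (W, p)
        Bh = (
            np.column_stack([np.bincount(hi, weights=XW[:, j], minlength=H) for j in range(p)])
            if H
            else None
        )
        Yw, Yh = solver.solve(Bw, Bh)
        C = A.copy()
        if W:
            C -= Bw.T @ Yw
        if H:
            C -= Bh.T @ Yh
        sw, sh = solver.solve(gw, gh)
        rhs = gb.copy()
        if W:
            rhs -= Bw.T @ sw
        if H:
            rhs -= Bh.T @ sh
        db = np.linalg.solve(C, rhs)
        rw = gw - Bw @ db if W else None
        rh = gh - Bh @ db if H else None
        duw, duh = solver.solve(rw, rh)

        if gmax < gtol and abs(f0 - f_prev) < 1e-10 * (1 + abs(f0)):
            f_prev = f0
            break

        step = 1.0
        for _half in range(25):
            b1 = beta + step * db
            u1w = uw + step * duw if W else None
            u1h = uh + step * duh if H else None
            eta1 = X @ b1
            if W:
                eta1 = eta1 + u1w[wi]
            if H:
                eta1 = eta1 + u1h[hi]
            f1 = _penalized_ll(y, eta1, u1w, u1h, s2w, s2h)
            if f1 >= f0 - 1e-12:
                break
            step *= 0.5
        beta, uw, uh = b1, u1w, u1h
        if abs(f1 - f_prev) < 1e-10 * (1 + abs(f1)):
            f_prev = f1
            break
        f_prev = f1

    profile = f_prev - 0.5 * solver.logdet
    if W:
        profile -= 0.5 * W * math.log(s2w)
    if H:
        profile -= 0.5 * H * math.log(s2h)
    var_w, var_h = solver.posterior_var()
    cov_beta = np.linalg.inv(C)
    return {
        "beta": beta,
        "uw": uw,
        "uh": uh,
        "profile_ll": profile,
        "cov_beta": cov_beta,
        "var_uw": var_w,
        "var_uh": var_h,
        "penalized_ll": f_prev,
    }


def _fit_laplace(y, X, wi, W, hi, H, hw, start_sigma2=(0.05, 0.1), sigma2_fixed=None):
    """Profile the Laplace likelihood over (log s2w, log s2h)."""
    n, p = X.shape
    state = {
        "beta": np.zeros(p),
        "uw": np.zeros(W) if W else None,
        "uh": np.zeros(H) if H else None,
    }
    state["beta"][0] = math.log(max(y.mean(), 1e-3) / max(1 - y.mean(), 1e-3))

    free = []  # indices into (w, h) that are optimized
    if sigma2_fixed is None:
        sigma2_fixed = (None, None)
    s2w_fix, s2h_fix = sigma2_fixed
    if W and s2w_fix is None:
        free.append("w")
    if H and s2h_fix is None:
        free.append("h")

    def run(x):
        s2 = dict(w=s2w_fix, h=s2h_fix)
        for k, xi in zip(free, x):
            s2[k] = float(np.exp(np.clip(xi, -14.0, 6.0)))
        res = _pirls(
            y, X, wi, W, hi, H, hw,
            s2["w"] if W else 1.0, s2["h"] if H else 1.0,
            state["beta"], state["uw"] if W else np.zeros(0), state["uh"] if H else np.zeros(0),
        )
        state["beta"] = res["beta"]
        if W:
            state["uw"] = res["uw"]
        if H:
            state["uh"] = res["uh"]
        return res, (s2["w"], s2["h"])

    if free:
        x0 = []
        s0w, s0h = start_sigma2
        if "w" in free:
            x0.append(math.log(max(s0w, 1e-4)))
        if "h" in free:
            x0.append(math.log(max(s0h, 1e-4)))

        def nll(x):
            res, _ = run(x)
            return -res["profile_ll"]

        opt = minimize(
            nll,
            np.asarray(x0),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400},
        )
        xhat = opt.x
        res, (s2w, s2h) = run(xhat)
        n_evals = opt.nfev
        # curvature of the profile deviance on the log-variance scale
        ci = _sigma2_wald_ci(nll, xhat)
    else:
        res, (s2w, s2h) = run([])
        ci = []
        n_evals = 1

    out = {
        "beta": res["beta"],
        "cov_beta": res["cov_beta"],
        "uw": res["uw"],
        "uh": res["uh"],
        "var_uw": res["var_uw"],
        "var_uh": res["var_uh"],
        "loglik": res["profile_ll"],
        "s2w": s2w,
        "s2h": s2h,
        "n_evals": n_evals,
    }
    ci_map = dict(zip(free, ci))
    out["s2w_ci"] = ci_map.get("w")
    out["s2h_ci"] = ci_map.get("h")
    return out


def _sigma2_wald_ci(nll, xhat, h=0.1):
    """Per-component 95% CI from log-scale curvature (central differences).

    Off-diagonal curvature is ignored (the two variance components are close
    to orthogonal in the profile likelihood); near-boundary or non-convex
    curvature yields a conservative wide interval flagged by the caller.
    """
    f0 = nll(xhat)
    cis = []
    for i in range(len(xhat)):
        e = np.zeros_like(xhat)
        e[i] = h
        d2 = (nll(xhat + e) - 2 * f0 + nll(xhat - e)) / h**2
        if d2 <= 0 or not np.isfinite(d2):
            cis.append((0.0, float("inf")))
            continue
        se = 1.0 / math.sqrt(d2)
        lo, hi = xhat[i] - 1.96 * se, xhat[i] + 1.96 * se
        cis.append((float(np.exp(lo)), float(np.exp(min(hi, 50.0)))))
    return cis


# ---------------------------------------------------------------------------
# MCMC backend
# ---------------------------------------------------------------------------

def split_rhat(x: np.ndarray, nsplit: int = 4) -> float:
    """Potential-scale-reduction factor from one chain split into segments."""
    x = np.asarray(x, float)
    m = len(x) // nsplit
    if m < 2:
        return float("nan")
    seg = x[: m * nsplit].reshape(nsplit, m)
    w = seg.var(axis=1, ddof=1).mean()
    b = m * seg.mean(axis=1).var(ddof=1)
    if w <= 0:
        return 1.0
    return float(math.sqrt(((m - 1) / m * w + b / m) / w))


def _bernoulli_ll(y, eta):
    return y * eta - np.logaddexp(0.0, eta)


def _fit_mcmc(
    y, X, wi, W, hi, H, hw,
    start, n_iter=5000, burn=1000, thin=1, seed=0,
    prior_ab=(0.001, 0.001),
):
    """Metropolis-within-Gibbs sampler; see module docstring for the scheme."""
    rng = np.random.default_rng(seed)
    n, p = X.shape
    a0, b0 = prior_ab

    beta = start["beta"].copy()
    uw = start["uw"].copy() if W else None
    uh = start["uh"].copy() if H else None
    s2w = max(start.get("s2w") or 0.05, 1e-4)
    s2h = max(start.get("s2h") or 0.05, 1e-4)

    chol_beta = np.linalg.cholesky(start["cov_beta"]) * 2.38 / math.sqrt(p)
    beta_fac = 1.0
    sc_w = 2.4 * np.sqrt(start["var_uw"]) if W else None
    sc_h = 2.4 * np.sqrt(start["var_uh"]) if H else None

    eta = X @ beta
    if W:
        eta = eta + uw[wi]
    if H:
        eta = eta + uh[hi]

    keep = n_iter // thin
    beta_draws = np.empty((keep, p))
    s2_draws = np.empty((keep, 2))
    dev_draws = np.empty(keep)
    uw_sum = np.zeros(W) if W else None
    uw_sq = np.zeros(W) if W else None
    uh_sum = np.zeros(H) if H else None
    uh_sq = np.zeros(H) if H else None

    acc_b = 0
    acc_w = np.zeros(W) if W else None
    acc_h = np.zeros(H) if H else None
    win_b, win_w, win_h = 0, None, None
    if W:
        win_w = np.zeros(W)
    if H:
        win_h = np.zeros(H)

    kidx = 0
    for it in range(burn + n_iter):
        # --- ward intercepts (vectorized scalar MH) ---
        if W:
            prop = rng.normal(0.0, 1.0, W) * sc_w
            d_eta = prop[wi]
            dll = np.bincount(
                wi, weights=_bernoulli_ll(y, eta + d_eta) - _bernoulli_ll(y, eta), minlength=W
            )
            dll -= 0.5 * ((uw + prop) ** 2 - uw**2) / s2w
            acc = np.log(rng.random(W)) < dll
            uw = uw + prop * acc
            eta = eta + (prop * acc)[wi]
            if it < burn:
                win_w += acc
            else:
                acc_w += acc
        # --- hospital intercepts ---
        if H:
            prop = rng.normal(0.0, 1.0, H) * sc_h
            d_eta = prop[hi]
            dll = np.bincount(
                hi, weights=_bernoulli_ll(y, eta + d_eta) - _bernoulli_ll(y, eta), minlength=H
            )
            dll -= 0.5 * ((uh + prop) ** 2 - uh**2) / s2h
            acc = np.log(rng.random(H)) < dll
            uh = uh + prop * acc
            eta = eta + (prop * acc)[hi]
            if it < burn:
                win_h += acc
            else:
                acc_h += acc
        # --- fixed effects (joint RW) ---
        dbeta = beta_fac * (chol_beta @ rng.normal(0.0, 1.0, p))
        d_eta = X @ dbeta
        dll = float(np.sum(_bernoulli_ll(y, eta + d_eta) - _bernoulli_ll(y, eta)))
        if math.log(rng.random()) < dll:
            beta = beta + dbeta
            eta = eta + d_eta
            if it >= burn:
                acc_b += 1
            else:
                win_b += 1
        # --- variances (conjugate Gibbs) ---
        if W:
            s2w = 1.0 / rng.gamma(a0 + 0.5 * W, 1.0 / (b0 + 0.5 * float(uw @ uw)))
        if H:
            s2h = 1.0 / rng.gamma(a0 + 0.5 * H, 1.0 / (b0 + 0.5 * float(uh @ uh)))

        # --- burn-in adaptation, every 100 iterations ---
        if it < burn and (it + 1) % 100 == 0:
            if W:
                sc_w = np.clip(sc_w * np.exp((win_w / 100 - 0.44)), 1e-3, 10.0)
                win_w[:] = 0
            if H:
                sc_h = np.clip(sc_h * np.exp((win_h / 100 - 0.44)), 1e-3, 10.0)
                win_h[:] = 0
            beta_fac = float(np.clip(beta_fac * math.exp(win_b / 100 - 0.234), 0.05, 20.0))
            win_b = 0
        if (it + 1) % 500 == 0:  # guard against floating-point drift in eta
            eta = X @ beta
            if W:
                eta = eta + uw[wi]
            if H:
                eta = eta + uh[hi]

        if it >= burn and (it - burn) % thin == 0:
            beta_draws[kidx] = beta
            s2_draws[kidx] = (s2w if W else np.nan, s2h if H else np.nan)
            dev_draws[kidx] = -2.0 * float(np.sum(_bernoulli_ll(y, eta)))
            if W:
                uw_sum += uw
                uw_sq += uw**2
            if H:
                uh_sum += uh
                uh_sq += uh**2
            kidx += 1

    beta_draws = beta_draws[:kidx]
    s2_draws = s2_draws[:kidx]
    dev_draws = dev_draws[:kidx]

    out = {
        "beta_draws": beta_draws,
        "s2_draws": s2_draws,
        "dev_draws": dev_draws,
        "accept_beta": acc_b / max(kidx, 1),
    }
    # posterior means of u and deviance at posterior means -> conditional DIC
    eta_hat = X @ beta_draws.mean(axis=0)
    if W:
        uw_mean = uw_sum / kidx
        out["uw_mean"] = uw_mean
        out["uw_sd"] = np.sqrt(np.maximum(uw_sq / kidx - uw_mean**2, 0.0))
        out["accept_w"] = float((acc_w / kidx).mean())
        eta_hat = eta_hat + uw_mean[wi]
    if H:
        uh_mean = uh_sum / kidx
        out["uh_mean"] = uh_mean
        out["uh_sd"] = np.sqrt(np.maximum(uh_sq / kidx - uh_mean**2, 0.0))
        out["accept_h"] = float((acc_h / kidx).mean())
        eta_hat = eta_hat + uh_mean[hi]
    dev_bar = float(dev_draws.mean())
    dev_hat = -2.0 * float(np.sum(_bernoulli_ll(y, eta_hat)))
    out["deviance_bar"] = dev_bar
    out["p_d"] = dev_bar - dev_hat
    out["dic"] = dev_bar + out["p_d"]

    rhats = {}
    if W:
        rhats["sigma2_ward"] = split_rhat(s2_draws[:, 0])
    if H:
        rhats["sigma2_hospital"] = split_rhat(s2_draws[:, 1])
    rhats["deviance"] = split_rhat(dev_draws)
    out["rhat"] = rhats
    return out


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class MultilevelLogit:
    """Logistic regression with optional nested ward/hospital random intercepts.

    Parameters
    ----------
    endog : array of 0/1 outcomes.
    exog : (n, p) fixed-effect design matrix including an intercept column.
    exog_names : column names for ``exog``.
    ward, hospital : per-row cluster labels (opaque); ward labels must nest
        strictly within hospital labels when both are given.
    """

    def __init__(self, endog, exog, exog_names=None, ward=None, hospital=None,
                 design_info=None):
        self.endog = np.asarray(endog, float)
        if not np.isin(self.endog, (0.0, 1.0)).all():
            raise ValueError("outcome must be binary 0/1")
        self.exog = np.asarray(exog, float)
        n, p = self.exog.shape
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{i}" for i in range(p)
        ]
        _check_rank(self.exog, self.exog_names)
        self.design_info = design_info

        self.levels = tuple(
            lv for lv, lab in (("hospital", hospital), ("ward", ward)) if lab is not None
        )
        self.ward_labels = self.hospital_labels = None
        self._wi = self._hi = self._hw = None
        self._W = self._H = 0
        if ward is not None:
            ward = pd.Series(ward).reset_index(drop=True)
            self.ward_labels = pd.Index(pd.unique(ward))
            self._wi = self.ward_labels.get_indexer(ward).astype(np.intp)
            self._W = len(self.ward_labels)
        if hospital is not None:
            hospital = pd.Series(hospital).reset_index(drop=True)
            self.hospital_labels = pd.Index(pd.unique(hospital))
            self._hi = self.hospital_labels.get_indexer(hospital).astype(np.intp)
            self._H = len(self.hospital_labels)
        if ward is not None and hospital is not None:
            nh = pd.Series(self._hi).groupby(pd.Series(self._wi)).nunique()
            if (nh > 1).any():
                bad = [self.ward_labels[i] for i in nh.index[nh > 1][:5]]
                raise ValueError(f"ward(s) {bad} span multiple hospitals")
            hw = np.empty(self._W, dtype=np.intp)
            hw[self._wi] = self._hi
            self._hw = hw

    # -- construction from a dataframe -----------------------------------
    @classmethod
    def from_dataframe(
        cls,
        data,
        response: str,
        terms,
        ward: str | None = None,
        hospital: str | None = None,
        ref_levels: dict | None = None,
    ) -> "MultilevelLogit":
        df = getattr(data, "data", data)  # accepts CohortTable or DataFrame
        X, info = build_design(df, terms, ref_levels)
        return cls(
            df[response].to_numpy(float),
            X,
            exog_names=info.names,
            ward=df[ward] if ward else None,
            hospital=df[hospital] if hospital else None,
            design_info=info,
        )

    # -- fitting ----------------------------------------------------------
    def fit(self, method: str = "laplace", **kwargs) -> "MultilevelResults":
        """Fit the model; ``method`` is ``laplace``, ``mcmc`` or ``glm``.

        ``glm`` (automatic when no random levels are present) delegates to
        statsmodels' maximum-likelihood logistic fit.
        """
        if method == "mcmc":
            return self.fit_mcmc(**kwargs)
        if not self.levels or method == "glm":
            if self.levels:
                raise ValueError("glm method is only for models without random levels")
            return self._fit_glm()
        if method != "laplace":
            raise ValueError(f"unknown method {method!r}")
        return self._fit_laplace(**kwargs)

    def _fit_glm(self) -> "MultilevelResults":
        glm = sm.GLM(self.endog, self.exog, family=sm.families.Binomial())
        res = glm.fit()
        return MultilevelResults(
            model=self,
            method="glm",
            params=pd.Series(res.params, index=self.exog_names),
            cov_params=pd.DataFrame(
                res.cov_params(), index=self.exog_names, columns=self.exog_names
            ),
            sigma2={},
            ranef={},
            loglik=float(res.llf),
            converged=bool(res.converged),
            diagnostics={"backend": "statsmodels.GLM"},
        )

    def _fit_laplace(
        self, start_sigma2=(0.05, 0.1), sigma2_fixed=None
    ) -> "MultilevelResults":
        wi, W, hi, H, hw = self._structure(sigma2_fixed)
        fixed = None
        if sigma2_fixed is not None:
            sw = sigma2_fixed.get("ward") if W else None
            sh = sigma2_fixed.get("hospital") if H else None
            fixed = (sw, sh)
        raw = _fit_laplace(
            self.endog, self.exog, wi, W, hi, H, hw,
            start_sigma2=start_sigma2, sigma2_fixed=fixed,
        )
        sigma2, ranef = {}, {}
        if W:
            sigma2["ward"] = VarianceComponent(
                raw["s2w"], raw["s2w_ci"], boundary=raw["s2w"] < BOUNDARY_TOL
            )
            ranef["ward"] = pd.DataFrame(
                {"u": raw["uw"], "se": np.sqrt(raw["var_uw"])},
                index=self._ranef_index("ward"),
            )
        if H:
            sigma2["hospital"] = VarianceComponent(
                raw["s2h"], raw["s2h_ci"], boundary=raw["s2h"] < BOUNDARY_TOL
            )
            ranef["hospital"] = pd.DataFrame(
                {"u": raw["uh"], "se": np.sqrt(raw["var_uh"])},
                index=self._ranef_index("hospital"),
            )
        return MultilevelResults(
            model=self,
            method="laplace",
            params=pd.Series(raw["beta"], index=self.exog_names),
            cov_params=pd.DataFrame(
                raw["cov_beta"], index=self.exog_names, columns=self.exog_names
            ),
            sigma2=sigma2,
            ranef=ranef,
            loglik=raw["loglik"],
            converged=True,
            diagnostics={"n_profile_evals": raw["n_evals"]},
        )

    def fit_mcmc(
        self,
        n_iter: int = 5000,
        burn: int = 1000,
        thin: int = 1,
        seed: int = 0,
        start: "MultilevelResults | None" = None,
        rhat_threshold: float = 1.05,
        on_nonconvergence: str = "raise",
        prior_ab: tuple = (0.001, 0.001),
    ) -> "MultilevelResults":
        """MCMC fit started from the Laplace mode (RIGLS->MCMC in spirit)."""
        wi, W, hi, H, hw = self._structure(None)
        if start is None and self.levels:
            start = self._fit_laplace()
        if start is not None:
            st = {
                "beta": start.params.to_numpy(),
                "cov_beta": start.cov_params.to_numpy(),
                "uw": start.ranef["ward"]["u"].to_numpy() if W else None,
                "uh": start.ranef["hospital"]["u"].to_numpy() if H else None,
                "var_uw": start.ranef["ward"]["se"].to_numpy() ** 2 if W else None,
                "var_uh": start.ranef["hospital"]["se"].to_numpy() ** 2 if H else None,
                "s2w": start.sigma2["ward"].estimate if W else None,
                "s2h": start.sigma2["hospital"].estimate if H else None,
            }
        else:  # no random levels: start from the ML fit
            glm = self._fit_glm()
            st = {
                "beta": glm.params.to_numpy(),
                "cov_beta": glm.cov_params.to_numpy(),
                "uw": None, "uh": None, "var_uw": None, "var_uh": None,
                "s2w": None, "s2h": None,
            }
        raw = _fit_mcmc(
            self.endog, self.exog, wi, W, hi, H, hw,
            st, n_iter=n_iter, burn=burn, thin=thin, seed=seed, prior_ab=prior_ab,
        )
        rhats = raw["rhat"]
        bad = {k: v for k, v in rhats.items() if k.startswith("sigma2") and v > rhat_threshold}
        converged = not bad
        if bad:
            msg = f"split-Rhat above {rhat_threshold} for {sorted(bad)}: {bad}"
            if on_nonconvergence == "raise":
                raise ConvergenceError(msg, diagnostics=rhats)
            warnings.warn(msg)

        q = lambda a, axis=0: np.quantile(a, [0.5, 0.025, 0.975], axis=axis)
        bq = q(raw["beta_draws"])
        params = pd.Series(bq[0], index=self.exog_names)
        cov = pd.DataFrame(
            np.cov(raw["beta_draws"].T).reshape(len(params), len(params)),
            index=self.exog_names, columns=self.exog_names,
        )
        sigma2, ranef = {}, {}
        if W:
            sq = q(raw["s2_draws"][:, 0])
            sigma2["ward"] = VarianceComponent(
                float(sq[0]), (float(sq[1]), float(sq[2])), boundary=sq[0] < BOUNDARY_TOL
            )
            ranef["ward"] = pd.DataFrame(
                {"u": raw["uw_mean"], "se": raw["uw_sd"]}, index=self._ranef_index("ward")
            )
        if H:
            sq = q(raw["s2_draws"][:, 1])
            sigma2["hospital"] = VarianceComponent(
                float(sq[0]), (float(sq[1]), float(sq[2])), boundary=sq[0] < BOUNDARY_TOL
            )
            ranef["hospital"] = pd.DataFrame(
                {"u": raw["uh_mean"], "se": raw["uh_sd"]}, index=self._ranef_index("hospital")
            )
        return MultilevelResults(
            model=self,
            method="mcmc",
            params=params,
            cov_params=cov,
            sigma2=sigma2,
            ranef=ranef,
            loglik=float("nan"),
            converged=converged,
            diagnostics={
                "rhat": rhats,
                "accept_beta": raw["accept_beta"],
                "accept_ward": raw.get("accept_w"),
                "accept_hospital": raw.get("accept_h"),
                "n_kept": len(raw["dev_draws"]),
            },
            mcmc={
                "beta_ci": pd.DataFrame(
                    bq[1:].T, index=self.exog_names, columns=["lo", "hi"]
                ),
                "deviance_bar": raw["deviance_bar"],
                "p_d": raw["p_d"],
                "dic": raw["dic"],
                "s2_draws": raw["s2_draws"],
            },
        )

    # -- helpers -----------------------------------------------------------
    def _structure(self, sigma2_fixed):
        """Active random-effect structure, dropping levels pinned at zero."""
        wi, W, hw = self._wi, self._W, self._hw
        hi, H = self._hi, self._H
        if sigma2_fixed:
            if sigma2_fixed.get("ward") == 0:
                wi, W, hw = None, 0, None
            if sigma2_fixed.get("hospital") == 0:
                hi, H, hw = None, 0, None
        if W and not H:
            hw = None
        if H and not W:
            hw = None
        return wi, W, hi, H, hw

    def _ranef_index(self, level):
        labels = self.ward_labels if level == "ward" else self.hospital_labels
        return pd.Index(labels, name=level)


@dataclasses.dataclass
class VarianceComponent:
    """A variance estimate with its 95% interval and boundary flag."""

    estimate: float
    ci95: tuple | None = None
    boundary: bool = False

    def __post_init__(self):
        if self.estimate < 0:
            raise ValueError("variance estimate must be non-negative")


class MultilevelResults:
    """Fit results: fixed effects, variance components, shrunken residuals.

    The same container backs single-level ML fits (``method='glm'``), Laplace
    fits and MCMC fits; MCMC-only quantities (DIC, credible intervals) raise
    informative errors elsewhere.
    """

    def __init__(
        self, model, method, params, cov_params, sigma2, ranef,
        loglik, converged, diagnostics, mcmc=None,
    ):
        self.model = model
        self.method = method
        self.params = params
        self.cov_params = cov_params
        self.sigma2 = sigma2
        self.ranef = ranef
        self.loglik = loglik
        self.converged = converged
        self.diagnostics = diagnostics
        self._mcmc = mcmc or {}
        self.nobs = len(model.endog)

    # -- fixed effects -----------------------------------------------------
    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.cov_params.to_numpy())), index=self.params.index
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        if self.method == "mcmc":
            return self._mcmc["beta_ci"].copy()
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lo": self.params - z * self.bse, "hi": self.params + z * self.bse}
        )

    def odds_ratios(self) -> pd.DataFrame:
        """exp(beta) with 95% intervals, intercept dropped."""
        ci = self.conf_int()
        out = pd.DataFrame(
            {"OR": np.exp(self.params), "lo": np.exp(ci["lo"]), "hi": np.exp(ci["hi"])}
        )
        return out.drop(index="intercept", errors="ignore")

    # -- information criteria ----------------------------------------------
    @property
    def aic(self) -> float:
        if self.method == "mcmc" or not np.isfinite(self.loglik):
            raise DicUnavailableError("AIC is defined for likelihood-based fits only")
        k = len(self.params) + len(self.sigma2)
        return -2.0 * self.loglik + 2 * k

    @property
    def dic(self) -> float:
        """Conditional deviance information criterion (MCMC fits only)."""
        if self.method != "mcmc":
            raise DicUnavailableError(
                "DIC requires an MCMC fit; this is a "
                f"{self.method!r} fit — report `aic` instead"
            )
        return self._mcmc["dic"]

    @property
    def deviance_bar(self) -> float:
        if self.method != "mcmc":
            raise DicUnavailableError("posterior mean deviance requires an MCMC fit")
        return self._mcmc["deviance_bar"]

    @property
    def p_d(self) -> float:
        if self.method != "mcmc":
            raise DicUnavailableError("effective parameter count requires an MCMC fit")
        return self._mcmc["p_d"]

    # -- random effects -----------------------------------------------------
    def random_effects(self, level: str, se: str = "diagnostic") -> pd.DataFrame:
        """Shrunken residuals at ``level`` with SEs and 95% intervals.

        ``se='diagnostic'`` (default) uses the posterior SD of each cluster
        intercept, the convention behind caterpillar-plot intervals;
        ``se='comparative'`` uses sqrt(sigma2 - posterior variance), the
        spread of the estimator around the true intercept.
        """
        if level not in self.ranef:
            raise KeyError(
                f"fit has no {level!r} random level (has {sorted(self.ranef)})"
            )
        tab = self.ranef[level].copy()
        if se == "comparative":
            s2 = self.sigma2[level].estimate
            tab["se"] = np.sqrt(np.maximum(s2 - tab["se"] ** 2, 0.0))
        elif se != "diagnostic":
            raise ValueError("se must be 'diagnostic' or 'comparative'")
        tab["lo"] = tab["u"] - 1.96 * tab["se"]
        tab["hi"] = tab["u"] + 1.96 * tab["se"]
        return tab

    # -- prediction ----------------------------------------------------------
    def linear_predictor(self, data=None, include_levels=("hospital", "ward")):
        """Per-record linear predictor, optionally adding cluster residuals.

        With ``data=None`` the fitting records are scored.  Each level named
        in ``include_levels`` (and present in the fit) contributes its
        shrunken residual; a record whose cluster has no residual in the fit
        raises rather than silently contributing zero.
        """
        include = set(include_levels)
        unknown_levels = include - {"hospital", "ward"}
        if unknown_levels:
            raise ValueError(f"unknown level(s) {sorted(unknown_levels)}")
        if data is None:
            eta = self.model.exog @ self.params.to_numpy()
            if "ward" in include and "ward" in self.ranef:
                eta = eta + self.ranef["ward"]["u"].to_numpy()[self.model._wi]
            if "hospital" in include and "hospital" in self.ranef:
                eta = eta + self.ranef["hospital"]["u"].to_numpy()[self.model._hi]
            return eta
        df = getattr(data, "data", data)
        if self.model.design_info is None:
            raise ValueError("fit was not built from a dataframe; score data=None only")
        X = design_from_info(df, self.model.design_info)
        eta = X @ self.params.to_numpy()
        for level, col in (("ward", "ward_id"), ("hospital", "hospital_id")):
            if level in include and level in self.ranef:
                u = self.ranef[level]["u"]
                labels = df[col]
                missing = set(labels) - set(u.index)
                if missing:
                    raise KeyError(
                        f"no fitted {level} residual for cluster(s) {sorted(missing)[:5]}"
                    )
                eta = eta + labels.map(u).to_numpy()
        return eta

    # -- presentation ---------------------------------------------------------
    def summary(self) -> str:
        lines = [
            f"MultilevelLogit results ({self.method}), n = {self.nobs}",
            f"random levels: {sorted(self.ranef) or 'none'}",
            "",
            "Fixed effects (odds-ratio scale):",
        ]
        ors = self.odds_ratios()
        for name, row in ors.iterrows():
            lines.append(
                f"  {name:<42s} {row.OR:7.2f}  ({row.lo:.2f}-{row.hi:.2f})"
            )
        if self.sigma2:
            lines.append("")
            lines.append("Variance components (logit scale):")
            for level, vc in self.sigma2.items():
                ci = (
                    f"({vc.ci95[0]:.3f}-{vc.ci95[1]:.3f})" if vc.ci95 else "(n/a)"
                )
                flag = "  [boundary]" if vc.boundary else ""
                lines.append(f"  {level:<10s} {vc.estimate:8.4f}  {ci}{flag}")
        try:
            lines.append("")
            lines.append(f"DIC: {self.dic:.3f} (pD = {self.p_d:.1f})")
        except DicUnavailableError:
            if np.isfinite(self.loglik):
                lines.append("")
                lines.append(f"log-likelihood: {self.loglik:.3f}  AIC: {self.aic:.3f}")
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<MultilevelResults method={self.method} n={self.nobs} "
            f"levels={sorted(self.ranef)}>"
        )


# ---------------------------------------------------------------------------
# spec-facing convenience operations
# ---------------------------------------------------------------------------

def fit_single_level(
    cohort, terms, response: str = "death30", ref_levels=None
) -> MultilevelResults:
    """Maximum-likelihood single-level logistic fit (no random terms)."""
    model = MultilevelLogit.from_dataframe(
        cohort, response, terms, ref_levels=ref_levels
    )
    return model.fit()


def fit_three_level(
    cohort,
    terms,
    response: str = "death30",
    ref_levels=None,
    ward: str = "ward_id",
    hospital: str = "hospital_id",
    method: str = "laplace",
    **kwargs,
) -> MultilevelResults:
    """Three-level fit: patients in wards in hospitals (both random levels)."""
    model = MultilevelLogit.from_dataframe(
        cohort, response, terms, ward=ward, hospital=hospital, ref_levels=ref_levels
    )
    return model.fit(method=method, **kwargs)


def shrunken_residuals(fit: MultilevelResults, level: str, se: str = "diagnostic"):
    """Per-cluster shrunken residuals (u, SE, 95% interval) at ``level``."""
    return fit.random_effects(level, se=se)
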