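"""Spatial panel econometrics: SDM / SAR / SEM by concentrated quasi-ML.

The spatial Durbin model (SDM) for a balanced panel of n units over T
periods, with unit effects mu_i and time effects gamma_t, is

    y_t = rho W y_t + X_t beta + W X_t theta + mu + gamma_t 1 + eps_t,

with W the row-standardized contiguity matrix.  Setting theta = 0 gives
the spatial autoregressive model (SAR); the spatial error model (SEM)
instead puts the autocorrelation in the disturbance, u_t = lambda W u_t +
eps_t.  Fixed effects are absorbed by the within (two-way demeaning)
transformation, which commutes with W because row-standardized W maps
constants to constants.  Estimation concentrates the Gaussian likelihood
in the scalar spatial parameter; the Jacobian term T * ln|I - rho W| is
evaluated from the (real) eigenvalues of W, and the admissible interval is
(1/omega_min, 1).  Standard errors come from the analytic information
matrix.  Marginal effects of regressor k follow LeSage & Pace:
S_k(W) = (I - rho W)^{-1}(beta_k I + theta_k W); the direct effect is the
mean diagonal of S_k, the total effect the mean row sum, and the indirect
(spillover) effect their difference, with simulation inference from
multivariate-normal parameter draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

from .spatial_autocorr import WeightMatrix

__all__ = [
    "SpatialPanelSpec",
    "SpatialModelFit",
    "EffectsDecomposition",
    "SpecTestResult",
    "demean_two_way",
    "fit_spatial_panel",
    "fit_spatial_panel_re",
    "lm_tests",
    "lr_test",
    "wald_theta_zero",
    "wald_common_factor",
    "hausman_test",
    "lr_wald_hausman",
    "decompose_effects",
]

_RHO_EPS = 1e-6
_LOG2PI = np.log(2 * np.pi)


@dataclass
class SpatialPanelSpec:
    """Model specification: response (n, T), regressors (n, T, k), weights.

    ``model`` is one of ``sdm``/``sar``/``sem``; ``effects`` chooses which
    fixed effects the within transformation absorbs.
    """

    response: np.ndarray
    regressors: np.ndarray
    W: WeightMatrix
    model: str = "sdm"
    effects: str = "both"  # none | individual | time | both
    regressor_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.response = np.asarray(self.response, dtype=float)
        self.regressors = np.asarray(self.regressors, dtype=float)
        n, T = self.response.shape
        if self.regressors.shape[:2] != (n, T):
            raise ValueError("regressor array mismatches response panel shape")
        if self.W.n != n:
            raise ValueError("weight matrix dimension mismatches number of units")
        if self.model not in {"sdm", "sar", "sem"}:
            raise ValueError(f"model must be sdm|sar|sem, got {self.model!r}")
        if self.effects not in {"none", "individual", "time", "both"}:
            raise ValueError(f"bad effects spec {self.effects!r}")
        if not self.regressor_names:
            self.regressor_names = [f"X{j + 1}" for j in range(self.regressors.shape[2])]


@dataclass
class SpatialModelFit:
    model: str
    effects: str
    rho_or_lambda: float
    beta: np.ndarray
    theta: np.ndarray | None
    sigma2: float
    loglik: float
    vcov: np.ndarray  # over (beta[, theta], rho_or_lambda, sigma2)
    r2: float
    param_names: list[str]
    n: int
    T: int
    eigenvalues: np.ndarray
    nobs_eff: int = 0  # effective sample size of the (transformed) likelihood

    @property
    def n_slopes(self) -> int:
        return len(self.beta) + (len(self.theta) if self.theta is not None else 0)

    @property
    def slopes(self) -> np.ndarray:
        if self.theta is not None:
            return np.concatenate([self.beta, self.theta])
        return self.beta


@dataclass
class EffectsDecomposition:
    names: list[str]
    direct: np.ndarray
    indirect: np.ndarray
    total: np.ndarray
    direct_se: np.ndarray
    indirect_se: np.ndarray
    total_se: np.ndarray
    direct_p: np.ndarray
    indirect_p: np.ndarray
    total_p: np.ndarray
    draws: int
    seed: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "direct": self.direct, "direct_se": self.direct_se, "direct_p": self.direct_p,
                "indirect": self.indirect, "indirect_se": self.indirect_se,
                "indirect_p": self.indirect_p,
                "total": self.total, "total_se": self.total_se, "total_p": self.total_p,
            },
            index=self.names,
        )


@dataclass(frozen=True)
class SpecTestResult:
    name: str
    statistic: float
    df: int
    p_value: float
    note: str = ""


# ---------------------------------------------------------------------------
# transformations


def demean_two_way(
    response: np.ndarray, regressors: np.ndarray, effects: str = "both"
) -> tuple[np.ndarray, np.ndarray]:
    """Within transformation absorbing unit and/or period fixed effects.

    For ``effects='both'`` subtracts unit means and period means and adds
    back the grand mean from the response and every regressor.  Requires a
    balanced panel (full arrays).
    """
    y = np.asarray(response, dtype=float)
    X = np.asarray(regressors, dtype=float)
    if not np.isfinite(y).all() or not np.isfinite(X).all():
        raise ValueError("unbalanced panel: missing cells in response or regressors")

    def dm(a: np.ndarray) -> np.ndarray:
        # a has shape (n, T) or (n, T, k); axes 0=unit, 1=period
        out = a.astype(float, copy=True)
        if effects in ("individual", "both"):
            out = out - out.mean(axis=1, keepdims=True)
        if effects in ("time", "both"):
            # sequential demeaning equals y - y_i. - y_.t + y_.. for 'both'
            out = out - out.mean(axis=0, keepdims=True)
        return out

    return dm(y), dm(X)


def _stack(panel: np.ndarray) -> np.ndarray:
    """(n, T[, k]) -> (nT[, k]) stacked period-by-period (unit fastest)."""
    if panel.ndim == 2:
        return panel.flatten(order="F")
    n, T, k = panel.shape
    return panel.transpose(1, 0, 2).reshape(n * T, k)

def _wlag(panel: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Apply the static weight matrix within each period."""
    if panel.ndim == 2:
        return W @ panel
    return np.einsum("ij,jtk->itk", W, panel)


def _eigenvalues(W: WeightMatrix) -> np.ndarray:
    ev = np.linalg.eigvals(W.row_standardized)
    if np.abs(ev.imag).max() > 1e-8:
        raise ValueError("weight matrix has complex eigenvalues")
    return np.sort(ev.real)


def _rho_interval(ev: np.ndarray) -> tuple[float, float]:
    lo = 1.0 / ev.min() if ev.min() < 0 else -1.0 + _RHO_EPS
    return lo + _RHO_EPS, 1.0 - _RHO_EPS


# ---------------------------------------------------------------------------
# estimation


def fit_spatial_panel(spec: SpatialPanelSpec, transform: bool = True) -> SpatialModelFit:
    """Concentrated quasi-ML fit of the specified spatial panel model.

    The within transformation is applied internally according to
    ``spec.effects``.  Spatial lags are computed on the raw data and then
    demeaned: cross-section demeaning does not commute with a
    row-standardized W (its column sums differ from one), so demean-then-lag
    would misalign the lag regressor with the model implied by the within
    transformation.

    With ``transform=True`` (default) the likelihood is evaluated in the
    transformed space of the within operator: demeaning in the time
    direction removes one period, demeaning in the unit direction removes
    the constant eigenvector of W (eigenvalue 1), so the effective
    dimensions are (n-1) and/or (T-1) and the unit eigenvalue is dropped
    from the log-Jacobian.  This is the transformation estimator that keeps
    the two-way fixed-effects QMLE consistent at moderate n; ``False``
    reproduces the naive demeaned likelihood.
    """
    ydm, Xdm = demean_two_way(spec.response, spec.regressors, spec.effects)
    Wm = spec.W.row_standardized
    wydm, wXdm = demean_two_way(
        _wlag(spec.response, Wm), _wlag(spec.regressors, Wm), spec.effects)
    ev = _eigenvalues(spec.W)
    n, T = ydm.shape
    if transform:
        n_eff = n - 1 if spec.effects in ("time", "both") else n
        T_eff = T - 1 if spec.effects in ("individual", "both") else T
        ev_det = (np.delete(ev, np.argmin(np.abs(ev - 1.0)))
                  if spec.effects in ("time", "both") else ev)
    else:
        n_eff, T_eff, ev_det = n, T, ev
    dims = (n_eff, T_eff, ev_det)
    if spec.model == "sem":
        return _fit_sem(spec, ydm, Xdm, wydm, wXdm, Wm, ev, dims)
    return _fit_sar_sdm(spec, ydm, Xdm, wydm, wXdm, Wm, ev, dims)


def _concentrated_nll_factory(e0, ed, nT, T, ev):
    def nll(rho):
        e = e0 - rho * ed
        sse = e @ e
        return 0.5 * nT * np.log(sse / nT) - T * np.log(1.0 - rho * ev).sum()

    return nll


def _fit_sar_sdm(spec, ydm, Xdm, wydm, wXdm, Wm, ev, dims):
    n, T = ydm.shape
    n_eff, T_eff, ev_det = dims
    NT = n_eff * T_eff
    y = _stack(ydm)
    wy = _stack(wydm)
    X = _stack(Xdm)
    k = X.shape[1]
    if spec.model == "sdm":
        Z = np.hstack([X, _stack(wXdm)])
        names = list(spec.regressor_names) + [f"W*{v}" for v in spec.regressor_names]
    else:
        Z = X
        names = list(spec.regressor_names)
    K = Z.shape[1]

    ZtZ = Z.T @ Z
    b0 = np.linalg.solve(ZtZ, Z.T @ y)
    bd = np.linalg.solve(ZtZ, Z.T @ wy)
    e0 = y - Z @ b0
    ed = wy - Z @ bd

    lo, hi = _rho_interval(ev)
    nll = _concentrated_nll_factory(e0, ed, NT, T_eff, ev_det)
    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    rho = float(res.x)
    if rho <= lo + 1e-5 or rho >= hi - 1e-5:
        raise RuntimeError(
            f"spatial parameter at admissible boundary (rho={rho:.6f}, "
            f"interval=({lo:.4f}, {hi:.4f}))")
    delta = b0 - rho * bd
    e = e0 - rho * ed
    sigma2 = float(e @ e) / NT
    loglik = float(-0.5 * NT * (_LOG2PI + 1.0) - 0.5 * NT * np.log(sigma2)
                   + T_eff * np.log(1.0 - rho * ev_det).sum())

    # analytic information matrix over (delta, rho, sigma2); trace terms use
    # the within-projected lag operator so they refer to the transformed space
    A_inv = np.linalg.inv(np.eye(n) - rho * Wm)
    P = (np.eye(n) - np.ones((n, n)) / n
         if spec.effects in ("time", "both") else np.eye(n))
    C = P @ (Wm @ A_inv) @ P
    pred = (Z @ delta)  # nT
    Ppanel = pred.reshape(T, n).T  # (n, T)
    cp = _stack(Wm @ (A_inv @ Ppanel))
    info = np.zeros((K + 2, K + 2))
    info[:K, :K] = ZtZ / sigma2
    info[:K, K] = Z.T @ cp / sigma2
    info[K, :K] = info[:K, K]
    info[K, K] = T_eff * (np.trace(C @ C) + np.trace(C.T @ C)) + (cp @ cp) / sigma2
    info[K, K + 1] = T_eff * np.trace(C) / sigma2
    info[K + 1, K] = info[K, K + 1]
    info[K + 1, K + 1] = NT / (2 * sigma2 ** 2)
    vcov = np.linalg.inv(info)
    vcov = 0.5 * (vcov + vcov.T)

    fitted = _stack(A_inv @ Ppanel)
    r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2) if np.std(fitted) > 0 else 0.0

    beta = delta[:k]
    theta = delta[k:] if spec.model == "sdm" else None
    return SpatialModelFit(
        model=spec.model,
        effects=spec.effects,
        rho_or_lambda=rho,
        beta=beta,
        theta=theta,
        sigma2=sigma2,
        loglik=loglik,
        vcov=vcov,
        r2=r2,
        param_names=names + ["rho", "sigma2"],
        n=n,
        T=T,
        eigenvalues=ev,
        nobs_eff=NT,
    )


def _fit_sem(spec, ydm, Xdm, wydm, wXdm, Wm, ev, dims):
    n, T = ydm.shape
    n_eff, T_eff, ev_det = dims
    NT = n_eff * T_eff
    k = Xdm.shape[2]
    lo, hi = _rho_interval(ev)
    yv, wy = _stack(ydm), _stack(wydm)
    Xv, wX = _stack(Xdm), _stack(wXdm)

    def transformed(lam):
        # spatially filter, lags already demeaned consistently with the model
        return yv - lam * wy, Xv - lam * wX

    def nll(lam):
        ys, Xs = transformed(lam)
        b, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        e = ys - Xs @ b
        return 0.5 * NT * np.log((e @ e) / NT) - T_eff * np.log(1.0 - lam * ev_det).sum()

    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    lam = float(res.x)
    if lam <= lo + 1e-5 or lam >= hi - 1e-5:
        raise RuntimeError(f"spatial error parameter at boundary (lambda={lam:.6f})")
    ys, Xs = transformed(lam)
    XtX = Xs.T @ Xs
    beta = np.linalg.solve(XtX, Xs.T @ ys)
    e = ys - Xs @ beta
    sigma2 = float(e @ e) / NT
    loglik = float(-0.5 * NT * (_LOG2PI + 1.0) - 0.5 * NT * np.log(sigma2)
                   + T_eff * np.log(1.0 - lam * ev_det).sum())

    B_inv = np.linalg.inv(np.eye(n) - lam * Wm)
    P = (np.eye(n) - np.ones((n, n)) / n
         if spec.effects in ("time", "both") else np.eye(n))
    C = P @ (Wm @ B_inv) @ P
    info = np.zeros((k + 2, k + 2))
    info[:k, :k] = XtX / sigma2
    info[k, k] = T_eff * (np.trace(C @ C) + np.trace(C.T @ C))
    info[k, k + 1] = T_eff * np.trace(C) / sigma2
    info[k + 1, k] = info[k, k + 1]
    info[k + 1, k + 1] = NT / (2 * sigma2 ** 2)
    vcov = np.linalg.inv(info)
    vcov = 0.5 * (vcov + vcov.T)

    fitted = _stack(np.einsum("itk,k->it", Xdm, beta))
    yflat = _stack(ydm)
    r2 = float(np.corrcoef(fitted, yflat)[0, 1] ** 2) if np.std(fitted) > 0 else 0.0
    return SpatialModelFit(
        model="sem",
        effects=spec.effects,
        rho_or_lambda=lam,
        beta=beta,
        theta=None,
        sigma2=sigma2,
        loglik=loglik,
        vcov=vcov,
        r2=r2,
        param_names=list(spec.regressor_names) + ["lambda", "sigma2"],
        n=n,
        T=T,
        eigenvalues=ev,
        nobs_eff=NT,
    )


def fit_spatial_panel_re(spec: SpatialPanelSpec) -> SpatialModelFit:
    """Random-effects counterpart used by the Hausman test.

    The individual effect is treated as random: variance components are
    estimated from within and between residuals, the data quasi-demeaned by
    the factor 1 - sqrt(sigma_nu^2 / (T sigma_mu^2 + sigma_nu^2)), and the
    same concentrated spatial likelihood is then maximized on the
    transformed data.
    """
    y = spec.response
    X = spec.regressors
    n, T = y.shape
    k = X.shape[2]
    # within residual variance
    yw, Xw = demean_two_way(y, X, "individual")
    Zw = _stack(Xw)
    bw, *_ = np.linalg.lstsq(Zw, _stack(yw), rcond=None)
    ew = _stack(yw) - Zw @ bw
    sig_nu2 = float(ew @ ew) / max(n * (T - 1) - k, 1)
    # between regression
    yb = y.mean(axis=1)
    Xb = X.mean(axis=1)
    Xb1 = np.column_stack([np.ones(n), Xb])
    bb, *_ = np.linalg.lstsq(Xb1, yb, rcond=None)
    eb = yb - Xb1 @ bb
    sig1_2 = max(float(eb @ eb) / max(n - k - 1, 1) * T, sig_nu2 + 1e-12)
    vartheta = 1.0 - np.sqrt(sig_nu2 / sig1_2)

    yq = y - vartheta * y.mean(axis=1, keepdims=True)
    Xq = X - vartheta * X.mean(axis=1, keepdims=True)
    # time effects stay fixed (demeaned); only the individual effect is random
    keep_time = spec.effects in ("time", "both")
    re_spec = SpatialPanelSpec(
        response=yq, regressors=Xq, W=spec.W, model=spec.model,
        effects="time" if keep_time else "none",
        regressor_names=list(spec.regressor_names),
    )
    fit = fit_spatial_panel(re_spec)
    fit.effects = "random"
    return fit


# ---------------------------------------------------------------------------
# specification tests


def lm_tests(
    response: np.ndarray,
    regressors: np.ndarray,
    W: WeightMatrix,
    effects: str = "both",
) -> list[SpecTestResult]:
    """Anselin-type LM-lag / LM-error tests and robust variants for panels.

    Computed from pooled OLS residuals on the within-transformed data.
    Because the within projection does not commute with W, the classic
    trace formulas are replaced by the exact normal-theory null moments of
    the two score statistics under the combined demeaning-and-residual
    projection: each statistic is centered at its null mean and scaled by
    its null variance, and the robust variants partial one centered score
    out of the other using their analytic covariance.  Each statistic is
    asymptotically chi-square(1) under its null.
    """
    Wm = W.row_standardized
    y = np.asarray(response, dtype=float)
    Xr = np.asarray(regressors, dtype=float)
    n, T = y.shape
    ydm, Xdm = demean_two_way(y, Xr, effects)
    wydm, _ = demean_two_way(_wlag(y, Wm), _wlag(Xr, Wm), effects)
    yv = _stack(ydm)
    X = _stack(Xdm)
    wy = _stack(wydm)
    XtX = X.T @ X
    if np.linalg.cond(XtX) > 1e12:
        raise np.linalg.LinAlgError("singular regressor matrix in LM tests")
    b = np.linalg.solve(XtX, X.T @ yv)
    e = yv - X @ b

    # projection of the within transformation on the stacked space
    In, IT = np.eye(n), np.eye(T)
    Pn = In - np.ones((n, n)) / n if effects in ("time", "both") else In
    QT = IT - np.ones((T, T)) / T if effects in ("individual", "both") else IT
    Q = np.kron(QT, Pn)
    A = np.kron(IT, Wm)
    H = Q - X @ np.linalg.solve(XtX, X.T)  # symmetric idempotent: residual-maker after within
    df = float(np.trace(H))
    sigma2 = float(e @ e) / df

    B1 = H @ A @ Q
    B2 = B1 @ H
    c1 = H @ (A @ (X @ b))
    d_lag = float(e @ wy) / sigma2
    d_err = float(e @ (A @ e)) / sigma2
    m1, m2 = float(np.trace(B1)), float(np.trace(B2))
    v1 = float(c1 @ c1) / sigma2 + float(np.trace(B1 @ B1) + np.trace(B1 @ B1.T))
    v2 = float(np.trace(B2 @ B2) + np.trace(B2 @ B2.T))
    v12 = float(np.trace(B1 @ B2) + np.trace(B1 @ B2.T))
    u1, u2 = d_lag - m1, d_err - m2

    def chi1(stat: float, name: str) -> SpecTestResult:
        stat = max(stat, 0.0)
        return SpecTestResult(name, stat, 1, float(stats.chi2.sf(stat, 1)))

    return [
        chi1(u1 ** 2 / v1, "lm_lag"),
        chi1(u2 ** 2 / v2, "lm_error"),
        chi1((u1 - v12 / v2 * u2) ** 2 / (v1 - v12 ** 2 / v2), "robust_lm_lag"),
        chi1((u2 - v12 / v1 * u1) ** 2 / (v2 - v12 ** 2 / v1), "robust_lm_error"),
    ]


def lr_test(full: SpatialModelFit, nested: SpatialModelFit,
            df: int | None = None, name: str = "lr",
            small_sample: bool = True) -> SpecTestResult:
    """Likelihood-ratio test of a nested against a full fit on the same data.

    With ``small_sample=True`` the statistic is scaled by (N - K)/N, where
    N is the effective sample size and K the full model's slope count: for
    Gaussian likelihoods LR = N log(RSS0/RSS1) has null mean approximately
    q N/(N - K), so the scaling restores the chi-square(q) calibration.
    """
    if df is None:
        df = (len(full.param_names)) - (len(nested.param_names))
    if df < 0:
        raise ValueError("models are not nested: full model has fewer parameters")
    stat = max(2.0 * (full.loglik - nested.loglik), 0.0)
    if small_sample and full.nobs_eff > full.n_slopes:
        stat *= (full.nobs_eff - full.n_slopes) / full.nobs_eff
    dfree = max(df, 1)
    return SpecTestResult(name, stat, dfree, float(stats.chi2.sf(stat, dfree)))


def wald_theta_zero(fit: SpatialModelFit) -> SpecTestResult:
    """Wald test that all spatially lagged regressor coefficients vanish (SDM -> SAR)."""
    if fit.model != "sdm" or fit.theta is None:
        raise ValueError("theta restriction requires an SDM fit")
    k = len(fit.beta)
    idx = np.arange(k, 2 * k)
    V = fit.vcov[np.ix_(idx, idx)]
    stat = float(fit.theta @ np.linalg.solve(V, fit.theta))
    return SpecTestResult("wald_sar", max(stat, 0.0), k, float(stats.chi2.sf(stat, k)))


def wald_common_factor(fit: SpatialModelFit) -> SpecTestResult:
    """Wald test of theta = -rho * beta, the condition under which SDM reduces to SEM."""
    if fit.model != "sdm" or fit.theta is None:
        raise ValueError("common-factor restriction requires an SDM fit")
    k = len(fit.beta)
    rho = fit.rho_or_lambda
    g = fit.theta + rho * fit.beta
    # gradient wrt (beta, theta, rho)
    G = np.zeros((k, 2 * k + 1))
    G[:, :k] = rho * np.eye(k)
    G[:, k:2 * k] = np.eye(k)
    G[:, 2 * k] = fit.beta
    idx = np.arange(2 * k + 1)  # beta, theta, rho contiguous in vcov
    V = G @ fit.vcov[np.ix_(idx, idx)] @ G.T
    stat = float(g @ np.linalg.solve(V, g))
    return SpecTestResult("wald_sem", max(stat, 0.0), k, float(stats.chi2.sf(stat, k)))


def hausman_test(fit_fe: SpatialModelFit, fit_re: SpatialModelFit) -> SpecTestResult:
    """Hausman contrast of fixed- vs random-effects slope estimates.

    H = d' (V_FE - V_RE)^+ d over the common slope coefficients; a
    non-positive-definite middle matrix falls back to the Moore–Penrose
    pseudoinverse with df = rank, noted in the result.
    """
    if fit_fe.model != fit_re.model:
        raise ValueError("Hausman test requires the same model under FE and RE")
    K = fit_fe.n_slopes
    d = fit_fe.slopes - fit_re.slopes
    V = 0.5 * (fit_fe.vcov[:K, :K] - fit_re.vcov[:K, :K])
    V = V + V.T
    eigs, vecs = np.linalg.eigh(V)
    note = ""
    tol = max(abs(eigs).max(), 1e-30) * 1e-10
    if eigs.min() <= tol:
        # Moore–Penrose-type fallback: contrast restricted to the subspace
        # where the FE estimator is genuinely less efficient
        note = "non-PSD difference matrix; positive-eigenvalue pseudoinverse used"
        keep = eigs > tol
        df = max(int(keep.sum()), 1)
        proj = vecs[:, keep].T @ d
        stat = float((proj ** 2 / eigs[keep]).sum()) if keep.any() else 0.0
    else:
        stat = float(d @ np.linalg.solve(V, d))
        df = K
    stat = max(stat, 0.0)
    return SpecTestResult("hausman", stat, df, float(stats.chi2.sf(stat, df)), note)


def lr_wald_hausman(
    sdm: SpatialModelFit,
    sar: SpatialModelFit,
    sem: SpatialModelFit,
    sdm_re: SpatialModelFit | None = None,
) -> list[SpecTestResult]:
    """The degradation battery: LR and Wald SDM->SAR / SDM->SEM (+ optional Hausman)."""
    k = len(sdm.beta)
    out = [
        lr_test(sdm, sar, df=k, name="lr_sar"),
        lr_test(sdm, sem, df=k, name="lr_sem"),
        wald_theta_zero(sdm),
        wald_common_factor(sdm),
    ]
    if sdm_re is not None:
        out.append(hausman_test(sdm, sdm_re))
    return out


# ---------------------------------------------------------------------------
# effects decomposition


def decompose_effects(
    fit: SpatialModelFit,
    W: WeightMatrix,
    draws: int = 1000,
    seed: int = 20240816,
) -> EffectsDecomposition:
    """LeSage–Pace direct / indirect / total marginal effects with MC inference.

    Point estimates use the fitted parameters; standard errors and normal
    p-values come from ``draws`` multivariate-normal parameter draws using
    the fit's covariance (reproducible given ``seed``).
    """
    if fit.model not in {"sdm", "sar"}:
        raise ValueError("effects decomposition is defined for SDM and SAR fits")
    k = len(fit.beta)
    n = W.n
    Wm = W.row_standardized
    lo, hi = _rho_interval(fit.eigenvalues)
    if not lo <= fit.rho_or_lambda <= hi:
        raise ValueError("rho outside admissible interval")

    def summaries(beta, theta, rho):
        A_inv = np.linalg.inv(np.eye(n) - rho * Wm)
        diag_a = np.trace(A_inv) / n
        diag_aw = np.trace(A_inv @ Wm) / n
        tot_a = A_inv.sum() / n
        tot_aw = (A_inv @ Wm).sum() / n
        direct = beta * diag_a + theta * diag_aw
        total = beta * tot_a + theta * tot_aw
        return direct, total - direct, total

    theta_hat = fit.theta if fit.theta is not None else np.zeros(k)
    direct, indirect, total = summaries(fit.beta, theta_hat, fit.rho_or_lambda)

    K = fit.n_slopes
    idx = np.arange(K + 1)  # slopes + rho
    mean = np.concatenate([fit.slopes, [fit.rho_or_lambda]])
    cov = fit.vcov[np.ix_(idx, idx)]
    rng = np.random.default_rng(seed)
    sample = rng.multivariate_normal(mean, cov, size=draws, method="svd")
    sims = np.empty((draws, 3, k))
    for d in range(draws):
        b = sample[d, :k]
        th = sample[d, k:2 * k] if fit.model == "sdm" else np.zeros(k)
        rho = float(np.clip(sample[d, -1], lo, hi))
        sims[d] = np.stack(summaries(b, th, rho))
    se = sims.std(axis=0, ddof=1)
    mu = sims.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, mu / se, np.inf)
    p = 2 * stats.norm.sf(np.abs(z))
    return EffectsDecomposition(
        names=list(fit.param_names[:k]),
        direct=direct, indirect=indirect, total=total,
        direct_se=se[0], indirect_se=se[1], total_se=se[2],
        direct_p=p[0], indirect_p=p[1], total_p=p[2],
        draws=draws, seed=seed,
    )
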