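"""Linear mixed model with random intercept and slope, fitted by REML.

Stage 1 of the two-stage risk model.  For domain score y_ij of subject i
at time t_ij (years since baseline),

    y_ij = x_ij' beta + b0_i + b1_i t_ij + e_ij,
    (b0_i, b1_i) ~ N(0, G),   e_ij ~ N(0, sigma2),

with fixed covariates x = (1, t, baseline_age, sex, education).  The
restricted likelihood is profiled over beta (GLS) and sigma2, leaving a
3-parameter optimisation over the log-Cholesky factor of the *relative*
random-effect covariance G / sigma2, as in lme4.  All per-evaluation work
uses per-subject sufficient statistics (Z'Z, Z'X, Z'y, X'X, X'y, y'y),
batched over subjects with 2x2 Woodbury identities, so a single objective
evaluation is O(n_subjects) small-matrix algebra regardless of visit
counts.  Integer subject weights (for nonparametric bootstrap resamples)
multiply each subject's contribution.

Empirical best linear unbiased predictors (EBLUPs) of the subject random
effects are

    b_hat_i = G Z_i' V_i^{-1} (y_i - X_i beta_hat),   V_i = Z_i G Z_i' + sigma2 I,

computed here via the equivalent factored form
Lambda (I + Lambda' Z'Z Lambda)^{-1} Lambda' Z' r with
Lambda Lambda' = G / sigma2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

logger = logging.getLogger("cogrisk")

__all__ = ["LmmSpec", "LmmFit", "SuffStats", "build_suffstats", "fit_lmm_reml",
           "compute_eblup", "eblups_all"]

FIXED_COVARIATES = ("baseline_age", "sex", "education")
FIXED_NAMES = ("intercept", "time") + FIXED_COVARIATES

_LOGL_BOUNDS = (-8.0, 4.0)
_OFFDIAG_BOUND = 50.0


@dataclass
class LmmSpec:
    """Model specification for one domain."""

    response: str
    time_col: str = "visit_year"
    covariates: tuple = FIXED_COVARIATES


@dataclass
class LmmFit:
    """REML fit for one domain.

    ``beta`` is ordered as (intercept, time, baseline_age, sex,
    education); entries for columns dropped as collinear (e.g. the time
    fixed effect at the baseline landmark, where every time is 0) are 0
    and listed in ``dropped_columns``.  ``G`` is the 2x2 random-effect
    covariance in z^2 / z^2-per-year units, ``sigma2`` the residual
    variance.
    """

    beta: np.ndarray
    beta_names: tuple
    G: np.ndarray
    sigma2: float
    reml_loglik: float
    converged: bool
    n_subjects: int
    n_obs: int
    slope_pinned: bool = False
    dropped_columns: tuple = ()
    theta: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))
    n_iter: int = 0

    def to_dict(self):
        return {
            "beta": self.beta.tolist(),
            "beta_names": list(self.beta_names),
            "G": self.G.tolist(),
            "sigma2": self.sigma2,
            "reml_loglik": self.reml_loglik,
            "converged": self.converged,
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
            "slope_pinned": self.slope_pinned,
            "dropped_columns": list(self.dropped_columns),
        }


@dataclass
class SuffStats:
    """Per-subject sufficient statistics for the profiled REML objective.

    ``Maug`` stacks Z'[X, y] per subject (response appended as the last
    column of the augmented design), ``Caug`` the corresponding [X, y]'
    [X, y] cross-products, and ``Paug[s, a, b]`` the outer products
    Maug[s, a] (x) Maug[s, b] precomputed so that one objective
    evaluation reduces to elementwise 2x2 algebra over subjects plus a
    single tensor contraction.
    """

    ids: np.ndarray          # (S,)
    n: np.ndarray            # (S,) visits per subject
    ZtZ: np.ndarray          # (S, 2, 2)
    Maug: np.ndarray         # (S, 2, p+1) = Z'[X, y]
    Caug: np.ndarray         # (S, p+1, p+1) = [X, y]'[X, y]
    Paug: np.ndarray         # (S, 2, 2, p+1, p+1)
    col_names: tuple
    kept: np.ndarray         # boolean mask of retained design columns
    has_slope_info: bool

    @property
    def ZtX(self):
        return self.Maug[:, :, :-1]

    @property
    def Zty(self):
        return self.Maug[:, :, -1]


def _design(df, spec):
    t = df[spec.time_col].to_numpy(dtype=float)
    cols = [np.ones_like(t), t]
    for c in spec.covariates:
        cols.append(df[c].to_numpy(dtype=float))
    X = np.column_stack(cols)
    Z = X[:, :2]
    y = df[spec.response].to_numpy(dtype=float)
    return X, Z, y, t


def build_suffstats(df, spec: LmmSpec) -> SuffStats:
    """Aggregate one domain's long data into per-subject cross-products.

    Rows with a missing response are ignored (the mixed model handles
    unbalanced, incomplete follow-up by construction).  Fixed-design
    columns with no variation across the retained rows — other than the
    intercept — are dropped and recorded.
    """
    df = df.loc[df[spec.response].notna()]
    if not np.isfinite(df[spec.response].to_numpy(dtype=float)).all():
        raise ValueError(f"non-finite values in response {spec.response!r}")
    if df["id"].nunique() < 2:
        raise ValueError("need at least 2 subjects to fit the mixed model")
    df = df.sort_values("id", kind="mergesort")
    X, Z, y, t = _design(df, spec)

    names = ("intercept", spec.time_col) + tuple(spec.covariates)
    spread = X.max(axis=0) - X.min(axis=0)
    kept = spread > 1e-12
    kept[0] = True
    dropped = tuple(n for n, k in zip(names, kept) if not k)
    if dropped:
        logger.debug("dropping constant fixed-effect columns: %s", dropped)
    Xk = X[:, kept]

    ids, starts = np.unique(df["id"].to_numpy(), return_index=True)
    order = np.argsort(starts)
    ids, starts = ids[order], np.sort(starts)
    bounds = np.r_[starts, len(df)]
    n = np.diff(bounds)

    def seg(prod):  # sum within subject blocks
        return np.add.reduceat(prod, starts, axis=0)

    Xa = np.column_stack([Xk, y])  # augmented design: response last
    ZtZ = seg(Z[:, :, None] * Z[:, None, :])
    Maug = seg(Z[:, :, None] * Xa[:, None, :])
    Caug = seg(Xa[:, :, None] * Xa[:, None, :])
    Paug = Maug[:, :, None, :, None] * Maug[:, None, :, None, :]

    # Slope variance is identified only if some subject has >= 2 visits at
    # distinct times.
    has_slope = bool(np.any((n >= 2) & (ZtZ[:, 1, 1] * n - seg(t) ** 2 > 1e-12)))
    return SuffStats(ids, n, ZtZ, Maug, Caug, Paug, names, kept, has_slope)


def _lambda(theta):
    L = np.zeros((2, 2))
    L[0, 0] = np.exp(theta[0])
    L[1, 0] = theta[1]
    L[1, 1] = np.exp(theta[2])
    return L


class _FitContext:
    """Weight-dependent, theta-independent precomputations for one fit."""

    def __init__(self, ss: SuffStats, w: np.ndarray):
        self.w = w
        self.K00 = ss.ZtZ[:, 0, 0]
        self.K01 = ss.ZtZ[:, 0, 1]
        self.K11 = ss.ZtZ[:, 1, 1]
        m = ss.Maug.shape[2]
        self.m = m
        self.P2 = ss.Paug.reshape(len(w) * 4, m * m)
        self.base = np.tensordot(w, ss.Caug, axes=1)   # (m, m)
        self.N = float(w @ ss.n)


def _woodbury_2x2(theta, ctx):
    """Entries of A = I + L'KL and B = L A^{-1} L' for every subject,
    expanded symbolically for the lower-triangular 2x2 L."""
    l0, l1, l2 = np.exp(theta[0]), theta[1], np.exp(theta[2])
    K00, K01, K11 = ctx.K00, ctx.K01, ctx.K11
    u = l0 * K00 + l1 * K01
    v = l0 * K01 + l1 * K11
    A00 = 1.0 + u * l0 + v * l1
    A01 = v * l2
    A11 = 1.0 + l2 * l2 * K11
    det = A00 * A11 - A01 * A01
    B00 = l0 * l0 * A11 / det
    B01 = l0 * (l1 * A11 - l2 * A01) / det
    B11 = (l1 * l1 * A11 - 2.0 * l1 * l2 * A01 + l2 * l2 * A00) / det
    return det, B00, B01, B11


def _profiled_pieces(theta, ss, w, ctx=None):
    """Weighted GLS pieces at relative covariance Lambda Lambda'.

    Returns (sum_logdetA, S_XX, S_Xy, S_yy, N): the augmented
    [X, y]' W^{-1} [X, y] sums with W_i^{-1} = I - Z_i B_i Z_i' by
    Woodbury, B_i = Lambda A_i^{-1} Lambda'.
    """
    if ctx is None:
        ctx = _FitContext(ss, w)
    det, B00, B01, B11 = _woodbury_2x2(theta, ctx)
    wB = np.empty((len(det), 4))
    wB[:, 0] = ctx.w * B00
    wB[:, 1] = wB[:, 2] = ctx.w * B01
    wB[:, 3] = ctx.w * B11
    corr = (wB.reshape(-1) @ ctx.P2).reshape(ctx.m, ctx.m)
    S = ctx.base - corr
    p = ctx.m - 1
    sum_logdet = float(ctx.w @ np.log(det))
    return sum_logdet, S[:p, :p], S[:p, p], float(S[p, p]), ctx.N


def _neg2_profiled_reml(theta, ss, w, ctx=None):
    sum_logdet, S_XX, S_Xy, S_yy, N = _profiled_pieces(theta, ss, w, ctx)
    p = S_XX.shape[0]
    sign, logdet_SXX = np.linalg.slogdet(S_XX)
    if sign <= 0:
        return 1e12
    beta = np.linalg.solve(S_XX, S_Xy)
    rss = max(S_yy - beta @ S_Xy, 1e-300)
    return sum_logdet + logdet_SXX + (N - p) * np.log(rss)


def _neg2_profiled_reml_with_grad(theta, ss, w, ctx):
    """Objective and its analytic gradient in theta.

    Uses d log|A| = 2 tr(A^{-1} L'K dL), dB = H + H' with
    H_j = (I - BK) E_j (L A^{-1})', and the envelope identity
    d rss = c' dS c at the GLS optimum, c = (-beta, 1).
    """
    l0, l1, l2 = np.exp(theta[0]), theta[1], np.exp(theta[2])
    K00, K01, K11 = ctx.K00, ctx.K01, ctx.K11
    u = l0 * K00 + l1 * K01          # (L'K)[0, :] entries
    v = l0 * K01 + l1 * K11
    A00 = 1.0 + u * l0 + v * l1
    A01 = v * l2
    A11 = 1.0 + l2 * l2 * K11
    det = A00 * A11 - A01 * A01
    Ai00, Ai01, Ai11 = A11 / det, -A01 / det, A00 / det
    B00 = l0 * l0 * Ai00
    B01 = l0 * (l1 * Ai00 + l2 * Ai01)
    B11 = l1 * l1 * Ai00 + 2.0 * l1 * l2 * Ai01 + l2 * l2 * Ai11

    S_count = len(det)
    wgt = ctx.w

    # Columns of C = L A^{-1} and of Mk = I - BK (for dB = H + H',
    # H_j = outer(Mk[:, r_j], C[:, c_j])).
    C00 = l0 * Ai00
    C10 = l1 * Ai00 + l2 * Ai01
    C01 = l0 * Ai01
    C11 = l1 * Ai01 + l2 * Ai11
    Mk00 = 1.0 - (B00 * K00 + B01 * K01)
    Mk10 = -(B01 * K00 + B11 * K01)
    Mk01 = -(B00 * K01 + B01 * K11)
    Mk11 = 1.0 - (B01 * K01 + B11 * K11)

    # Stack the four contraction weight vectors (B, dB_0, dB_1, dB_2)
    # into one matmul against the precomputed outer-product tensor.
    W4 = np.empty((4, 4, S_count))
    W4[0, 0] = wgt * B00
    W4[0, 1] = W4[0, 2] = wgt * B01
    W4[0, 3] = wgt * B11
    for j, (Mr0, Mr1, Cc0, Cc1) in enumerate(
            ((Mk00, Mk10, C00, C10), (Mk01, Mk11, C00, C10), (Mk01, Mk11, C01, C11)),
            start=1):
        W4[j, 0] = wgt * (2.0 * Mr0 * Cc0)
        W4[j, 1] = W4[j, 2] = wgt * (Mr0 * Cc1 + Mr1 * Cc0)
        W4[j, 3] = wgt * (2.0 * Mr1 * Cc1)
    contr = (W4.transpose(0, 2, 1).reshape(4, -1) @ ctx.P2).reshape(4, ctx.m, ctx.m)

    S = ctx.base - contr[0]
    p = ctx.m - 1
    S_XX, S_Xy, S_yy = S[:p, :p], S[:p, p], float(S[p, p])
    sign, logdet_SXX = np.linalg.slogdet(S_XX)
    if sign <= 0:
        return 1e12, np.zeros(3)
    S_XX_inv = np.linalg.inv(S_XX)
    beta = S_XX_inv @ S_Xy
    rss = max(S_yy - beta @ S_Xy, 1e-300)
    f = float(wgt @ np.log(det)) + logdet_SXX + (ctx.N - p) * np.log(rss)

    # T = A^{-1} L'K entries needed for d log|A| = 2 tr(A^{-1} L'K E_j).
    T00 = Ai00 * u + Ai01 * l2 * K01
    T01 = Ai00 * v + Ai01 * l2 * K11
    T11 = Ai01 * v + Ai11 * l2 * K11

    c = np.empty(ctx.m)
    c[:p] = -beta
    c[p] = 1.0
    grad = np.empty(3)
    tvals = (T00, T01, T11)
    for j in range(3):
        dS = -contr[j + 1]
        grad[j] = (2.0 * float(wgt @ tvals[j])
                   + float(np.sum(S_XX_inv * dS[:p, :p]))
                   + (ctx.N - p) * float(c @ dS @ c) / rss)
    grad *= np.array([l0, 1.0, l2])  # chain rule: theta0, theta2 are logs
    return f, grad


def fit_lmm_reml(data, spec=None, *, weights=None, theta0=None,
                 suffstats=None, gtol=1e-4, ftol=1e-11, maxiter=500) -> LmmFit:
    """Fit the random-intercept-and-slope model by profiled REML.

    Parameters
    ----------
    data : long DataFrame with columns id, the time column, the response
        and the fixed covariates.  Ignored when ``suffstats`` is given.
    spec : LmmSpec (required unless ``suffstats`` is given).
    weights : optional per-subject nonnegative weights aligned with the
        subject order of the sufficient statistics (bootstrap multiplicities);
        default all ones.
    theta0 : optional warm start for the 3 log-Cholesky parameters of
        G / sigma2.

    When no subject has two visits at distinct times the random-slope
    parameters are pinned at the boundary (G's slope row/column = 0) and
    ``slope_pinned`` is set.
    """
    ss = suffstats if suffstats is not None else build_suffstats(data, spec)
    S = len(ss.ids)
    w = np.ones(S) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (S,):
        raise ValueError("weights must have one entry per subject")
    active = w > 0
    if active.sum() < 2:
        raise ValueError("need at least 2 weighted subjects")

    pin_slope = not ss.has_slope_info
    if theta0 is None:
        theta0 = np.array([-0.35, 0.0, -2.3])  # lam00 ~ 0.7, lam11 ~ 0.1
    theta0 = np.clip(np.asarray(theta0, dtype=float),
                     [_LOGL_BOUNDS[0], -_OFFDIAG_BOUND, _LOGL_BOUNDS[0]],
                     [_LOGL_BOUNDS[1], _OFFDIAG_BOUND, _LOGL_BOUNDS[1]])

    ctx = _FitContext(ss, w)

    def _minimize(fun, x0, bounds):
        res = minimize(fun, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter, "gtol": gtol, "ftol": ftol})
        if not res.success:
            # Flat profiles (weakly identified slope variance) can abort the
            # quasi-Newton line search; polish with a derivative-free pass,
            # then give the quasi-Newton step one restart from the polished
            # point.  Tolerances are scaled to the objective (O(N)).
            res2 = minimize(lambda x: fun(x)[0], res.x, method="Nelder-Mead",
                            bounds=bounds,
                            options={"maxiter": 500, "fatol": 1e-7, "xatol": 1e-6})
            if res2.fun <= res.fun + 1e-12:
                res = res2
            if not res.success:
                res3 = minimize(fun, res.x, jac=True, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": maxiter, "gtol": gtol, "ftol": ftol})
                if res3.fun <= res.fun + 1e-12:
                    res = res3
        return res

    if pin_slope:
        fixed_tail = np.array([0.0, _LOGL_BOUNDS[0]])

        def fun1(th1):
            f, g = _neg2_profiled_reml_with_grad(np.r_[th1, fixed_tail], ss, w, ctx)
            return f, g[:1]

        res = _minimize(fun1, theta0[:1], [_LOGL_BOUNDS])
        theta = np.r_[res.x, fixed_tail]
    else:
        res = _minimize(
            lambda th: _neg2_profiled_reml_with_grad(th, ss, w, ctx),
            theta0,
            [_LOGL_BOUNDS, (-_OFFDIAG_BOUND, _OFFDIAG_BOUND), _LOGL_BOUNDS])
        theta = res.x

    # Scale-aware convergence: the optimizer's line search can abort at
    # float precision while the projected gradient is already negligible
    # relative to the objective (O(N) log-likelihood units).
    f_final, g_final = _neg2_profiled_reml_with_grad(theta, ss, w, ctx)
    lo = np.array([_LOGL_BOUNDS[0], -_OFFDIAG_BOUND, _LOGL_BOUNDS[0]])
    hi = np.array([_LOGL_BOUNDS[1], _OFFDIAG_BOUND, _LOGL_BOUNDS[1]])
    proj = np.where((theta <= lo + 1e-12) & (g_final > 0), 0.0, g_final)
    proj = np.where((theta >= hi - 1e-12) & (proj < 0), 0.0, proj)
    if pin_slope:
        proj = proj[:1]
    grad_ok = np.max(np.abs(proj)) < max(1e-6, 1e-6 * abs(f_final))

    sum_logdet, S_XX, S_Xy, S_yy, N = _profiled_pieces(theta, ss, w, ctx)
    p = S_XX.shape[0]
    beta_k = np.linalg.solve(S_XX, S_Xy)
    rss = max(S_yy - beta_k @ S_Xy, 0.0)
    sigma2 = rss / max(N - p, 1.0)
    L = _lambda(theta)
    G = sigma2 * (L @ L.T)
    if pin_slope:
        G[1, :] = 0.0
        G[:, 1] = 0.0

    beta = np.zeros(len(ss.col_names))
    beta[ss.kept] = beta_k
    dropped = tuple(n for n, k in zip(ss.col_names, ss.kept) if not k)

    sign, logdet_SXX = np.linalg.slogdet(S_XX)
    log_s2 = np.log(max(sigma2, 1e-300))
    loglik = -0.5 * (
        sum_logdet + logdet_SXX - p * log_s2
        + (N - p) * (np.log(2.0 * np.pi) + log_s2 + 1.0)
    )
    converged = (bool(res.success) or bool(grad_ok)) and np.isfinite(loglik)
    if not converged:
        logger.warning("REML optimiser did not converge for %s: %s",
                       getattr(spec, "response", "<suffstats>"), res.message)
    if pin_slope:
        warnings.warn(
            "no subject has two visits at distinct times; random-slope "
            "variance pinned at zero", stacklevel=2)
    return LmmFit(
        beta=beta, beta_names=ss.col_names, G=G, sigma2=float(sigma2),
        reml_loglik=float(loglik), converged=converged,
        n_subjects=int(active.sum()), n_obs=int(w @ ss.n),
        slope_pinned=pin_slope, dropped_columns=dropped,
        theta=theta, n_iter=int(res.nit),
    )


# ---------------------------------------------------------------------------
# EBLUPs
# ---------------------------------------------------------------------------

def eblups_all(fit: LmmFit, ss: SuffStats) -> np.ndarray:
    """Random-effect predictions for every subject in the sufficient
    statistics, as an (S, 2) array of (b0_hat, b1_hat).

    Unaffected by bootstrap weights: the EBLUP of a duplicated subject is
    identical for each copy.
    """
    if fit.sigma2 <= 1e-12:
        # Degenerate noise-free limit: fall back to the dense per-subject
        # formula with a small ridge.
        return np.array([
            _eblup_dense(fit, ss, i) for i in range(len(ss.ids))
        ])
    L = _chol_psd(fit.G / fit.sigma2)
    A = np.eye(2) + np.einsum("ab,sbc,cd->sad", L.T, ss.ZtZ, L)
    det = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] * A[:, 1, 0]
    inv = np.empty_like(A)
    inv[:, 0, 0], inv[:, 1, 1] = A[:, 1, 1], A[:, 0, 0]
    inv[:, 0, 1], inv[:, 1, 0] = -A[:, 0, 1], -A[:, 1, 0]
    inv /= det[:, None, None]
    Ztr = ss.Zty - np.einsum("sap,p->sa", ss.ZtX, fit.beta[ss.kept])
    return np.einsum("ab,sbc,cd,sd->sa", L, inv, L.T, Ztr)


def _chol_psd(M):
    """Factor a PSD 2x2 matrix as Lambda Lambda' (eigen square root, so
    singular G — e.g. a pinned slope — is handled)."""
    vals, vecs = np.linalg.eigh(M)
    return vecs @ np.diag(np.sqrt(np.maximum(vals, 0.0)))


def _eblup_dense(fit, ss, i):
    # Reconstruct Z'r-based dense solve from sufficient statistics is not
    # possible rowwise; this path only serves sigma2 ~ 0, where the
    # Woodbury factorisation is ill-posed.  Use V = Z G Z' + (sigma2 +
    # ridge) I assembled from cross-products via the identity
    # b = G (Z'Z G + (sigma2 + ridge) I)^{-1} Z'r.
    ridge = 1e-10
    Ztr = ss.Zty[i] - ss.ZtX[i] @ fit.beta[ss.kept]
    M = ss.ZtZ[i] @ fit.G + (fit.sigma2 + ridge) * np.eye(2)
    return fit.G @ np.linalg.solve(M, Ztr)


def compute_eblup(fit: LmmFit, subject_visits: pd.DataFrame, spec: LmmSpec):
    """EBLUP (b0_hat, b1_hat) for one subject's visits in one domain.

    Evaluates Lambda (I + Lambda' Z'Z Lambda)^{-1} Lambda' Z'(y - X beta)
    with Lambda Lambda' = G / sigma2, which equals the textbook
    G Z' V^{-1} (y - X beta).  A numerically singular system falls back to
    a dense solve with a 1e-10 ridge (logged).
    """
    df = subject_visits.loc[subject_visits[spec.response].notna()]
    if len(df) == 0:
        raise ValueError("subject has no non-missing visit for this domain")
    X, Z, y, _ = _design(df, spec)
    r = y - X @ fit.beta  # dropped-column betas are stored as 0
    if fit.sigma2 > 1e-12:
        L = _chol_psd(fit.G / fit.sigma2)
        A = np.eye(2) + L.T @ (Z.T @ Z) @ L
        try:
            b = L @ np.linalg.solve(A, L.T @ (Z.T @ r))
        except np.linalg.LinAlgError:
            b = None
        if b is not None:
            return b
    V = Z @ fit.G @ Z.T + fit.sigma2 * np.eye(len(y))
    try:
        sol = np.linalg.solve(V, r)
    except np.linalg.LinAlgError:
        logger.warning("singular marginal covariance in EBLUP; adding 1e-10 ridge")
        sol = np.linalg.solve(V + 1e-10 * np.eye(len(y)), r)
    return fit.G @ (Z.T @ sol)
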