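"""Two-stage dynamic risk model.

Stage 1 (``cogrisk.lmm``) summarises each subject's trajectory in every
cognitive domain as EBLUP random-intercept and random-slope estimates.
Stage 2 plugs those point estimates, together with baseline age, sex and
education, into a logistic regression for the binary lifetime-AD outcome,
fitted by maximum likelihood (Newton / iteratively reweighted least
squares).  Both stages are refit from scratch at every landmark year on
the data visible by that year, so the predicted risk of a subject updates
as assessments accrue.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.linalg import qr as scipy_qr
from scipy.special import expit

from .cohort import LandmarkDataset
from .lmm import LmmFit, LmmSpec, SuffStats, build_suffstats, eblups_all, fit_lmm_reml

logger = logging.getLogger("cogrisk")

__all__ = ["LogisticFit", "DynamicModelFit", "fit_logistic_mle",
           "predict_proba", "predict_risk", "fit_dynamic_model"]

SEPARATION_THRESHOLD = 30.0
DEMOGRAPHIC_COLS = ("baseline_age", "sex", "education")


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression fit.

    ``gamma`` is ordered as the supplied feature columns followed by the
    intercept (last).  Collinear columns are dropped (coefficient 0,
    recorded in ``dropped_columns``); ``cov`` is the inverse observed
    Fisher information on the retained columns, expanded with zero
    rows/columns for dropped ones.
    """

    gamma: np.ndarray
    names: tuple
    cov: np.ndarray
    loglik: float
    converged: bool
    n: int
    separation_flag: bool = False
    dropped_columns: tuple = ()

    def to_dict(self):
        return {
            "gamma": self.gamma.tolist(),
            "names": list(self.names),
            "loglik": self.loglik,
            "converged": self.converged,
            "n": self.n,
            "separation_flag": self.separation_flag,
            "dropped_columns": list(self.dropped_columns),
        }


def _independent_columns(X, tol=1e-8):
    """Indices of a maximal linearly independent column subset (pivoted QR)."""
    if X.shape[1] == 0:
        return np.array([], dtype=int)
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    _, R, piv = scipy_qr(X / scale, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > tol * diag[0])) if diag.size and diag[0] > 0 else 0
    return np.sort(piv[:rank])


def fit_logistic_mle(features, outcomes, *, names=None, weights=None,
                     tol=1e-8, maxiter=100) -> LogisticFit:
    """Fit P(y=1 | x) = logistic(gamma' [x, 1]) by Newton's method.

    Iterates until the log-likelihood gradient has max-norm below
    ``tol`` or the log-likelihood itself stops changing (relative change
    below 1e-10 over a full Newton step) — the latter is the standard
    IRLS plateau criterion and is what terminates (quasi-)separated
    problems, where the MLE lies at infinity but the fitted
    probabilities have converged.  Quasi-separation is flagged when any
    coefficient exceeds 30 in absolute value; the fit is still returned.
    An intercept column is appended last.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(outcomes, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and outcomes have different lengths")
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if (w * y).sum() == 0 or (w * (1 - y)).sum() == 0:
        raise ValueError("both outcome classes must be present")

    if names is None:
        names = tuple(f"x{j}" for j in range(X.shape[1]))
    names = tuple(names) + ("intercept",)
    Xi = np.column_stack([X, np.ones(len(y))])

    keep = _independent_columns(Xi * np.sqrt(w)[:, None])
    dropped = tuple(names[j] for j in range(Xi.shape[1]) if j not in keep)
    Xk = Xi[:, keep]

    beta = np.zeros(Xk.shape[1])
    converged = False
    for _ in range(maxiter):
        eta = Xk @ beta
        p = expit(eta)
        grad = Xk.T @ (w * (y - p))
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        W = w * p * (1.0 - p)
        H = Xk.T @ (Xk * W[:, None])
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(len(beta)), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # Step-halving on the weighted log-likelihood.
        ll_old = _bernoulli_loglik(eta, y, w)
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _bernoulli_loglik(Xk @ cand, y, w)
            if ll_new >= ll_old - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if scale == 1.0 and ll_new - ll_old < 1e-10 * (abs(ll_new) + 1.0):
            converged = True
            break

    eta = Xk @ beta
    ll = _bernoulli_loglik(eta, y, w)
    p = expit(eta)
    W = w * p * (1.0 - p)
    H = Xk.T @ (Xk * W[:, None])
    try:
        cov_k = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_k = np.linalg.pinv(H)

    separation = bool(np.max(np.abs(beta)) > SEPARATION_THRESHOLD)
    if separation:
        logger.warning("possible quasi-separation: max |gamma| = %.1f", np.max(np.abs(beta)))
    if not converged:
        logger.warning("logistic Newton did not reach gradient tolerance %.1e", tol)

    gamma = np.zeros(Xi.shape[1])
    gamma[keep] = beta
    cov = np.zeros((Xi.shape[1], Xi.shape[1]))
    cov[np.ix_(keep, keep)] = cov_k
    return LogisticFit(gamma=gamma, names=names, cov=cov, loglik=float(ll),
                       converged=converged, n=int(len(y)),
                       separation_flag=separation, dropped_columns=dropped)


def _bernoulli_loglik(eta, y, w):
    # log(1 + e^eta) computed stably.
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def predict_proba(fit: LogisticFit, features) -> np.ndarray:
    """logistic(gamma' [x, 1]) for a feature matrix in fit column order."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    eta = np.column_stack([X, np.ones(X.shape[0])]) @ fit.gamma
    return expit(eta)


# ---------------------------------------------------------------------------
# Pipeline composition
# ---------------------------------------------------------------------------

@dataclass
class DynamicModelFit:
    """One landmark model: stage-1 fits per domain, stage-2 logistic fit,
    and per-subject predicted risks."""

    landmark_year: float | None
    domains: tuple
    lmm_fits: dict
    logistic_fit: LogisticFit
    features: pd.DataFrame          # EBLUPs + demographics per included subject
    risks: pd.Series                # predicted P(AD) indexed by subject id
    y: pd.Series                    # outcome indexed by subject id
    tally: dict = dc_field(default_factory=dict)

    @property
    def valid(self) -> bool:
        return (self.logistic_fit.converged
                and all(f.converged for f in self.lmm_fits.values()))

    def to_dict(self):
        return {
            "landmark_year": self.landmark_year,
            "domains": list(self.domains),
            "stage1": {str(d): f.to_dict() for d, f in self.lmm_fits.items()},
            "stage2": self.logistic_fit.to_dict(),
            "n": int(len(self.y)),
            "tally": self.tally,
            "valid": self.valid,
        }

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2,
                      default=lambda o: o.item() if hasattr(o, "item") else str(o))


def _feature_names(domains):
    names = []
    for d in domains:
        names += [f"domain_{d}_b0", f"domain_{d}_b1"]
    return tuple(names) + DEMOGRAPHIC_COLS


def fit_dynamic_model(landmark: LandmarkDataset, domains=None, *,
                      weights=None, impute_missing_zero=False,
                      _cache=None, theta0=None, gtol=1e-4) -> DynamicModelFit:
    """Fit the full two-stage model on one landmark dataset.

    Parameters
    ----------
    landmark : dataset from the cohort builder (subjects carry ``y``).
    domains : iterable of 1-based domain indices; default: every
        ``domain_<d>`` column present in the visit table.
    weights : optional integer multiplicities per subject (aligned with
        ``landmark.subjects`` row order) realising a nonparametric
        bootstrap resample in which duplicated subjects count as distinct.
    impute_missing_zero : include subjects missing a whole domain by
        setting that domain's EBLUPs to 0 (population mean) instead of
        dropping them.

    Subjects without any usable visit in some modelled domain are dropped
    from stage 2 (tallied) unless ``impute_missing_zero``.
    """
    visits, subjects = landmark.visits, landmark.subjects
    if domains is None:
        domains = tuple(
            int(c.split("_")[1]) for c in visits.columns if c.startswith("domain_")
        )
    domains = tuple(domains)
    if len(domains) == 0:
        raise ValueError("domain subset must be non-empty")

    long = visits.merge(subjects[["id", "baseline_age", "sex", "education"]],
                        on="id", validate="many_to_one")

    sub_index = pd.Index(subjects["id"])
    eff = {}
    lmm_fits = {}
    for d in domains:
        col = f"domain_{d}"
        if col not in visits.columns:
            raise KeyError(f"visit table has no column {col!r}")
        spec = LmmSpec(response=col)
        if _cache is not None and col in _cache:
            ss = _cache[col]
        else:
            ss = build_suffstats(long, spec)
            if _cache is not None:
                _cache[col] = ss
        w_d = None
        if weights is not None:
            w_map = pd.Series(np.asarray(weights, dtype=float), index=sub_index)
            w_d = w_map.reindex(ss.ids).fillna(0.0).to_numpy()
        fit = fit_lmm_reml(None, spec, suffstats=ss, weights=w_d,
                           theta0=theta0.get(d) if isinstance(theta0, dict) else theta0,
                           gtol=gtol)
        lmm_fits[d] = fit
        b = eblups_all(fit, ss)
        eff[d] = pd.DataFrame(
            {f"domain_{d}_b0": b[:, 0], f"domain_{d}_b1": b[:, 1]}, index=ss.ids
        )

    feat = subjects.set_index("id")[list(DEMOGRAPHIC_COLS) + ["y"]]
    for d in domains:
        feat = feat.join(eff[d], how="left")
    cols = list(_feature_names(domains))
    if impute_missing_zero:
        feat[cols[:-3]] = feat[cols[:-3]].fillna(0.0)
    complete = feat[cols].notna().all(axis=1)
    tally = dict(landmark.tally)
    tally["missing_domain_dropped"] = int((~complete).sum())
    feat = feat.loc[complete]

    w2 = None
    if weights is not None:
        w_map = pd.Series(np.asarray(weights, dtype=float), index=sub_index)
        w2 = w_map.reindex(feat.index).to_numpy()
        in_resample = w2 > 0
    else:
        in_resample = np.ones(len(feat), dtype=bool)

    fit2 = fit_logistic_mle(
        feat.loc[in_resample, cols].to_numpy(),
        feat.loc[in_resample, "y"].to_numpy(),
        names=cols,
        weights=w2[in_resample] if w2 is not None else None,
    )
    risks = pd.Series(predict_proba(fit2, feat[cols].to_numpy()),
                      index=feat.index, name="risk")
    return DynamicModelFit(
        landmark_year=landmark.landmark_year, domains=domains,
        lmm_fits=lmm_fits, logistic_fit=fit2,
        features=feat[cols], risks=risks, y=feat["y"].astype(int),
        tally=tally,
    )


def predict_risk(model: DynamicModelFit, subjects, visits,
                 spec_time_col="visit_year") -> pd.Series:
    """Predicted AD risk for (possibly new) subjects given their visits.

    Computes the EBLUPs for each subject under the frozen stage-1 fits
    and applies the stage-2 model; subjects missing a modelled domain or
    a demographic covariate raise an error.
    """
    from .lmm import compute_eblup

    for c in DEMOGRAPHIC_COLS:
        if subjects[c].isna().any():
            raise ValueError(f"missing demographic covariate {c!r}")
    long = visits.merge(subjects[["id", "baseline_age", "sex", "education"]],
                        on="id", validate="many_to_one")
    rows = {}
    for sid, g in long.groupby("id", sort=False):
        row = {}
        for d in model.domains:
            spec = LmmSpec(response=f"domain_{d}", time_col=spec_time_col)
            b = compute_eblup(model.lmm_fits[d], g, spec)
            row[f"domain_{d}_b0"], row[f"domain_{d}_b1"] = b
        rows[sid] = row
    feat = pd.DataFrame.from_dict(rows, orient="index").join(
        subjects.set_index("id")[list(DEMOGRAPHIC_COLS)]
    )
    cols = list(_feature_names(model.domains))
    return pd.Series(predict_proba(model.logistic_fit, feat[cols].to_numpy()),
                     index=feat.index, name="risk")
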