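"""Discrimination, calibration and model-selection machinery.

* AUC(t): the Mann-Whitney estimate of the probability that a random
  incident-AD case receives a higher landmark-t risk score than a random
  cognitively intact subject (ties count 1/2).
* Bootstrap internal validation: subjects are resampled with replacement
  (all their visits travel with them), the entire two-stage pipeline is
  refit on each resample, and a 2.5/97.5 percentile interval summarises
  the B replicate AUCs (B = 1000 by default).
* DeLong's test compares two correlated AUCs computed on the same
  subjects via placement values.
* Calibration: Brier score plus decile calibration (mean predicted risk
  vs observed event rate per risk decile).
* AUC-based forward stepwise selection over cognitive domains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

from .cohort import LandmarkDataset, build_landmark_dataset
from .twostage import fit_dynamic_model, fit_logistic_mle, predict_proba

logger = logging.getLogger("cogrisk")

__all__ = ["DynamicAucResult", "CalibrationResult", "compute_auc",
           "bootstrap_auc_ci", "delong_test", "brier_score",
           "calibration_deciles", "stepwise_domain_selection", "auc_by_year"]

DEFAULT_BOOTSTRAP = 1000


@dataclass
class DynamicAucResult:
    landmark_year: float | None
    auc: float
    ci_low: float
    ci_high: float
    n_bootstrap: int
    n_cases: int
    n_controls: int
    n_redrawn: int = 0
    valid: bool = True
    brier: float | None = None
    bootstrap_sd: float | None = None

    def as_row(self) -> dict:
        return {
            "landmark_year": self.landmark_year, "auc": self.auc,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "n_bootstrap": self.n_bootstrap, "n_cases": self.n_cases,
            "n_controls": self.n_controls, "n_redrawn": self.n_redrawn,
            "valid": self.valid, "brier": self.brier,
            "bootstrap_sd": self.bootstrap_sd,
        }


@dataclass
class CalibrationResult:
    bin_edges: np.ndarray
    mean_predicted: np.ndarray
    observed_rate: np.ndarray
    counts: np.ndarray
    brier: float
    n_bins: int = 10
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin": np.arange(1, len(self.counts) + 1),
            "mean_predicted": self.mean_predicted,
            "observed_rate": self.observed_rate,
            "count": self.counts,
        })


# ---------------------------------------------------------------------------
# Core metrics
# ---------------------------------------------------------------------------

def compute_auc(scores, labels) -> float:
    """Mann-Whitney AUC with ties counted 1/2: the probability that a
    uniformly chosen case outscores a uniformly chosen control."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = sps.rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def brier_score(probs, outcomes) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


def _placements(scores, y):
    """DeLong placement values via midranks: V10 (per case) and V01
    (per control)."""
    s = np.asarray(scores, dtype=float)
    cases, controls = s[y == 1], s[y == 0]
    m, n = len(cases), len(controls)
    all_r = sps.rankdata(np.r_[cases, controls])
    case_r = sps.rankdata(cases)
    ctrl_r = sps.rankdata(controls)
    v10 = (all_r[:m] - case_r) / n
    v01 = 1.0 - (all_r[m:] - ctrl_r) / m
    return v10, v01


def delong_test(scores_a, scores_b, labels):
    """DeLong's test for two correlated AUCs on the same subjects.

    Returns (auc_a, auc_b, z, p) with a two-sided normal p-value.  A zero
    variance estimate (e.g. identical score vectors) yields z = 0, p = 1
    with a logged warning.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("scores_a, scores_b and labels must have equal length")
    auc_a = compute_auc(a, y)
    auc_b = compute_auc(b, y)
    v10a, v01a = _placements(a, y)
    v10b, v01b = _placements(b, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        logger.warning("DeLong variance estimate is zero; reporting p = 1")
        return auc_a, auc_b, 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return auc_a, auc_b, float(z), float(p)


def calibration_deciles(probs, outcomes) -> CalibrationResult:
    """Decile calibration: subjects are cut into ten equal-count risk bins
    (quantile edges, ties resolved toward the lower bin); each bin
    reports its mean predicted probability and observed event rate.
    Fewer than 10 distinct predictions fall back to distinct-value bins
    with a warning."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if len(p) < 10:
        raise ValueError("need at least 10 subjects for decile calibration")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")

    distinct = np.unique(p)
    degenerate = distinct.size < 10
    if degenerate:
        logger.warning("only %d distinct predictions; using distinct-value bins",
                       distinct.size)
        edges = np.r_[-np.inf, (distinct[:-1] + distinct[1:]) / 2.0, np.inf]
    else:
        q = np.quantile(p, np.linspace(0, 1, 11))
        edges = np.r_[-np.inf, np.unique(q[1:-1]), np.inf]
    # np.digitize(right=True): a value on an edge joins the lower bin.
    idx = np.digitize(p, edges[1:-1], right=True)
    k = edges.size - 1
    counts = np.bincount(idx, minlength=k)
    mean_pred = np.array([p[idx == j].mean() if counts[j] else np.nan for j in range(k)])
    obs = np.array([y[idx == j].mean() if counts[j] else np.nan for j in range(k)])
    keep = counts > 0
    return CalibrationResult(
        bin_edges=edges, mean_predicted=mean_pred[keep],
        observed_rate=obs[keep], counts=counts[keep],
        brier=brier_score(p, y), n_bins=int(keep.sum()), degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Bootstrap internal validation
# ---------------------------------------------------------------------------

class _BootstrapEngine:
    """Pre-aligned pipeline refitter for bootstrap resamples.

    Builds the per-domain sufficient statistics and all index maps once,
    so that each resample costs only the warm-started REML fits, the
    EBLUP evaluations, one weighted logistic fit and one weighted AUC —
    the same computation as :func:`cogrisk.fit_dynamic_model` with
    integer subject weights, without per-iteration table alignment.
    """

    def __init__(self, landmark, domains, point_model):
        from .lmm import build_suffstats, LmmSpec

        subjects, visits = landmark.subjects, landmark.visits
        self.domains = point_model.domains if domains is None else tuple(domains)
        long = visits.merge(
            subjects[["id", "baseline_age", "sex", "education"]],
            on="id", validate="many_to_one")
        sub_ids = pd.Index(subjects["id"])
        self.S = len(sub_ids)
        self.y = subjects["y"].to_numpy()
        self.Xdem = subjects[["baseline_age", "sex", "education"]].to_numpy(float)
        self.ss = {}
        self.pos = {}
        self.warm = {d: f.theta for d, f in point_model.lmm_fits.items()}
        complete = np.ones(self.S, dtype=bool)
        for d in self.domains:
            ss = build_suffstats(long, LmmSpec(response=f"domain_{d}"))
            self.ss[d] = ss
            pos = sub_ids.get_indexer(ss.ids)
            if (pos < 0).any():
                raise ValueError("visit table contains unknown subject ids")
            self.pos[d] = pos
            present = np.zeros(self.S, dtype=bool)
            present[pos] = True
            complete &= present
        self.complete = complete
        self.F = np.zeros((self.S, 2 * len(self.domains) + 3))
        self.F[:, -3:] = self.Xdem
        # Stage-2 warm start: reuse the point fit's column pruning and
        # coefficients (a resample that introduces new collinearity is
        # caught by the solve fallback below).
        pf = point_model.logistic_fit
        self.keep2 = np.array([j for j, nm in enumerate(pf.names)
                               if nm not in pf.dropped_columns])
        self.gamma0 = pf.gamma[self.keep2]

    def _newton(self, Xk, y, w, beta0, tol=1e-8, maxiter=40):
        from .twostage import _bernoulli_loglik

        beta = beta0.copy()
        ll = _bernoulli_loglik(Xk @ beta, y, w)
        for _ in range(maxiter):
            eta = Xk @ beta
            p = expit(eta)
            grad = Xk.T @ (w * (y - p))
            if np.max(np.abs(grad)) < tol:
                return beta, True
            H = Xk.T @ (Xk * (w * p * (1.0 - p))[:, None])
            try:
                step = np.linalg.solve(H + 1e-12 * np.eye(len(beta)), grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            scale = 1.0
            for _ in range(25):
                cand_ll = _bernoulli_loglik(Xk @ (beta + scale * step), y, w)
                if cand_ll >= ll - 1e-12:
                    break
                scale *= 0.5
            beta = beta + scale * step
            # IRLS plateau: a full undamped step that leaves the
            # log-likelihood unchanged means the fitted probabilities have
            # converged (the MLE may sit at infinity under separation).
            if scale == 1.0 and cand_ll - ll < 1e-10 * (abs(cand_ll) + 1.0):
                return beta, True
            ll = cand_ll
        return beta, False

    def replicate_auc(self, counts, gtol=5.0, ftol=1e-9):
        """Refit both stages under the given subject multiplicities and
        return the resample AUC (None if the resample is single-class)."""
        from .lmm import fit_lmm_reml, eblups_all

        for k, d in enumerate(self.domains):
            w_d = counts[self.pos[d]].astype(float)
            fit = fit_lmm_reml(None, None, suffstats=self.ss[d],
                               weights=w_d, theta0=self.warm[d], gtol=gtol, ftol=ftol)
            if not fit.converged:
                raise ValueError(f"stage-1 fit failed for domain {d}")
            self.F[self.pos[d], 2 * k:2 * k + 2] = eblups_all(fit, self.ss[d])
        use = self.complete & (counts > 0)
        y_u, w_u = self.y[use], counts[use].astype(float)
        if (w_u * y_u).sum() == 0 or (w_u * (1 - y_u)).sum() == 0:
            return None
        Xi = np.column_stack([self.F[use], np.ones(int(use.sum()))])
        beta, ok = self._newton(Xi[:, self.keep2], y_u, w_u, self.gamma0)
        if not ok:
            # The warm start can be hostile when the point fit sits in a
            # (quasi-)separated region; retry from zero before giving up.
            beta, ok = self._newton(Xi[:, self.keep2], y_u, w_u,
                                    np.zeros_like(self.gamma0))
        if not ok:
            raise ValueError("stage-2 fit failed")
        scores = expit(Xi[:, self.keep2] @ beta)
        return compute_auc(np.repeat(scores, counts[use]), np.repeat(y_u, counts[use]))


def _weighted_auc_from_model(model, weights_map):
    w = weights_map.reindex(model.risks.index).fillna(0.0).to_numpy().astype(int)
    s = np.repeat(model.risks.to_numpy(), w)
    y = np.repeat(model.y.to_numpy(), w)
    if y.sum() == 0 or (1 - y).sum() == 0:
        return None
    return compute_auc(s, y)


def bootstrap_auc_ci(landmark: LandmarkDataset, domains=None, *,
                     B=DEFAULT_BOOTSTRAP, rng=None, refit=True,
                     max_redraw_frac=0.20, gtol_boot=5.0, ftol_boot=1e-9,
                     point_model=None) -> DynamicAucResult:
    """AUC with a percentile bootstrap confidence interval.

    Each iteration resamples subjects with replacement (their full visit
    histories travel with them) and — in the default ``refit`` mode —
    refits both stages on the resample before scoring it.  Iterations
    whose resample contains a single outcome class or fails to fit are
    redrawn; more than ``max_redraw_frac`` x B redraws aborts.  With
    ``refit=False`` the original model's risk scores are merely
    re-evaluated on each resample (fast approximate mode).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(rng)
    model = point_model if point_model is not None else fit_dynamic_model(landmark, domains)
    auc = compute_auc(model.risks.to_numpy(), model.y.to_numpy())
    bri = brier_score(model.risks.to_numpy(), model.y.to_numpy())

    subjects = landmark.subjects
    S = len(subjects)
    sub_index = pd.Index(subjects["id"])
    engine = _BootstrapEngine(landmark, domains, model) if refit else None

    reps = np.empty(B)
    redrawn = 0
    max_redraws = int(np.ceil(max_redraw_frac * B))
    i = 0
    while i < B:
        counts = rng.multinomial(S, np.full(S, 1.0 / S))
        try:
            if refit:
                rep = engine.replicate_auc(counts, gtol=gtol_boot, ftol=ftol_boot)
            else:
                wmap = pd.Series(counts.astype(float), index=sub_index)
                rep = _weighted_auc_from_model(model, wmap)
        except (ValueError, np.linalg.LinAlgError) as err:
            logger.debug("bootstrap iteration failed (%s); redrawing", err)
            rep = None
        if rep is None:
            redrawn += 1
            if redrawn > max_redraws:
                raise ValueError(
                    f"more than {max_redraw_frac:.0%} of bootstrap resamples "
                    "were degenerate; the dataset is too small or imbalanced")
            continue
        reps[i] = rep
        i += 1

    # Bias-corrected percentile interval (BCa with acceleration 0).  Refit
    # replicates evaluated on their own resample carry the apparent-AUC
    # optimism a second time, shifting the replicate distribution upward;
    # the median-bias correction z0 recentres the percentile endpoints.
    z0 = sps.norm.ppf(np.clip(np.mean(reps < auc), 1.0 / (2 * B), 1 - 1.0 / (2 * B)))
    alphas = sps.norm.cdf(2.0 * z0 + sps.norm.ppf([0.025, 0.975]))
    lo, hi = np.quantile(reps, alphas)
    if not (lo <= auc <= hi):
        logger.warning("point AUC %.3f outside bootstrap CI (%.3f, %.3f) "
                       "(Monte-Carlo wobble)", auc, lo, hi)
    return DynamicAucResult(
        landmark_year=landmark.landmark_year, auc=auc,
        ci_low=float(lo), ci_high=float(hi), n_bootstrap=B,
        n_cases=int(model.y.sum()), n_controls=int((1 - model.y).sum()),
        n_redrawn=redrawn, valid=model.valid, brier=bri,
        bootstrap_sd=float(np.std(reps, ddof=1)),
    )


# ---------------------------------------------------------------------------
# Annual landmark table and stepwise selection
# ---------------------------------------------------------------------------

def auc_by_year(subjects, visits, domains=None, years=range(11), *,
                B=DEFAULT_BOOTSTRAP, rng=None, refit=True, variant="lifetime",
                subsample_k=None):
    """AUC(t) for each landmark year with bootstrap CIs.

    Returns (DataFrame shaped like the annual-update table — one row per
    landmark year — and the list of fitted landmark models).  Invalid
    landmarks are marked in the ``valid`` column; the table is still
    emitted.
    """
    from .cohort import subsample_visits

    rng = np.random.default_rng(rng)
    rows, models = [], []
    for t in years:
        lm = build_landmark_dataset(subjects, visits, t, variant=variant)
        if subsample_k is not None:
            lm.visits = subsample_visits(lm.visits, subsample_k, rng)
        try:
            model = fit_dynamic_model(lm, domains)
            res = bootstrap_auc_ci(lm, domains, B=B, rng=rng, refit=refit,
                                   point_model=model)
        except (ValueError, np.linalg.LinAlgError) as err:
            logger.warning("landmark year %s invalid: %s", t, err)
            res = DynamicAucResult(float(t), np.nan, np.nan, np.nan, B,
                                   0, 0, valid=False)
            model = None
        rows.append(res.as_row())
        models.append(model)
    return pd.DataFrame(rows), models


def stepwise_domain_selection(subjects, visits, candidates=(1, 2, 3, 4, 5), *,
                              t_star=10, improvement_threshold=0.001,
                              B=0, rng=None):
    """Forward stepwise selection of cognitive domains by landmark-t* AUC.

    Starts from the single best domain, greedily adds the domain with the
    largest AUC gain, and stops when the best improvement falls below the
    threshold (default 0.001) or all candidates are included.  With B > 0
    a bootstrap CI is attached to each selected step.  Fit failures abort
    the search and return the partial path.
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate domains")
    rng = np.random.default_rng(rng)
    lm = build_landmark_dataset(subjects, visits, t_star, variant="stepwise")

    def apparent_auc(domains):
        m = fit_dynamic_model(lm, domains)
        return compute_auc(m.risks.to_numpy(), m.y.to_numpy())

    selected: list[int] = []
    path = []
    best_auc = -np.inf
    try:
        while candidates:
            scores = {d: apparent_auc(selected + [d]) for d in candidates}
            d_best = max(scores, key=scores.get)
            gain = scores[d_best] - (best_auc if selected else -np.inf)
            if selected and gain < improvement_threshold:
                break
            selected.append(d_best)
            candidates.remove(d_best)
            best_auc = scores[d_best]
            step = {"step": len(selected), "added_domain": d_best,
                    "domains": tuple(selected), "auc": best_auc}
            if B > 0:
                res = bootstrap_auc_ci(lm, tuple(selected), B=B, rng=rng)
                step["ci_low"], step["ci_high"] = res.ci_low, res.ci_high
            path.append(step)
    except (ValueError, np.linalg.LinAlgError) as err:
        logger.warning("stepwise selection aborted: %s; returning partial path", err)
    return pd.DataFrame(path)
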