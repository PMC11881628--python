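"""Stage-1 REML mixed model and EBLUPs."""

import numpy as np
import pandas as pd
import pytest

import cogrisk
from cogrisk.lmm import (LmmFit, LmmSpec, _FitContext, _neg2_profiled_reml,
                         build_suffstats, compute_eblup, eblups_all, fit_lmm_reml)

SPEC = LmmSpec(response="y")


def _simulate(beta, G, sigma2, n_subjects, n_visits, seed, age_sd=7.5):
    """Long data from the exact stage-1 model (age covariate centred, so
    the intercept is not entangled with the age coefficient)."""
    rng = np.random.default_rng(seed)
    age = rng.normal(0.0, age_sd, n_subjects)
    sex = (rng.random(n_subjects) < 0.5).astype(float)
    edu = rng.integers(0, 4, n_subjects).astype(float)
    b = rng.multivariate_normal(np.zeros(2), G, size=n_subjects)
    rows = []
    for i in range(n_subjects):
        t = np.arange(n_visits, dtype=float)
        mu = (beta[0] + beta[1] * t + beta[2] * age[i] + beta[3] * sex[i]
              + beta[4] * edu[i] + b[i, 0] + b[i, 1] * t)
        y = mu + rng.normal(0, np.sqrt(sigma2), n_visits)
        rows.append(pd.DataFrame({
            "id": f"s{i:04d}", "visit_year": t, "y": y,
            "baseline_age": age[i], "sex": sex[i], "education": edu[i]}))
    return pd.concat(rows, ignore_index=True), b


def test_reml_parameter_recovery():
    """Single-seed recovery at n=1000 x 8: within-subject parameters tightly,
    between-subject coefficients within ~3 standard errors (their sampling
    SD at this n is ~0.03 for a binary covariate, set by the random-intercept
    variance, not by estimator quality)."""
    beta = np.array([0.2, -0.05, -0.01, 0.1, 0.05])
    G = np.array([[0.25, 0.0], [0.0, 0.01]])
    df, _ = _simulate(beta, G, 0.09, 1000, 8, seed=1)
    fit = fit_lmm_reml(df, SPEC)
    assert fit.converged
    assert fit.beta[1] == pytest.approx(beta[1], rel=0.10)      # time slope
    assert fit.beta[0] == pytest.approx(beta[0], abs=0.06)
    assert fit.beta[2] == pytest.approx(beta[2], abs=0.008)
    assert fit.beta[3] == pytest.approx(beta[3], abs=0.10)
    assert fit.beta[4] == pytest.approx(beta[4], abs=0.05)
    assert abs(fit.G[0, 0] - 0.25) / 0.25 < 0.20
    assert abs(fit.G[1, 1] - 0.01) / 0.01 < 0.20
    assert abs(fit.sigma2 - 0.09) / 0.09 < 0.20


def test_noise_free_limit_recovers_ols():
    """sigma2 = 0 and G = 0: the fit collapses to the OLS solution with the
    residual variance at the boundary."""
    beta = np.array([0.2, -0.05, -0.01, 0.1, 0.05])
    df, _ = _simulate(beta, np.zeros((2, 2)), 0.0, 80, 5, seed=2)
    fit = fit_lmm_reml(df, SPEC)
    assert fit.sigma2 <= 1e-6
    X = np.column_stack([np.ones(len(df)), df["visit_year"], df["baseline_age"],
                         df["sex"], df["education"]])
    ols = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)[0]
    np.testing.assert_allclose(fit.beta, ols, atol=1e-6)


def test_balanced_intercept_only_matches_anova_closed_form():
    """With the slope column zeroed (all visits at time 0) and balanced
    groups, REML variance components equal the one-way ANOVA estimators
    sigma2 = MSE, tau2 = (MSB - MSE) / k."""
    rng = np.random.default_rng(3)
    n, k = 60, 5
    b = rng.normal(0, np.sqrt(0.4), n)
    rows = []
    for i in range(n):
        y = 1.5 + b[i] + rng.normal(0, 0.6, k)
        rows.append(pd.DataFrame({"id": f"s{i}", "visit_year": 0.0, "y": y,
                                  "baseline_age": 0.0, "sex": 0.0, "education": 0.0}))
    df = pd.concat(rows, ignore_index=True)
    with pytest.warns(UserWarning, match="slope"):
        fit = fit_lmm_reml(df, SPEC)
    ybar_i = df.groupby("id")["y"].mean().to_numpy()
    ybar = df["y"].mean()
    msb = k * np.sum((ybar_i - ybar) ** 2) / (n - 1)
    mse = float(((df["y"] - df.groupby("id")["y"].transform("mean")) ** 2).sum() / (n * (k - 1)))
    assert fit.slope_pinned
    assert fit.G[1, 1] == 0.0
    assert fit.sigma2 == pytest.approx(mse, rel=1e-4)
    assert fit.G[0, 0] == pytest.approx((msb - mse) / k, rel=1e-3)
    assert fit.beta[0] == pytest.approx(ybar, abs=1e-8)


def test_reml_objective_not_worse_than_start():
    df, _ = _simulate(np.array([0.2, -0.05, -0.01, 0.1, 0.05]),
                      np.array([[0.3, 0.02], [0.02, 0.005]]), 0.05, 200, 6, seed=4)
    ss = build_suffstats(df, SPEC)
    w = np.ones(len(ss.ids))
    ctx = _FitContext(ss, w)
    theta0 = np.array([-0.35, 0.0, -2.3])
    fit = fit_lmm_reml(None, SPEC, suffstats=ss, theta0=theta0)
    assert (_neg2_profiled_reml(fit.theta, ss, w, ctx)
            <= _neg2_profiled_reml(theta0, ss, w, ctx) + 1e-9)


def test_fit_invariant_to_row_order_and_relabeling():
    df, _ = _simulate(np.array([0.2, -0.05, -0.01, 0.1, 0.05]),
                      np.diag([0.25, 0.01]), 0.09, 150, 6, seed=5)
    fit1 = fit_lmm_reml(df, SPEC)
    shuffled = df.sample(frac=1.0, random_state=0)
    shuffled["id"] = "zz" + shuffled["id"].str[1:]
    fit2 = fit_lmm_reml(shuffled, SPEC)
    np.testing.assert_allclose(fit1.beta, fit2.beta, atol=1e-8)
    np.testing.assert_allclose(fit1.G, fit2.G, atol=1e-8)


def test_non_finite_response_rejected():
    df, _ = _simulate(np.zeros(5), np.diag([0.1, 0.01]), 0.1, 10, 3, seed=6)
    df.loc[3, "y"] = np.inf
    with pytest.raises(ValueError, match="non-finite"):
        fit_lmm_reml(df, SPEC)


def test_cross_check_against_statsmodels_mixedlm():
    """Independent reference: statsmodels MixedLM (REML) on 50 random
    small datasets; fixed effects within 1e-4, variance components within
    1e-3."""
    sm = pytest.importorskip("statsmodels.api")
    import warnings

    def sm_theta(G, s2):
        L = np.linalg.cholesky(G / s2 + 1e-12 * np.eye(2))
        return np.array([np.log(L[0, 0]), L[1, 0], np.log(max(L[1, 1], 1e-8))])

    rng = np.random.default_rng(7)
    checked = 0
    for rep in range(50):
        G0 = np.diag(rng.uniform([0.1, 0.005], [0.5, 0.03]))
        df, _ = _simulate(rng.normal(0, 0.3, 5), G0, rng.uniform(0.05, 0.2),
                          n_subjects=40, n_visits=5, seed=100 + rep)
        fit = fit_lmm_reml(df, SPEC)
        X = np.column_stack([np.ones(len(df)), df["visit_year"], df["baseline_age"],
                             df["sex"], df["education"]])
        Z = X[:, :2]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = sm.MixedLM(df["y"], X, groups=df["id"], exog_re=Z)
            ref = md.fit(reml=True, method="lbfgs", maxiter=5000,
                         pgtol=1e-12, factr=10.0)
        # Both fits must sit at the same optimum of the (common) restricted
        # likelihood; reps where the reference stalls at a strictly worse
        # objective value are its own non-convergence, not a disagreement.
        ss = build_suffstats(df, SPEC)
        w = np.ones(len(ss.ids))
        ctx = _FitContext(ss, w)
        f_mine = _neg2_profiled_reml(fit.theta, ss, w, ctx)
        try:
            f_ref = _neg2_profiled_reml(sm_theta(np.asarray(ref.cov_re), ref.scale),
                                        ss, w, ctx)
        except np.linalg.LinAlgError:
            continue
        assert f_mine <= f_ref + 1e-4   # never at a worse optimum than the reference
        if not ref.converged or abs(f_ref - f_mine) > 1e-5:
            continue
        checked += 1
        np.testing.assert_allclose(fit.beta, ref.fe_params, atol=1e-4)
        np.testing.assert_allclose(fit.G, np.asarray(ref.cov_re), atol=1e-3)
        assert fit.sigma2 == pytest.approx(ref.scale, abs=1e-3)
    assert checked >= 40


# ---------------------------------------------------------------------------
# EBLUPs
# ---------------------------------------------------------------------------

def _manual_fit(beta, G, sigma2):
    return LmmFit(beta=np.asarray(beta, float), beta_names=("intercept", "visit_year",
                  "baseline_age", "sex", "education"), G=np.asarray(G, float),
                  sigma2=sigma2, reml_loglik=0.0, converged=True,
                  n_subjects=1, n_obs=3)


def _subject_df(t, y, age=70.0, sex=1.0, edu=2.0):
    return pd.DataFrame({"id": "s", "visit_year": t, "y": y,
                         "baseline_age": age, "sex": sex, "education": edu})


def test_eblup_zero_G_full_shrinkage():
    fit = _manual_fit([0.1, -0.02, 0.0, 0.0, 0.0], np.zeros((2, 2)), 0.2)
    b = compute_eblup(fit, _subject_df([0.0, 1, 2], [1.0, -2, 3]), SPEC)
    np.testing.assert_allclose(b, [0.0, 0.0], atol=1e-12)


def test_eblup_noise_free_limit_is_subject_ols():
    """As sigma2 -> 0, the EBLUP approaches the subject's own least-squares
    intercept/slope deviation from the fixed-effect fit."""
    beta = np.array([0.5, -0.1, 0.0, 0.0, 0.0])
    fit = _manual_fit(beta, np.diag([0.3, 0.02]), 1e-12)
    t = np.array([0.0, 1, 2, 3])
    dev = 0.8 - 0.25 * t           # true subject deviation
    y = beta[0] + beta[1] * t + dev
    b = compute_eblup(fit, _subject_df(t, y), SPEC)
    np.testing.assert_allclose(b, [0.8, -0.25], atol=1e-4)


def test_eblup_matches_dense_gls_formula():
    """Three-visit subject with fixed numeric (beta, G, sigma2): the EBLUP
    equals G Z' V^{-1} (y - X beta) evaluated by explicit 3x3 inversion."""
    beta = np.array([0.2, -0.05, -0.01, 0.1, 0.05])
    G = np.array([[0.3, 0.04], [0.04, 0.02]])
    s2 = 0.11
    fit = _manual_fit(beta, G, s2)
    df = _subject_df([0.0, 1, 3], [0.4, -0.3, 0.9], age=72.0, sex=0.0, edu=1.0)
    X = np.column_stack([np.ones(3), df["visit_year"], df["baseline_age"],
                         df["sex"], df["education"]])
    Z = X[:, :2]
    r = df["y"].to_numpy() - X @ beta
    V = Z @ G @ Z.T + s2 * np.eye(3)
    expected = G @ Z.T @ np.linalg.inv(V) @ r
    np.testing.assert_allclose(compute_eblup(fit, df, SPEC), expected, atol=1e-10)


def test_eblup_shrinks_toward_zero_with_fewer_visits():
    """Intercept-only case: the EBLUP norm never exceeds the raw subject
    mean deviation, and shrinkage weakens as visits accumulate."""
    fit = _manual_fit([0.0, 0.0, 0.0, 0.0, 0.0], np.diag([0.3, 0.0]), 0.5)
    rng = np.random.default_rng(11)
    for k in (1, 3, 8):
        y = rng.normal(1.0, 0.1, k)
        b = compute_eblup(fit, _subject_df(np.zeros(k), y), SPEC)
        raw = y.mean()
        shrink = 0.3 / (0.3 + 0.5 / k)
        assert abs(b[0]) <= abs(raw) + 1e-12
        assert b[0] == pytest.approx(shrink * raw, rel=1e-9)


def test_batched_eblups_agree_with_per_subject_formula():
    df, _ = _simulate(np.array([0.2, -0.05, -0.01, 0.1, 0.05]),
                      np.diag([0.25, 0.01]), 0.09, 50, 6, seed=12)
    fit = fit_lmm_reml(df, SPEC)
    ss = build_suffstats(df, SPEC)
    batched = eblups_all(fit, ss)
    for i, sid in enumerate(ss.ids[:10]):
        one = compute_eblup(fit, df[df["id"] == sid], SPEC)
        np.testing.assert_allclose(batched[i], one, atol=1e-9)
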