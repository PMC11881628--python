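"""Synthetic longitudinal cohort generator.

Emulates the structure of an aging cohort followed with annual cognitive
assessments: subjects enter dementia-free in their mid-70s, contribute up to
11 annual visits with five correlated z-scored cognitive-domain composites,
and either develop incident Alzheimer's disease (AD) before death, die
AD-free, or drop out.  The generative model mirrors the analysis model — a
linear mixed model per domain with subject-level random intercepts and
slopes, and a logistic lifetime-risk model on the true random effects plus
demographics — so that every downstream stage can be tested by parameter
recovery against known ground truth.

Conventions
-----------
* Sex is coded female = 1, male = 0.
* Education is ordinal 0-3 (no high school / high school / some college /
  college and higher).
* Time is years since baseline; the age covariate is centred at
  ``baseline_age_mean`` inside the generative linear predictors so that the
  domain intercepts are interpretable as the score of an average-aged
  subject at baseline.
* Mortality follows a Gompertz hazard ``h0 * exp(b * (age - 75))``,
  independent of cognition (the lifetime outcome treats death only as the
  censoring horizon; death is not modelled as a competing risk).
* AD onset for cases is placed after baseline and strictly before death by
  inverse-sampling an exponential waiting time whose rate increases with
  the steepness of the subject's true cognitive decline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "default_config",
    "null_risk_config",
    "single_domain_config",
    "generate_cohort",
    "generate_raw_tests",
    "recompute_composites_from_tests",
    "SUBJECT_COLUMNS",
    "VISIT_KEY_COLUMNS",
]

#: Required columns of the subject table, in emission order.
SUBJECT_COLUMNS = [
    "id",
    "baseline_age",
    "sex",
    "education",
    "ad_status",
    "onset_age",
    "death_age",
    "last_contact_age",
    "cohort_label",
    "baseline_impaired_flag",
    "non_ad_dementia_flag",
    "mci_flag",
]

#: Key (non-score) columns of the visit table.
VISIT_KEY_COLUMNS = ["id", "visit_year", "age_at_visit"]

AD = "incident_AD"
CN = "cognitively_intact"


class ConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Per-domain parameters are arrays with one entry (row) per domain.
    ``fixed_effects_per_domain`` has columns
    ``[intercept, time_slope, age, sex, education]`` in z-units per covariate
    unit; ``re_cov_per_domain`` stacks the 2x2 covariance of the
    (intercept, slope) random effects; ``risk_*`` are the coefficients of
    the logistic lifetime-risk model on the true random effects and
    demographics (age centred at ``baseline_age_mean``).
    """

    n_subjects: int = 2000
    seed: int = 0
    baseline_age_mean: float = 77.5
    baseline_age_sd: float = 7.5
    prop_female: float = 0.75
    education_probs: np.ndarray = field(
        default_factory=lambda: np.array([0.047, 0.131, 0.178, 0.644])
    )
    n_domains: int = 5
    fixed_effects_per_domain: np.ndarray = field(
        default_factory=lambda: np.tile(
            np.array([0.25, -0.03, -0.02, 0.05, 0.10]), (5, 1)
        )
    )
    re_cov_per_domain: np.ndarray = field(
        default_factory=lambda: np.tile(
            np.array([[0.30, 0.0], [0.0, 0.004]]), (5, 1, 1)
        )
    )
    residual_sd_per_domain: np.ndarray = field(
        default_factory=lambda: np.full(5, 0.25)
    )
    # Logistic lifetime-risk model on the TRUE random effects.
    risk_intercept: float = -1.55
    risk_b0: np.ndarray = field(default_factory=lambda: np.full(5, -0.12))
    risk_b1: np.ndarray = field(default_factory=lambda: np.full(5, -11.0))
    risk_age: float = 0.02
    risk_sex: float = 0.10
    risk_education: float = 0.0
    # Visit process.
    max_visits: int = 11
    visit_interval: float = 1.0
    dropout_hazard: float = 0.03
    death_rate_params: tuple[float, float] = (0.035, 0.09)  # (h0 at 75, slope)
    # AD onset placement (cases only).
    onset_rate: float = 0.045
    onset_slope_weight: float = 0.6
    # Raw-test emulation (for composite-construction testing).
    tests_per_domain: np.ndarray = field(default_factory=lambda: np.array([4, 2, 7, 3, 3]))
    test_noise_sd: float = 0.2
    # Eligibility-flag fractions (default: a clean cohort).
    frac_baseline_impaired: float = 0.0
    frac_non_ad_dementia: float = 0.0
    frac_late_mci: float = 0.0
    cohort_label: str = "synthetic"

    def __post_init__(self) -> None:
        self.education_probs = np.asarray(self.education_probs, dtype=float)
        self.fixed_effects_per_domain = np.atleast_2d(
            np.asarray(self.fixed_effects_per_domain, dtype=float)
        )
        self.re_cov_per_domain = np.asarray(self.re_cov_per_domain, dtype=float)
        if self.re_cov_per_domain.ndim == 2:
            self.re_cov_per_domain = self.re_cov_per_domain[None, :, :]
        self.residual_sd_per_domain = np.atleast_1d(
            np.asarray(self.residual_sd_per_domain, dtype=float)
        )
        self.risk_b0 = np.atleast_1d(np.asarray(self.risk_b0, dtype=float))
        self.risk_b1 = np.atleast_1d(np.asarray(self.risk_b1, dtype=float))
        self.tests_per_domain = np.atleast_1d(
            np.asarray(self.tests_per_domain, dtype=int)
        )
        self.validate()

    def validate(self) -> None:
        D = self.n_domains
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.max_visits < 1:
            raise ConfigError("max_visits must be >= 1")
        if not 0.0 <= self.prop_female <= 1.0:
            raise ConfigError("prop_female must lie in [0, 1]")
        if self.baseline_age_sd <= 0:
            raise ConfigError("baseline_age_sd must be > 0")
        if abs(self.education_probs.sum() - 1.0) > 1e-9:
            raise ConfigError("education_probs must sum to 1 within 1e-9")
        if np.any(self.education_probs < 0) or np.any(self.education_probs > 1):
            raise ConfigError("education_probs must lie in [0, 1]")
        for name, arr, shape in [
            ("fixed_effects_per_domain", self.fixed_effects_per_domain, (D, 5)),
            ("re_cov_per_domain", self.re_cov_per_domain, (D, 2, 2)),
            ("residual_sd_per_domain", self.residual_sd_per_domain, (D,)),
            ("risk_b0", self.risk_b0, (D,)),
            ("risk_b1", self.risk_b1, (D,)),
            ("tests_per_domain", self.tests_per_domain, (D,)),
        ]:
            if arr.shape != shape:
                raise ConfigError(f"{name} must have shape {shape}, got {arr.shape}")
        if np.any(self.residual_sd_per_domain <= 0):
            raise ConfigError("residual SDs must be > 0")
        if np.any(self.tests_per_domain < 1):
            raise ConfigError("tests_per_domain entries must be >= 1")
        if self.test_noise_sd < 0:
            raise ConfigError("test_noise_sd must be >= 0")
        for d in range(D):
            G = self.re_cov_per_domain[d]
            if not np.allclose(G, G.T, atol=1e-12):
                raise ConfigError(f"re_cov_per_domain[{d}] is not symmetric")
            if np.min(np.linalg.eigvalsh(G)) < -1e-10:
                raise ConfigError(
                    f"re_cov_per_domain[{d}] is not positive semi-definite"
                )


def default_config(n_subjects: int = 2000, seed: int = 0, **overrides) -> GeneratorConfig:
    """The default study conditions: a cohort resembling a community aging
    study with ~26% incident AD, mean ~7 visits and a slope-dominated risk
    signal."""
    return replace(GeneratorConfig(), n_subjects=n_subjects, seed=seed, **overrides)


def null_risk_config(n_subjects: int = 2000, seed: int = 0, ad_fraction: float = 0.26) -> GeneratorConfig:
    """A cohort with no association between cognition and the AD outcome:
    all risk coefficients zero except the intercept, which is set so the
    marginal AD fraction equals ``ad_fraction``."""
    D = 5
    return default_config(
        n_subjects,
        seed,
        risk_intercept=float(np.log(ad_fraction / (1.0 - ad_fraction))),
        risk_b0=np.zeros(D),
        risk_b1=np.zeros(D),
        risk_age=0.0,
        risk_sex=0.0,
        risk_education=0.0,
    )


def single_domain_config(n_subjects: int = 400, seed: int = 0, **overrides) -> GeneratorConfig:
    """A one-domain variant of the default conditions (same trajectory and
    risk parameters for the remaining domain); used where a compact cohort
    suffices."""
    base = GeneratorConfig()
    cfg = dict(
        n_subjects=n_subjects,
        seed=seed,
        n_domains=1,
        fixed_effects_per_domain=base.fixed_effects_per_domain[:1],
        re_cov_per_domain=base.re_cov_per_domain[:1],
        residual_sd_per_domain=base.residual_sd_per_domain[:1],
        risk_intercept=-1.15,
        risk_b0=base.risk_b0[:1],
        risk_b1=base.risk_b1[:1] * 1.5,
        tests_per_domain=base.tests_per_domain[:1],
    )
    cfg.update(overrides)
    return replace(GeneratorConfig(), **cfg)


def _simulate_death_times(rng, baseline_age, params):
    """Years from baseline to death under the Gompertz hazard
    h(age) = h0 * exp(b * (age - 75)), by inversion of the cumulative
    hazard.  Floored at 1 year after baseline, capped at age 110."""
    h0, b = params
    e = rng.exponential(size=baseline_age.shape)
    t = np.log1p(b * e / (h0 * np.exp(b * (baseline_age - 75.0)))) / b
    return np.clip(t, 1.0, 110.0 - baseline_age)


def generate_cohort(config: GeneratorConfig):
    """Draw a full synthetic cohort.

    Returns
    -------
    subjects : pandas.DataFrame
        One row per subject with the columns in :data:`SUBJECT_COLUMNS`.
    visits : pandas.DataFrame
        One row per assessment with id, visit_year, age_at_visit and
        ``domain_1`` .. ``domain_D`` composite scores.
    true_effects : pandas.DataFrame
        Long table of the true per-subject, per-domain random effects
        (columns id, domain, b0, b1) — the recovery-test ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, D = config.n_subjects, config.n_domains

    ids = np.array([f"S{i:05d}" for i in range(n)])
    age0 = np.clip(
        rng.normal(config.baseline_age_mean, config.baseline_age_sd, n), 55.0, 100.0
    )
    sex = (rng.random(n) < config.prop_female).astype(int)
    education = rng.choice(4, size=n, p=config.education_probs)

    # True random effects: (n, D, 2).
    b = np.empty((n, D, 2))
    for d in range(D):
        b[:, d, :] = rng.multivariate_normal(
            np.zeros(2), config.re_cov_per_domain[d], size=n
        )

    age_c = age0 - config.baseline_age_mean
    eta = (
        config.risk_intercept
        + b[:, :, 0] @ config.risk_b0
        + b[:, :, 1] @ config.risk_b1
        + config.risk_age * age_c
        + config.risk_sex * sex
        + config.risk_education * education
    )
    is_ad = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))

    death_t = _simulate_death_times(rng, age0, config.death_rate_params)

    # Onset placement for cases: waiting time after baseline whose rate
    # grows with the (standardised, sign-flipped) mean true slope.
    slope_sd = np.sqrt(np.maximum(config.re_cov_per_domain[:, 1, 1], 1e-12))
    s = (b[:, :, 1] / slope_sd).mean(axis=1)
    rate = config.onset_rate * np.exp(config.onset_slope_weight * (-s))
    onset_t = np.full(n, np.nan)
    raw_onset = 0.5 + rng.exponential(1.0 / rate)
    late = raw_onset >= death_t
    raw_onset[late] = np.maximum(0.25, death_t[late] * rng.uniform(0.3, 0.95, late.sum()))
    onset_t[is_ad] = raw_onset[is_ad]

    # Visit process: annual grid truncated at dropout, death and (for
    # cases) AD onset.  The baseline visit always survives the truncation.
    drop_t = rng.exponential(1.0 / max(config.dropout_hazard, 1e-12), n)
    grid = np.arange(config.max_visits) * config.visit_interval
    tmat = np.tile(grid, (n, 1))  # (n, V)
    limit = np.minimum(death_t, drop_t)
    limit = np.where(is_ad, np.minimum(limit, raw_onset), limit)
    keep = tmat < limit[:, None]
    keep[:, 0] = True  # baseline assessment always observed

    sidx, vidx = np.nonzero(keep)
    t = tmat[sidx, vidx]
    scores = np.empty((t.size, D))
    for d in range(D):
        fe = config.fixed_effects_per_domain[d]
        mu = (
            fe[0]
            + fe[1] * t
            + fe[2] * age_c[sidx]
            + fe[3] * sex[sidx]
            + fe[4] * education[sidx]
            + b[sidx, d, 0]
            + b[sidx, d, 1] * t
        )
        scores[:, d] = mu + rng.normal(0.0, config.residual_sd_per_domain[d], t.size)

    visits = pd.DataFrame({"id": ids[sidx], "visit_year": t, "age_at_visit": age0[sidx] + t})
    for d in range(D):
        visits[f"domain_{d + 1}"] = scores[:, d]

    last_contact = visits.groupby("id", sort=False)["age_at_visit"].max()

    baseline_impaired = rng.random(n) < config.frac_baseline_impaired
    non_ad_dementia = rng.random(n) < config.frac_non_ad_dementia
    mci_flag = np.full(n, np.nan)
    late_mci = (~is_ad) & (rng.random(n) < config.frac_late_mci)
    mci_flag[late_mci] = rng.uniform(2.0, 15.0, late_mci.sum())

    subjects = pd.DataFrame(
        {
            "id": ids,
            "baseline_age": age0,
            "sex": sex,
            "education": education,
            "ad_status": np.where(is_ad, AD, CN),
            "onset_age": age0 + onset_t,
            "death_age": age0 + death_t,
            "last_contact_age": last_contact.reindex(ids).to_numpy(),
            "cohort_label": config.cohort_label,
            "baseline_impaired_flag": baseline_impaired,
            "non_ad_dementia_flag": non_ad_dementia,
            "mci_flag": mci_flag,
        }
    )

    true_effects = pd.DataFrame(
        {
            "id": np.repeat(ids, D),
            "domain": np.tile(np.arange(1, D + 1), n),
            "b0": b[:, :, 0].ravel(),
            "b1": b[:, :, 1].ravel(),
        }
    )
    return subjects, visits, true_effects


def _test_scale(domain: int, k: int) -> tuple[float, float]:
    # Fixed, arbitrary raw-score scales per (domain, test) pair.
    return 20.0 + 5.0 * domain + 2.0 * k, 3.0 + 0.5 * k


def generate_raw_tests(visits: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Expand domain composites into raw per-test scores.

    Each raw test is the domain composite mapped to a test-specific
    mean/SD scale, plus independent Gaussian noise of SD
    ``config.test_noise_sd`` (in composite z-units).  Re-standardising the
    raw tests against the cohort baseline and averaging within domain
    approximately restores the composites.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1_000_003)
    out = visits[VISIT_KEY_COLUMNS].copy()
    for d in range(1, config.n_domains + 1):
        col = f"domain_{d}"
        if col not in visits.columns:
            raise KeyError(f"visit table has no composite column {col!r}")
        comp = visits[col].to_numpy(dtype=float)
        for k in range(int(config.tests_per_domain[d - 1])):
            mu, sd = _test_scale(d, k)
            noise = rng.normal(0.0, config.test_noise_sd, comp.size) if config.test_noise_sd > 0 else 0.0
            out[f"test_d{d}_t{k}"] = mu + sd * (comp + noise)
    return out


def synthetic_test_map(config: GeneratorConfig) -> dict[str, int]:
    """Column -> domain mapping for tables from :func:`generate_raw_tests`."""
    return {
        f"test_d{d}_t{k}": d
        for d in range(1, config.n_domains + 1)
        for k in range(int(config.tests_per_domain[d - 1]))
    }


def recompute_composites_from_tests(raw: pd.DataFrame, config: GeneratorConfig):
    """Convenience round-trip: z-score raw tests against the cohort
    baseline and average within domain (delegates to the cohort builder)."""
    from .cohort import compute_domain_composites

    return compute_domain_composites(raw, synthetic_test_map(config), stats="estimate")
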