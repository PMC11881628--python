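"""Cohort construction: composite scoring, eligibility, landmark datasets.

Implements the data-preparation conventions of the analysis:

* five cognitive-domain composites, each the mean of the available per-test
  z-scores, standardised against the cohort's baseline mean and SD;
* eligibility filters for the lifetime outcome (exclude baseline
  impairment, non-AD dementia, late MCI among non-progressors, and
  subjects with no evaluations) and the age-bounded variants (AD onset
  before age 85 or 90);
* landmark datasets: for the model evaluated "at year t", only visits
  observed by year t — and for incident-AD cases only visits strictly
  before onset — inform the fit, with at most 11 visits per subject;
* prediction-horizon datasets, visit subsampling designs, and a
  baseline-characteristics summary table with Kruskal-Wallis / chi-square
  group tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic import AD, CN

__all__ = [
    "ROSMAP_TEST_MAP",
    "DOMAIN_NAMES",
    "LandmarkDataset",
    "compute_domain_composites",
    "apply_lifetime_eligibility",
    "apply_age_bounded_eligibility",
    "build_landmark_dataset",
    "build_horizon_dataset",
    "subsample_visits",
    "cohort_summary",
]

MAX_VISITS = 11

DOMAIN_NAMES = {
    1: "perceptual_speed",
    2: "visuospatial",
    3: "episodic_memory",
    4: "semantic_memory",
    5: "working_memory",
}

#: Canonical neuropsychological-battery mapping: test column -> domain index
#: (4 perceptual-speed, 2 visuospatial, 7 episodic, 3 semantic, 3
#: working-memory tests).
ROSMAP_TEST_MAP = {
    "symbol_digits": 1,
    "number_comparison": 1,
    "stroop_color_naming": 1,
    "stroop_word_reading": 1,
    "line_orientation": 2,
    "progressive_matrices": 2,
    "word_list_immediate": 3,
    "word_list_recall": 3,
    "word_list_recognition": 3,
    "east_boston_immediate": 3,
    "east_boston_delayed": 3,
    "logical_memory_i": 3,
    "logical_memory_ii": 3,
    "boston_naming": 4,
    "category_fluency": 4,
    "reading_test": 4,
    "digits_forward": 5,
    "digits_backward": 5,
    "digit_ordering": 5,
}


@dataclass
class LandmarkDataset:
    """Analysis-ready data for one landmark model.

    ``subjects`` carries the binary outcome in column ``y``; ``visits``
    holds only the assessments eligible at this landmark.  ``tally``
    counts subjects removed per rule while building the dataset.
    """

    landmark_year: float | None
    subjects: pd.DataFrame
    visits: pd.DataFrame
    tally: dict = dc_field(default_factory=dict)
    variant: str = "lifetime"

    @property
    def n_cases(self) -> int:
        return int(self.subjects["y"].sum())

    @property
    def n_controls(self) -> int:
        return int((1 - self.subjects["y"]).sum())


# ---------------------------------------------------------------------------
# Composite scoring
# ---------------------------------------------------------------------------

def compute_domain_composites(raw, test_map, stats="estimate"):
    """Build per-domain composite z-scores from raw test scores.

    Parameters
    ----------
    raw : DataFrame with id, visit_year, age_at_visit and one column per
        test.  Missing test scores are permitted (NaN).
    test_map : mapping of test column name -> domain index (1-based).
        Every non-key column of ``raw`` must be mapped.
    stats : "estimate" or mapping of test column -> (mean, sd).
        With "estimate", means and SDs are computed from the cohort's
        baseline visits (minimum visit_year per subject) and returned for
        reuse, so that later visits are scored on the baseline scale.

    Returns
    -------
    (visits, stats) : the visit table with ``domain_<d>`` composite
    columns (NaN where all of a domain's tests are missing), and the
    standardisation statistics actually used.
    """
    key_cols = [c for c in ("id", "visit_year", "age_at_visit") if c in raw.columns]
    if "id" not in key_cols or "visit_year" not in key_cols:
        raise ValueError("raw test table must have 'id' and 'visit_year' columns")
    test_cols = [c for c in raw.columns if c not in key_cols]
    unmapped = [c for c in test_cols if c not in test_map]
    if unmapped:
        raise ValueError(f"unmapped test columns: {unmapped}")

    if stats == "estimate":
        is_baseline = raw["visit_year"] == raw.groupby("id")["visit_year"].transform("min")
        base = raw.loc[is_baseline]
        stats = {}
        for c in test_cols:
            m = float(base[c].mean())
            s = float(base[c].std(ddof=1))
            if not np.isfinite(s) or s <= 0:
                raise ValueError(f"test {c!r} has zero variance at baseline; cannot standardise")
            stats[c] = (m, s)
    else:
        for c in test_cols:
            if c not in stats:
                raise ValueError(f"no standardisation stats supplied for test {c!r}")
            if stats[c][1] <= 0:
                raise ValueError(f"test {c!r} has non-positive SD in supplied stats")

    out = raw[key_cols].copy()
    domains = sorted(set(test_map[c] for c in test_cols))
    for d in domains:
        cols = [c for c in test_cols if test_map[c] == d]
        z = np.column_stack([(raw[c] - stats[c][0]) / stats[c][1] for c in cols])
        with np.errstate(invalid="ignore"):
            out[f"domain_{d}"] = np.nanmean(z, axis=1)
    return out, stats


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------

def _require_complete_demographics(subjects, tally):
    ok = (
        subjects["baseline_age"].notna()
        & subjects["sex"].notna()
        & subjects["education"].notna()
    )
    tally["missing_demographics"] = int((~ok).sum())
    return subjects.loc[ok]


def apply_lifetime_eligibility(subjects, visits=None):
    """Eligibility for the lifetime outcome.

    Removes, in order (each subject tallied at its first matching rule):
    subjects impaired at baseline; subjects who developed non-AD dementia;
    non-progressors whose MCI onset came more than 10 years after
    baseline; subjects with no clinical evaluation (requires ``visits``);
    and subjects with missing demographic covariates.  Non-progressors
    with MCI within 10 years of baseline are retained in the cognitively
    intact group (the literal reading of the rule).
    """
    s = subjects
    tally = {}
    bad = s["baseline_impaired_flag"].fillna(False).astype(bool)
    tally["baseline_impaired"] = int(bad.sum())
    s = s.loc[~bad]

    bad = s["non_ad_dementia_flag"].fillna(False).astype(bool)
    tally["non_ad_dementia"] = int(bad.sum())
    s = s.loc[~bad]

    mci = pd.to_numeric(s["mci_flag"], errors="coerce")
    bad = (s["ad_status"] != AD) & mci.notna() & (mci > 10.0)
    tally["late_mci"] = int(bad.sum())
    s = s.loc[~bad]

    if visits is not None:
        has_visit = s["id"].isin(visits["id"].unique())
        tally["no_evaluation"] = int((~has_visit).sum())
        s = s.loc[has_visit]
    else:
        tally["no_evaluation"] = 0

    s = _require_complete_demographics(s, tally)
    return s.copy(), tally


def apply_age_bounded_eligibility(subjects, age_cut, allow_any_cut=False):
    """Redefine the outcome as AD onset before ``age_cut`` (85 or 90).

    Excludes cognitively intact subjects who died at or before the cut
    (their AD-free status at the cut is not demonstrable had they lived)
    and AD cases with onset after the cut.  Retained AD cases all have
    onset <= cut, so ``ad_status`` continues to encode the outcome.
    """
    if age_cut not in (85, 90) and not allow_any_cut:
        raise ValueError("age_cut must be 85 or 90 (pass allow_any_cut=True to override)")
    s = subjects
    tally = {}
    death = pd.to_numeric(s["death_age"], errors="coerce")
    onset = pd.to_numeric(s["onset_age"], errors="coerce")
    is_ad = s["ad_status"] == AD

    bad = (~is_ad) & death.notna() & (death <= age_cut)
    tally[f"cn_died_by_{age_cut}"] = int(bad.sum())
    s, is_ad, onset = s.loc[~bad], is_ad.loc[~bad], onset.loc[~bad]

    bad = is_ad & (onset > age_cut)
    tally[f"ad_after_{age_cut}"] = int(bad.sum())
    s = s.loc[~bad]
    return s.copy(), tally


# ---------------------------------------------------------------------------
# Landmark / horizon datasets
# ---------------------------------------------------------------------------

def _outcome(subjects):
    return (subjects["ad_status"] == AD).astype(int)

def _pre_onset(merged):
    """Mask of visits usable for modelling: strictly before AD onset."""
    onset = pd.to_numeric(merged["onset_age"], errors="coerce")
    return onset.isna() | (merged["age_at_visit"] < onset)


def _cap_visits(visits, max_visits=MAX_VISITS):
    order = visits.sort_values(["id", "visit_year"], kind="mergesort")
    ranked = order.groupby("id").cumcount()
    return order.loc[ranked < max_visits]


def build_landmark_dataset(subjects, visits, t, *, max_visits=MAX_VISITS,
                           allow_any_year=False, variant="lifetime"):
    """Visits observed by landmark year ``t`` (and, for AD cases, strictly
    before onset), capped at the ``max_visits`` earliest; the outcome is
    unchanged by ``t``."""
    if not (0 <= t <= 10) and not allow_any_year:
        raise ValueError("landmark year must lie in 0..10 (pass allow_any_year=True to override)")
    merged = visits.merge(
        subjects[["id", "onset_age"]], on="id", how="inner", validate="many_to_one"
    )
    keep = (merged["visit_year"] <= t) & _pre_onset(merged)
    kept = _cap_visits(merged.loc[keep].drop(columns=["onset_age"]), max_visits)

    subj = subjects.loc[subjects["id"].isin(kept["id"].unique())].copy()
    tally = {"no_qualifying_visits": int(len(subjects) - len(subj))}
    subj["y"] = _outcome(subj)
    return LandmarkDataset(float(t), subj, kept.reset_index(drop=True), tally, variant)


def build_horizon_dataset(subjects, visits, horizon, *, max_visits=MAX_VISITS):
    """Prediction-horizon design: AD cases keep visits at least ``horizon``
    years (5 or 10) before onset; AD-free subjects keep visits within 5
    years of their last visit.  Subjects left without a qualifying visit
    are dropped and tallied."""
    if horizon not in (5, 10):
        raise ValueError("horizon must be 5 or 10")
    merged = visits.merge(
        subjects[["id", "onset_age", "ad_status"]], on="id", how="inner",
        validate="many_to_one",
    )
    onset = pd.to_numeric(merged["onset_age"], errors="coerce")
    is_ad = merged["ad_status"] == AD
    last = merged.groupby("id")["visit_year"].transform("max")
    keep = np.where(
        is_ad,
        merged["age_at_visit"] <= onset - horizon,
        merged["visit_year"] >= last - 5.0,
    )
    kept = _cap_visits(merged.loc[keep].drop(columns=["onset_age", "ad_status"]), max_visits)

    subj = subjects.loc[subjects["id"].isin(kept["id"].unique())].copy()
    tally = {"no_qualifying_visits": int(len(subjects) - len(subj))}
    subj["y"] = _outcome(subj)
    return LandmarkDataset(None, subj, kept.reset_index(drop=True), tally,
                           f"horizon{horizon}")


def subsample_visits(visits, k, rng):
    """Reduced-schedule design: keep the first and last visit and ``k - 2``
    uniformly chosen intermediate visits per subject (k = 3 or 4);
    subjects with at most k visits keep them all."""
    if k not in (3, 4):
        raise ValueError("k must be 3 or 4")
    rng = np.random.default_rng(rng)
    pieces = []
    for _, g in visits.sort_values(["id", "visit_year"], kind="mergesort").groupby("id", sort=False):
        if len(g) <= k:
            pieces.append(g)
            continue
        mid = rng.choice(len(g) - 2, size=k - 2, replace=False) + 1
        pieces.append(g.iloc[np.sort(np.r_[0, mid, len(g) - 1])])
    return pd.concat(pieces, ignore_index=True)


# ---------------------------------------------------------------------------
# Baseline characteristics table
# ---------------------------------------------------------------------------

def cohort_summary(subjects, baseline_visits):
    """Baseline-characteristics table comparing incident-AD and
    cognitively intact groups: mean +/- SD with Kruskal-Wallis H p-values
    for continuous variables, counts (%) with chi-square p-values (no
    continuity correction) for categorical ones."""
    y = _outcome(subjects)
    if y.sum() == 0 or (1 - y).sum() == 0:
        raise ValueError("both outcome groups must be non-empty")
    ad = subjects.loc[y == 1]
    cn = subjects.loc[y == 0]

    merged = baseline_visits.merge(subjects[["id", "ad_status"]], on="id")
    rows = []

    def kw_row(name, a, b):
        a, b = np.asarray(a, float), np.asarray(b, float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        stat, p = sps.kruskal(a, b)
        rows.append(
            dict(variable=name, test="kruskal_wallis",
                 ad=f"{a.mean():.2f} ± {a.std(ddof=1):.2f}",
                 cn=f"{b.mean():.2f} ± {b.std(ddof=1):.2f}",
                 statistic=float(stat), p_value=float(p))
        )

    def chi2_row(name, a, b, levels):
        table = np.array(
            [[np.sum(np.asarray(a) == lv) for lv in levels],
             [np.sum(np.asarray(b) == lv) for lv in levels]]
        )
        table = table[:, table.sum(axis=0) > 0]
        stat, p, _, _ = sps.chi2_contingency(table, correction=False)
        rows.append(
            dict(variable=name, test="chi_square",
                 ad="/".join(str(int(v)) for v in table[0]),
                 cn="/".join(str(int(v)) for v in table[1]),
                 statistic=float(stat), p_value=float(p))
        )

    kw_row("baseline_age", ad["baseline_age"], cn["baseline_age"])
    chi2_row("sex_female", ad["sex"], cn["sex"], [1, 0])
    chi2_row("education", ad["education"], cn["education"], [0, 1, 2, 3])
    for col in (c for c in merged.columns if c.startswith("domain_")):
        kw_row(col, merged.loc[merged["ad_status"] == AD, col],
               merged.loc[merged["ad_status"] == CN, col])
    out = pd.DataFrame(rows)
    out.attrs["n_ad"], out.attrs["n_cn"] = len(ad), len(cn)
    return out
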