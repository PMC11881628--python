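"""Shared fixtures: a small synthetic cohort and a hand-traceable toy cohort."""

import numpy as np
import pandas as pd
import pytest

import cogrisk


@pytest.fixture(scope="session")
def small_cohort():
    """A 600-subject default-condition cohort reused across read-only tests."""
    cfg = cogrisk.default_config(n_subjects=600, seed=42)
    subjects, visits, true_effects = cogrisk.generate_cohort(cfg)
    return cfg, subjects, visits, true_effects


def _visit_rows(sid, baseline_age, years):
    return pd.DataFrame({
        "id": sid,
        "visit_year": list(years),
        "age_at_visit": [baseline_age + y for y in years],
    })


@pytest.fixture()
def toy_cohort():
    """Six hand-constructed subjects exercising every eligibility rule.

    A: clean, cognitively intact, 12 visit records (years 0..10 plus a
       re-test at 9.5) -> the 11-visit cap drops the year-10 record.
    B: impaired at baseline (excluded first).
    C: developed non-AD dementia (excluded second).
    D: non-progressor whose MCI came 12 years after baseline (excluded).
    E: incident AD at baseline_age + 6 with an (ignored) MCI flag -- the
       late-MCI rule applies only to non-progressors; visits run past
       onset, so pre-onset truncation must drop years 6 and 7.
    F: cognitively intact with MCI at year 4 (retained; rule is > 10),
       died at 84 -> excluded from the pre-85 analysis.
    """
    subjects = pd.DataFrame([
        dict(id="A", baseline_age=70.0, sex=1, education=3, ad_status="cognitively_intact",
             onset_age=np.nan, death_age=np.nan, last_contact_age=80.0, cohort_label="toy",
             baseline_impaired_flag=False, non_ad_dementia_flag=False, mci_flag=np.nan),
        dict(id="B", baseline_age=75.0, sex=0, education=1, ad_status="cognitively_intact",
             onset_age=np.nan, death_age=np.nan, last_contact_age=77.0, cohort_label="toy",
             baseline_impaired_flag=True, non_ad_dementia_flag=False, mci_flag=np.nan),
        dict(id="C", baseline_age=72.0, sex=1, education=2, ad_status="cognitively_intact",
             onset_age=np.nan, death_age=np.nan, last_contact_age=74.0, cohort_label="toy",
             baseline_impaired_flag=False, non_ad_dementia_flag=True, mci_flag=np.nan),
        dict(id="D", baseline_age=76.0, sex=1, education=0, ad_status="cognitively_intact",
             onset_age=np.nan, death_age=np.nan, last_contact_age=81.0, cohort_label="toy",
             baseline_impaired_flag=False, non_ad_dementia_flag=False, mci_flag=12.0),
        dict(id="E", baseline_age=74.0, sex=0, education=2, ad_status="incident_AD",
             onset_age=80.0, death_age=84.0, last_contact_age=81.0, cohort_label="toy",
             baseline_impaired_flag=False, non_ad_dementia_flag=False, mci_flag=12.0),
        dict(id="F", baseline_age=78.0, sex=1, education=3, ad_status="cognitively_intact",
             onset_age=np.nan, death_age=84.0, last_contact_age=83.0, cohort_label="toy",
             baseline_impaired_flag=False, non_ad_dementia_flag=False, mci_flag=4.0),
    ])
    visits = pd.concat([
        _visit_rows("A", 70.0, list(range(11)) + [9.5]),
        _visit_rows("B", 75.0, [0, 1, 2]),
        _visit_rows("C", 72.0, [0, 1, 2]),
        _visit_rows("D", 76.0, [0, 1, 2, 3, 4, 5]),
        _visit_rows("E", 74.0, [0, 1, 2, 3, 4, 5, 6, 7]),
        _visit_rows("F", 78.0, [0, 1, 2, 3, 4, 5]),
    ], ignore_index=True).sort_values(["id", "visit_year"], ignore_index=True)
    rng = np.random.default_rng(7)
    for d in range(1, 6):
        visits[f"domain_{d}"] = rng.normal(0.0, 1.0, len(visits)).round(3)
    return subjects, visits
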