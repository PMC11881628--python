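"""Cohort builder: composites, eligibility, landmark/horizon datasets."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import cogrisk
from cogrisk.cohort import build_horizon_dataset, subsample_visits


# ---------------------------------------------------------------------------
# Composites
# ---------------------------------------------------------------------------

def _raw(rows, cols):
    df = pd.DataFrame(rows, columns=["id", "visit_year"] + cols)
    return df


def test_composite_single_test_fixed_stats():
    raw = _raw([["s1", 0, 12.0]], ["t1"])
    out, _ = cogrisk.compute_domain_composites(raw, {"t1": 1}, stats={"t1": (10.0, 2.0)})
    assert out.loc[0, "domain_1"] == pytest.approx(1.0)


def test_composite_symmetric_tests_cancel():
    raw = _raw([["s1", 0, 12.0, 8.0]], ["t1", "t2"])
    stats = {"t1": (10.0, 2.0), "t2": (10.0, 2.0)}
    out, _ = cogrisk.compute_domain_composites(raw, {"t1": 1, "t2": 1}, stats=stats)
    assert out.loc[0, "domain_1"] == pytest.approx(0.0)


def test_composite_partial_missing_matches_hand_average():
    """Seven-test domain with three tests missing: the composite is the
    plain average of the four available z-scores."""
    cols = [f"t{k}" for k in range(7)]
    vals = [14.0, np.nan, 8.0, 11.0, np.nan, np.nan, 9.5]
    raw = _raw([["s1", 0, *vals]], cols)
    stats = {c: (10.0, 2.0) for c in cols}
    out, _ = cogrisk.compute_domain_composites(raw, {c: 3 for c in cols}, stats=stats)
    zs = [(v - 10.0) / 2.0 for v in vals if not np.isnan(v)]
    assert out.loc[0, "domain_3"] == pytest.approx(sum(zs) / len(zs))


def test_composite_commutes_with_column_permutation():
    rng = np.random.default_rng(0)
    cols = [f"t{k}" for k in range(5)]
    raw = _raw([[f"s{i}", 0, *rng.normal(10, 2, 5)] for i in range(40)], cols)
    tmap = {c: 1 + (k % 2) for k, c in enumerate(cols)}
    out1, _ = cogrisk.compute_domain_composites(raw, tmap)
    shuffled = raw[["id", "visit_year"] + cols[::-1]]
    out2, _ = cogrisk.compute_domain_composites(shuffled, tmap)
    for d in (1, 2):
        np.testing.assert_allclose(out1[f"domain_{d}"], out2[f"domain_{d}"])


def test_composite_errors():
    raw = _raw([["s1", 0, 5.0, 1.0], ["s2", 0, 5.0, 2.0]], ["t1", "t2"])
    with pytest.raises(ValueError, match="t1"):
        cogrisk.compute_domain_composites(raw, {"t1": 1, "t2": 1})  # t1 zero variance
    with pytest.raises(ValueError, match="unmapped"):
        cogrisk.compute_domain_composites(raw, {"t1": 1})


def test_estimated_stats_are_baseline_anchored():
    raw = pd.DataFrame({
        "id": ["a", "a", "b", "b"],
        "visit_year": [0, 1, 0, 1],
        "t1": [8.0, 7.0, 12.0, 11.0],
    })
    out, stats = cogrisk.compute_domain_composites(raw, {"t1": 1})
    m, s = stats["t1"]
    assert m == pytest.approx(10.0) and s == pytest.approx(np.sqrt(8.0))
    np.testing.assert_allclose(out["domain_1"], (raw["t1"] - m) / s)


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------

def test_lifetime_eligibility_hand_trace(toy_cohort):
    subjects, visits = toy_cohort
    eligible, tally = cogrisk.apply_lifetime_eligibility(subjects, visits)
    assert sorted(eligible["id"]) == ["A", "E", "F"]
    assert tally["baseline_impaired"] == 1
    assert tally["non_ad_dementia"] == 1
    assert tally["late_mci"] == 1
    assert tally["no_evaluation"] == 0
    # tallies partition the removed subjects
    assert sum(tally.values()) == len(subjects) - len(eligible)


def test_lifetime_eligibility_identity_on_clean_table(small_cohort):
    _, subjects, visits, _ = small_cohort
    eligible, tally = cogrisk.apply_lifetime_eligibility(subjects, visits)
    assert len(eligible) == len(subjects)
    assert all(v == 0 for v in tally.values())
    assert not eligible["baseline_impaired_flag"].any()


def test_eligibility_idempotent(toy_cohort):
    subjects, visits = toy_cohort
    once, _ = cogrisk.apply_lifetime_eligibility(subjects, visits)
    twice, tally2 = cogrisk.apply_lifetime_eligibility(once, visits)
    pd.testing.assert_frame_equal(once, twice)
    assert sum(tally2.values()) == 0


@pytest.mark.parametrize("cut,expected_ids,expected_tally", [
    (85, ["A", "E"], {"cn_died_by_85": 1, "ad_after_85": 0}),
    (90, ["A", "E"], {"cn_died_by_90": 1, "ad_after_90": 0}),
])
def test_age_bounded_eligibility(toy_cohort, cut, expected_ids, expected_tally):
    subjects, visits = toy_cohort
    eligible, _ = cogrisk.apply_lifetime_eligibility(subjects, visits)
    out, tally = cogrisk.apply_age_bounded_eligibility(eligible, cut)
    assert sorted(out["id"]) == expected_ids
    assert tally == expected_tally


def test_age_bounded_rules_pointwise():
    def one(status, onset, death, cut):
        s = pd.DataFrame([dict(id="x", baseline_age=70.0, sex=1, education=1,
                               ad_status=status, onset_age=onset, death_age=death)])
        out, _ = cogrisk.apply_age_bounded_eligibility(s, cut)
        return len(out) == 1

    assert not one("cognitively_intact", np.nan, 84.0, 85)   # died at/before cut
    assert one("incident_AD", 86.0, 95.0, 90)                # onset 86 <= 90: kept
    assert not one("incident_AD", 86.0, 95.0, 85)            # onset after 85: dropped
    with pytest.raises(ValueError):
        cogrisk.apply_age_bounded_eligibility(pd.DataFrame(), 80)


# ---------------------------------------------------------------------------
# Landmark and horizon datasets
# ---------------------------------------------------------------------------

def test_landmark_t0_baseline_only(toy_cohort):
    subjects, visits = toy_cohort
    eligible, _ = cogrisk.apply_lifetime_eligibility(subjects, visits)
    lm = cogrisk.build_landmark_dataset(eligible, visits, 0)
    assert (lm.visits["visit_year"] == 0).all()
    assert lm.visits.groupby("id").size().eq(1).all()
    assert set(lm.subjects["id"]) == {"A", "E", "F"}


def test_landmark_pre_onset_truncation_and_cap(toy_cohort):
    subjects, visits = toy_cohort
    eligible, _ = cogrisk.apply_lifetime_eligibility(subjects, visits)
    lm = cogrisk.build_landmark_dataset(eligible, visits, 10)
    # E: onset at baseline + 6 -> years 0..5 only, outcome still 1
    e = lm.visits.loc[lm.visits["id"] == "E", "visit_year"]
    assert sorted(e) == [0, 1, 2, 3, 4, 5]
    assert lm.subjects.set_index("id").loc["E", "y"] == 1
    # A: 12 qualifying records -> the 11 earliest are kept (year 10 dropped)
    a = lm.visits.loc[lm.visits["id"] == "A", "visit_year"]
    assert len(a) == 11
    assert sorted(a) == [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 9.5]


def test_landmark_monotone_in_t(small_cohort):
    _, subjects, visits, _ = small_cohort
    eligible, _ = cogrisk.apply_lifetime_eligibility(subjects, visits)
    prev = None
    for t in range(0, 11, 2):
        lm = cogrisk.build_landmark_dataset(eligible, visits, t)
        keys = set(map(tuple, lm.visits[["id", "visit_year"]].to_numpy()))
        if prev is not None:
            assert prev <= keys
        prev = keys


def test_landmark_year_range_checked(toy_cohort):
    subjects, visits = toy_cohort
    with pytest.raises(ValueError):
        cogrisk.build_landmark_dataset(subjects, visits, 12)
    cogrisk.build_landmark_dataset(subjects, visits, 12, allow_any_year=True)


def test_horizon_dataset_hand_trace(toy_cohort):
    subjects, visits = toy_cohort
    eligible, _ = cogrisk.apply_lifetime_eligibility(subjects, visits)
    hz = build_horizon_dataset(eligible, visits, 5)
    # E: onset 80, horizon 5 -> age_at_visit <= 75 -> years 0, 1
    assert sorted(hz.visits.loc[hz.visits["id"] == "E", "visit_year"]) == [0, 1]
    # A (no AD): last visit year 10 -> keep visit_year >= 5
    assert sorted(hz.visits.loc[hz.visits["id"] == "A", "visit_year"]) == [5, 6, 7, 8, 9, 9.5, 10]
    # F (no AD): visits 0..5, last 5 -> all kept
    assert sorted(hz.visits.loc[hz.visits["id"] == "F", "visit_year"]) == [0, 1, 2, 3, 4, 5]
    with pytest.raises(ValueError):
        build_horizon_dataset(eligible, visits, 7)


def test_horizon_drops_cases_without_qualifying_visits():
    subjects = pd.DataFrame([
        dict(id="x", baseline_age=70.0, sex=1, education=1, ad_status="incident_AD",
             onset_age=73.0, death_age=80.0),
        dict(id="y", baseline_age=70.0, sex=0, education=2, ad_status="cognitively_intact",
             onset_age=np.nan, death_age=np.nan),
    ])
    visits = pd.concat([
        pd.DataFrame({"id": "x", "visit_year": [0, 1, 2], "age_at_visit": [70.0, 71, 72]}),
        pd.DataFrame({"id": "y", "visit_year": [0, 1, 2], "age_at_visit": [70.0, 71, 72]}),
    ], ignore_index=True)
    visits["domain_1"] = 0.0
    hz = build_horizon_dataset(subjects, visits, 5)
    # x: onset baseline+3, horizon 5 -> no visit at age <= 68 -> dropped
    assert list(hz.subjects["id"]) == ["y"]
    assert hz.tally["no_qualifying_visits"] == 1


# ---------------------------------------------------------------------------
# Visit subsampling
# ---------------------------------------------------------------------------

def test_subsample_keeps_all_when_few_visits():
    v = pd.DataFrame({"id": ["a"] * 3 + ["b"] * 2,
                      "visit_year": [0, 1, 2, 0, 1],
                      "age_at_visit": [70, 71, 72, 80, 81.0]})
    out = subsample_visits(v, 3, rng=0)
    assert len(out) == 5  # both subjects keep everything
    with pytest.raises(ValueError):
        subsample_visits(v, 5, rng=0)


def test_subsample_intermediate_uniformity():
    v = pd.DataFrame({"id": "a", "visit_year": np.arange(11.0),
                      "age_at_visit": 70 + np.arange(11.0)})
    rng = np.random.default_rng(123)
    freq = np.zeros(11)
    n_draws = 10_000
    for _ in range(n_draws):
        out = subsample_visits(v, 3, rng)
        years = set(out["visit_year"])
        assert {0.0, 10.0} <= years and len(years) == 3
        mid = (years - {0.0, 10.0}).pop()
        freq[int(mid)] += 1
    props = freq[1:10] / n_draws
    assert np.all(np.abs(props - 1 / 9) < 0.03)


# ---------------------------------------------------------------------------
# Cohort summary table
# ---------------------------------------------------------------------------

def test_cohort_summary_identical_groups_give_null_chi2():
    subjects = pd.DataFrame({
        "id": [f"s{i}" for i in range(40)],
        "baseline_age": np.tile([70.0, 75, 80, 85], 10),
        "sex": np.tile([0, 1], 20),
        "education": np.tile([0, 1, 2, 3], 10),
        "ad_status": ["incident_AD"] * 20 + ["cognitively_intact"] * 20,
    })
    baseline = pd.DataFrame({"id": subjects["id"], "visit_year": 0, "age_at_visit": 70.0})
    table = cogrisk.cohort_summary(subjects, baseline)
    sex_row = table.set_index("variable").loc["sex_female"]
    assert sex_row["statistic"] == pytest.approx(0.0, abs=1e-12)
    assert sex_row["p_value"] == pytest.approx(1.0)


def test_kruskal_wallis_matches_hand_ranks():
    """H for {1,2,3} vs {4,5,6} is 12/(N(N+1)) * sum n_g (rbar_g - rbar)^2
    = 3.857... with no ties."""
    a, b = [1.0, 2, 3], [4.0, 5, 6]
    stat, _ = sps.kruskal(a, b)
    assert stat == pytest.approx(12 / (6 * 7) * (3 * (2 - 3.5) ** 2 + 3 * (5 - 3.5) ** 2))
    assert stat == pytest.approx(3.8571428, abs=1e-6)


def test_chi2_matches_closed_form_2x2():
    a, b, c, d = 477, 140, 1324, 443
    n = a + b + c + d
    expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    stat, _, _, _ = sps.chi2_contingency(np.array([[a, b], [c, d]]), correction=False)
    assert stat == pytest.approx(expected, rel=1e-12)


def test_cohort_summary_requires_both_groups(toy_cohort):
    subjects, visits = toy_cohort
    cn_only = subjects[subjects["ad_status"] == "cognitively_intact"]
    with pytest.raises(ValueError):
        cogrisk.cohort_summary(cn_only, visits[visits["visit_year"] == 0])
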