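"""Config-driven end-to-end runner.

Orchestrates: cohort input (CSV or synthetic generation) -> eligibility
filtering -> the landmark loop of two-stage model fits -> discrimination /
calibration evaluation -> tidy CSV outputs, plots and a markdown report.
Every run is deterministic given the configuration and seed; the resolved
configuration and all exclusion tallies are echoed into the run log.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as ch
from . import evaluation as ev
from . import synthetic as syn

logger = logging.getLogger("cogrisk")

__all__ = ["RunConfig", "run", "validate_input", "load_cohort_csv",
           "write_cohort_csv"]

VARIANTS = ("lifetime", "pre85", "pre90", "horizon5", "horizon10",
            "visits3", "visits4")

CONFIG_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """One analysis run.

    Exactly one input source: either ``subjects_csv``/``visits_csv`` or a
    synthetic ``generator`` section (keyword overrides for the default
    generator conditions).  Defaults mirror the published analysis
    settings: bootstrap B = 1000, landmark years 0..10, risk deciles.
    """

    variant: str = "lifetime"
    subjects_csv: str | None = None
    visits_csv: str | None = None
    generator: dict | None = None
    domains: object = "all"        # "all" | "stepwise" | list of indices
    years: list = field(default_factory=lambda: list(range(11)))
    bootstrap: int = ev.DEFAULT_BOOTSTRAP
    seed: int = 0
    out_dir: str = "cogrisk_out"
    refit_bootstrap: bool = True
    plots: bool = True
    allow_partial: bool = False
    sex_coding: str = "female=1"
    education_coding: str = "ordinal 0-3"
    schema_version: int = CONFIG_SCHEMA_VERSION

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.bootstrap < 2:
            raise ValueError("bootstrap must be >= 2")
        has_csv = self.subjects_csv is not None or self.visits_csv is not None
        if has_csv == (self.generator is not None):
            raise ValueError("exactly one input source required: CSV paths or generator")
        if has_csv and (self.subjects_csv is None or self.visits_csv is None):
            raise ValueError("both subjects_csv and visits_csv are required")

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# CSV I/O and validation
# ---------------------------------------------------------------------------

REQUIRED_SUBJECT_COLS = ["id", "baseline_age", "sex", "education", "ad_status"]
REQUIRED_VISIT_COLS = ["id", "visit_year", "age_at_visit"]
OPTIONAL_SUBJECT_DEFAULTS = {
    "onset_age": np.nan, "death_age": np.nan, "last_contact_age": np.nan,
    "cohort_label": "unknown", "baseline_impaired_flag": False,
    "non_ad_dementia_flag": False, "mci_flag": np.nan,
}


def write_cohort_csv(subjects, visits, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects.to_csv(out / "subjects.csv", index=False)
    visits.to_csv(out / "visits.csv", index=False)
    return out / "subjects.csv", out / "visits.csv"


def load_cohort_csv(subjects_csv, visits_csv):
    subjects = pd.read_csv(subjects_csv)
    visits = pd.read_csv(visits_csv)
    findings = validate_input(subjects, visits)
    fatal = [f for f in findings if f["severity"] == "fatal"]
    if fatal:
        msgs = "; ".join(f["message"] for f in fatal)
        raise ValueError(f"input validation failed: {msgs}")
    for col, default in OPTIONAL_SUBJECT_DEFAULTS.items():
        if col not in subjects.columns:
            subjects[col] = default
    return subjects, visits, findings


def validate_input(subjects, visits):
    """Schema and invariant checks; returns a list of findings, each a
    dict with severity ('fatal' | 'warning'), message and offending rows."""
    findings = []

    def add(severity, message, rows=None):
        findings.append({"severity": severity, "message": message,
                         "rows": [] if rows is None else [int(r) for r in rows]})

    if isinstance(subjects, (str, Path)):
        subjects = pd.read_csv(subjects)
    if isinstance(visits, (str, Path)):
        visits = pd.read_csv(visits)

    for col in REQUIRED_SUBJECT_COLS:
        if col not in subjects.columns:
            add("fatal", f"subjects table missing required column {col!r}")
    for col in REQUIRED_VISIT_COLS:
        if col not in visits.columns:
            add("fatal", f"visits table missing required column {col!r}")
    if not any(c.startswith("domain_") for c in visits.columns):
        add("warning", "visits table has no domain_<d> composite columns")
    if findings and any(f["severity"] == "fatal" for f in findings):
        return findings

    bad = visits.index[pd.to_numeric(visits["visit_year"], errors="coerce") < 0]
    if len(bad):
        add("fatal", "negative visit_year", bad)

    if subjects["id"].duplicated().any():
        add("fatal", "duplicate subject ids",
            subjects.index[subjects["id"].duplicated()])

    is_ad = subjects["ad_status"] == syn.AD
    known = subjects["ad_status"].isin([syn.AD, syn.CN])
    if (~known).any():
        add("fatal", "unknown ad_status values", subjects.index[~known])
    if "onset_age" in subjects.columns:
        onset = pd.to_numeric(subjects["onset_age"], errors="coerce")
        bad = subjects.index[is_ad & onset.isna()]
        if len(bad):
            add("fatal", "incident_AD subject without onset_age", bad)
        bad = subjects.index[(~is_ad) & onset.notna()]
        if len(bad):
            add("fatal", "onset_age present for non-AD subject", bad)
        bad = subjects.index[is_ad & (onset <= subjects["baseline_age"])]
        if len(bad):
            add("fatal", "onset_age not after baseline_age", bad)
    elif is_ad.any():
        add("fatal", "incident_AD subjects present but no onset_age column")

    orphan = visits.index[~visits["id"].isin(subjects["id"])]
    if len(orphan):
        add("warning", "visits for unknown subject ids", orphan)

    merged = visits.merge(subjects[["id", "baseline_age"]], on="id", how="inner")
    drift = (merged["age_at_visit"]
             - merged["baseline_age"] - merged["visit_year"]).abs()
    bad = merged.index[drift > 1.0]
    if len(bad):
        add("warning", "age_at_visit deviates from baseline_age + visit_year by > 1 year", bad)
    return findings


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _setup_logging(out_dir):
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handler


def run(config: RunConfig) -> dict:
    """Execute one configured analysis; returns a dict of output paths
    and headline results."""
    out = Path(config.out_dir)
    handler = _setup_logging(out)
    try:
        return _run_inner(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_inner(config, out):
    rng = np.random.default_rng(config.seed)
    config.to_yaml(out / "config_echo.yaml")
    logger.info("run variant=%s seed=%d B=%d", config.variant, config.seed,
                config.bootstrap)

    if config.generator is not None:
        gen_cfg = syn.default_config(seed=config.seed, **config.generator)
        subjects, visits, _ = syn.generate_cohort(gen_cfg)
        logger.info("generated synthetic cohort: n=%d", len(subjects))
    else:
        subjects, visits, findings = load_cohort_csv(
            config.subjects_csv, config.visits_csv)
        for f in findings:
            logger.warning("input validation: %s (rows %s)", f["message"], f["rows"][:10])

    subjects, tally = ch.apply_lifetime_eligibility(subjects, visits)
    logger.info("lifetime eligibility tally: %s", tally)
    if config.variant in ("pre85", "pre90"):
        cut = 85 if config.variant == "pre85" else 90
        subjects, tally2 = ch.apply_age_bounded_eligibility(subjects, cut)
        logger.info("age-bounded (%d) tally: %s", cut, tally2)
        tally.update(tally2)

    domains = None if config.domains in ("all", "stepwise") else list(config.domains)
    results = {"out_dir": str(out), "tally": tally}

    stepwise_df = None
    if config.domains == "stepwise":
        stepwise_df = ev.stepwise_domain_selection(
            subjects, visits, B=0,
            rng=np.random.default_rng(config.seed + 11))
        stepwise_df.to_csv(out / "stepwise_path.csv", index=False)
        domains = list(stepwise_df["domains"].iloc[-1]) if len(stepwise_df) else None
        results["stepwise_domains"] = domains

    if config.variant in ("horizon5", "horizon10"):
        horizon = 5 if config.variant == "horizon5" else 10
        lm = ch.build_horizon_dataset(subjects, visits, horizon)
        res = ev.bootstrap_auc_ci(lm, domains, B=config.bootstrap,
                                  rng=rng, refit=config.refit_bootstrap)
        table = pd.DataFrame([res.as_row()])
        models = [ev.fit_dynamic_model(lm, domains)]
    else:
        subsample_k = {"visits3": 3, "visits4": 4}.get(config.variant)
        table, models = ev.auc_by_year(
            subjects, visits, domains, config.years,
            B=config.bootstrap, rng=rng, refit=config.refit_bootstrap,
            variant=config.variant, subsample_k=subsample_k)

    table.to_csv(out / "auc_by_year.csv", index=False)
    invalid = table.loc[~table["valid"].astype(bool)]
    if len(invalid):
        msg = f"{len(invalid)} landmark model(s) invalid (years {invalid['landmark_year'].tolist()})"
        if config.allow_partial:
            logger.warning(msg)
        else:
            raise RuntimeError(msg)

    final = next((m for m in reversed(models) if m is not None), None)
    if final is not None:
        cal = ev.calibration_deciles(final.risks.to_numpy(), final.y.to_numpy())
        cal.to_frame().to_csv(out / "calibration.csv", index=False)
        results["brier_final"] = cal.brier
        final.to_json(out / "model_final.json")

    baseline = visits.loc[visits["visit_year"] == visits.groupby("id")["visit_year"].transform("min")]
    try:
        ch.cohort_summary(subjects, baseline).to_csv(out / "cohort_table1.csv", index=False)
    except ValueError as err:
        logger.warning("cohort summary skipped: %s", err)

    if config.plots:
        _make_plots(table, final, out)

    _write_report(config, table, results, out)
    results["auc_table"] = table
    logger.info("run complete; outputs in %s", out)
    return results


def _make_plots(table, final, out):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ok = table["valid"].astype(bool)
    ax.plot(table.loc[ok, "landmark_year"], table.loc[ok, "auc"], "o-",
            label="combined model")
    ax.fill_between(table.loc[ok, "landmark_year"], table.loc[ok, "ci_low"],
                    table.loc[ok, "ci_high"], alpha=0.25)
    ax.set_xlabel("landmark year")
    ax.set_ylabel("AUC(t)")
    ax.set_ylim(0.4, 1.0)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "auc_trajectory.png", dpi=150)
    plt.close(fig)

    if final is not None:
        cal = ev.calibration_deciles(final.risks.to_numpy(), final.y.to_numpy())
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.plot(cal.mean_predicted, cal.observed_rate, "o-")
        ax.set_xlabel("mean predicted risk (decile)")
        ax.set_ylabel("observed AD rate")
        fig.tight_layout()
        fig.savefig(out / "calibration.png", dpi=150)
        plt.close(fig)


def _write_report(config, table, results, out):
    lines = [
        "# cogrisk run report",
        "",
        f"- variant: **{config.variant}**, seed {config.seed}, bootstrap B={config.bootstrap}",
        f"- exclusion tally: {results['tally']}",
        "",
        "## AUC by landmark year",
        "",
        table.to_markdown(index=False, floatfmt=".3f"),
        "",
    ]
    if "brier_final" in results:
        lines.append(f"Brier score of the final landmark model: {results['brier_final']:.3f}")
    (out / "report.md").write_text("\n".join(lines))
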