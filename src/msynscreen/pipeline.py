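"""End-to-end cohort analysis: CSV in, four report tables out.

The pipeline reads a participant-level CSV, excludes records that are
incomplete for the five-component rule (listwise deletion, every
exclusion logged with a reason), computes the seven indices, classifies
the syndrome, and produces:

* table1 — demographic counts/percentages by sex with chi-square tests
* table2 — component and syndrome prevalence by sex
* table3 — index means +/- SD by syndrome status and sex, with t-tests,
  and the BMI-class distribution
* table4 — per-index, per-stratum ROC summaries (AUC with CI, optimal
  cutoff, sensitivity/specificity, Youden J, discrimination band)

Everything is deterministic given the input, configuration and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atp3 import Atp3Classifier, Atp3Thresholds
from .descriptives import (
    bmi_category,
    chisq_independence,
    index_means_by_group,
    prevalence_summary,
)
from .indices import INDEX_NAMES, AnthropometricIndices, ParticipantRecord
from .roc import evaluate_index

__all__ = [
    "AnalysisConfig",
    "CohortReport",
    "COHORT_COLUMNS",
    "read_cohort",
    "as_records",
    "run_analysis",
    "write_report",
]

log = logging.getLogger("msynscreen")

#: Bit-exact cohort CSV schema.
COHORT_COLUMNS = [
    "id", "sex", "age", "height_cm", "weight_kg", "wc_cm",
    "sbp1", "sbp2", "dbp1", "dbp2",
    "fpg_mgdl", "tg_mgdl", "hdl_mgdl", "tc_mgdl",
    "treat_glucose", "treat_bp", "treat_tg", "treat_hdl",
    "smoking", "education", "income", "marital",
]

_MANDATORY = ["id", "sex", "height_cm", "weight_kg", "wc_cm", "sbp1", "dbp1",
              "fpg_mgdl", "tg_mgdl", "hdl_mgdl"]
_TREAT_COLS = ["treat_glucose", "treat_bp", "treat_tg", "treat_hdl"]
_POSITIVE = ["height_cm", "weight_kg", "wc_cm", "sbp1", "dbp1", "fpg_mgdl", "tg_mgdl", "hdl_mgdl"]


@dataclass
class AnalysisConfig:
    """Configuration of one pipeline run."""

    input: str | Path | None = None
    outdir: str | Path | None = None
    thresholds: Atp3Thresholds = field(default_factory=Atp3Thresholds)
    ci_method: str = "delong"
    strata: tuple = ("total", "male", "female")
    seed: int | None = None
    formats: tuple = ("csv", "json")

    def __post_init__(self):
        if self.ci_method not in ("delong", "hanley-mcneil", "bootstrap"):
            raise ValueError(f"unknown ci_method {self.ci_method!r}")
        bad = set(self.strata) - {"total", "male", "female"}
        if bad:
            raise ValueError(f"unknown strata {sorted(bad)}")


@dataclass
class CohortReport:
    """The four report tables plus the exclusion log."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    exclusions: pd.DataFrame
    n_analyzed: int
    n_input: int


def read_cohort(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a cohort CSV.

    Returns ``(valid_frame, exclusions)``.  A missing mandatory column
    is fatal; rows failing row-level validation (missing or
    non-positive analysis fields, unknown sex) are routed to the
    exclusion log with a reason, never silently dropped.  Missing
    treatment columns default to untreated with a logged notice;
    unknown extra columns are ignored with a notice.
    """
    raw = pd.read_csv(path, dtype={"id": str})
    missing_cols = [c for c in _MANDATORY if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"cohort CSV is missing mandatory column(s): {missing_cols}")
    extra = [c for c in raw.columns if c not in COHORT_COLUMNS]
    if extra:
        log.info("ignoring unknown columns: %s", extra)
    for col in _TREAT_COLS:
        if col not in raw.columns:
            log.info("column %r absent; defaulting to untreated", col)
            raw[col] = 0
    for col in ("sbp2", "dbp2", "tc_mgdl", "age"):
        if col not in raw.columns:
            raw[col] = np.nan

    reasons = pd.Series("", index=raw.index, dtype=object)
    for col in _MANDATORY[2:]:
        num = pd.to_numeric(raw[col], errors="coerce")
        bad = num.isna() | (num <= 0)
        reasons[bad & (reasons == "")] = f"missing or invalid {col.removesuffix('_mgdl').removesuffix('_cm').removesuffix('_kg')}"
        raw[col] = num
    bad_sex = ~raw["sex"].isin(["male", "female"])
    reasons[bad_sex & (reasons == "")] = "unknown sex"
    for col in ("sbp2", "dbp2", "tc_mgdl", "age"):
        raw[col] = pd.to_numeric(raw[col], errors="coerce")
    for col in _TREAT_COLS:
        raw[col] = pd.to_numeric(raw[col], errors="coerce").fillna(0).astype(int)

    excluded = reasons != ""
    exclusions = pd.DataFrame(
        {"id": raw.loc[excluded, "id"], "reason": reasons[excluded]}
    ).reset_index(drop=True)
    valid = raw.loc[~excluded].reset_index(drop=True)
    if excluded.any():
        log.info("excluded %d of %d rows (listwise)", int(excluded.sum()), len(raw))
    return valid, exclusions


def as_records(frame: pd.DataFrame) -> list[ParticipantRecord]:
    """Convert a validated cohort frame to ParticipantRecord objects."""

    def _opt(v):
        return None if pd.isna(v) else float(v)

    out = []
    for row in frame.itertuples(index=False):
        out.append(
            ParticipantRecord(
                id=row.id,
                sex=row.sex,
                age=_opt(row.age) or 0.0,
                height=float(row.height_cm),
                weight=float(row.weight_kg),
                wc=float(row.wc_cm),
                sbp1=float(row.sbp1),
                sbp2=_opt(row.sbp2),
                dbp1=float(row.dbp1),
                dbp2=_opt(row.dbp2),
                fpg=float(row.fpg_mgdl),
                tg=float(row.tg_mgdl),
                hdl=float(row.hdl_mgdl),
                tc=_opt(row.tc_mgdl),
                treat_glucose=bool(row.treat_glucose),
                treat_bp=bool(row.treat_bp),
                treat_tg=bool(row.treat_tg),
                treat_hdl=bool(row.treat_hdl),
            )
        )
    return out


def _demographics_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages by sex for categorical covariates, with
    chi-square contrasts (skipped when a variable is absent/constant)."""
    rows = []
    male = frame["sex"] == "male"
    for var in ("smoking", "education", "income", "marital"):
        if var not in frame.columns or frame[var].isna().all():
            continue
        levels = frame[var].astype(str)
        tab = pd.crosstab(levels, frame["sex"])
        p = np.nan
        if tab.shape[0] >= 2 and tab.shape[1] == 2 and (tab.to_numpy() >= 0).all():
            try:
                _, _, p = chisq_independence(tab.to_numpy())
            except ValueError:
                p = np.nan
        for level in tab.index:
            n_total = int(tab.loc[level].sum())
            rows.append(
                {
                    "variable": var,
                    "level": level,
                    "n_total": n_total,
                    "pct_total": 100.0 * n_total / len(frame),
                    "n_male": int(tab.loc[level].get("male", 0)),
                    "n_female": int(tab.loc[level].get("female", 0)),
                    "p": p,
                }
            )
    rows.append(
        {
            "variable": "sex",
            "level": "male",
            "n_total": int(male.sum()),
            "pct_total": 100.0 * male.mean(),
            "n_male": int(male.sum()),
            "n_female": 0,
            "p": np.nan,
        }
    )
    return pd.DataFrame(rows)


def run_analysis(config: AnalysisConfig, frame: pd.DataFrame | None = None) -> CohortReport:
    """Run the full analysis and return the report tables.

    ``frame`` may be passed directly (already validated); otherwise
    ``config.input`` is read via :func:`read_cohort`.
    """
    if frame is None:
        if config.input is None:
            raise ValueError("config.input or an in-memory frame is required")
        frame, exclusions = read_cohort(config.input)
    else:
        exclusions = pd.DataFrame(columns=["id", "reason"])
    n_input = len(frame) + len(exclusions)
    if len(frame) == 0:
        raise ValueError("no analyzable records")

    clf = Atp3Classifier(**_thresholds_params(config.thresholds))
    flags = clf.fit(frame).flag_frame(frame)
    msyn = flags["msyn"].to_numpy()
    panel = AnthropometricIndices().fit_transform(frame)

    table1 = _demographics_table(frame)
    table2 = prevalence_summary(flags, frame["sex"])
    table3 = index_means_by_group(panel, msyn, frame["sex"])
    table3_bmi = _bmi_class_table(panel, msyn, frame["sex"])
    table3 = pd.concat([table3, table3_bmi], ignore_index=True)

    rows = []
    masks = {"total": np.ones(len(frame), bool),
             "male": (frame["sex"] == "male").to_numpy(),
             "female": (frame["sex"] == "female").to_numpy()}
    for stratum in config.strata:
        mask = masks[stratum]
        y = msyn[mask]
        for name in INDEX_NAMES:
            scores = panel.loc[mask, name].to_numpy(dtype=float)
            base = {"stratum": stratum, "index": name}
            if y.size == 0 or y.all() or not y.any():
                rows.append({**base, "note": "not estimable: single-class labels"})
                continue
            summary = evaluate_index(
                scores, y, ci_method=config.ci_method, seed=config.seed
            )
            rows.append({**base, **summary.as_dict(), "note": ""})
    table4 = pd.DataFrame(rows)

    return CohortReport(
        table1=table1,
        table2=table2,
        table3=table3,
        table4=table4,
        exclusions=exclusions,
        n_analyzed=len(frame),
        n_input=n_input,
    )


def _thresholds_params(thr: Atp3Thresholds) -> dict:
    return {
        "wc_male": thr.wc_male, "wc_female": thr.wc_female, "fpg": thr.fpg,
        "sbp": thr.sbp, "dbp": thr.dbp, "tg": thr.tg,
        "hdl_male": thr.hdl_male, "hdl_female": thr.hdl_female,
    }


def _bmi_class_table(panel, msyn, sex) -> pd.DataFrame:
    cats = pd.Series(bmi_category(panel["bmi"].to_numpy()), index=panel.index)
    rows = []
    sex = np.asarray(sex)
    for stratum, mask in (
        ("total", np.ones(len(panel), bool)),
        ("male", sex == "male"),
        ("female", sex == "female"),
    ):
        sub = cats[mask]
        status = np.asarray(msyn)[mask]
        for cat in ("underweight", "normal", "overweight", "obese"):
            in_cat = sub == cat
            n = int(in_cat.sum())
            rows.append(
                {
                    "stratum": stratum,
                    "index": f"bmi_class_{cat}",
                    "mean_msyn": float(np.sum(in_cat & status)),
                    "sd_msyn": np.nan,
                    "mean_no_msyn": float(np.sum(in_cat & ~status)),
                    "sd_no_msyn": np.nan,
                    "t": np.nan,
                    "df": np.nan,
                    "p": np.nan,
                }
            )
    return pd.DataFrame(rows)


def write_report(report: CohortReport, outdir, config: AnalysisConfig | None = None) -> None:
    """Write tables as CSV (and a JSON summary) plus a run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("table1", "table2", "table3", "table4", "exclusions"):
        getattr(report, name).to_csv(outdir / f"{name}.csv", index=False)
    summary = {
        "n_input": report.n_input,
        "n_analyzed": report.n_analyzed,
        "n_excluded": len(report.exclusions),
        "table4": report.table4.to_dict(orient="records"),
    }
    (outdir / "report.json").write_text(json.dumps(summary, indent=2, default=str))
    if config is not None:
        import msynscreen

        manifest = {
            "package": "msynscreen",
            "version": getattr(msynscreen, "__version__", "unknown"),
            "ci_method": config.ci_method,
            "strata": list(config.strata),
            "seed": config.seed,
            "thresholds": _thresholds_params(config.thresholds),
            "input": str(config.input) if config.input else None,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("report written to %s", outdir)
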