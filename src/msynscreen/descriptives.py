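"""Stratified cohort descriptives: contingency tests, mean contrasts,
prevalence tables and BMI categories.

The statistical conventions match what a standard clinical-statistics
workflow (SPSS-style) reports by default: Pearson chi-square without
continuity correction for r x c tables, and the pooled-variance
two-sample t-test (Welch available via ``equal_var=False``).
Percentages are reported to one decimal place.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .indices import INDEX_NAMES

__all__ = [
    "chisq_independence",
    "two_sample_ttest",
    "prevalence_summary",
    "bmi_category",
    "index_means_by_group",
    "BMI_CATEGORIES",
]

BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")
# WHO cut-points; 18.5/25/30 left-closed on the heavier side
_BMI_EDGES = (18.5, 25.0, 30.0)


def chisq_independence(table):
    """Pearson chi-square test of independence on an r x c table.

    No continuity correction, any table at least 2 x 2.  Returns
    ``(statistic, df, p)``.  Zero expected counts are an error (merge
    sparse categories first).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2 x 2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    expected = stats.contingency.expected_freq(obs)
    if np.any(expected <= 0):
        raise ValueError("zero expected count; merge sparse categories before testing")
    chi2, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), int(dof), float(p)


def two_sample_ttest(x, y, equal_var: bool = True):
    """Two-sided independent-samples t-test; pooled variance by default.

    Returns ``(t, df, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bmi_category(bmi):
    """WHO BMI class: <18.5 underweight, [18.5,25) normal,
    [25,30) overweight, >=30 obese.  Scalar or array."""
    arr = np.asarray(bmi, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("bmi must be positive and finite")
    idx = np.searchsorted(_BMI_EDGES, arr, side="right")
    cats = np.asarray(BMI_CATEGORIES, dtype=object)[idx]
    return cats if arr.ndim else str(cats)


def prevalence_summary(flags: pd.DataFrame, sex: pd.Series | None = None) -> pd.DataFrame:
    """Prevalence of the syndrome and each abnormal component.

    ``flags`` is the classifier's flag frame (boolean component columns
    plus ``count`` and ``msyn``).  If ``sex`` is given, the output is
    stratified total / male / female; empty strata are reported as
    zero with a warning.  Percentages are within-stratum.
    """
    if len(flags) == 0:
        raise ValueError("empty cohort")
    strata = {"total": np.ones(len(flags), dtype=bool)}
    if sex is not None:
        sex = np.asarray(sex)
        strata["male"] = sex == "male"
        strata["female"] = sex == "female"
    items = [c for c in ("wc_abn", "fpg_abn", "bp_abn", "tg_abn", "hdl_abn", "msyn") if c in flags.columns]
    rows = []
    for name, mask in strata.items():
        sub = flags.loc[mask]
        n = len(sub)
        if n == 0:
            warnings.warn(f"stratum {name!r} is empty", stacklevel=2)
        for item in items:
            k = int(sub[item].sum()) if n else 0
            rows.append(
                {
                    "stratum": name,
                    "item": item,
                    "n_abnormal": k,
                    "n": n,
                    "pct": 100.0 * k / n if n else 0.0,
                }
            )
        # component-count distribution 0/1/2/3+
        if n:
            counts = sub["count"].to_numpy()
            for label, k in zip(
                ("0", "1", "2", "3+"),
                (
                    int(np.sum(counts == 0)),
                    int(np.sum(counts == 1)),
                    int(np.sum(counts == 2)),
                    int(np.sum(counts >= 3)),
                ),
            ):
                rows.append(
                    {
                        "stratum": name,
                        "item": f"components_{label}",
                        "n_abnormal": k,
                        "n": n,
                        "pct": 100.0 * k / n,
                    }
                )
    return pd.DataFrame(rows)


def index_means_by_group(
    panel: pd.DataFrame,
    msyn,
    sex=None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Mean +/- SD of each index by syndrome status, with t-tests.

    One row per (stratum, index): means and SDs for the
    syndrome-present and -absent groups and the two-sided pooled t-test
    p-value, mirroring the usual case/non-case descriptive table.
    """
    msyn = np.asarray(msyn).astype(bool)
    strata = {"total": np.ones(len(panel), dtype=bool)}
    if sex is not None:
        sex = np.asarray(sex)
        strata = {"total": strata["total"], "male": sex == "male", "female": sex == "female"}
    rows = []
    for name, mask in strata.items():
        sub = panel.loc[mask]
        status = msyn[mask]
        for col in INDEX_NAMES:
            if col not in panel.columns:
                continue
            present = sub.loc[status, col].to_numpy(dtype=float)
            absent = sub.loc[~status, col].to_numpy(dtype=float)
            if present.size >= 2 and absent.size >= 2:
                t, df, p = two_sample_ttest(present, absent, equal_var=equal_var)
            else:
                t = df = p = np.nan
            rows.append(
                {
                    "stratum": name,
                    "index": col,
                    "mean_msyn": present.mean() if present.size else np.nan,
                    "sd_msyn": present.std(ddof=1) if present.size > 1 else np.nan,
                    "mean_no_msyn": absent.mean() if absent.size else np.nan,
                    "sd_no_msyn": absent.std(ddof=1) if absent.size > 1 else np.nan,
                    "t": t,
                    "df": df,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)
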