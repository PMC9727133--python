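"""Rule-based metabolic-syndrome classification (NCEP ATP III).

A subject is diagnosed with metabolic syndrome when at least three of
five components are abnormal:

* central obesity     — WC >= 102 cm (men) / >= 88 cm (women)
* hyperglycemia       — FPG >= 100 mg/dL, or on glucose-lowering drugs
* elevated BP         — SBP >= 130 or DBP >= 85 mmHg, or on
                        antihypertensive drugs
* hypertriglyceridemia— TG >= 150 mg/dL, or on TG-lowering drugs
* low HDL-C           — HDL <= 40 mg/dL (men) / <= 50 mg/dL (women), or
                        on HDL-raising drugs

Every boundary is inclusive at the printed threshold (including the
"<=" for HDL).  Blood pressure uses the mean of the two seated
readings; if the second reading is missing the single reading is used
with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .indices import ParticipantRecord

__all__ = [
    "Atp3Thresholds",
    "ComponentFlags",
    "MissingComponentError",
    "Atp3Classifier",
    "mean_bp",
    "component_flags",
    "component_distribution",
    "COMPONENT_NAMES",
]

COMPONENT_NAMES = ("wc_abn", "fpg_abn", "bp_abn", "tg_abn", "hdl_abn")


class MissingComponentError(ValueError):
    """A record lacks a field required by the five-component rule."""

    def __init__(self, record_id, field):
        self.record_id = record_id
        self.field = field
        super().__init__(f"record {record_id}: missing {field}")


@dataclass(frozen=True)
class Atp3Thresholds:
    """Component cutoffs.  All inclusive at the stated value.

    ``hdl_*`` are *upper* bounds (abnormal at or below); everything
    else is a lower bound (abnormal at or above).
    """

    wc_male: float = 102.0    # cm
    wc_female: float = 88.0   # cm
    fpg: float = 100.0        # mg/dL
    sbp: float = 130.0        # mmHg
    dbp: float = 85.0         # mmHg
    tg: float = 150.0         # mg/dL
    hdl_male: float = 40.0    # mg/dL
    hdl_female: float = 50.0  # mg/dL

    def __post_init__(self):
        for f in (
            "wc_male", "wc_female", "fpg", "sbp", "dbp", "tg", "hdl_male", "hdl_female",
        ):
            if getattr(self, f) <= 0:
                raise ValueError(f"threshold {f} must be positive")

    def replace(self, **overrides) -> "Atp3Thresholds":
        return replace(self, **overrides)


@dataclass(frozen=True)
class ComponentFlags:
    """Per-subject component verdicts, abnormal count and diagnosis."""

    wc_abn: bool
    fpg_abn: bool
    bp_abn: bool
    tg_abn: bool
    hdl_abn: bool

    @property
    def count(self) -> int:
        return int(self.wc_abn) + int(self.fpg_abn) + int(self.bp_abn) + int(self.tg_abn) + int(self.hdl_abn)

    @property
    def msyn(self) -> bool:
        return self.count >= 3

    def as_dict(self) -> dict:
        return {
            **{name: getattr(self, name) for name in COMPONENT_NAMES},
            "count": self.count,
            "msyn": self.msyn,
        }


def mean_bp(sbp1, sbp2, dbp1, dbp2):
    """Average the two seated blood-pressure readings per channel.

    A missing (None/NaN) second reading falls back to the first with a
    warning; the first reading is mandatory.
    """

    def _one(first, second, channel):
        if first is None or not np.isfinite(first) or first <= 0:
            raise ValueError(f"{channel}: first reading required and positive")
        if second is None or not np.isfinite(second):
            warnings.warn(
                f"{channel}: second reading missing, using the single reading",
                stacklevel=3,
            )
            return float(first)
        if second <= 0:
            raise ValueError(f"{channel}: readings must be positive")
        return (float(first) + float(second)) / 2.0

    return _one(sbp1, sbp2, "sbp"), _one(dbp1, dbp2, "dbp")


def component_flags(
    record: ParticipantRecord, thresholds: Atp3Thresholds | None = None
) -> ComponentFlags:
    """Evaluate the five ATP III components for one record."""
    thr = thresholds or Atp3Thresholds()
    for field in ("wc", "fpg", "tg", "hdl", "sbp1", "dbp1"):
        v = getattr(record, field)
        if v is None or not np.isfinite(v):
            raise MissingComponentError(record.id, field)
    sbp, dbp = mean_bp(record.sbp1, record.sbp2, record.dbp1, record.dbp2)
    male = record.sex == "male"
    return ComponentFlags(
        wc_abn=record.wc >= (thr.wc_male if male else thr.wc_female),
        fpg_abn=record.fpg >= thr.fpg or record.treat_glucose,
        bp_abn=sbp >= thr.sbp or dbp >= thr.dbp or record.treat_bp,
        tg_abn=record.tg >= thr.tg or record.treat_tg,
        hdl_abn=record.hdl <= (thr.hdl_male if male else thr.hdl_female) or record.treat_hdl,
    )


def component_distribution(flags) -> pd.DataFrame:
    """Count subjects with 0 / 1 / 2 / >=3 abnormal components.

    Accepts a sequence of :class:`ComponentFlags` or a frame with a
    ``count`` column.  Returns a frame indexed ``0, 1, 2, 3+`` with
    ``n`` and ``pct`` columns; percentages are of the cohort and sum to
    100 up to rounding.
    """
    if isinstance(flags, pd.DataFrame):
        counts = flags["count"].to_numpy()
    else:
        counts = np.array([f.count for f in flags])
    if counts.size == 0:
        raise ValueError("empty cohort")
    bins = [
        int(np.sum(counts == 0)),
        int(np.sum(counts == 1)),
        int(np.sum(counts == 2)),
        int(np.sum(counts >= 3)),
    ]
    n = counts.size
    return pd.DataFrame(
        {"n": bins, "pct": [100.0 * b / n for b in bins]},
        index=pd.Index(["0", "1", "2", "3+"], name="components"),
    )


class Atp3Classifier:
    """Deterministic rule classifier with the scikit-learn protocol.

    Parameters mirror :class:`Atp3Thresholds`.  ``fit`` only validates
    (the rule has nothing to learn); ``predict`` returns the boolean
    metabolic-syndrome diagnosis; :meth:`flag_frame` exposes the
    per-component verdicts.

    The expected input is a cohort frame in the pipeline CSV schema
    (``sex``, ``wc_cm``, ``fpg_mgdl``, ``sbp1`` ... ``treat_hdl``).
    """

    def __init__(
        self,
        wc_male=102.0,
        wc_female=88.0,
        fpg=100.0,
        sbp=130.0,
        dbp=85.0,
        tg=150.0,
        hdl_male=40.0,
        hdl_female=50.0,
    ):
        self.wc_male = wc_male
        self.wc_female = wc_female
        self.fpg = fpg
        self.sbp = sbp
        self.dbp = dbp
        self.tg = tg
        self.hdl_male = hdl_male
        self.hdl_female = hdl_female

    _param_names = (
        "wc_male", "wc_female", "fpg", "sbp", "dbp", "tg", "hdl_male", "hdl_female",
    )

    def get_params(self, deep=True):
        return {name: getattr(self, name) for name in self._param_names}

    def set_params(self, **params):
        for name, value in params.items():
            if name not in self._param_names:
                raise ValueError(f"invalid parameter {name!r}")
            setattr(self, name, value)
        return self

    @property
    def thresholds(self) -> Atp3Thresholds:
        return Atp3Thresholds(**self.get_params())

    def fit(self, X, y=None):
        _ = self.thresholds  # construction validates positivity
        missing = [c for c in ("sex", "wc_cm", "fpg_mgdl", "tg_mgdl", "hdl_mgdl", "sbp1", "dbp1") if c not in X.columns]
        if missing:
            raise KeyError(f"missing required columns: {missing}")
        self.classes_ = np.array([False, True])
        self.n_features_in_ = X.shape[1]
        return self

    def _bp_means(self, X):
        sbp1 = X["sbp1"].to_numpy(dtype=float)
        dbp1 = X["dbp1"].to_numpy(dtype=float)
        sbp2 = X["sbp2"].to_numpy(dtype=float) if "sbp2" in X.columns else np.full_like(sbp1, np.nan)
        dbp2 = X["dbp2"].to_numpy(dtype=float) if "dbp2" in X.columns else np.full_like(dbp1, np.nan)
        n_single = int(np.sum(~np.isfinite(sbp2)) + np.sum(~np.isfinite(dbp2)))
        if n_single:
            warnings.warn(
                f"{n_single} blood-pressure channels have a single reading; using it as the mean",
                stacklevel=3,
            )
        sbp = np.where(np.isfinite(sbp2), (sbp1 + sbp2) / 2.0, sbp1)
        dbp = np.where(np.isfinite(dbp2), (dbp1 + dbp2) / 2.0, dbp1)
        return sbp, dbp

    def _treat(self, X, col):
        if col in X.columns:
            return X[col].fillna(0).astype(float).to_numpy() > 0
        warnings.warn(f"column {col!r} absent; assuming untreated", stacklevel=3)
        return np.zeros(len(X), dtype=bool)

    def flag_frame(self, X) -> pd.DataFrame:
        """Per-component booleans plus ``count`` and ``msyn`` columns."""
        thr = self.thresholds
        male = X["sex"].to_numpy() == "male"
        sbp, dbp = self._bp_means(X)
        flags = pd.DataFrame(index=X.index)
        flags["wc_abn"] = X["wc_cm"].to_numpy(dtype=float) >= np.where(male, thr.wc_male, thr.wc_female)
        flags["fpg_abn"] = (X["fpg_mgdl"].to_numpy(dtype=float) >= thr.fpg) | self._treat(X, "treat_glucose")
        flags["bp_abn"] = (sbp >= thr.sbp) | (dbp >= thr.dbp) | self._treat(X, "treat_bp")
        flags["tg_abn"] = (X["tg_mgdl"].to_numpy(dtype=float) >= thr.tg) | self._treat(X, "treat_tg")
        flags["hdl_abn"] = (
            X["hdl_mgdl"].to_numpy(dtype=float) <= np.where(male, thr.hdl_male, thr.hdl_female)
        ) | self._treat(X, "treat_hdl")
        flags["count"] = flags[list(COMPONENT_NAMES)].sum(axis=1).astype(int)
        flags["msyn"] = flags["count"] >= 3
        return flags

    def predict(self, X):
        if not hasattr(self, "classes_"):
            self.fit(X)
        return self.flag_frame(X)["msyn"].to_numpy()

    def fit_predict(self, X, y=None):
        return self.fit(X, y).predict(X)
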