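"""Anthropometric screening indices.

Seven indices are used to screen for metabolic syndrome from simple
anthropometry and a fasting lipid panel:

* BMI  — body mass index, weight / height**2 (kg/m**2)
* WC   — waist circumference (cm, carried through unchanged)
* WHtR — waist-to-height ratio (dimensionless)
* ABSI — a body shape index, WC normalised by height**0.5 * BMI**(2/3)
         (units m**(11/6) kg**(-2/3); WC and height in metres)
* BRI  — body roundness index, an eccentricity transform of WC and height
         (dimensionless, range -1.3 .. 364.2)
* CI   — conicity index, WC relative to a bicone trunk model
         (units m**(3/2) kg**(-1/2))
* VAI  — visceral adiposity index, a sex-specific composite of WC, BMI,
         triglycerides and HDL-C (biomarkers in mmol/L; dimensionless)

All calculators accept scalars or numpy arrays.  The canonical input
units are the cohort CSV's: cm for lengths, kg for weight, mg/dL for
biomarkers; metre conversions happen inside each formula.  Non-positive
or geometrically impossible inputs raise :class:`DomainError` rather
than propagating NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

import numpy as np

__all__ = [
    "DomainError",
    "ParticipantRecord",
    "IndexPanel",
    "AnthropometricIndices",
    "compute_bmi",
    "compute_whtr",
    "compute_absi",
    "compute_bri",
    "compute_ci",
    "compute_vai",
    "mgdl_to_mmol",
    "compute_index_panel",
    "INDEX_NAMES",
    "REPORT_DECIMALS",
]

#: Canonical index column order used throughout the package.
INDEX_NAMES = ("bmi", "wc", "whtr", "absi", "bri", "ci", "vai")

#: Decimal places used when *reporting* each index (full precision is
#: always kept internally).
REPORT_DECIMALS = {
    "bmi": 2,
    "wc": 2,
    "whtr": 3,
    "absi": 4,
    "bri": 2,
    "ci": 2,
    "vai": 2,
}

# mg/dL -> mmol/L divisors (molar mass based)
_MGDL_DIVISOR = {
    "glucose": 18.016,
    "tg": 88.57,
    "hdl": 38.67,
    "cholesterol": 38.67,
}


class DomainError(ValueError):
    """A measurement is outside the physical domain of a formula."""


def _require_positive(**named):
    for name, value in named.items():
        arr = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise DomainError(f"{name} must be finite")
        if np.any(arr <= 0):
            raise DomainError(f"{name} must be positive")


def _maybe_scalar(x):
    x = np.asarray(x)
    return x.item() if x.ndim == 0 else x


def compute_bmi(weight_kg, height_cm):
    """Body mass index in kg/m**2."""
    _require_positive(weight=weight_kg, height=height_cm)
    h_m = np.asarray(height_cm, dtype=float) / 100.0
    return _maybe_scalar(np.asarray(weight_kg, dtype=float) / h_m**2)


def compute_whtr(wc_cm, height_cm):
    """Waist-to-height ratio; unit invariant as long as both agree."""
    _require_positive(wc=wc_cm, height=height_cm)
    return _maybe_scalar(np.asarray(wc_cm, dtype=float) / np.asarray(height_cm, dtype=float))


def compute_absi(wc_cm, height_cm, bmi):
    """A Body Shape Index: WC_m / (height_m**0.5 * BMI**(2/3))."""
    _require_positive(wc=wc_cm, height=height_cm, bmi=bmi)
    wc_m = np.asarray(wc_cm, dtype=float) / 100.0
    h_m = np.asarray(height_cm, dtype=float) / 100.0
    return _maybe_scalar(wc_m / (np.sqrt(h_m) * np.asarray(bmi, dtype=float) ** (2.0 / 3.0)))


def compute_bri(wc_cm, height_cm):
    """Body roundness index.

    364.2 - 365.5 * sqrt(1 - (WC / 2pi)**2 / (0.5 * height)**2), both in
    the same length unit.  The square root requires WC < pi * height
    (the waist of a sphere of the person's height); larger waists are a
    geometric impossibility and raise :class:`DomainError`.
    """
    _require_positive(wc=wc_cm, height=height_cm)
    wc = np.asarray(wc_cm, dtype=float)
    h = np.asarray(height_cm, dtype=float)
    if np.any(wc > np.pi * h):
        raise DomainError("waist exceeds spherical bound (wc > pi * height)")
    ecc = (wc / (2.0 * np.pi)) ** 2 / (0.5 * h) ** 2
    return _maybe_scalar(364.2 - 365.5 * np.sqrt(np.clip(1.0 - ecc, 0.0, None)))


def compute_ci(wc_cm, weight_kg, height_cm):
    """Conicity index: WC_m / (0.109 * sqrt(weight_kg / height_m))."""
    _require_positive(wc=wc_cm, weight=weight_kg, height=height_cm)
    wc_m = np.asarray(wc_cm, dtype=float) / 100.0
    h_m = np.asarray(height_cm, dtype=float) / 100.0
    return _maybe_scalar(wc_m / (0.109 * np.sqrt(np.asarray(weight_kg, dtype=float) / h_m)))


def compute_vai(sex, wc_cm, bmi, tg_mmol, hdl_mmol):
    """Visceral adiposity index (sex-specific; TG and HDL in mmol/L).

    male:   WC/(39.68 + 1.88*BMI) * (TG/1.03) * (1.31/HDL)
    female: WC/(36.58 + 1.89*BMI) * (TG/0.81) * (1.52/HDL)

    The linear WC term uses the "+" denominator of the original
    definition; a subtracted form would be negative for typical adults.
    """
    _require_positive(wc=wc_cm, bmi=bmi, tg=tg_mmol, hdl=hdl_mmol)
    sex_arr = np.asarray(sex)
    valid = np.isin(sex_arr, ("male", "female"))
    if not np.all(valid):
        bad = np.unique(sex_arr[~valid]) if sex_arr.ndim else sex_arr
        raise ValueError(f"unknown sex: {bad!r} (expected 'male' or 'female')")
    wc = np.asarray(wc_cm, dtype=float)
    b = np.asarray(bmi, dtype=float)
    tg = np.asarray(tg_mmol, dtype=float)
    hdl = np.asarray(hdl_mmol, dtype=float)
    male = sex_arr == "male"
    vai_m = wc / (39.68 + 1.88 * b) * (tg / 1.03) * (1.31 / hdl)
    vai_f = wc / (36.58 + 1.89 * b) * (tg / 0.81) * (1.52 / hdl)
    return _maybe_scalar(np.where(male, vai_m, vai_f))


def mgdl_to_mmol(value_mgdl, analyte: str):
    """Convert mg/dL to mmol/L for glucose, triglycerides or cholesterol.

    Divisors: glucose 18.016, tg 88.57, hdl/cholesterol 38.67.
    """
    try:
        div = _MGDL_DIVISOR[analyte]
    except KeyError:
        raise ValueError(
            f"unknown analyte {analyte!r}; expected one of {sorted(_MGDL_DIVISOR)}"
        ) from None
    arr = np.asarray(value_mgdl, dtype=float)
    if np.any(arr < 0):
        raise DomainError("concentration must be non-negative")
    return _maybe_scalar(arr / div)


@dataclass(frozen=True)
class ParticipantRecord:
    """One subject's raw measurements.

    Lengths in cm, weight in kg, blood pressure in mmHg, biomarkers in
    mg/dL.  ``sbp2``/``dbp2`` may be None when only one blood-pressure
    reading was taken.  Categorical covariates are carried for
    descriptive tables only.
    """

    id: str
    sex: str
    age: float
    height: float
    weight: float
    wc: float
    sbp1: float
    dbp1: float
    fpg: float
    tg: float
    hdl: float
    sbp2: Optional[float] = None
    dbp2: Optional[float] = None
    tc: Optional[float] = None
    treat_glucose: bool = False
    treat_bp: bool = False
    treat_tg: bool = False
    treat_hdl: bool = False
    smoking: Optional[str] = None
    education: Optional[str] = None
    income: Optional[str] = None
    marital: Optional[str] = None

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError(f"record {self.id}: sex must be 'male' or 'female'")
        for name in ("height", "weight", "wc", "fpg", "tg", "hdl"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v) or v <= 0:
                raise DomainError(f"record {self.id}: {name} must be positive")


@dataclass(frozen=True)
class IndexPanel:
    """The seven computed index values for one subject."""

    bmi: float
    wc: float
    whtr: float
    absi: float
    bri: float
    ci: float
    vai: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_index_panel(record: ParticipantRecord) -> IndexPanel:
    """Compute all seven indices for one record.

    VAI is evaluated on mmol/L conversions of the record's mg/dL TG and
    HDL.  Domain errors are re-raised with the record id attached.
    """
    try:
        bmi = compute_bmi(record.weight, record.height)
        return IndexPanel(
            bmi=bmi,
            wc=record.wc,
            whtr=compute_whtr(record.wc, record.height),
            absi=compute_absi(record.wc, record.height, bmi),
            bri=compute_bri(record.wc, record.height),
            ci=compute_ci(record.wc, record.weight, record.height),
            vai=compute_vai(
                record.sex,
                record.wc,
                bmi,
                mgdl_to_mmol(record.tg, "tg"),
                mgdl_to_mmol(record.hdl, "hdl"),
            ),
        )
    except (DomainError, ValueError) as exc:
        raise type(exc)(f"record {record.id}: {exc}") from exc


class AnthropometricIndices:
    """Stateless transformer: raw cohort frame -> seven-index frame.

    Follows the scikit-learn transformer protocol (``fit`` validates and
    records the input columns, ``transform`` computes) so it composes
    with :class:`sklearn.pipeline.Pipeline`.  Expects the pipeline CSV
    column names: ``sex``, ``height_cm``, ``weight_kg``, ``wc_cm``,
    ``tg_mgdl``, ``hdl_mgdl``.
    """

    _required = ("sex", "height_cm", "weight_kg", "wc_cm", "tg_mgdl", "hdl_mgdl")

    def get_params(self, deep=True):  # no hyper-parameters
        return {}

    def set_params(self, **params):
        if params:
            raise ValueError(f"AnthropometricIndices takes no parameters: {params}")
        return self

    def fit(self, X, y=None):
        missing = [c for c in self._required if c not in X.columns]
        if missing:
            raise KeyError(f"missing required columns: {missing}")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        import pandas as pd

        if not hasattr(self, "feature_names_in_"):
            self.fit(X)
        sex = X["sex"].to_numpy()
        h = X["height_cm"].to_numpy(dtype=float)
        w = X["weight_kg"].to_numpy(dtype=float)
        wc = X["wc_cm"].to_numpy(dtype=float)
        tg = mgdl_to_mmol(X["tg_mgdl"].to_numpy(dtype=float), "tg")
        hdl = mgdl_to_mmol(X["hdl_mgdl"].to_numpy(dtype=float), "hdl")
        bmi = compute_bmi(w, h)
        out = pd.DataFrame(
            {
                "bmi": bmi,
                "wc": wc,
                "whtr": compute_whtr(wc, h),
                "absi": compute_absi(wc, h, bmi),
                "bri": compute_bri(wc, h),
                "ci": compute_ci(wc, w, h),
                "vai": compute_vai(sex, wc, bmi, tg, hdl),
            },
            index=X.index,
        )
        return out

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(INDEX_NAMES, dtype=object)
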