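"""Synthetic cohorts with the statistical structure the analysis assumes.

Two generators are provided:

* :func:`generate_binormal` — a known-truth score model (controls
  N(mu0, sigma0), cases N(mu1, sigma1)) whose exact AUC is the closed
  form Phi((mu1 - mu0) / sqrt(sigma0**2 + sigma1**2)); used to validate
  the ROC engine end to end.

* :func:`generate_cohort` — a sex-stratified participant-level cohort.
  Each subject belongs to a latent "syndrome-prone" or "non-prone"
  subpopulation; anthropometry (height, BMI, waist circumference) is a
  truncated trivariate normal whose class-conditional means and SDs
  default to the case/non-case summary statistics of the motivating
  cross-sectional study, and biomarkers (fasting glucose, log-normal
  triglycerides, HDL-C, bivariate-normal blood pressure) are shifted
  between the latent classes.  The shift magnitude is calibrated by
  bisection so that rule-based classification of the *generated* data
  reproduces the target syndrome prevalence (default 42.5%).

The generator reproduces first and second moments and one latent
mixture only; it does not attempt to copy the real joint dependence
structure, which the source summaries do not identify.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .atp3 import Atp3Classifier

__all__ = [
    "BinormalSpec",
    "CohortSpec",
    "CalibrationError",
    "analytic_auc_binormal",
    "generate_binormal",
    "generate_cohort",
    "fixture_cohort",
    "FIXTURE_EXPECTED_PANEL",
    "FIXTURE_EXPECTED_FLAGS",
]


class CalibrationError(RuntimeError):
    """Prevalence calibration could not reach the target."""


@dataclass(frozen=True)
class BinormalSpec:
    """Equal-or-unequal-variance binormal score model."""

    mu0: float = 0.0
    mu1: float = 1.0
    sigma0: float = 1.0
    sigma1: float = 1.0
    n0: int = 100
    n1: int = 100
    seed: int | None = None

    def __post_init__(self):
        if self.sigma0 <= 0 or self.sigma1 <= 0:
            raise ValueError("sigmas must be positive")
        if self.n0 < 1 or self.n1 < 1:
            raise ValueError("group sizes must be >= 1")


def analytic_auc_binormal(spec: BinormalSpec) -> float:
    """Closed-form AUC of the binormal model:
    Phi((mu1 - mu0) / sqrt(sigma0**2 + sigma1**2))."""
    return float(
        stats.norm.cdf((spec.mu1 - spec.mu0) / np.hypot(spec.sigma0, spec.sigma1))
    )


def generate_binormal(spec: BinormalSpec):
    """Draw scores and labels from the binormal model.

    Returns ``(scores, labels)`` with controls first; reproducible
    under a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    controls = rng.normal(spec.mu0, spec.sigma0, spec.n0)
    cases = rng.normal(spec.mu1, spec.sigma1, spec.n1)
    scores = np.concatenate([controls, cases])
    labels = np.concatenate([np.zeros(spec.n0, bool), np.ones(spec.n1, bool)])
    return scores, labels


# ---------------------------------------------------------------------------
# participant-level cohort
# ---------------------------------------------------------------------------

# class-conditional anthropometry defaults: (mean, sd) per sex and
# latent class, taken from the case/non-case summary table of the
# motivating study (WC and BMI), with heights chosen so that the
# implied waist-to-height ratios match the same table.
_ANTHRO = {
    # sex:      {"prone": {...}, "non": {...}, "height": (mean, sd)}
    "male": {
        "height": (171.0, 6.5),
        "prone": {"wc": (107.8, 11.5), "bmi": (30.6, 4.2)},
        "non": {"wc": (93.44, 11.34), "bmi": (25.9, 4.5)},
    },
    "female": {
        "height": (158.0, 6.0),
        "prone": {"wc": (100.98, 12.56), "bmi": (34.2, 6.0)},
        "non": {"wc": (84.31, 12.65), "bmi": (27.0, 5.9)},
    },
}

# biomarker class-conditional baselines: value = base + shift for the
# prone class (log-space for TG); sex-specific where the component
# prevalences differ strongly by sex.
_BIOMARKERS = {
    # name: (base_mean, sd, prone_shift) -- shift scaled by the
    # calibration multiplier
    "fpg": (92.0, 12.0, 22.0),        # mg/dL; prone class also wider (see code)
    "hdl_male": (45.0, 9.0, -6.0),    # mg/dL
    "hdl_female": (52.0, 10.0, -6.0),
    "sbp": (118.0, 12.0, 16.0),       # mmHg
    "dbp": (76.0, 8.0, 9.0),
    "log_tg_male": (np.log(125.0), 0.42, np.log(175.0 / 125.0)),
    "log_tg_female": (np.log(100.0), 0.42, np.log(150.0 / 100.0)),
}

_TREAT_P = {  # (non-prone, prone) treatment probabilities
    "treat_glucose": (0.02, 0.12),
    "treat_bp": (0.03, 0.15),
    "treat_tg": (0.01, 0.05),
    "treat_hdl": (0.005, 0.02),
}


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of the participant-level generator.

    Defaults emulate the motivating cross-sectional cohort: n = 756,
    54.2% male, target syndrome prevalence 42.5%, anthropometry
    moments from its case/non-case summary table.
    """

    n: int = 756
    sex_ratio: float = 410.0 / 756.0     # proportion male
    target_prevalence: float = 0.425
    corr_bmi_wc: float = 0.85
    corr_height_wc: float = 0.15
    corr_height_bmi: float = -0.05
    bp_corr: float = 0.7
    height_bounds: tuple = (140.0, 200.0)
    weight_bounds: tuple = (35.0, 160.0)
    wc_bounds: tuple = (50.0, 160.0)
    calibration_tol: float = 0.005
    max_calibration_iter: int = 25
    seed: int | None = None
    anthro: dict = field(default_factory=lambda: _ANTHRO)
    biomarkers: dict = field(default_factory=lambda: _BIOMARKERS)

    def __post_init__(self):
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target prevalence must be in (0, 1)")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        corr = self._corr_matrix()
        if np.any(np.linalg.eigvalsh(corr) <= 0):
            raise ValueError("anthropometry correlation matrix must be positive definite")

    def _corr_matrix(self):
        # order: height, bmi, wc
        return np.array(
            [
                [1.0, self.corr_height_bmi, self.corr_height_wc],
                [self.corr_height_bmi, 1.0, self.corr_bmi_wc],
                [self.corr_height_wc, self.corr_bmi_wc, 1.0],
            ]
        )


def _draw_anthro(rng, spec: CohortSpec, sex: np.ndarray, prone: np.ndarray):
    """Truncated correlated (height, bmi, wc) per sex and latent class."""
    n = sex.size
    height = np.empty(n)
    bmi = np.empty(n)
    wc = np.empty(n)
    chol = np.linalg.cholesky(spec._corr_matrix())
    todo = np.ones(n, dtype=bool)
    for _ in range(200):  # resample violations
        k = int(todo.sum())
        if k == 0:
            break
        z = rng.standard_normal((k, 3)) @ chol.T
        for s in ("male", "female"):
            for cls, mask_cls in (("prone", prone), ("non", ~prone)):
                m = todo & (sex == s) & mask_cls
                if not m.any():
                    continue
                sel = m[todo]  # positions within the redraw block
                pars = spec.anthro[s]
                h_mu, h_sd = pars["height"]
                wc_mu, wc_sd = pars[cls]["wc"]
                b_mu, b_sd = pars[cls]["bmi"]
                height[m] = h_mu + h_sd * z[sel, 0]
                bmi[m] = b_mu + b_sd * z[sel, 1]
                wc[m] = wc_mu + wc_sd * z[sel, 2]
        weight = bmi * (height / 100.0) ** 2
        ok = (
            (height >= spec.height_bounds[0])
            & (height <= spec.height_bounds[1])
            & (weight >= spec.weight_bounds[0])
            & (weight <= spec.weight_bounds[1])
            & (wc >= spec.wc_bounds[0])
            & (wc <= spec.wc_bounds[1])
            & (bmi > 0)
            & (wc < np.pi * height)
        )
        todo = ~ok
    if todo.any():
        raise CalibrationError("could not draw anthropometry within physiological bounds")
    return height, bmi, wc


def _biomarker_draws(rng, spec: CohortSpec, sex: np.ndarray):
    """Pre-draw standard-normal variates so the calibration shift can be
    rescaled without redrawing (keeps prevalence monotone in the shift)."""
    n = sex.size
    z = {name: rng.standard_normal(n) for name in ("fpg", "hdl", "log_tg")}
    # correlated BP pair
    z1 = rng.standard_normal(n)
    z2 = spec.bp_corr * z1 + np.sqrt(1 - spec.bp_corr**2) * rng.standard_normal(n)
    z["sbp"], z["dbp"] = z1, z2
    u = {name: rng.random(n) for name in _TREAT_P}
    return z, u


def _biomarkers_at(spec: CohortSpec, sex, prone, z, u, s: float):
    bio = spec.biomarkers
    male = sex == "male"
    out = {}

    def shifted(name, zkey=None):
        mu, sd, d = bio[name]
        # prone draws widen modestly with the shift (dispersed tail)
        sd_eff = sd * np.where(prone, 1.0 + 0.3 * min(s, 2.0) / 2.0, 1.0)
        return mu + s * d * prone + sd_eff * z[zkey or name]

    out["fpg_mgdl"] = np.clip(shifted("fpg"), 55.0, 450.0)
    hdl = np.where(male, shifted("hdl_male", "hdl"), shifted("hdl_female", "hdl"))
    out["hdl_mgdl"] = np.clip(hdl, 15.0, 120.0)
    log_tg = np.where(male, shifted("log_tg_male", "log_tg"), shifted("log_tg_female", "log_tg"))
    out["tg_mgdl"] = np.clip(np.exp(log_tg), 30.0, 1500.0)
    sbp = shifted("sbp")
    dbp = shifted("dbp")
    out["sbp"] = np.clip(sbp, 80.0, 240.0)
    out["dbp"] = np.clip(dbp, 45.0, 140.0)
    for name, (p_non, p_prone) in _TREAT_P.items():
        p_eff = np.where(prone, np.minimum(p_prone * (0.5 + 0.5 * s), 0.5), p_non)
        out[name] = (u[name] < p_eff).astype(int)
    return out


def _assemble_frame(spec, sex, prone, height, bmi, wc, bio, rng):
    n = sex.size
    weight = bmi * (height / 100.0) ** 2
    age = np.clip(rng.normal(41.0, 12.0, n), 20.0, 85.0)
    tc = np.clip(bio["hdl_mgdl"] + 0.2 * bio["tg_mgdl"] + rng.normal(110.0, 25.0, n), 90.0, 400.0)
    # two BP readings that average to the latent mean
    meas = rng.normal(0.0, 3.0, n)
    frame = pd.DataFrame(
        {
            "id": [f"S{i:05d}" for i in range(n)],
            "sex": sex,
            "age": np.round(age, 0),
            "height_cm": np.round(height, 1),
            "weight_kg": np.round(weight, 1),
            "wc_cm": np.round(wc, 1),
            "sbp1": np.round(bio["sbp"] + meas, 0),
            "sbp2": np.round(bio["sbp"] - meas, 0),
            "dbp1": np.round(bio["dbp"] + 0.6 * meas, 0),
            "dbp2": np.round(bio["dbp"] - 0.6 * meas, 0),
            "fpg_mgdl": np.round(bio["fpg_mgdl"], 1),
            "tg_mgdl": np.round(bio["tg_mgdl"], 1),
            "hdl_mgdl": np.round(bio["hdl_mgdl"], 1),
            "tc_mgdl": np.round(tc, 1),
            "treat_glucose": bio["treat_glucose"],
            "treat_bp": bio["treat_bp"],
            "treat_tg": bio["treat_tg"],
            "treat_hdl": bio["treat_hdl"],
            "smoking": rng.choice(
                ["non-smoker", "current", "former-or-negative"], n, p=[0.28, 0.33, 0.39]
            ),
            "education": rng.choice(["lt_bsc", "ge_bsc"], n, p=[0.69, 0.31]),
            "income": rng.choice(["low", "middle", "high"], n, p=[0.32, 0.51, 0.17]),
            "marital": rng.choice(["married", "single"], n, p=[0.79, 0.21]),
        }
    )
    frame["latent_prone"] = prone.astype(int)
    return frame


def generate_cohort(spec: CohortSpec | None = None, **overrides) -> pd.DataFrame:
    """Generate a participant-level cohort frame in the pipeline schema.

    The latent-class biomarker shift is calibrated by bisection (at
    most ``spec.max_calibration_iter`` iterations on the same random
    draws, so classified prevalence is monotone in the shift) until the
    rule-classified syndrome prevalence is within
    ``spec.calibration_tol`` of ``spec.target_prevalence``.

    Returns a :class:`pandas.DataFrame`; the auxiliary column
    ``latent_prone`` records the generating class and is not part of
    the pipeline CSV schema.
    """
    if spec is None:
        spec = CohortSpec(**overrides)
    elif overrides:
        raise TypeError("pass either a CohortSpec or keyword overrides, not both")
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    sex = np.where(rng.random(n) < spec.sex_ratio, "male", "female")
    prone = rng.random(n) < spec.target_prevalence
    height, bmi, wc = _draw_anthro(rng, spec, sex, prone)
    z, u = _biomarker_draws(rng, spec, sex)
    frame_rng_state = rng.bit_generator.state  # descriptive covariates drawn after calibration

    clf = Atp3Classifier()

    def prevalence(s: float) -> float:
        bio = _biomarkers_at(spec, sex, prone, z, u, s)
        rng2 = np.random.default_rng()
        rng2.bit_generator.state = frame_rng_state
        frame = _assemble_frame(spec, sex, prone, height, bmi, wc, bio, rng2)
        return float(clf.fit_predict(frame).mean()), frame

    lo, hi = 0.0, 4.0
    p_lo, _ = prevalence(lo)
    p_hi, frame_hi = prevalence(hi)
    target = spec.target_prevalence
    if not (min(p_lo, p_hi) - spec.calibration_tol <= target <= max(p_lo, p_hi) + spec.calibration_tol):
        raise CalibrationError(
            f"target prevalence {target:.3f} outside attainable range "
            f"[{min(p_lo, p_hi):.3f}, {max(p_lo, p_hi):.3f}]"
        )
    best_frame, best_err = frame_hi, abs(p_hi - target)
    for _ in range(spec.max_calibration_iter):
        mid = 0.5 * (lo + hi)
        p_mid, frame_mid = prevalence(mid)
        if abs(p_mid - target) < best_err:
            best_frame, best_err = frame_mid, abs(p_mid - target)
        if best_err <= spec.calibration_tol:
            break
        if (p_mid < target) == (p_lo < target):
            lo, p_lo = mid, p_mid
        else:
            hi = mid
    return best_frame


# ---------------------------------------------------------------------------
# deterministic 12-subject fixture
# ---------------------------------------------------------------------------

_FIXTURE_ROWS = [
    # id, sex, age, h, w, wc, sbp1, sbp2, dbp1, dbp2, fpg, tg, hdl, tc, tglu, tbp, ttg, thdl
    ("F01", "male", 45, 175.0, 85.0, 98.5, 130, 130, 85, 85, 100.0, 150.0, 38.67, 190.0, 0, 0, 0, 0),
    ("F02", "female", 38, 160.0, 47.0, 64.0, 105, 103, 66, 64, 82.0, 70.0, 62.0, 150.0, 0, 0, 0, 0),  # underweight, fully normal
    ("F03", "male", 52, 180.0, 110.0, 112.0, 142, 138, 92, 88, 118.0, 210.0, 34.0, 230.0, 0, 0, 0, 0),
    ("F04", "female", 61, 155.0, 78.0, 95.0, 150, 146, 94, 90, 128.0, 185.0, 42.0, 215.0, 1, 1, 0, 0),
    ("F05", "male", 29, 182.0, 76.0, 84.0, 118, 116, 74, 72, 88.0, 95.0, 52.0, 170.0, 0, 0, 0, 0),
    ("F06", "female", 47, 162.0, 70.0, 88.0, 124, 122, 80, 78, 96.0, 120.0, 48.0, 195.0, 0, 0, 0, 0),
    ("F07", "male", 57, 170.0, 95.0, 104.0, 128, 126, 84, 82, 104.0, 145.0, 41.0, 205.0, 0, 1, 0, 0),
    ("F08", "female", 33, 168.0, 60.0, 74.0, 110, 108, 70, 68, 85.0, 80.0, 65.0, 160.0, 0, 0, 0, 0),
    ("F09", "male", 41, 176.0, 88.0, 100.0, 135, 131, 88, 86, 99.0, 155.0, 39.0, 210.0, 0, 0, 0, 0),
    ("F10", "female", 55, 150.0, 80.0, 102.0, 138, 136, 88, 86, 140.0, 200.0, 38.0, 240.0, 0, 0, 1, 0),
    ("F11", "male", 36, 168.0, 72.0, 90.0, 122, 120, 78, 76, 92.0, 130.0, 46.0, 180.0, 0, 0, 0, 0),
    ("F12", "female", 44, 165.0, 92.0, 99.5, 126, 124, 82, 80, 101.0, 152.0, 49.0, 220.0, 0, 0, 0, 0),
]


def fixture_cohort() -> pd.DataFrame:
    """A deterministic 12-subject cohort used as a regression baseline.

    Hand-constructed to exercise every classifier component, both
    sexes, an underweight subject with no abnormal components, exact
    threshold boundaries and treatment overrides.  Expected index
    panels and component flags live in :data:`FIXTURE_EXPECTED_PANEL`
    and :data:`FIXTURE_EXPECTED_FLAGS`.
    """
    cols = [
        "id", "sex", "age", "height_cm", "weight_kg", "wc_cm",
        "sbp1", "sbp2", "dbp1", "dbp2",
        "fpg_mgdl", "tg_mgdl", "hdl_mgdl", "tc_mgdl",
        "treat_glucose", "treat_bp", "treat_tg", "treat_hdl",
    ]
    frame = pd.DataFrame(_FIXTURE_ROWS, columns=cols)
    frame["smoking"] = "non-smoker"
    frame["education"] = "lt_bsc"
    frame["income"] = "middle"
    frame["marital"] = "married"
    return frame


#: Expected seven-index panel of the fixture, frozen from direct
#: evaluation of the formulas (rounded to reporting precision:
#: 4 dp ABSI, 3 dp WHtR, 2 dp otherwise).
FIXTURE_EXPECTED_PANEL = {
    "F01": {"bmi": 27.76, "wc": 98.5, "whtr": 0.563, "absi": 0.0812, "bri": 4.61, "ci": 1.30, "vai": 2.31},
    "F02": {"bmi": 18.36, "wc": 64.0, "whtr": 0.400, "absi": 0.0727, "bri": 1.67, "ci": 1.08, "vai": 0.83},
}

#: Expected component flags of the fixture (frozen by hand-applying the
#: rule at the stated thresholds).
FIXTURE_EXPECTED_FLAGS = {
    "F01": {"wc_abn": False, "fpg_abn": True, "bp_abn": True, "tg_abn": True, "hdl_abn": True, "count": 4, "msyn": True},
    "F02": {"wc_abn": False, "fpg_abn": False, "bp_abn": False, "tg_abn": False, "hdl_abn": False, "count": 0, "msyn": False},
    "F03": {"wc_abn": True, "fpg_abn": True, "bp_abn": True, "tg_abn": True, "hdl_abn": True, "count": 5, "msyn": True},
    "F04": {"wc_abn": True, "fpg_abn": True, "bp_abn": True, "tg_abn": True, "hdl_abn": True, "count": 5, "msyn": True},
    "F05": {"wc_abn": False, "fpg_abn": False, "bp_abn": False, "tg_abn": False, "hdl_abn": False, "count": 0, "msyn": False},
    "F06": {"wc_abn": True, "fpg_abn": False, "bp_abn": False, "tg_abn": False, "hdl_abn": True, "count": 2, "msyn": False},
    "F07": {"wc_abn": True, "fpg_abn": True, "bp_abn": True, "tg_abn": False, "hdl_abn": False, "count": 3, "msyn": True},
    "F08": {"wc_abn": False, "fpg_abn": False, "bp_abn": False, "tg_abn": False, "hdl_abn": False, "count": 0, "msyn": False},
    "F09": {"wc_abn": False, "fpg_abn": False, "bp_abn": True, "tg_abn": True, "hdl_abn": True, "count": 3, "msyn": True},
    "F10": {"wc_abn": True, "fpg_abn": True, "bp_abn": True, "tg_abn": True, "hdl_abn": True, "count": 5, "msyn": True},
    "F11": {"wc_abn": False, "fpg_abn": False, "bp_abn": False, "tg_abn": False, "hdl_abn": False, "count": 0, "msyn": False},
    "F12": {"wc_abn": True, "fpg_abn": True, "bp_abn": False, "tg_abn": True, "hdl_abn": True, "count": 4, "msyn": True},
}
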