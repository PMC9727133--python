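"""Unit and property tests for the seven index calculators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msynscreen.indices import (
    AnthropometricIndices,
    DomainError,
    ParticipantRecord,
    compute_absi,
    compute_bmi,
    compute_bri,
    compute_ci,
    compute_index_panel,
    compute_vai,
    compute_whtr,
    mgdl_to_mmol,
)

# realistic adult ranges for property tests
heights = st.floats(min_value=140.0, max_value=200.0)
weights = st.floats(min_value=35.0, max_value=160.0)
waists = st.floats(min_value=50.0, max_value=160.0)


@pytest.mark.parametrize(
    "weight, height, expected",
    [(100.0, 200.0, 25.0), (1.0, 100.0, 1.0), (85.0, 175.0, 27.7551)],
)
def test_bmi_examples(weight, height, expected):
    assert compute_bmi(weight, height) == pytest.approx(expected, abs=1e-4)


@pytest.mark.parametrize(
    "wc, height, expected",
    [(90.0, 180.0, 0.5), (170.0, 170.0, 1.0), (98.5, 175.0, 0.5629)],
)
def test_whtr_examples(wc, height, expected):
    assert compute_whtr(wc, height) == pytest.approx(expected, abs=1e-4)


@pytest.mark.parametrize(
    "wc, height, bmi, expected",
    [
        (100.0, 100.0, 1.0, 1.0),  # all unit factors
        (98.5, 175.0, 27.755102, 0.081225),
        (80.0, 160.0, 25.0, 0.073972),
    ],
)
def test_absi_examples(wc, height, bmi, expected):
    assert compute_absi(wc, height, bmi) == pytest.approx(expected, abs=1e-5)


def test_bri_examples():
    h = 175.0
    # float cancellation in 1 - (wc/2pi)^2/(0.5h)^2 leaves ~1e-16,
    # amplified by the sqrt to ~1e-5 in the result
    assert compute_bri(np.pi * h, h) == pytest.approx(364.2, abs=1e-4)
    assert compute_bri(98.5, 175.0) == pytest.approx(4.614, abs=1e-3)
    # wc -> 0 limit approaches 364.2 - 365.5 = -1.3
    assert compute_bri(1e-6, 175.0) == pytest.approx(-1.3, abs=1e-6)


def test_bri_rejects_waist_beyond_spherical_bound():
    with pytest.raises(DomainError, match="spherical"):
        compute_bri(176.0 * np.pi, 175.0)


@pytest.mark.parametrize(
    "wc, weight, height, expected",
    [
        (10.9, 1.0, 100.0, 1.0),  # constants cancel: weight/height_m = 1
        (98.5, 85.0, 175.0, 1.29664),
        (80.0, 64.0, 160.0, 1.16047),
    ],
)
def test_ci_examples(wc, weight, height, expected):
    assert compute_ci(wc, weight, height) == pytest.approx(expected, abs=1e-4)


def test_vai_all_ones_calibration():
    # with WC equal to the linear term and TG/HDL at the reference
    # values, every factor is exactly 1 for both sexes
    bmi = 25.0
    assert compute_vai("male", 39.68 + 1.88 * bmi, bmi, 1.03, 1.31) == pytest.approx(1.0)
    assert compute_vai("female", 36.58 + 1.89 * bmi, bmi, 0.81, 1.52) == pytest.approx(1.0)


def test_vai_male_example():
    assert compute_vai("male", 98.5, 27.755102, 1.7, 1.0) == pytest.approx(2.31843, abs=1e-4)


def test_vai_unknown_sex():
    with pytest.raises(ValueError, match="sex"):
        compute_vai("other", 90.0, 25.0, 1.5, 1.2)


@pytest.mark.parametrize(
    "value, analyte, expected, tol",
    [
        (100.0, "glucose", 5.55, 0.005),
        (150.0, "tg", 1.69, 0.005),
        (0.0, "hdl", 0.0, 1e-12),
        (38.67, "hdl", 1.0, 1e-4),
    ],
)
def test_mgdl_to_mmol(value, analyte, expected, tol):
    assert mgdl_to_mmol(value, analyte) == pytest.approx(expected, abs=tol)


def test_mgdl_to_mmol_unknown_analyte():
    with pytest.raises(ValueError, match="analyte"):
        mgdl_to_mmol(100.0, "sodium")


@pytest.mark.parametrize("fn, args", [
    (compute_bmi, (0.0, 170.0)),
    (compute_bmi, (70.0, -1.0)),
    (compute_whtr, (0.0, 170.0)),
    (compute_absi, (90.0, 170.0, 0.0)),
    (compute_ci, (90.0, 0.0, 170.0)),
])
def test_nonpositive_inputs_are_domain_errors(fn, args):
    with pytest.raises(DomainError):
        fn(*args)


@settings(derandomize=True, max_examples=200)
@given(wc=waists, h=heights)
def test_whtr_unit_invariance(wc, h):
    assert compute_whtr(wc, h) == pytest.approx(compute_whtr(wc / 100.0, h / 100.0), rel=1e-12)


@settings(derandomize=True, max_examples=200)
@given(wc=waists, h=heights, w=weights, d=st.floats(min_value=0.1, max_value=10.0))
def test_monotone_increasing_in_waist(wc, h, w, d):
    """Every index grows strictly with waist at fixed height/weight."""
    bmi = compute_bmi(w, h)
    assert compute_whtr(wc + d, h) > compute_whtr(wc, h)
    assert compute_absi(wc + d, h, bmi) > compute_absi(wc, h, bmi)
    assert compute_bri(wc + d, h) > compute_bri(wc, h)
    assert compute_ci(wc + d, w, h) > compute_ci(wc, w, h)
    assert compute_vai("male", wc + d, bmi, 1.5, 1.2) > compute_vai("male", wc, bmi, 1.5, 1.2)


@settings(derandomize=True, max_examples=200)
@given(wc=waists, h=heights)
def test_bri_bounds(wc, h):
    bri = compute_bri(wc, h)
    assert -1.3 <= bri < 364.2


def test_panel_matches_single_index_operations(rng):
    """compute_index_panel equals element-wise single-index calls."""
    for i in range(1000):
        h = rng.uniform(140, 200)
        w = rng.uniform(35, 160)
        wc = rng.uniform(50, 160)
        sex = "male" if rng.random() < 0.5 else "female"
        tg = rng.uniform(40, 600)
        hdl = rng.uniform(20, 100)
        rec = ParticipantRecord(
            id=f"r{i}", sex=sex, age=40, height=h, weight=w, wc=wc,
            sbp1=120, dbp1=80, fpg=90, tg=tg, hdl=hdl,
        )
        panel = compute_index_panel(rec)
        bmi = compute_bmi(w, h)
        assert panel.bmi == pytest.approx(bmi, rel=1e-14)
        assert panel.wc == wc
        assert panel.whtr == pytest.approx(compute_whtr(wc, h), rel=1e-14)
        assert panel.absi == pytest.approx(compute_absi(wc, h, bmi), rel=1e-14)
        assert panel.bri == pytest.approx(compute_bri(wc, h), rel=1e-14)
        assert panel.ci == pytest.approx(compute_ci(wc, w, h), rel=1e-14)
        assert panel.vai == pytest.approx(
            compute_vai(sex, wc, bmi, mgdl_to_mmol(tg, "tg"), mgdl_to_mmol(hdl, "hdl")),
            rel=1e-14,
        )


def test_panel_propagates_record_id():
    rec = ParticipantRecord(
        id="X9", sex="male", age=40, height=175, weight=85, wc=175 * np.pi + 1,
        sbp1=120, dbp1=80, fpg=90, tg=150, hdl=40,
    )
    with pytest.raises(DomainError, match="X9"):
        compute_index_panel(rec)


def test_transformer_agrees_with_panel(fixture_frame):
    """The sklearn-style transformer reproduces per-record panels."""
    out = AnthropometricIndices().fit_transform(fixture_frame)
    assert list(out.columns) == ["bmi", "wc", "whtr", "absi", "bri", "ci", "vai"]
    row = out.iloc[0]
    assert row["bmi"] == pytest.approx(27.7551, abs=1e-4)
    assert row["absi"] == pytest.approx(0.081225, abs=1e-5)
    assert row["vai"] == pytest.approx(2.3097, abs=1e-3)  # TG 150 mg/dL -> 1.6936 mmol/L


def test_transformer_missing_column(fixture_frame):
    with pytest.raises(KeyError, match="wc_cm"):
        AnthropometricIndices().fit(fixture_frame.drop(columns=["wc_cm"]))
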