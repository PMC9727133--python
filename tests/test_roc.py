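"""ROC engine: oracle equivalence, CI methods, Youden optimum, bands."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msynscreen.roc import (
    YoudenCutpoint,
    auc_ci,
    auc_trapezoid,
    build_roc,
    delong_se,
    discrimination_band,
    evaluate_index,
    hanley_mcneil_se,
    youden_optimal,
)
from msynscreen.simulate import BinormalSpec, generate_binormal


def mann_whitney_auc(scores, labels):
    """Independent oracle: pairwise concordance count."""
    pos = scores[labels]
    neg = scores[~labels]
    gt = np.sum(pos[:, None] > neg[None, :])
    ties = np.sum(pos[:, None] == neg[None, :])
    return (gt + 0.5 * ties) / (pos.size * neg.size)


def brute_force_youden(scores, labels):
    """Independent oracle: exhaustive enumeration over observed cutoffs."""
    best = None
    for c in np.unique(scores):
        pred = scores > c
        sens = pred[labels].mean()
        spec = (~pred[~labels]).mean()
        j = sens + spec - 1.0
        key = (round(j, 12), round(sens, 12), -c)
        if best is None or key > best[0]:
            best = (key, c, sens, spec, j)
    return best[1:]


def test_perfect_separation():
    scores = np.array([1.0, 2.0, 3.0, 4.0])
    labels = np.array([False, False, True, True])
    curve = build_roc(scores, labels)
    assert auc_trapezoid(curve) == 1.0
    cutoff, sens, spec, j = youden_optimal(curve)
    assert j == 1.0 and sens == 1.0 and spec == 1.0
    assert cutoff == 2.0  # smallest observed value achieving J=1


def test_constant_scores_are_uninformative():
    scores = np.ones(10)
    labels = np.array([True, False] * 5)
    curve = build_roc(scores, labels)
    assert auc_trapezoid(curve) == 0.5
    assert curve.thresholds.size == 2  # -inf and the single value


def test_interleaved_example():
    scores = np.array([1.0, 2.0, 3.0, 4.0])
    labels = np.array([False, True, False, True])
    curve = build_roc(scores, labels)
    assert auc_trapezoid(curve) == pytest.approx(0.75)
    cutoff, sens, spec, j = youden_optimal(curve)
    # ties at c=1 (sens 1, spec .5) and c=3 (sens .5, spec 1); the
    # screening tie-break prefers sensitivity
    assert j == pytest.approx(0.5)
    assert cutoff == 1.0 and sens == 1.0 and spec == 0.5


def test_degenerate_labels_raise():
    with pytest.raises(ValueError, match="degenerate"):
        build_roc(np.array([1.0, 2.0]), np.array([True, True]))


def test_oracle_equivalence_500_random_instances(rng):
    """Trapezoidal AUC == Mann-Whitney count and Youden == brute force,
    exactly, on small tied instances."""
    checked = 0
    while checked < 500:
        n = int(rng.integers(4, 31))
        scores = rng.integers(0, 6, n).astype(float)  # heavy ties
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            continue
        curve = build_roc(scores, labels)
        assert auc_trapezoid(curve) == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)
        cutoff, sens, spec, j = youden_optimal(curve)
        bc, bs, bsp, bj = brute_force_youden(scores, labels)
        assert j == pytest.approx(bj, abs=1e-12)
        assert cutoff == bc and sens == pytest.approx(bs) and spec == pytest.approx(bsp)
        checked += 1


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.integers(0, 8), min_size=4, max_size=40), st.data())
def test_roc_monotone_in_threshold(values, data):
    labels = np.array(data.draw(st.lists(st.booleans(), min_size=len(values), max_size=len(values))))
    if labels.all() or not labels.any():
        return
    curve = build_roc(np.array(values, dtype=float), labels)
    assert np.all(np.diff(curve.sens) <= 1e-12)
    assert np.all(np.diff(curve.spec) >= -1e-12)
    # extremes present
    assert curve.sens[0] == 1.0 and curve.spec[0] == 0.0
    assert curve.sens[-1] == 0.0 and curve.spec[-1] == 1.0


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.floats(-5, 5), min_size=4, max_size=40, unique=True), st.data())
def test_label_flip_antisymmetry(values, data):
    labels = np.array(data.draw(st.lists(st.booleans(), min_size=len(values), max_size=len(values))))
    if labels.all() or not labels.any():
        return
    scores = np.array(values)
    a = auc_trapezoid(build_roc(scores, labels))
    a_neg = auc_trapezoid(build_roc(-scores, labels))
    assert a + a_neg == pytest.approx(1.0, abs=1e-12)


def test_hanley_mcneil_worked_example():
    """A=0.75 with 50/50 gives the textbook interval (0.654, 0.846)."""
    se = hanley_mcneil_se(0.75, 50, 50)
    assert se == pytest.approx(0.048836, abs=1e-5)
    lo = 0.75 - 1.959964 * se
    hi = 0.75 + 1.959964 * se
    assert (round(lo, 3), round(hi, 3)) == (0.654, 0.846)


def test_hanley_mcneil_symmetric_at_half():
    scores, labels = generate_binormal(BinormalSpec(mu1=0.0, n0=50, n1=50, seed=3))
    lo, hi = auc_ci(scores, labels, method="hanley-mcneil")
    auc = auc_trapezoid(build_roc(scores, labels))
    assert hi - auc == pytest.approx(auc - lo, abs=1e-12)


def test_delong_matches_reference_implementation():
    """Frozen oracle: DeLong CI from R pROC ci.auc on this dataset is
    (0.8174665149, 1.0) around AUC 0.9141414141."""
    rng = np.random.default_rng(20230407)
    scores = np.round(rng.normal(0, 1, 40) + np.repeat([0.0, 1.2], [22, 18]), 3)
    labels = np.repeat([False, True], [22, 18])
    assert auc_trapezoid(build_roc(scores, labels)) == pytest.approx(0.9141414141, abs=1e-9)
    lo, hi = auc_ci(scores, labels, method="delong")
    assert lo == pytest.approx(0.8174665149, abs=1e-9)
    assert hi == 1.0  # clipped


def test_delong_and_bootstrap_interval_widths_agree(rng):
    scores, labels = generate_binormal(BinormalSpec(mu1=1.0, n0=100, n1=100, seed=12))
    lo_d, hi_d = auc_ci(scores, labels, method="delong")
    lo_b, hi_b = auc_ci(scores, labels, method="bootstrap", seed=99, n_boot=2000)
    width_d, width_b = hi_d - lo_d, hi_b - lo_b
    assert abs(width_d - width_b) / width_d < 0.2


def test_unknown_ci_method():
    with pytest.raises(ValueError, match="method"):
        auc_ci(np.array([1.0, 2.0]), np.array([False, True]), method="jackknife")


@pytest.mark.parametrize(
    "auc, band",
    [
        (0.95, "excellent"), (0.9, "excellent"),
        (0.83, "good"), (0.8, "good"),
        (0.75, "fair"), (0.69, "poor"), (0.58, "failed"), (0.5, "failed"),
    ],
)
def test_discrimination_bands(auc, band):
    assert discrimination_band(auc) == band


def test_band_below_chance_warns():
    with pytest.warns(UserWarning, match="below chance"):
        assert discrimination_band(0.4) == "failed"
    with pytest.raises(ValueError):
        discrimination_band(1.2)


def test_evaluate_index_consistency(rng):
    scores, labels = generate_binormal(BinormalSpec(mu1=1.5, n0=200, n1=150, seed=5))
    summary = evaluate_index(scores, labels)
    assert summary.ci_low <= summary.auc <= summary.ci_high
    assert summary.youden == pytest.approx(
        summary.sens_at_cutoff + summary.spec_at_cutoff - 1.0, abs=1e-15
    )
    assert summary.band == discrimination_band(summary.auc)
    assert summary.n_pos == 150 and summary.n_neg == 200


def test_evaluate_index_perfect():
    summary = evaluate_index(np.array([1.0, 2, 3, 10, 11, 12]), np.array([0, 0, 0, 1, 1, 1], bool))
    assert summary.auc == 1.0 and summary.youden == 1.0 and summary.band == "excellent"


def test_youden_cutpoint_estimator():
    """fit/predict round-trip with sklearn-style attributes."""
    scores, labels = generate_binormal(BinormalSpec(mu1=2.0, n0=300, n1=300, seed=21))
    est = YoudenCutpoint(ci_method="hanley-mcneil").fit(scores, labels)
    assert 0.85 <= est.auc_ <= 1.0
    assert est.ci_low_ <= est.auc_ <= est.ci_high_
    pred = est.predict(scores)
    assert pred.dtype == bool
    sens = pred[labels].mean()
    spec = (~pred[~labels]).mean()
    assert est.youden_ == pytest.approx(sens + spec - 1.0, abs=1e-12)
    # params round-trip like an sklearn estimator
    est2 = YoudenCutpoint(**est.get_params())
    assert est2.get_params() == est.get_params()


def test_youden_cutpoint_composes_with_sklearn():
    from sklearn.model_selection import cross_val_score  # noqa: F401  (protocol check)

    scores, labels = generate_binormal(BinormalSpec(mu1=1.0, n0=60, n1=60, seed=8))
    est = YoudenCutpoint().fit(scores.reshape(-1, 1), labels)
    assert est.predict(scores.reshape(-1, 1)).shape == (120,)
    assert est.score(scores.reshape(-1, 1), labels) == pytest.approx(est.youden_, abs=0.2)
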