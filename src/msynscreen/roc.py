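"""ROC curves, AUC confidence intervals and Youden-optimal cutoffs.

The empirical ROC curve is built with the positivity rule
``score > threshold`` (higher index values predict disease), one
operating point per distinct observed score plus the all-positive
extreme.  The trapezoidal area under that curve equals the
Mann-Whitney two-sample probability estimate
P(X_case > X_control) + 0.5 * P(tie), which is the basis of both
analytic confidence-interval methods:

* Hanley-McNeil — the classic variance approximation based on
  Q1 = A/(2-A), Q2 = 2A^2/(1+A);
* DeLong — the nonparametric structural-components estimator
  (default, no distributional assumption);
* bootstrap — stratified percentile interval.

The Youden-optimal cutoff maximises J = sensitivity + specificity - 1
over observed score values; ties in J are broken in favour of higher
sensitivity, then the smaller cutoff (a screening context prefers not
to miss cases).  Cutoffs are reported as observed values with the
"greater than" reading, without midpoint interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RocCurve",
    "RocSummary",
    "YoudenCutpoint",
    "build_roc",
    "auc_trapezoid",
    "auc_ci",
    "youden_optimal",
    "discrimination_band",
    "evaluate_index",
    "hanley_mcneil_se",
    "delong_se",
    "sens_spec_wilson_ci",
]

_BANDS = (
    (0.9, "excellent"),
    (0.8, "good"),
    (0.7, "fair"),
    (0.6, "poor"),
    (0.0, "failed"),
)


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC operating points.

    ``thresholds`` is ascending and starts at ``-inf`` (the
    call-everything-positive extreme); ``sens``/``spec`` are aligned
    proportions under the rule "positive iff score > threshold".
    """

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class RocSummary:
    """One evaluation row: AUC with CI, optimal cutoff, J, band."""

    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    sens_ci: tuple
    spec_ci: tuple
    youden: float
    band: str
    n_pos: int
    n_neg: int
    ci_method: str

    def as_dict(self) -> dict:
        d = {
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "cutoff": self.cutoff,
            "sens": self.sens_at_cutoff,
            "spec": self.spec_at_cutoff,
            "sens_ci_low": self.sens_ci[0],
            "sens_ci_high": self.sens_ci[1],
            "spec_ci_low": self.spec_ci[0],
            "spec_ci_high": self.spec_ci[1],
            "youden": self.youden,
            "band": self.band,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "ci_method": self.ci_method,
        }
        return d


def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("degenerate labels: both classes must be present")
    return scores, labels, n_pos, n_neg


def build_roc(scores, labels) -> RocCurve:
    """Empirical ROC curve under the positivity rule score > threshold."""
    scores, labels, n_pos, n_neg = _check_scores_labels(scores, labels)
    uniq, inverse, counts = np.unique(scores, return_inverse=True, return_counts=True)
    thresholds = np.concatenate(([-np.inf], uniq))
    # pos/neg counts at each unique value, then cumulative from above
    pos_at = np.bincount(inverse, weights=labels.astype(float), minlength=uniq.size)
    neg_at = counts - pos_at
    pos_above = np.concatenate(([n_pos], n_pos - np.cumsum(pos_at)))
    neg_above = np.concatenate(([n_neg], n_neg - np.cumsum(neg_at)))
    sens = pos_above / n_pos           # P(score > t | case)
    spec = 1.0 - neg_above / n_neg     # P(score <= t | control)
    return RocCurve(thresholds=thresholds, sens=sens, spec=spec, n_pos=n_pos, n_neg=n_neg)


def auc_trapezoid(curve: RocCurve) -> float:
    """Trapezoidal area over (1 - specificity, sensitivity).

    Identical to the normalised Mann-Whitney statistic
    (#{case > control} + 0.5 * #{ties}) / (n_pos * n_neg).
    """
    # thresholds ascend, so (fpr, sens) descend along the stored arrays;
    # reversing walks the ROC path from (0,0) to (1,1)
    x = (1.0 - curve.spec)[::-1]
    y = curve.sens[::-1]
    return float(np.trapezoid(y, x))


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of the empirical AUC."""
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a)
        + (n_pos - 1) * (q1 - a * a)
        + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def _delong_components(scores, labels):
    """Per-observation structural components (midrank placements)."""
    x = scores[labels]      # cases
    y = scores[~labels]     # controls
    m, n = x.size, y.size
    all_scores = np.concatenate([x, y])
    ranks_all = stats.rankdata(all_scores)        # midranks in pooled sample
    ranks_x = stats.rankdata(x)
    ranks_y = stats.rankdata(y)
    v10 = (ranks_all[:m] - ranks_x) / n           # P(x_i > Y) + 0.5 P(tie)
    v01 = 1.0 - (ranks_all[m:] - ranks_y) / m
    auc = float(v10.mean())
    return auc, v10, v01


def delong_se(scores, labels) -> float:
    """DeLong nonparametric standard error of the empirical AUC."""
    scores, labels, n_pos, n_neg = _check_scores_labels(scores, labels)
    _, v10, v01 = _delong_components(scores, labels)
    s10 = np.var(v10, ddof=1) if n_pos > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n_neg > 1 else 0.0
    return float(np.sqrt(s10 / n_pos + s01 / n_neg))


def auc_ci(
    scores,
    labels,
    method: str = "delong",
    level: float = 0.95,
    seed=None,
    n_boot: int = 2000,
):
    """Confidence interval for the AUC, clipped to [0, 1].

    ``method`` is one of ``hanley-mcneil``, ``delong`` (Wald intervals
    auc +/- z * SE) or ``bootstrap`` (stratified percentile; requires a
    seed for reproducibility).
    """
    scores, labels, n_pos, n_neg = _check_scores_labels(scores, labels)
    auc = auc_trapezoid(build_roc(scores, labels))
    z = stats.norm.ppf(0.5 + level / 2.0)
    if method == "hanley-mcneil":
        se = hanley_mcneil_se(auc, n_pos, n_neg)
        lo, hi = auc - z * se, auc + z * se
    elif method == "delong":
        se = delong_se(scores, labels)
        lo, hi = auc - z * se, auc + z * se
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos = scores[labels]
        neg = scores[~labels]
        reps = np.empty(n_boot)
        for b in range(n_boot):
            ps = rng.choice(pos, size=n_pos, replace=True)
            ns = rng.choice(neg, size=n_neg, replace=True)
            bs = np.concatenate([ps, ns])
            bl = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
            reps[b] = auc_trapezoid(build_roc(bs, bl))
        alpha = 1.0 - level
        lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))


def youden_optimal(curve: RocCurve):
    """Cutoff maximising J = sens + spec - 1 over observed score values.

    Returns ``(cutoff, sens, spec, J)``.  Ties in J are broken by
    higher sensitivity, then by smaller cutoff.
    """
    # skip the -inf extreme: cutoffs are observed values
    thr = curve.thresholds[1:]
    sens = curve.sens[1:]
    spec = curve.spec[1:]
    j = sens + spec - 1.0
    # lexicographic maximum of (J, sens, -threshold); thr is ascending,
    # so among equal (J, sens) the first occurrence is the smallest cutoff
    tol = 1e-12
    best = 0
    for i in range(1, j.size):
        if j[i] > j[best] + tol:
            best = i
        elif j[i] >= j[best] - tol and sens[i] > sens[best] + tol:
            best = i
    return float(thr[best]), float(sens[best]), float(spec[best]), float(j[best])


def discrimination_band(auc: float) -> str:
    """Map an AUC to the conventional discrimination label.

    [0.9, 1.0] excellent, [0.8, 0.9) good, [0.7, 0.8) fair,
    [0.6, 0.7) poor, [0.5, 0.6) failed.  Below 0.5 the index is worse
    than chance; it is labelled "failed" with a warning.
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"AUC must be in [0, 1], got {auc}")
    if auc < 0.5:
        import warnings

        warnings.warn(f"AUC {auc:.3f} is below chance", stacklevel=2)
        return "failed"
    for lo, label in _BANDS:
        if auc >= lo:
            return label
    return "failed"  # pragma: no cover


def sens_spec_wilson_ci(k: int, n: int, level: float = 0.95):
    """Wilson score interval for a simple proportion k/n."""
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(k, n, alpha=1.0 - level, method="wilson")
    return float(lo), float(hi)


def evaluate_index(
    scores,
    labels,
    ci_method: str = "delong",
    level: float = 0.95,
    seed=None,
    n_boot: int = 2000,
) -> RocSummary:
    """Full single-index evaluation: AUC, CI, band, Youden cutoff."""
    scores, labels, n_pos, n_neg = _check_scores_labels(scores, labels)
    curve = build_roc(scores, labels)
    auc = auc_trapezoid(curve)
    lo, hi = auc_ci(scores, labels, method=ci_method, level=level, seed=seed, n_boot=n_boot)
    cutoff, sens, spec, j = youden_optimal(curve)
    sens_ci = sens_spec_wilson_ci(int(round(sens * n_pos)), n_pos, level)
    spec_ci = sens_spec_wilson_ci(int(round(spec * n_neg)), n_neg, level)
    return RocSummary(
        auc=auc,
        ci_low=lo,
        ci_high=hi,
        cutoff=cutoff,
        sens_at_cutoff=sens,
        spec_at_cutoff=spec,
        sens_ci=sens_ci,
        spec_ci=spec_ci,
        youden=j,
        band=discrimination_band(auc),
        n_pos=n_pos,
        n_neg=n_neg,
        ci_method=ci_method,
    )


class YoudenCutpoint:
    """Threshold classifier fitted at the Youden-optimal cutoff.

    scikit-learn style estimator: ``fit(X, y)`` takes a single score
    column (1-d array or ``(n, 1)``) and binary labels, computes the
    empirical ROC, AUC with confidence interval, discrimination band
    and the Youden-optimal cutoff; ``predict`` applies
    ``score > cutoff_``.

    Parameters
    ----------
    ci_method : {"delong", "hanley-mcneil", "bootstrap"}
        AUC confidence-interval method.
    level : float
        Confidence level (default 0.95).
    random_state : int or None
        Seed for the bootstrap CI.
    n_boot : int
        Bootstrap replicates.

    Attributes (after fit)
    ----------------------
    auc_, ci_low_, ci_high_, cutoff_, sensitivity_, specificity_,
    youden_, band_, curve_ : fitted quantities as described above.
    """

    def __init__(self, ci_method="delong", level=0.95, random_state=None, n_boot=2000):
        self.ci_method = ci_method
        self.level = level
        self.random_state = random_state
        self.n_boot = n_boot

    def get_params(self, deep=True):
        return {
            "ci_method": self.ci_method,
            "level": self.level,
            "random_state": self.random_state,
            "n_boot": self.n_boot,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    @staticmethod
    def _scores(X):
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 2:
            if arr.shape[1] != 1:
                raise ValueError("expected a single score column")
            arr = arr[:, 0]
        return arr

    def fit(self, X, y):
        scores = self._scores(X)
        summary = evaluate_index(
            scores,
            y,
            ci_method=self.ci_method,
            level=self.level,
            seed=self.random_state,
            n_boot=self.n_boot,
        )
        self.summary_ = summary
        self.curve_ = build_roc(scores, y)
        self.auc_ = summary.auc
        self.ci_low_ = summary.ci_low
        self.ci_high_ = summary.ci_high
        self.cutoff_ = summary.cutoff
        self.sensitivity_ = summary.sens_at_cutoff
        self.specificity_ = summary.spec_at_cutoff
        self.youden_ = summary.youden
        self.band_ = summary.band
        self.classes_ = np.array([False, True])
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        if not hasattr(self, "cutoff_"):
            raise AttributeError("YoudenCutpoint is not fitted")
        return self._scores(X) > self.cutoff_

    def score(self, X, y):
        """Youden J of the fitted cutoff on new data."""
        pred = self.predict(X)
        y = np.asarray(y).astype(bool)
        sens = np.mean(pred[y]) if y.any() else np.nan
        spec = np.mean(~pred[~y]) if (~y).any() else np.nan
        return float(sens + spec - 1.0)
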