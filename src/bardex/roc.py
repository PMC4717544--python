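"""Empirical ROC analysis of the displacement index against reoperation.

The score is the per-unit |BDI| magnitude; the positive class is group B
(reoperation required).  Candidate thresholds are the distinct observed
scores plus one sentinel above the maximum, and a unit is predicted positive
when score >= threshold.  The area under the empirical curve is computed by
the trapezoidal rule, which for this construction equals the Mann-Whitney
concordance probability with ties counted one half.

The confidence interval for the AUC uses the DeLong structural-components
variance estimator by default (deterministic); a stratified percentile
bootstrap is available as an alternative.  The operating threshold is chosen
by maximizing the Youden index J = sensitivity + specificity - 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .errors import DegenerateROCError, ValidationError

log = logging.getLogger("bardex.roc")

POSITIVE_GROUP = "B"


@dataclass(frozen=True)
class ROCPoint:
    threshold: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class ROCCurve:
    points: tuple[ROCPoint, ...]  # sorted by threshold ascending
    n_pos: int
    n_neg: int
    auc: float


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float


@dataclass(frozen=True)
class IntervalEstimate:
    point: float
    lower: float
    upper: float
    level: float
    method: str  # delong | bootstrap
    p_value: float | None = None  # two-sided test of AUC = 0.5 (DeLong z)


def _split_classes(
    scores: Sequence[float], labels: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have equal length")
    pos = scores[labels == POSITIVE_GROUP]
    neg = scores[labels != POSITIVE_GROUP]
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateROCError(
            f"degenerate ROC: need both classes, got {len(neg)} A / {len(pos)} B"
        )
    return pos, neg


def roc_curve(scores: Sequence[float], labels: Sequence[str]) -> ROCCurve:
    """Build the empirical ROC curve of ``scores`` against group labels.

    ``labels`` holds "A" (negative) / "B" (positive) per unit.  The returned
    points sweep thresholds from the minimum observed score (sensitivity 1,
    specificity 0) to a sentinel above the maximum (sensitivity 0,
    specificity 1).
    """
    pos, neg = _split_classes(scores, labels)
    thresholds = np.unique(np.concatenate([pos, neg]))
    thresholds = np.append(thresholds, thresholds[-1] + 1.0)  # sentinel
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    # score >= t is positive: sens = #(pos >= t)/n_pos, spec = #(neg < t)/n_neg
    # (kept as exact count ratios so equal-J ties compare exactly)
    sens = (len(pos) - np.searchsorted(pos_sorted, thresholds, side="left")) / len(pos)
    spec = np.searchsorted(neg_sorted, thresholds, side="left") / len(neg)
    fpr = 1.0 - spec
    # thresholds ascend, so fpr descends from 1 to 0; integrate in fpr order
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))
    points = tuple(
        ROCPoint(float(t), float(se), float(sp))
        for t, se, sp in zip(thresholds, sens, spec)
    )
    return ROCCurve(points=points, n_pos=len(pos), n_neg=len(neg), auc=auc)


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks of x (ties get the average rank), 1-based."""
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n, dtype=float)
    out[order] = ranks
    return out


def delong_variance(
    scores: Sequence[float], labels: Sequence[str]
) -> tuple[float, float]:
    """(AUC, variance of AUC) by the DeLong structural-components estimator."""
    pos, neg = _split_classes(scores, labels)
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n  # per-positive placement values
    v10 = 1.0 - (tz[m:] - ty) / m  # per-negative placement values
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    var = s01 / m + s10 / n
    return float(auc), float(max(var, 0.0))


def auc_ci(
    scores: Sequence[float],
    labels: Sequence[str],
    method: str = "delong",
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int | None = None,
) -> IntervalEstimate:
    """Confidence interval (and AUC=0.5 test) for the area under the curve.

    DeLong: normal interval from the structural-components variance,
    truncated to [0, 1]; the p-value is the two-sided normal tail of
    z = (AUC - 0.5)/SE.  Bootstrap: percentile interval over ``n_boot``
    stratified resamples driven by ``seed``.
    """
    if not (0 < level < 1):
        raise ValidationError(f"level must be in (0,1), got {level!r}")
    auc, var = delong_variance(scores, labels)
    se = float(np.sqrt(var))
    if se == 0.0:
        if auc in (0.0, 1.0):
            log.warning("degenerate AUC interval: zero variance at AUC=%s", auc)
        p_value = 0.0 if auc != 0.5 else 1.0
    else:
        z0 = (auc - 0.5) / se
        p_value = float(2.0 * norm.sf(abs(z0)))
    if method == "delong":
        z = float(norm.ppf(0.5 + level / 2.0))
        lower = max(0.0, auc - z * se)
        upper = min(1.0, auc + z * se)
    elif method == "bootstrap":
        if n_boot < 1:
            raise ValidationError("bootstrap requires n_boot >= 1")
        pos, neg = _split_classes(scores, labels)
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            bp = rng.choice(pos, size=len(pos), replace=True)
            bn = rng.choice(neg, size=len(neg), replace=True)
            reps[b] = _fast_auc(bp, bn)
        alpha = (1.0 - level) / 2.0
        lower, upper = np.quantile(reps, [alpha, 1.0 - alpha]).tolist()
    else:
        raise ValidationError(f"unknown CI method {method!r}")
    lower = min(lower, auc)
    upper = max(upper, auc)
    return IntervalEstimate(
        point=auc,
        lower=float(lower),
        upper=float(upper),
        level=level,
        method=method,
        p_value=p_value,
    )


def _fast_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney AUC (ties 0.5) via midranks; used by the bootstrap."""
    m = len(pos)
    tz = _midrank(np.concatenate([pos, neg]))
    return float((tz[:m].sum() - m * (m + 1) / 2.0) / (m * len(neg)))


def optimal_cutoff(curve: ROCCurve) -> CutoffResult:
    """Youden-optimal operating threshold of an ROC curve.

    Maximizes J = sensitivity + specificity - 1 over the curve's thresholds;
    ties are broken toward higher sensitivity, then lower threshold (the
    curve's threshold order makes these coincide).  A curve whose best J is
    not positive carries no usable operating point: the sentinel threshold is
    returned with a warning.
    """
    js = np.array([p.sensitivity + p.specificity - 1.0 for p in curve.points])
    if js.max() <= 0.0:
        log.warning("no informative threshold (max Youden J <= 0); "
                    "reporting the sentinel")
        p = curve.points[-1]
        return CutoffResult(p.threshold, p.sensitivity, p.specificity, float(js[-1]))
    # sensitivity is non-increasing in threshold, so the first argmax also
    # maximizes sensitivity and minimizes the threshold among ties
    i = int(np.argmax(js))
    p = curve.points[i]
    return CutoffResult(
        cutoff=p.threshold,
        sensitivity=p.sensitivity,
        specificity=p.specificity,
        youden_j=float(js[i]),
    )


#: Published decision threshold on the |BDI| scale (percent).
DEFAULT_CUTOFF = 8.7


def decide_reoperation(magnitude: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """Apply the decision rule: recommend correction when |BDI| >= cutoff."""
    if magnitude < 0:
        raise ValidationError(f"magnitude must be >= 0, got {magnitude!r}")
    if not (cutoff > 0):
        raise ValidationError(f"cutoff must be > 0, got {cutoff!r}")
    return "recommend_correction" if magnitude >= cutoff else "no_correction"
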