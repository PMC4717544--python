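"""Independent brute-force oracles used only by the test suite.

Each function recomputes a statistic by the most direct definition available
(exhaustive enumeration, exact rational arithmetic, pairwise counting), kept
deliberately independent of the library implementations it checks.
"""

from fractions import Fraction
from math import comb

import numpy as np


def concordance_auc(pos, neg) -> float:
    """AUC as the pairwise concordance probability, ties counted one half."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def exhaustive_youden(scores, labels):
    """Best (J, sensitivity, specificity, threshold) by trying every observed
    score plus a sentinel, predicting positive when score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == "B"]
    neg = scores[labels != "B"]
    best = None
    for t in sorted(set(scores)) + [scores.max() + 1.0]:
        sens = float(np.mean(pos >= t))
        spec = float(np.mean(neg < t))
        j = sens + spec - 1.0
        key = (j, sens, -t)  # prefer high J, then high sens, then low threshold
        if best is None or key > best[0]:
            best = (key, (j, sens, spec, t))
    return best[1]


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p as an exact rational: sum of hypergeometric point
    probabilities not exceeding the observed table's probability."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    total = Fraction(0)
    for x in range(lo, hi + 1):
        px = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        if px <= p_obs:
            total += px
    return total


def pearson_chi2(table) -> float:
    """Pearson statistic straight from the definition sum (O-E)^2 / E."""
    obs = np.asarray(table, dtype=float)
    rowsum = obs.sum(axis=1, keepdims=True)
    colsum = obs.sum(axis=0, keepdims=True)
    expected = rowsum * colsum / obs.sum()
    return float(((obs - expected) ** 2 / expected).sum())


def anova_f(groups) -> float:
    """One-way F from explicit between/within sums of squares."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = len(allv) - len(groups)
    return float((ssb / dfb) / (ssw / dfw))


def tertile_partition(magnitudes: dict):
    """Brute-force stable three-way split by (magnitude, bar_id)."""
    ordered = sorted(magnitudes, key=lambda k: (magnitudes[k], k))
    n = len(ordered)
    base, extra = divmod(n, 3)
    sizes = [base + (1 if i < extra else 0) for i in range(3)]
    labels = {}
    i = 0
    for t, s in enumerate(sizes, start=1):
        for k in ordered[i : i + s]:
            labels[k] = t
        i += s
    return labels
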