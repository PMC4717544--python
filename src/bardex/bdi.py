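"""Bar Displacement Index (BDI) computation and tertile stratification.

For a series of bar-position distances D0 (baseline, day after surgery) and
follow-ups D1..Dk, the index relative to an extreme follow-up distance Dx is

    BDI = (D0 - Dx) / D0 * 100

A positive index means the distance shrank (the bar moved upward, toward the
sternal reference point); a negative index means it grew (downward movement).
Two signed indices are computed per bar — against the minimal and the maximal
follow-up distance — and the single per-bar severity score is the larger
absolute deviation, matching the |BDI| used for tertile stratification and
the reoperation threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .io import BarSeries

Direction = str  # none | upward | downward | both


@dataclass(frozen=True)
class BDIResult:
    """Signed displacement indices for one bar.

    ``bdi_up >= 0`` is the index against the minimal follow-up distance
    (upward deviation), ``bdi_down <= 0`` against the maximal follow-up
    distance (downward deviation); ``magnitude = max(bdi_up, -bdi_down)``.
    """

    bar_id: str
    patient_id: str
    d0_mm: float
    d_min_mm: float
    d_max_mm: float
    bdi_up: float
    bdi_down: float
    magnitude: float
    direction: Direction


def compute_bdi(series: BarSeries, epsilon: float = 0.0) -> BDIResult:
    """Compute the displacement indices of one bar series.

    The extreme distances are taken over follow-up measurements only (the
    baseline is excluded).  ``epsilon`` (percent) is the minimum deviation
    counted as movement when classifying direction; the default counts any
    nonzero deviation.
    """
    if len(series.measurements) < 2:
        raise ValidationError(f"bar {series.bar_id!r}: no follow-up measurements")
    d0 = series.d0_mm
    follow = series.followup_distances
    d_min = min(follow)
    d_max = max(follow)
    bdi_up = max(0.0, (d0 - d_min) / d0 * 100.0)
    bdi_down = min(0.0, (d0 - d_max) / d0 * 100.0)
    magnitude = max(bdi_up, -bdi_down)
    return BDIResult(
        bar_id=series.bar_id,
        patient_id=series.patient_id,
        d0_mm=d0,
        d_min_mm=d_min,
        d_max_mm=d_max,
        bdi_up=bdi_up,
        bdi_down=bdi_down,
        magnitude=magnitude,
        direction=_direction(bdi_up, bdi_down, epsilon),
    )


def _direction(bdi_up: float, bdi_down: float, epsilon: float) -> Direction:
    up = bdi_up > epsilon
    down = -bdi_down > epsilon
    if up and down:
        return "both"
    if up:
        return "upward"
    if down:
        return "downward"
    return "none"


def classify_direction(result: BDIResult, epsilon: float = 0.0) -> Direction:
    """Direction label of a computed result (deterministic from the indices)."""
    return _direction(result.bdi_up, result.bdi_down, epsilon)


def patient_magnitude(
    results: Sequence[BDIResult], rule: str = "max"
) -> float:
    """Aggregate the bar-level magnitudes of one patient to a single score.

    Patients carry one or two bars; the default rule takes the worst bar
    (clinically conservative), ``rule="mean"`` averages instead.
    """
    if not results:
        raise ValidationError("patient_magnitude: empty result collection")
    pids = {r.patient_id for r in results}
    if len(pids) != 1:
        raise ValidationError(
            f"patient_magnitude: results span several patients: {sorted(pids)}"
        )
    mags = [r.magnitude for r in results]
    if rule == "max":
        return max(mags)
    if rule == "mean":
        return float(np.mean(mags))
    raise ValidationError(f"unknown aggregation rule {rule!r}")


@dataclass(frozen=True)
class TertileAssignment:
    """Rank-based split of bar magnitudes into three (near-)equal groups.

    ``boundaries`` are the maximal magnitudes of tertiles 1 and 2; ``labels``
    maps every bar_id to its tertile 1..3; ``summaries`` holds per-tertile
    (n, min, max, mean).
    """

    boundaries: tuple[float, float]
    labels: dict[str, int]
    summaries: dict[int, dict[str, float]]

    def sizes(self) -> tuple[int, int, int]:
        vals = list(self.labels.values())
        return (vals.count(1), vals.count(2), vals.count(3))


def assign_tertiles(magnitudes: Mapping[str, float]) -> TertileAssignment:
    """Split bars into magnitude tertiles.

    Bars are sorted by (magnitude, bar_id) — the stable key makes ties
    deterministic — and cut into three consecutive groups whose sizes differ
    by at most one (30/30/30 for 90 bars).
    """
    n = len(magnitudes)
    if n < 3:
        raise ValidationError(f"assign_tertiles: need >=3 bars, got {n}")
    ordered = sorted(magnitudes.items(), key=lambda kv: (kv[1], kv[0]))
    chunks = np.array_split(np.arange(n), 3)
    labels: dict[str, int] = {}
    summaries: dict[int, dict[str, float]] = {}
    for t, idx in enumerate(chunks, start=1):
        mags = [ordered[i][1] for i in idx]
        for i in idx:
            labels[ordered[i][0]] = t
        summaries[t] = {
            "n": float(len(idx)),
            "min": float(min(mags)),
            "max": float(max(mags)),
            "mean": float(np.mean(mags)),
        }
    return TertileAssignment(
        boundaries=(summaries[1]["max"], summaries[2]["max"]),
        labels=labels,
        summaries=summaries,
    )


def bdi_table(
    results: Iterable[BDIResult], assignment: TertileAssignment | None = None
):
    """Flatten results (plus optional tertile labels) into a DataFrame."""
    import pandas as pd

    rows = []
    for r in sorted(results, key=lambda r: r.bar_id):
        rows.append(
            {
                "bar_id": r.bar_id,
                "patient_id": r.patient_id,
                "d0_mm": r.d0_mm,
                "d_min_mm": r.d_min_mm,
                "d_max_mm": r.d_max_mm,
                "bdi_up": r.bdi_up,
                "bdi_down": r.bdi_down,
                "magnitude": r.magnitude,
                "direction": r.direction,
                "tertile": assignment.labels[r.bar_id] if assignment else None,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "bar_id",
            "patient_id",
            "d0_mm",
            "d_min_mm",
            "d_max_mm",
            "bdi_up",
            "bdi_down",
            "magnitude",
            "direction",
            "tertile",
        ],
    )
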