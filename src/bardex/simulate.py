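"""Synthetic cohort generator for the displacement-index pipeline.

No patient-level measurements from the original study are available, so
every pipeline stage is exercised on simulated cohorts.  The generator
emulates the study's composition: 61 patients carrying 90 bars (29 of them
with parallel double bars), 7 requiring reoperation, five serial lateral
radiographs per bar (postoperative days 1, 7, 14, 30, 90), group-conditional
covariate distributions matching the published summary statistics, and
per-bar maximal |BDI| drawn from group-dependent normal scales.

The displacement scales of the two groups are calibrated so that the
closed-form binormal AUC, Phi(delta / sqrt(sd_A^2 + sd_B^2)), equals the
study's reported discrimination of 0.858: with sd_A = 3 and sd_B = 5 the
group-B mean exceeds the group-A mean by Phi^-1(0.858) * sqrt(34) ≈ 6.2
index points (A: 4.0 ± 3.0, B: 10.2 ± 5.0).

Magnitude draws are truncated at zero by resampling, so the realized mean
slightly exceeds the configured one when the scale puts appreciable mass
below zero; the analytic truncated-normal mean is the exact contract.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from scipy.stats import norm

from .errors import ValidationError
from .grading import ClinicalFlags
from .io import DEFAULT_SCHEDULE_DAYS, BarSeries, Measurement, PatientRecord

_MAX_RESAMPLE = 1000


@dataclass(frozen=True)
class Scale:
    """Mean and standard deviation of a normal draw (before truncation)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError(f"sd must be >= 0, got {self.sd!r}")


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """All distributional parameters of the simulated cohort.

    Defaults reproduce the study composition: 61 patients, 29/61 with double
    bars (hence 90 bars), 7/61 reoperated, baseline bar-position distance
    50 ± 8 mm, radiographs on days 1/7/14/30/90, and group-conditional
    covariates set to the published means ± SDs.  Direction frequencies
    follow the reported 42 upward / 27 downward / 21 both of 90 bars.
    """

    n_patients: int = 61
    p_double_bar: float = 29 / 61
    p_reoperation: float = 7 / 61
    baseline_distance: Scale = field(default_factory=lambda: Scale(50.0, 8.0))
    followup_days: tuple[int, ...] = DEFAULT_SCHEDULE_DAYS[1:]  # after day-1 baseline
    displacement_scale_A: Scale = field(default_factory=lambda: Scale(4.0, 3.0))
    displacement_scale_B: Scale = field(default_factory=lambda: Scale(10.2, 5.0))
    p_upward: float = 42 / 90
    p_both: float = 21 / 90
    # group-conditional covariate scales (study group A vs B)
    age: tuple[Scale, Scale] = (Scale(14.0, 7.5), Scale(23.3, 12.0))
    height_m: tuple[Scale, Scale] = (Scale(1.5, 0.3), Scale(1.6, 0.3))
    bmi: tuple[Scale, Scale] = (Scale(18.2, 2.8), Scale(19.5, 2.4))
    pre_hi: tuple[Scale, Scale] = (Scale(4.0, 1.1), Scale(5.0, 1.0))
    post_hi: tuple[Scale, Scale] = (Scale(2.7, 0.4), Scale(3.2, 0.5))
    p_male: float = 54 / 61
    p_symmetric: float = 32 / 61
    p_urgent_given_b: float = 3 / 7  # category 4 among reoperation patients
    p_moderate_given_a: float = 8 / 54  # category 2 among non-reoperation patients
    trajectory_noise_sd: float = 0.2  # of the target deviation
    age_bounds: tuple[float, float] = (3.0, 40.0)
    hi_lower: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_double_bar",
            "p_reoperation",
            "p_upward",
            "p_both",
            "p_male",
            "p_symmetric",
            "p_urgent_given_b",
            "p_moderate_given_a",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0,1], got {v!r}")
        if self.p_upward + self.p_both > 1.0 + 1e-12:
            raise ValidationError("p_upward + p_both must not exceed 1")
        if self.n_patients < 2:
            raise ValidationError("n_patients must be >= 2")
        days = self.followup_days
        if len(days) < 1 or any(d < 1 for d in days) or any(
            b <= a for a, b in zip(days, days[1:])
        ):
            raise ValidationError(
                "followup_days must be strictly increasing and >= 1"
            )

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "SyntheticCohortConfig":
        raw = json.loads(Path(path).read_text())

        def scale(v):  # lists arrive from JSON
            return Scale(**v) if isinstance(v, dict) else v

        for k in ("baseline_distance", "displacement_scale_A", "displacement_scale_B"):
            if k in raw:
                raw[k] = scale(raw[k])
        for k in ("age", "height_m", "bmi", "pre_hi", "post_hi"):
            if k in raw:
                raw[k] = tuple(scale(v) for v in raw[k])
        for k in ("followup_days", "age_bounds"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)


def binormal_auc(mu0: float, sd0: float, mu1: float, sd1: float) -> float:
    """Closed-form AUC of two normal score distributions.

    Returns Phi((mu1 - mu0) / sqrt(sd0^2 + sd1^2)); with both SDs zero the
    limit is 0, 0.5 or 1 by the sign of mu1 - mu0.
    """
    if sd0 < 0 or sd1 < 0:
        raise ValidationError("standard deviations must be >= 0")
    denom = float(np.hypot(sd0, sd1))
    if denom == 0.0:
        d = mu1 - mu0
        return 0.5 if d == 0 else (1.0 if d > 0 else 0.0)
    return float(norm.cdf((mu1 - mu0) / denom))


def _trunc_normal(
    rng: np.random.Generator,
    scale: Scale,
    low: float = -np.inf,
    high: float = np.inf,
) -> float:
    """One normal draw resampled into (low, high); clipped after too many tries."""
    for _ in range(_MAX_RESAMPLE):
        v = rng.normal(scale.mean, scale.sd)
        if low < v < high:
            return float(v)
    return float(np.clip(scale.mean, low, high))


def _exact_count(n: int, p: float) -> int:
    return int(round(n * p))


def _plant_trajectory(
    rng: np.random.Generator,
    cfg: SyntheticCohortConfig,
    d0: float,
    magnitude: float,
    direction: str,
) -> tuple[Measurement, ...]:
    """Build follow-up distances whose extreme deviation realizes the target.

    The target deviation is planted at a uniformly chosen follow-up day; the
    days before ramp toward it with multiplicative noise (clipped so nothing
    overshoots the extreme) and the days after hold a partial deviation.  For
    a both-direction bar a smaller opposite-sign deviation is planted at
    another day, so the primary extreme still defines the magnitude.
    """
    days = cfg.followup_days
    k = len(days)
    sign = 1.0 if direction in ("upward", "both") else -1.0
    delta = magnitude / 100.0 * d0  # mm, subtracted when the bar moves up
    star = int(rng.integers(k))
    fractions = np.empty(k)
    for i in range(k):
        if i < star:
            base = (i + 1) / (star + 1)
        elif i == star:
            base = 1.0
        else:
            base = rng.uniform(0.5, 1.0)
        noisy = base * (1.0 + cfg.trajectory_noise_sd * rng.normal())
        fractions[i] = 1.0 if i == star else float(np.clip(noisy, 0.0, 0.999))
    distances = d0 - sign * delta * fractions
    if direction == "both" and k >= 2:
        other_days = [i for i in range(k) if i != star]
        j = other_days[int(rng.integers(len(other_days)))]
        secondary = delta * rng.uniform(0.2, 0.8)
        distances[j] = d0 + sign * secondary
    if direction == "none":
        distances = np.full(k, d0)
    baseline_day = 1 if days[0] > 1 else 0
    out = [Measurement(baseline_day, float(d0))]
    out.extend(
        Measurement(int(day), float(dist)) for day, dist in zip(days, distances)
    )
    return tuple(out)


_CATEGORY_FLAGS = {
    1: ClinicalFlags(False, False, False, False),
    2: ClinicalFlags(True, True, False, False),
    3: ClinicalFlags(True, True, True, False),
    4: ClinicalFlags(True, True, True, True),
}


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[PatientRecord], list[BarSeries], dict[str, str]]:
    """Generate a reproducible cohort of patients, bar series, and labels.

    Returns ``(patients, bars, labels)`` where ``labels`` maps bar_id to its
    patient's group ("A"/"B").  Group sizes and the double-bar count are
    allocated exactly (``round(n * fraction)`` via a seeded permutation), so
    the defaults reproduce the study composition deterministically: 61
    patients, 90 bars, 7 reoperations.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    n_reop = _exact_count(n, config.p_reoperation)
    n_double = _exact_count(n, config.p_double_bar)
    groups = np.array(["A"] * n, dtype=object)
    groups[rng.permutation(n)[:n_reop]] = "B"
    double = np.zeros(n, dtype=bool)
    double[rng.permutation(n)[:n_double]] = True

    patients: list[PatientRecord] = []
    bars: list[BarSeries] = []
    labels: dict[str, str] = {}
    width = len(str(n))
    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        g = 0 if groups[i] == "A" else 1
        if groups[i] == "B":
            category = 4 if rng.random() < config.p_urgent_given_b else 3
        else:
            category = 2 if rng.random() < config.p_moderate_given_a else 1
        height = _trunc_normal(rng, config.height_m[g], low=0.5, high=2.2)
        bmi = _trunc_normal(rng, config.bmi[g], low=8.0, high=45.0)
        pre_hi = _trunc_normal(rng, config.pre_hi[g], low=config.hi_lower)
        patients.append(
            PatientRecord(
                patient_id=pid,
                age=_trunc_normal(rng, config.age[g], *config.age_bounds),
                sex="male" if rng.random() < config.p_male else "female",
                height_m=height,
                weight_kg=bmi * height**2,
                bmi=bmi,
                pre_hi=pre_hi,
                post_hi=_trunc_normal(rng, config.post_hi[g], low=config.hi_lower),
                pectus_type=(
                    "symmetric" if rng.random() < config.p_symmetric else "asymmetric"
                ),
                n_bars=2 if double[i] else 1,
                flags=_CATEGORY_FLAGS[category],
                reoperated=bool(groups[i] == "B"),
            )
        )
        scale = (
            config.displacement_scale_B if groups[i] == "B"
            else config.displacement_scale_A
        )
        for b in range(2 if double[i] else 1):
            bar_id = f"{pid}-b{b + 1}"
            d0 = _trunc_normal(rng, config.baseline_distance, low=1.0)
            magnitude = _trunc_normal(rng, scale, low=0.0, high=95.0)
            u = rng.random()
            if u < config.p_both:
                direction = "both"
            elif u < config.p_both + config.p_upward:
                direction = "upward"
            else:
                direction = "downward"
            bars.append(
                BarSeries(
                    bar_id=bar_id,
                    patient_id=pid,
                    measurements=_plant_trajectory(
                        rng, config, d0, magnitude, direction
                    ),
                )
            )
            labels[bar_id] = str(groups[i])
    return patients, bars, labels


def generate_scores(
    rng: np.random.Generator,
    n_neg: int,
    n_pos: int,
    scale_neg: Scale,
    scale_pos: Scale,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw binormal score samples (negatives, positives) for calibration
    studies; unlike cohort magnitudes these are not truncated."""
    return (
        rng.normal(scale_neg.mean, scale_neg.sd, n_neg),
        rng.normal(scale_pos.mean, scale_pos.sd, n_pos),
    )
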