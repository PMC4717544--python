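"""Reading, validating, and writing the cohort tables.

Two plain-CSV schemas are the interchange format of the pipeline:

``measurements.csv``
    one row per (bar, timepoint):
    ``bar_id,patient_id,timepoint_days,distance_mm``

``patients.csv``
    one row per patient:
    ``patient_id,age,sex,height_m,weight_kg,bmi,pre_hi,post_hi,pectus_type,
    n_bars,flag_displaced,flag_morph_change,flag_correction_necessary,
    flag_organ_compression,reoperated``

Distances are bar-position distances in mm measured on lateral chest
radiographs; the first measurement of each series is the post-operative
baseline D0.  Covariates may be missing (empty cell); each downstream
statistic excludes missing values pairwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Sequence, Union

import pandas as pd

from .errors import SchemaError, ValidationError
from .grading import ClinicalFlags

log = logging.getLogger("bardex.io")

Source = Union[str, Path, IO[str]]

MEASUREMENT_COLUMNS = ["bar_id", "patient_id", "timepoint_days", "distance_mm"]
PATIENT_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "height_m",
    "weight_kg",
    "bmi",
    "pre_hi",
    "post_hi",
    "pectus_type",
    "n_bars",
    "flag_displaced",
    "flag_morph_change",
    "flag_correction_necessary",
    "flag_organ_compression",
    "reoperated",
]

#: Conventional radiograph schedule: day 1, 1 week, 2 weeks, 1 month, 3 months.
DEFAULT_SCHEDULE_DAYS = (1, 7, 14, 30, 90)

_BASELINE_WARN_DAY = 3  # baseline is expected "the day after surgery"


@dataclass(frozen=True)
class Measurement:
    timepoint_days: int
    distance_mm: float


@dataclass(frozen=True)
class BarSeries:
    """Ordered serial bar-position distances for one pectus bar.

    The first measurement is the baseline D0 (taken the day after surgery);
    all later measurements are follow-up candidates for the extreme distance
    Dx.  Timepoints are days since surgery, strictly increasing; distances
    are strictly positive.
    """

    bar_id: str
    patient_id: str
    measurements: tuple[Measurement, ...]

    def __post_init__(self) -> None:
        if len(self.measurements) < 2:
            raise ValidationError(
                f"bar {self.bar_id!r}: needs a baseline plus >=1 follow-up, "
                f"got {len(self.measurements)} measurement(s)"
            )
        days = [m.timepoint_days for m in self.measurements]
        if any(d < 0 for d in days):
            raise ValidationError(f"bar {self.bar_id!r}: negative timepoint_days")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValidationError(
                f"bar {self.bar_id!r}: timepoint_days not strictly increasing"
            )
        for m in self.measurements:
            if not (m.distance_mm > 0):
                raise ValidationError(
                    f"bar {self.bar_id!r}, day {m.timepoint_days}: "
                    f"distance_mm must be > 0, got {m.distance_mm!r}"
                )
        if days[0] > _BASELINE_WARN_DAY:
            log.warning(
                "bar %s: earliest measurement at day %d used as baseline D0 "
                "(expected within %d days of surgery)",
                self.bar_id,
                days[0],
                _BASELINE_WARN_DAY,
            )

    @property
    def d0_mm(self) -> float:
        return self.measurements[0].distance_mm

    @property
    def followup_distances(self) -> tuple[float, ...]:
        return tuple(m.distance_mm for m in self.measurements[1:])


@dataclass(frozen=True)
class PatientRecord:
    """One patient's covariates, clinical flags, and outcome.

    Continuous covariates may be missing (NaN).  When height, weight and BMI
    are all present, BMI must agree with weight/height^2 within 0.5 kg/m^2.
    """

    patient_id: str
    age: float
    sex: str  # male | female
    height_m: float
    weight_kg: float
    bmi: float
    pre_hi: float
    post_hi: float
    pectus_type: str  # symmetric | asymmetric
    n_bars: int  # 1 | 2
    flags: ClinicalFlags = field(
        default_factory=lambda: ClinicalFlags(False, False, False, False)
    )
    reoperated: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValidationError(
                f"patient {self.patient_id!r}: sex must be male/female, "
                f"got {self.sex!r}"
            )
        if self.pectus_type not in ("symmetric", "asymmetric"):
            raise ValidationError(
                f"patient {self.patient_id!r}: pectus_type must be "
                f"symmetric/asymmetric, got {self.pectus_type!r}"
            )
        if self.n_bars not in (1, 2):
            raise ValidationError(
                f"patient {self.patient_id!r}: n_bars must be 1 or 2, "
                f"got {self.n_bars!r}"
            )
        trio = (self.height_m, self.weight_kg, self.bmi)
        if all(v is not None and not math.isnan(v) for v in trio):
            implied = self.weight_kg / self.height_m**2
            if abs(implied - self.bmi) > 0.5:
                raise ValidationError(
                    f"patient {self.patient_id!r}: bmi {self.bmi:.2f} "
                    f"inconsistent with weight/height^2 = {implied:.2f}"
                )


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {', '.join(missing)}")


def read_measurements(source: Source) -> list[BarSeries]:
    """Parse a measurements CSV into one validated :class:`BarSeries` per bar.

    Rows are grouped by ``bar_id`` and sorted by ``timepoint_days``; input
    row order is irrelevant.  Bars are returned sorted by ``bar_id``.
    """
    df = pd.read_csv(source, float_precision="round_trip")
    _require_columns(df, MEASUREMENT_COLUMNS, "measurements")
    dup = df.duplicated(subset=["bar_id", "timepoint_days"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["bar_id", "timepoint_days"]].drop_duplicates()
        raise ValidationError(
            "duplicate (bar_id, timepoint_days) rows: "
            + "; ".join(f"({r.bar_id}, {r.timepoint_days})" for r in pairs.itertuples())
        )
    bad = df.index[~(df["distance_mm"] > 0)]
    if len(bad) > 0:
        i = int(bad[0])
        raise ValidationError(
            f"measurements row {i} (bar {df.at[i, 'bar_id']!r}): "
            f"distance_mm must be > 0, got {df.at[i, 'distance_mm']!r}"
        )
    series: list[BarSeries] = []
    for bar_id, g in df.sort_values("timepoint_days").groupby("bar_id", sort=True):
        pids = g["patient_id"].unique()
        if len(pids) != 1:
            raise ValidationError(
                f"bar {bar_id!r} mapped to multiple patients: {sorted(pids)}"
            )
        series.append(
            BarSeries(
                bar_id=str(bar_id),
                patient_id=str(pids[0]),
                measurements=tuple(
                    Measurement(int(r.timepoint_days), float(r.distance_mm))
                    for r in g.itertuples()
                ),
            )
        )
    return series


def _as_flag(value: object, column: str, patient_id: str) -> bool:
    try:
        iv = int(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        iv = -1
    if iv not in (0, 1):
        raise ValidationError(
            f"patient {patient_id!r}: {column} must be 0 or 1, got {value!r}"
        )
    return bool(iv)


def read_patients(source: Source) -> list[PatientRecord]:
    """Parse a patients CSV into validated :class:`PatientRecord` objects."""
    df = pd.read_csv(source, float_precision="round_trip")
    _require_columns(df, PATIENT_COLUMNS, "patients")
    records: list[PatientRecord] = []
    for r in df.itertuples():
        pid = str(r.patient_id)
        flags = ClinicalFlags(
            displaced=_as_flag(r.flag_displaced, "flag_displaced", pid),
            morph_change=_as_flag(r.flag_morph_change, "flag_morph_change", pid),
            correction_necessary=_as_flag(
                r.flag_correction_necessary, "flag_correction_necessary", pid
            ),
            organ_compression=_as_flag(
                r.flag_organ_compression, "flag_organ_compression", pid
            ),
        )
        records.append(
            PatientRecord(
                patient_id=pid,
                age=float(r.age),
                sex=str(r.sex),
                height_m=float(r.height_m),
                weight_kg=float(r.weight_kg),
                bmi=float(r.bmi),
                pre_hi=float(r.pre_hi),
                post_hi=float(r.post_hi),
                pectus_type=str(r.pectus_type),
                n_bars=int(r.n_bars),
                flags=flags,
                reoperated=_as_flag(r.reoperated, "reoperated", pid),
            )
        )
    records.sort(key=lambda p: p.patient_id)
    return records


def validate_cohort(
    bars: Iterable[BarSeries], patients: Iterable[PatientRecord]
) -> None:
    """Cross-table check: each patient's n_bars equals their bar count."""
    counts: dict[str, int] = {}
    for b in bars:
        counts[b.patient_id] = counts.get(b.patient_id, 0) + 1
    for p in patients:
        have = counts.get(p.patient_id, 0)
        if have != p.n_bars:
            raise ValidationError(
                f"patient {p.patient_id!r}: n_bars={p.n_bars} but "
                f"{have} bar series present"
            )


def measurements_frame(bars: Iterable[BarSeries]) -> pd.DataFrame:
    rows = [
        (b.bar_id, b.patient_id, m.timepoint_days, m.distance_mm)
        for b in sorted(bars, key=lambda b: b.bar_id)
        for m in b.measurements
    ]
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def patients_frame(patients: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = []
    for p in sorted(patients, key=lambda p: p.patient_id):
        rows.append(
            (
                p.patient_id,
                p.age,
                p.sex,
                p.height_m,
                p.weight_kg,
                p.bmi,
                p.pre_hi,
                p.post_hi,
                p.pectus_type,
                p.n_bars,
                int(p.flags.displaced),
                int(p.flags.morph_change),
                int(p.flags.correction_necessary),
                int(p.flags.organ_compression),
                int(p.reoperated),
            )
        )
    return pd.DataFrame(rows, columns=PATIENT_COLUMNS)


def write_cohort(
    bars: Iterable[BarSeries],
    patients: Iterable[PatientRecord],
    out_dir: Union[str, Path],
) -> tuple[Path, Path]:
    """Write ``measurements.csv`` and ``patients.csv`` under ``out_dir``.

    Column order is fixed and floats use the shortest round-tripping
    representation, so output is byte-stable and
    ``read(write(cohort)) == cohort`` field for field.
    """
    bars = list(bars)
    patients = list(patients)
    validate_cohort(bars, patients)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m_path = out / "measurements.csv"
    p_path = out / "patients.csv"
    measurements_frame(bars).to_csv(m_path, index=False, lineterminator="\n")
    patients_frame(patients).to_csv(p_path, index=False, lineterminator="\n")
    return m_path, p_path


def scale_series(series: BarSeries, factor: float) -> BarSeries:
    """Return a copy of ``series`` with every distance multiplied by ``factor``."""
    if not (factor > 0):
        raise ValidationError(f"scale factor must be > 0, got {factor!r}")
    return replace(
        series,
        measurements=tuple(
            Measurement(m.timepoint_days, m.distance_mm * factor)
            for m in series.measurements
        ),
    )
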