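"""End-to-end orchestration: tables in, report bundle out.

``run_pipeline`` chains the stages — read and validate the cohort, compute
per-bar displacement indices, grade patients, build the ROC of |BDI| against
the reoperation group, select the Youden-optimal threshold, and produce the
group-comparison and tertile tables — then writes the full report bundle:

    bdi.csv, grades.csv, roc.json, roc_points.csv, table2.csv, table3.csv,
    summary.json
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from . import bdi as bdi_mod
from . import io as io_mod
from . import roc as roc_mod
from . import stats as stats_mod
from .errors import BardexError, ValidationError
from .grading import grade_displacement

log = logging.getLogger("bardex.pipeline")

BUNDLE_FILES = (
    "bdi.csv",
    "grades.csv",
    "roc.json",
    "roc_points.csv",
    "table2.csv",
    "table3.csv",
    "summary.json",
)


@dataclass
class PipelineConfig:
    measurements_path: Union[str, Path]
    patients_path: Union[str, Path]
    out_dir: Union[str, Path]
    unit: str = "bar"  # bar | patient — unit of the ROC analysis
    label_by: str = "grade"  # grade | reoperated
    cutoff_override: float | None = None
    ci_method: str = "delong"
    n_boot: int = 2000
    level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.unit not in ("bar", "patient"):
            raise ValidationError(f"unit must be bar|patient, got {self.unit!r}")
        if not (0 < self.level < 1):
            raise ValidationError(f"level must be in (0,1), got {self.level!r}")
        if self.ci_method == "bootstrap" and self.n_boot < 1:
            raise ValidationError("n_boot must be >= 1 for bootstrap")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Returns the in-memory bundle (a dict mirroring the written files).
    Deterministic for a fixed config and seed.
    """
    log.info("stage=io reading %s, %s", config.measurements_path, config.patients_path)
    bars = io_mod.read_measurements(config.measurements_path)
    patients = io_mod.read_patients(config.patients_path)
    io_mod.validate_cohort(bars, patients)

    log.info("stage=bdi computing indices for %d bars", len(bars))
    results = [bdi_mod.compute_bdi(b) for b in bars]
    magnitudes = {r.bar_id: r.magnitude for r in results}
    tertiles = bdi_mod.assign_tertiles(magnitudes)

    log.info("stage=grading grading %d patients", len(patients))
    grades = {p.patient_id: grade_displacement(p.flags) for p in patients}
    group_of = {
        p.patient_id: stats_mod.patient_group(p, config.label_by) for p in patients
    }

    log.info("stage=roc unit=%s ci=%s seed=%d", config.unit, config.ci_method,
             config.seed)
    if config.unit == "bar":
        scores = [r.magnitude for r in results]
        labels = [group_of[r.patient_id] for r in results]
    else:
        by_patient: dict[str, list] = {}
        for r in results:
            by_patient.setdefault(r.patient_id, []).append(r)
        pids = sorted(by_patient)
        scores = [bdi_mod.patient_magnitude(by_patient[pid]) for pid in pids]
        labels = [group_of[pid] for pid in pids]
    curve = roc_mod.roc_curve(scores, labels)
    interval = roc_mod.auc_ci(
        scores,
        labels,
        method=config.ci_method,
        level=config.level,
        n_boot=config.n_boot,
        seed=config.seed,
    )
    cut = roc_mod.optimal_cutoff(curve)
    applied_cutoff = (
        config.cutoff_override if config.cutoff_override is not None else cut.cutoff
    )
    decisions = {
        r.bar_id: roc_mod.decide_reoperation(r.magnitude, applied_cutoff)
        for r in results
    }

    log.info("stage=stats group comparison and tertile tables")
    table2 = stats_mod.compare_groups(patients, label_by=config.label_by)
    table3 = stats_mod.tertile_table(patients, results, tertiles)

    direction_counts = {
        d: sum(1 for r in results if r.direction == d)
        for d in ("upward", "downward", "both", "none")
    }
    roc_report = {
        "auc": interval.point,
        "ci": [interval.lower, interval.upper],
        "ci_level": interval.level,
        "ci_method": interval.method,
        "p_value_vs_chance": interval.p_value,
        "cutoff": cut.cutoff,
        "sensitivity": cut.sensitivity,
        "specificity": cut.specificity,
        "youden_j": cut.youden_j,
        "n_pos": curve.n_pos,
        "n_neg": curve.n_neg,
        "unit": config.unit,
    }
    summary = {
        "n_patients": len(patients),
        "n_bars": len(bars),
        "group_sizes": {
            g: sum(1 for v in group_of.values() if v == g) for g in ("A", "B")
        },
        "direction_counts": direction_counts,
        "tertile_boundaries": list(tertiles.boundaries),
        "tertile_sizes": list(tertiles.sizes()),
        "applied_cutoff": applied_cutoff,
        "n_recommend_correction": sum(
            1 for v in decisions.values() if v == "recommend_correction"
        ),
        "roc": roc_report,
        "table2_p_values": {r.variable: r.p_value for r in table2},
        "seed": config.seed,
    }

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bdi_df = bdi_mod.bdi_table(results, tertiles)
    bdi_df["decision"] = [decisions[b] for b in bdi_df["bar_id"]]
    bdi_df.to_csv(out / "bdi.csv", index=False, lineterminator="\n")
    grades_df = pd.DataFrame(
        [
            {
                "patient_id": pid,
                "category": g.category,
                "label": g.label,
                "group": g.group,
            }
            for pid, g in sorted(grades.items())
        ]
    )
    grades_df.to_csv(out / "grades.csv", index=False, lineterminator="\n")
    (out / "roc.json").write_text(json.dumps(roc_report, indent=2) + "\n")
    pd.DataFrame(
        [(p.threshold, p.sensitivity, p.specificity) for p in curve.points],
        columns=["threshold", "sensitivity", "specificity"],
    ).to_csv(out / "roc_points.csv", index=False, lineterminator="\n")
    stats_mod.reports_frame(table2).to_csv(
        out / "table2.csv", index=False, lineterminator="\n"
    )
    stats_mod.reports_frame(table3).to_csv(
        out / "table3.csv", index=False, lineterminator="\n"
    )
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    log.info("stage=report bundle written to %s", out)
    return summary


def render_summary(bundle: dict) -> str:
    """One-page plain-text summary of a pipeline report bundle."""
    required = (
        "n_patients",
        "n_bars",
        "group_sizes",
        "direction_counts",
        "roc",
        "applied_cutoff",
        "table2_p_values",
        "tertile_boundaries",
    )
    for key in required:
        if key not in bundle:
            raise BardexError(f"render_summary: bundle is missing {key!r}")
    roc = bundle["roc"]
    lines = [
        "Bar displacement analysis summary",
        "=================================",
        f"Cohort: {bundle['n_patients']} patients, {bundle['n_bars']} bars "
        f"(group A: {bundle['group_sizes']['A']}, group B: {bundle['group_sizes']['B']})",
        "Displacement direction: "
        + ", ".join(f"{k} {v}" for k, v in bundle["direction_counts"].items()),
        f"Tertile boundaries (|BDI| %): "
        f"{bundle['tertile_boundaries'][0]:.1f}, {bundle['tertile_boundaries'][1]:.1f}",
        "",
        f"AUC: {roc['auc']:.3f} "
        f"({roc['ci_level'] * 100:.0f}% CI {roc['ci'][0]:.3f}-{roc['ci'][1]:.3f}, "
        f"{roc['ci_method']}, unit={roc['unit']})",
        f"Youden-optimal cutoff: {roc['cutoff']:.2f} "
        f"(sensitivity {roc['sensitivity']:.2f}, specificity {roc['specificity']:.2f}, "
        f"J {roc['youden_j']:.2f})",
        f"Decision threshold applied: recommend correction when |BDI| >= "
        f"{bundle['applied_cutoff']:.2f} "
        f"({bundle.get('n_recommend_correction', 0)} bar(s) flagged)",
        "",
        "Group comparison p-values:",
    ]
    for var, p in bundle["table2_p_values"].items():
        lines.append(f"  {var}: p = {p:.4f}")
    return "\n".join(lines) + "\n"
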