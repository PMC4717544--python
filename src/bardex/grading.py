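"""Four-category clinical grading of pectus bar displacement.

Displacement after bar insertion is graded 1 (mild) to 4 (urgent) from four
clinical observations: whether the bar has moved on imaging, whether the
movement produced externally visible morphologic change of the chest wall,
whether the surgeon judges correction necessary, and whether the displaced
bar compresses intrathoracic organs (or carries a high risk of organ injury
or an abnormal EKG).  Grades 1-2 form group A (no reoperation); grades 3-4
form group B (reoperation required).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

GRADE_LABELS = {1: "Mild", 2: "Moderate", 3: "Severe", 4: "Urgent"}


@dataclass(frozen=True)
class ClinicalFlags:
    """Clinical observations that determine the displacement grade.

    Invariants: organ compression implies the bar is displaced, and a
    judgment that correction is necessary implies a morphologic change
    was observed.
    """

    displaced: bool
    morph_change: bool
    correction_necessary: bool
    organ_compression: bool

    def __post_init__(self) -> None:
        if self.organ_compression and not self.displaced:
            raise ValidationError(
                "invalid flags: organ_compression requires displaced"
            )
        if self.correction_necessary and not self.morph_change:
            raise ValidationError(
                "invalid flags: correction_necessary requires morph_change"
            )


@dataclass(frozen=True)
class DisplacementGrade:
    category: int  # 1..4
    label: str  # Mild / Moderate / Severe / Urgent
    group: str  # "A" (no reoperation) or "B" (reoperation)


def reoperation_group(category: int) -> str:
    """Map a displacement category to its management group.

    Categories 1-2 -> group A (no surgical intervention needed);
    categories 3-4 -> group B (reoperation required).
    """
    if category not in (1, 2, 3, 4):
        raise ValidationError(f"category must be in 1..4, got {category!r}")
    return "A" if category <= 2 else "B"


def grade_displacement(flags: ClinicalFlags) -> DisplacementGrade:
    """Grade bar displacement from the clinical flags.

    The grade is the most severe category supported by the flags:

    * 4 (Urgent)   — organ compression / high risk of organ injury;
    * 3 (Severe)   — correction of the displacement is necessary;
    * 2 (Moderate) — displacement with external morphologic change but no
      correction needed;
    * 1 (Mild)     — no displacement, or displacement without any external
      morphologic change.

    Monotone: setting an additional severity flag never lowers the category.
    """
    if flags.organ_compression:
        category = 4
    elif flags.correction_necessary:
        category = 3
    elif flags.displaced and flags.morph_change:
        category = 2
    else:
        category = 1
    return DisplacementGrade(
        category=category,
        label=GRADE_LABELS[category],
        group=reoperation_group(category),
    )
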