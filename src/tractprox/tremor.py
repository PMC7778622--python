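"""UPDRS-III resting-tremor scoring, response classification, inclusion.

Resting tremor is scored 0-4 on five items — right arm, left arm, right
leg, left leg, lips/jaw — so the global score tops out at 20 and the
per-side limb score (arm + leg) at 8.  Percentages divide by those maxima;
the improvement is the pre-minus-post percentage difference and a
hemisphere counts as a responder only for a strictly positive improvement
(zero or negative change is "no improvement").  A hemisphere enters the
imaging analysis only if the contralateral body half had any resting
tremor at baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ITEMS = ("arm_right", "arm_left", "leg_right", "leg_left", "lips_jaw")
GLOBAL_MAX = 20
LIMB_MAX = 8


@dataclass
class TremorAssessment:
    """One UPDRS-III examination (items 0-4 each)."""

    arm_right: int
    arm_left: int
    leg_right: int
    leg_left: int
    lips_jaw: int
    updrs3_total: int
    state: str = "OFF-MED"
    visit_month: float = 0

    def __post_init__(self) -> None:
        for name in ITEMS:
            v = getattr(self, name)
            if not 0 <= v <= 4:
                raise ValueError(f"{name} must be in [0, 4], got {v}")
        if self.updrs3_total < self.resting_tremor_sum:
            raise ValueError("UPDRS III total cannot be below the tremor item sum")

    @property
    def resting_tremor_sum(self) -> int:
        return sum(getattr(self, n) for n in ITEMS)

    def limb_sum(self, side: str) -> int:
        return getattr(self, f"arm_{side}") + getattr(self, f"leg_{side}")


@dataclass
class HemisphereRecord:
    """Per-hemisphere analysis row."""

    hemisphere: str
    side: str
    pre_pct: float
    post_pct: float
    improvement_pct: float
    responder: bool
    included: bool
    distance_mm: float = float("nan")
    threshold: int = 0
    flags: str = ""


def tremor_percentage(a: TremorAssessment, scope: str) -> float:
    """Score as a percentage of its maximum: the global resting-tremor
    sum over 20, or one side's arm+leg over 8."""
    if scope == "global":
        return 100.0 * a.resting_tremor_sum / GLOBAL_MAX
    if scope in ("left-limbs", "right-limbs"):
        side = scope.split("-")[0]
        return 100.0 * a.limb_sum(side) / LIMB_MAX
    raise ValueError(f"unknown scope {scope!r}")


def classify_response(pre_pct: float, post_pct: float):
    """Improvement = pre - post; responder only if strictly positive."""
    improvement = pre_pct - post_pct
    return improvement, improvement > 0


def include_hemisphere(baseline: TremorAssessment, side: str) -> bool:
    """A hemisphere is analyzed only if the CONTRALATERAL body half had
    resting tremor at baseline."""
    contralateral = "left" if side == "right" else "right"
    return baseline.limb_sum(contralateral) > 0


def updrs_minus_tremor(a: TremorAssessment) -> int:
    """UPDRS III total with the resting-tremor items removed."""
    out = a.updrs3_total - a.resting_tremor_sum
    if out < 0:
        raise ValueError("tremor sum exceeds UPDRS III total")
    return out


# ---------------------------------------------------------------------------
# table-level helpers (TSV schema: patient, visit_month, state, items, total)

def assessment_from_row(row) -> TremorAssessment:
    return TremorAssessment(
        arm_right=int(row["arm_right"]), arm_left=int(row["arm_left"]),
        leg_right=int(row["leg_right"]), leg_left=int(row["leg_left"]),
        lips_jaw=int(row["lips_jaw"]), updrs3_total=int(row["updrs3_total"]),
        state=str(row["state"]), visit_month=float(row["visit_month"]),
    )


def select_visits(tremor: pd.DataFrame, visit_rule: str = "latest"):
    """Baseline and follow-up assessment per patient.

    ``visit_rule`` picks which OFF-MED/ON-STIM visit enters the analysis
    when several exist: "latest" (default) or "earliest".
    """
    out = {}
    for patient, grp in tremor.groupby("patient"):
        base = grp[grp["state"] == "OFF-MED"]
        post = grp[grp["state"] == "OFF-MED/ON-STIM"]
        if base.empty or post.empty:
            raise ValueError(f"patient {patient}: missing baseline or follow-up visit")
        chosen = post.sort_values("visit_month").iloc[-1 if visit_rule == "latest" else 0]
        out[patient] = (assessment_from_row(base.iloc[0]), assessment_from_row(chosen))
    return out


def hemisphere_outcomes(tremor: pd.DataFrame, visit_rule: str = "latest"):
    """Per-hemisphere pre/post contralateral limb percentages.

    Returns a DataFrame with one row per (patient, hemisphere side),
    including excluded hemispheres (contralateral limb sum 0 at
    baseline) with ``included=False``.
    """
    rows = []
    for patient, (base, post) in select_visits(tremor, visit_rule).items():
        for side in ("right", "left"):
            scope = ("left" if side == "right" else "right") + "-limbs"
            pre = tremor_percentage(base, scope)
            pst = tremor_percentage(post, scope)
            improvement, responder = classify_response(pre, pst)
            rows.append(dict(
                patient=patient, side=side, hemisphere=f"P{patient:02d}-{side[0].upper()}",
                pre_pct=pre, post_pct=pst, improvement_pct=improvement,
                responder=responder, included=include_hemisphere(base, side),
            ))
    return pd.DataFrame(rows)
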