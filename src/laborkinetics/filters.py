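"""Sample-selection chain and stratification.

Reproduces the study's selection funnel on an assembled cohort: term,
vertex, spontaneous-onset labours admitted at <= 6 cm that ended in vaginal
birth with no severe adverse outcome or malformation and at least two
cervical assessments.  A record failing several criteria is attributed to the
first failing one in flow-chart order; the *included* set is order-invariant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .cohort import LabourRecord

TERM_LOW_WK = 37.0
TERM_HIGH_WK = 41.0 + 6.0 / 7.0  # 41 weeks + 6 days, inclusive

#: attribution order of the selection criteria.
CRITERIA = (
    "not_term",
    "not_vertex",
    "induced_onset",
    "admission_above_6cm",
    "prior_uterine_scar",
    "intrapartum_cesarean",
    "adverse_outcome",
    "severe_malformation",
    "fewer_than_two_exams",
)


def _failing_criterion(rec: LabourRecord) -> str | None:
    if rec.gest_age_wk is None:
        raise ValueError(f"{rec.woman_id}: missing gestational age")
    if not TERM_LOW_WK <= rec.gest_age_wk <= TERM_HIGH_WK:
        return "not_term"
    if rec.presentation != "vertex":
        return "not_vertex"
    if rec.onset_type != "spontaneous":
        return "induced_onset"
    if rec.admission_dilatation > 6:
        return "admission_above_6cm"
    if rec.prior_scar:
        return "prior_uterine_scar"
    if rec.mode_of_birth == "cesarean":
        return "intrapartum_cesarean"
    if rec.adverse_outcome:
        return "adverse_outcome"
    if rec.severe_malformation:
        return "severe_malformation"
    if len(rec.exams) < 2:
        return "fewer_than_two_exams"
    return None


@dataclass
class FlowCounts:
    """Per-criterion exclusion counts for the selection funnel."""

    n_input: int
    excluded: dict[str, int] = field(default_factory=dict)
    n_included: int = 0

    def check_conservation(self) -> None:
        if self.n_input != self.n_included + sum(self.excluded.values()):
            raise AssertionError("flow counts do not conserve the input")

    def to_json(self) -> str:
        return json.dumps(
            {"input": self.n_input, "excluded": self.excluded,
             "included": self.n_included}, indent=2)

    def to_text(self) -> str:
        lines = [f"assessed for eligibility: {self.n_input}"]
        for name in CRITERIA:
            n = self.excluded.get(name, 0)
            if n:
                lines.append(f"  excluded ({name.replace('_', ' ')}): {n}")
        lines.append(f"included in analysis: {self.n_included}")
        return "\n".join(lines)


def apply_inclusion(records: list[LabourRecord]) -> tuple[list[LabourRecord], FlowCounts]:
    """Apply the selection chain; returns the included cohort and the funnel."""
    counts = FlowCounts(n_input=len(records), excluded={c: 0 for c in CRITERIA})
    included: list[LabourRecord] = []
    for rec in records:
        why = _failing_criterion(rec)
        if why is None:
            included.append(rec)
        else:
            counts.excluded[why] += 1
    counts.n_included = len(included)
    counts.check_conservation()
    return included, counts


def exclude_augmented(records: list[LabourRecord]) -> list[LabourRecord]:
    """Sensitivity split: keep only labours without oxytocin augmentation."""
    return [r for r in records if not r.oxytocin]


def stratify(records: list[LabourRecord], keys: tuple[str, ...] = ("parity_group",),
             ) -> dict[tuple, list[LabourRecord]]:
    """Partition a cohort by parity group and/or admission dilatation."""
    allowed = {"parity_group", "admission_dilatation"}
    bad = set(keys) - allowed
    if bad:
        raise KeyError(f"unknown stratification keys: {sorted(bad)}")
    out: dict[tuple, list[LabourRecord]] = {}
    for rec in records:
        key = tuple(getattr(rec, k) for k in keys)
        out.setdefault(key, []).append(rec)
    return out
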