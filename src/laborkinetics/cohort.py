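"""Cohort containers and long-format CSV I/O.

A cohort is a list of :class:`LabourRecord`, one per woman, each holding the
ordered cervical-dilatation exams (hours since admission, integer cm), the
inclusion covariates and the exactly-recorded time of full dilatation.  The
on-disk form is the long CSV schema with one row per exam.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

log = logging.getLogger(__name__)

#: mandatory long-format columns (one row per exam).
CSV_COLUMNS = [
    "woman_id",
    "parity_group",
    "exam_time_h",
    "dilatation_cm",
    "oxytocin",
    "onset_type",
    "presentation",
    "gest_age_wk",
    "prior_scar",
    "mode_of_birth",
    "adverse_outcome",
    "severe_malformation",
    "full_dilatation_time_h",
]


@dataclass
class LabourRecord:
    """One woman's exam series plus covariates and outcome flags."""

    woman_id: str
    parity_group: str  # "0", "1" or "2+"
    exams: list[tuple[float, int]]  # (hours since admission, dilatation cm)
    oxytocin: bool = False
    onset_type: str = "spontaneous"  # or "induced"
    presentation: str = "vertex"  # or "other"
    gest_age_wk: float = 39.0  # decimal weeks (37.0 .. 41+6/7 is term)
    prior_scar: bool = False
    mode_of_birth: str = "vaginal"  # "vaginal", "cesarean", "operative_vaginal"
    adverse_outcome: bool = False
    severe_malformation: bool = False
    full_dilatation_time_h: float | None = None
    meta: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def admission_dilatation(self) -> int:
        return self.exams[0][1]

    def validate(self) -> None:
        if not self.exams:
            raise ValueError(f"{self.woman_id}: record has no exams")
        times = [t for t, _ in self.exams]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError(f"{self.woman_id}: exam times decrease")
        if any(not 0 <= d <= 10 for _, d in self.exams):
            raise ValueError(f"{self.woman_id}: dilatation outside 0..10")

    def copy(self) -> "LabourRecord":
        return replace(self, exams=list(self.exams), meta=dict(self.meta))


def cohort_to_frame(records: list[LabourRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        for t, d in r.exams:
            rows.append(
                (
                    r.woman_id,
                    r.parity_group,
                    round(t, 4),
                    d,
                    int(r.oxytocin),
                    r.onset_type,
                    r.presentation,
                    round(r.gest_age_wk, 3),
                    int(r.prior_scar),
                    r.mode_of_birth,
                    int(r.adverse_outcome),
                    int(r.severe_malformation),
                    round(r.full_dilatation_time_h, 4)
                    if r.full_dilatation_time_h is not None
                    else "",
                )
            )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_cohort(records: list[LabourRecord], path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def frame_to_cohort(df: pd.DataFrame, strict: bool = False) -> list[LabourRecord]:
    """Assemble records from a long-format frame; malformed women are logged
    and dropped (or raised when ``strict``)."""
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file lacks mandatory columns: {missing}")
    records: list[LabourRecord] = []
    n_bad = 0
    for wid, grp in df.groupby("woman_id", sort=False):
        grp = grp.sort_values("exam_time_h", kind="stable")
        first = grp.iloc[0]
        full = first["full_dilatation_time_h"]
        full = None if pd.isna(full) or full == "" else float(full)
        rec = LabourRecord(
            woman_id=str(wid),
            parity_group=str(first["parity_group"]),
            exams=[(float(t), int(d)) for t, d in zip(grp["exam_time_h"], grp["dilatation_cm"])],
            oxytocin=bool(int(first["oxytocin"])),
            onset_type=str(first["onset_type"]),
            presentation=str(first["presentation"]),
            gest_age_wk=float(first["gest_age_wk"]),
            prior_scar=bool(int(first["prior_scar"])),
            mode_of_birth=str(first["mode_of_birth"]),
            adverse_outcome=bool(int(first["adverse_outcome"])),
            severe_malformation=bool(int(first["severe_malformation"])),
            full_dilatation_time_h=full,
        )
        try:
            rec.validate()
        except ValueError as err:
            n_bad += 1
            if strict:
                raise
            log.warning("dropping malformed record: %s", err)
            continue
        records.append(rec)
    if n_bad:
        log.info("dropped %d malformed record(s)", n_bad)
    return records


def read_cohort(path, column_map: dict[str, str] | None = None, strict: bool = False) -> list[LabourRecord]:
    """Read a long-format cohort CSV.

    ``column_map`` renames foreign column names onto the native schema, so a
    deposited file with its own dictionary can be ingested unchanged.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    return frame_to_cohort(df, strict=strict)
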