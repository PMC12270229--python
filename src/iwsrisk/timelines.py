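"""Patient timeline container and delimited-file ingest.

Raw inputs are four long-format CSV tables (vitals, medication
administrations, WAT-1 assessments, patient statics), all time-stamped in
hours since extubation (t=0).  Ingest validates records and collects
rejected rows in a report instead of silently dropping them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .schema import DRUGS, VITALS

logger = logging.getLogger(__name__)

WAT1_THRESHOLD = 3  # score >= 3 flags withdrawal in a 4-h interval


@dataclass
class PatientTimeline:
    """All raw records for one patient, anchored at extubation (t=0 h).

    ``vitals`` maps variable name -> list of (timestamp_h, value);
    ``med_admins`` maps drug name -> list of (timestamp_h, dose_mg);
    ``wat1_scores`` is a list of (timestamp_h, integer score 0-12).
    """

    patient_id: str
    weight_kg: float
    age_months: float
    mech_vent_duration_h: float
    prior_withdrawal_history: int = 0
    vitals: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    med_admins: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    wat1_scores: list[tuple[float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.weight_kg <= 0:
            raise ValueError(f"patient {self.patient_id}: weight_kg must be > 0")
        if self.age_months < 0 or self.mech_vent_duration_h < 0:
            raise ValueError(f"patient {self.patient_id}: negative static field")

    def n_epochs(self, epoch_hours: float = 4.0) -> int:
        """Number of complete epochs covered by any record for this patient."""
        last = 0.0
        for recs in self.vitals.values():
            for t, _ in recs:
                last = max(last, t)
        for recs in self.med_admins.values():
            for t, _ in recs:
                last = max(last, t)
        for t, _ in self.wat1_scores:
            last = max(last, t)
        import math

        return int(math.floor(last / epoch_hours)) + 1 if last > 0 else 1

    def sort_records(self) -> None:
        for recs in self.vitals.values():
            recs.sort(key=lambda r: r[0])
        for recs in self.med_admins.values():
            recs.sort(key=lambda r: r[0])
        self.wat1_scores.sort(key=lambda r: r[0])


@dataclass
class ValidationReport:
    """Rows rejected at ingest, with reasons."""

    rejected: list[dict] = field(default_factory=list)

    def reject(self, table: str, row: dict, reason: str) -> None:
        entry = {"table": table, "reason": reason, **row}
        self.rejected.append(entry)
        logger.warning("rejected %s row (%s): %s", table, reason, row)

    def __len__(self) -> int:
        return len(self.rejected)


def load_timelines(
    vitals_csv: str | Path,
    meds_csv: str | Path,
    wat1_csv: str | Path,
    patients_csv: str | Path,
) -> tuple[dict[str, PatientTimeline], ValidationReport]:
    """Read the four CSV tables into per-patient timelines.

    Returns (timelines keyed by patient_id, validation report).  Invalid
    records — negative doses, out-of-range WAT-1 scores, non-positive
    weights, negative timestamps, unknown variables — are rejected and
    reported.
    """
    report = ValidationReport()

    patients = pd.read_csv(patients_csv, dtype={"patient_id": str})
    timelines: dict[str, PatientTimeline] = {}
    for row in patients.to_dict("records"):
        pid = str(row["patient_id"])
        if pid in timelines:
            report.reject("patients", row, "duplicate patient_id")
            continue
        if row["weight_kg"] <= 0:
            report.reject("patients", row, "non-positive weight_kg")
            continue
        timelines[pid] = PatientTimeline(
            patient_id=pid,
            weight_kg=float(row["weight_kg"]),
            age_months=float(row["age_months"]),
            mech_vent_duration_h=float(row["mech_vent_duration_h"]),
            prior_withdrawal_history=int(row.get("prior_withdrawal_history", 0)),
        )

    vitals = pd.read_csv(vitals_csv, dtype={"patient_id": str})
    seen_vitals: set[tuple[str, str, float]] = set()
    for row in vitals.to_dict("records"):
        pid, var = str(row["patient_id"]), str(row["variable"])
        t, val = float(row["timestamp_h"]), float(row["value"])
        if pid not in timelines:
            report.reject("vitals", row, "unknown patient_id")
        elif var not in VITALS:
            report.reject("vitals", row, "unknown variable")
        elif t < 0:
            report.reject("vitals", row, "negative timestamp")
        elif (pid, var, t) in seen_vitals:
            report.reject("vitals", row, "duplicate timestamp")
        else:
            seen_vitals.add((pid, var, t))
            timelines[pid].vitals.setdefault(var, []).append((t, val))

    meds = pd.read_csv(meds_csv, dtype={"patient_id": str})
    for row in meds.to_dict("records"):
        pid, drug = str(row["patient_id"]), str(row["drug"])
        t, dose = float(row["timestamp_h"]), float(row["dose_mg"])
        if pid not in timelines:
            report.reject("meds", row, "unknown patient_id")
        elif drug not in DRUGS:
            report.reject("meds", row, "unknown drug")
        elif t < 0:
            report.reject("meds", row, "negative timestamp")
        elif dose < 0:
            report.reject("meds", row, "negative dose")
        else:
            timelines[pid].med_admins.setdefault(drug, []).append((t, dose))

    wat1 = pd.read_csv(wat1_csv, dtype={"patient_id": str})
    for row in wat1.to_dict("records"):
        pid = str(row["patient_id"])
        t, score = float(row["timestamp_h"]), int(row["score"])
        if pid not in timelines:
            report.reject("wat1", row, "unknown patient_id")
        elif t < 0:
            report.reject("wat1", row, "negative timestamp")
        elif not 0 <= score <= 12:
            report.reject("wat1", row, "score outside [0, 12]")
        else:
            timelines[pid].wat1_scores.append((t, score))

    for tl in timelines.values():
        tl.sort_records()
    return timelines, report
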