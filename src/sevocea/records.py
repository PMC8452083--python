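"""Data model and delimited-table I/O for the cohort's three record levels.

Three granularities are stored as plain delimited text, one file each:

* per-patient baseline records (:class:`PatientRecord`),
* per-visit pain scores (:class:`VisitRecord`),
* per-resource-use entries (:class:`ResourceUseRecord`).

Reference tables (:class:`UnitCostTable`, :class:`CPIIndex`) live in a YAML
or CSV config.  Readers validate field ranges on construction and
cross-reference patient ids; :func:`validate_cohort` reports cohort-level
invariant violations without raising.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "ADMISSION",
    "ANALGESIC_CATEGORIES",
    "CATEGORIES",
    "ATTRIBUTIONS",
    "SchemaError",
    "ReferentialError",
    "RecordValidationError",
    "PatientRecord",
    "VisitRecord",
    "ResourceUseRecord",
    "UnitCostTable",
    "CPIIndex",
    "Finding",
    "ValidationReport",
    "load_study_tables",
    "write_study_tables",
    "load_workbook_tables",
    "validate_cohort",
    "patients_to_frame",
    "visits_to_frame",
    "resources_to_frame",
]

#: Category key for hospital admissions (the only category carrying
#: complication flags, attribution and length of stay).
ADMISSION = "hospital_admission"

#: Categories whose costs count as analgesic-treatment costs.
ANALGESIC_CATEGORIES = frozenset(
    {"sevoflurane_mL", "syringe_10mL", "syringe_fill", "opioid", "nonopioid"}
)

#: Consultation subtypes (primary care and hospital, scheduled and not).
CONSULT_CATEGORIES = frozenset(
    {
        "pc_sched_medical_first",
        "pc_sched_medical_next",
        "pc_sched_mednurse_first",
        "pc_sched_mednurse_next",
        "pc_sched_nurse",
        "pc_nonsched_simple",
        "pc_nonsched_observation",
        "pc_nonsched_referral",
        "hosp_sched_first",
        "hosp_sched_next",
        "hosp_nonsched_discharge",
        "hosp_nonsched_admit",
    }
)

#: Full canonical category set.
CATEGORIES = frozenset(
    ANALGESIC_CATEGORIES | CONSULT_CATEGORIES | {ADMISSION, "hyperbaric_session"}
)

#: Admission attribution levels; nested: ``pain`` implies ``ulcer`` implies
#: ``any``.
ATTRIBUTIONS = ("any", "ulcer", "pain")


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


class ReferentialError(ValueError):
    """A child table references patient ids absent from the patient table."""


class RecordValidationError(ValueError):
    """A field value violates its documented range."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise RecordValidationError(msg)


@dataclass(frozen=True)
class PatientRecord:
    """One patient's baseline covariates and follow-up events.

    ``ulcer_number`` is stored raw; truncation at 4 happens only when the
    regression design matrix is built, so the data round-trip losslessly.
    """

    patient_id: str
    group: int  # 1 = sevoflurane add-on, 0 = conventional analgesia
    aht: int
    ulcer_duration: float  # months
    ulcer_number: int
    ulcer_depth: int  # 0 superficial, 1 beyond dermis
    baseline_pain: float  # NRS 0-10
    death_month: Optional[float] = None
    amputation_month: Optional[float] = None

    def __post_init__(self) -> None:
        _check(self.group in (0, 1), f"group must be 0/1, got {self.group}")
        _check(self.aht in (0, 1), f"aht must be 0/1, got {self.aht}")
        _check(self.ulcer_depth in (0, 1), f"ulcer_depth must be 0/1, got {self.ulcer_depth}")
        _check(self.ulcer_duration >= 0, f"ulcer_duration must be >= 0, got {self.ulcer_duration}")
        _check(self.ulcer_number >= 1, f"ulcer_number must be >= 1, got {self.ulcer_number}")
        _check(0 <= self.baseline_pain <= 10, f"baseline_pain outside NRS 0-10: {self.baseline_pain}")
        for name in ("death_month", "amputation_month"):
            val = getattr(self, name)
            if val is not None:
                _check(0 < val <= 12, f"{name} must lie in (0, 12], got {val}")

    @property
    def event_month(self) -> Optional[float]:
        """Earliest of death/amputation month, or None."""
        months = [m for m in (self.death_month, self.amputation_month) if m is not None]
        return min(months) if months else None


@dataclass(frozen=True)
class VisitRecord:
    """One pain assessment: months since first Pain Clinic visit and NRS score."""

    patient_id: str
    time: float  # months since first visit, >= 0
    pain: float  # NRS 0-10 (integers in charted data)

    def __post_init__(self) -> None:
        _check(self.time >= 0, f"visit time must be >= 0, got {self.time}")
        _check(self.time <= 12, f"visit time beyond the 12-month horizon: {self.time}")
        _check(0 <= self.pain <= 10, f"pain outside NRS 0-10: {self.pain}")


@dataclass(frozen=True)
class ResourceUseRecord:
    """One consumed health resource in its natural unit.

    ``attribution``, ``complication``, ``length_of_stay`` and
    ``diagnosis_class`` are meaningful only for hospital admissions.
    ``year`` is the calendar year of expenditure; None means the amount is
    already expressed in reference-year euros.
    """

    patient_id: str
    category: str
    quantity: float
    attribution: str = "any"
    complication: Optional[int] = None
    length_of_stay: Optional[float] = None
    diagnosis_class: str = "default"
    year: Optional[int] = None

    def __post_init__(self) -> None:
        _check(self.category in CATEGORIES, f"unknown resource category: {self.category!r}")
        _check(self.quantity >= 0, f"quantity must be >= 0, got {self.quantity}")
        _check(self.attribution in ATTRIBUTIONS, f"unknown attribution: {self.attribution!r}")
        if self.category != ADMISSION:
            _check(
                self.complication is None and self.length_of_stay is None,
                f"complication/length_of_stay only valid for {ADMISSION}, "
                f"got them on {self.category!r}",
            )
        else:
            if self.complication is not None:
                _check(self.complication in (0, 1), "complication must be 0/1")
            if self.length_of_stay is not None:
                _check(self.length_of_stay >= 0, "length_of_stay must be >= 0")


@dataclass
class UnitCostTable:
    """Per-category unit costs in reference-year euros.

    ``unit_costs`` maps every non-admission category to euros per natural
    unit.  Admission tariffs are keyed by diagnosis class in ``drg_with`` /
    ``drg_without``; ``per_diem_rate`` supports the per-day costing variant.
    The syringe-filling labour cost is derived:
    ``pharmacist_hourly_wage / syringes_per_hour``.
    """

    unit_costs: dict[str, float] = field(default_factory=dict)
    drg_with: dict[str, float] = field(default_factory=dict)
    drg_without: dict[str, float] = field(default_factory=dict)
    per_diem_rate: float = 0.0
    pharmacist_hourly_wage: float = 0.0
    syringes_per_hour: float = 200.0

    def __post_init__(self) -> None:
        if self.syringes_per_hour <= 0:
            raise RecordValidationError("syringes_per_hour must be > 0")
        for name, val in self.unit_costs.items():
            if val < 0:
                raise RecordValidationError(f"negative unit cost for {name!r}: {val}")
        for table in (self.drg_with, self.drg_without):
            for name, val in table.items():
                if val < 0:
                    raise RecordValidationError(f"negative DRG tariff for {name!r}: {val}")
        if self.per_diem_rate < 0 or self.pharmacist_hourly_wage < 0:
            raise RecordValidationError("costs must be >= 0")
        self.unit_costs.setdefault("syringe_fill", self.syringe_fill_cost)

    @property
    def syringe_fill_cost(self) -> float:
        """Labour cost of filling one syringe: hourly wage / syringes per hour."""
        return self.pharmacist_hourly_wage / self.syringes_per_hour


@dataclass
class CPIIndex:
    """Consumer Price Index series used to express costs in reference-year euros."""

    index: dict[int, float] = field(default_factory=dict)
    reference_year: int = 2016

    def __post_init__(self) -> None:
        for year, val in self.index.items():
            if val <= 0:
                raise RecordValidationError(f"CPI index for {year} must be > 0, got {val}")
        self.index.setdefault(self.reference_year, 100.0)

    def factor(self, year: Optional[int]) -> float:
        """Multiplier converting year-``year`` euros to reference-year euros."""
        if year is None or year == self.reference_year:
            return 1.0
        if year not in self.index:
            raise KeyError(f"year {year} not present in the CPI table")
        return self.index[self.reference_year] / self.index[year]


# ---------------------------------------------------------------------------
# table I/O

_PATIENT_REQUIRED = ("patient_id", "group", "aht", "ulcer_duration",
                     "ulcer_number", "ulcer_depth", "baseline_pain")
_PATIENT_OPTIONAL = ("death_month", "amputation_month")
_VISIT_REQUIRED = ("patient_id", "time", "pain")
_RESOURCE_REQUIRED = ("patient_id", "category", "quantity")
_RESOURCE_OPTIONAL = ("attribution", "complication", "length_of_stay",
                      "diagnosis_class", "year")


def _read_table(path, delimiter: Optional[str]) -> pd.DataFrame:
    if delimiter is None:
        # sniff comma vs tab
        return pd.read_csv(path, sep=None, engine="python")
    return pd.read_csv(path, sep=delimiter)


def _apply_map(frame: pd.DataFrame, column_map: Optional[Mapping[str, str]]) -> pd.DataFrame:
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    return frame


def _require(frame: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what} table is missing mandatory column(s): {', '.join(missing)}")


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def _opt_int(value) -> Optional[int]:
    v = _opt_float(value)
    return None if v is None else int(v)


def patients_from_frame(frame: pd.DataFrame) -> list[PatientRecord]:
    _require(frame, _PATIENT_REQUIRED, "patient")
    out = []
    for row in frame.to_dict("records"):
        out.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                group=int(row["group"]),
                aht=int(row["aht"]),
                ulcer_duration=float(row["ulcer_duration"]),
                ulcer_number=int(row["ulcer_number"]),
                ulcer_depth=int(row["ulcer_depth"]),
                baseline_pain=float(row["baseline_pain"]),
                death_month=_opt_float(row.get("death_month")),
                amputation_month=_opt_float(row.get("amputation_month")),
            )
        )
    return out


def visits_from_frame(frame: pd.DataFrame) -> list[VisitRecord]:
    _require(frame, _VISIT_REQUIRED, "visit")
    return [
        VisitRecord(patient_id=str(r["patient_id"]), time=float(r["time"]), pain=float(r["pain"]))
        for r in frame.to_dict("records")
    ]


def resources_from_frame(frame: pd.DataFrame) -> list[ResourceUseRecord]:
    _require(frame, _RESOURCE_REQUIRED, "resource")
    out = []
    for row in frame.to_dict("records"):
        attribution = row.get("attribution")
        if attribution is None or (isinstance(attribution, float) and math.isnan(attribution)):
            attribution = "any"
        diagnosis = row.get("diagnosis_class")
        if diagnosis is None or (isinstance(diagnosis, float) and math.isnan(diagnosis)):
            diagnosis = "default"
        out.append(
            ResourceUseRecord(
                patient_id=str(row["patient_id"]),
                category=str(row["category"]),
                quantity=float(row["quantity"]),
                attribution=str(attribution),
                complication=_opt_int(row.get("complication")),
                length_of_stay=_opt_float(row.get("length_of_stay")),
                diagnosis_class=str(diagnosis),
                year=_opt_int(row.get("year")),
            )
        )
    return out


def patients_to_frame(patients: Iterable[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(p) for p in patients],
                        columns=list(_PATIENT_REQUIRED) + list(_PATIENT_OPTIONAL))


def visits_to_frame(visits: Iterable[VisitRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(v) for v in visits], columns=list(_VISIT_REQUIRED))


def resources_to_frame(resources: Iterable[ResourceUseRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in resources],
                        columns=list(_RESOURCE_REQUIRED) + list(_RESOURCE_OPTIONAL))


def _cross_reference(patients, visits, resources) -> None:
    known = {p.patient_id for p in patients}
    orphans = sorted(
        {v.patient_id for v in visits if v.patient_id not in known}
        | {r.patient_id for r in resources if r.patient_id not in known}
    )
    if orphans:
        raise ReferentialError(
            "patient id(s) referenced but absent from the patient table: "
            + ", ".join(orphans)
        )


def load_study_tables(
    patient_path,
    visit_path,
    resource_path=None,
    column_map: Optional[Mapping[str, Mapping[str, str]]] = None,
    delimiter: Optional[str] = None,
) -> tuple[list[PatientRecord], list[VisitRecord], list[ResourceUseRecord]]:
    """Read the three canonical tables from delimited text.

    Parameters
    ----------
    column_map
        Optional per-table header remapping, keyed by ``"patients"``,
        ``"visits"``, ``"resources"``; each value maps file headers to
        canonical field names.
    delimiter
        Field separator; sniffed (comma/tab) when None.

    Raises
    ------
    SchemaError
        If a mandatory column is missing after remapping.
    ReferentialError
        If visit or resource rows reference unknown patient ids.
    RecordValidationError
        If any field is out of range (e.g. NRS pain outside 0-10).
    """
    column_map = column_map or {}
    patients = patients_from_frame(
        _apply_map(_read_table(patient_path, delimiter), column_map.get("patients"))
    )
    visits = visits_from_frame(
        _apply_map(_read_table(visit_path, delimiter), column_map.get("visits"))
    )
    resources: list[ResourceUseRecord] = []
    if resource_path is not None:
        resources = resources_from_frame(
            _apply_map(_read_table(resource_path, delimiter), column_map.get("resources"))
        )
    _cross_reference(patients, visits, resources)
    return patients, visits, resources


def write_study_tables(patients, visits, resources, patient_path, visit_path, resource_path) -> None:
    """Write the three canonical tables as CSV (lossless round-trip)."""
    patients_to_frame(patients).to_csv(patient_path, index=False)
    visits_to_frame(visits).to_csv(visit_path, index=False)
    resources_to_frame(resources).to_csv(resource_path, index=False)


def load_workbook_tables(
    xlsx_path,
    sheet_map: Mapping[str, str],
    column_map: Optional[Mapping[str, Mapping[str, str]]] = None,
):
    """Ingestion shim for a single-workbook deposit.

    ``sheet_map`` names the worksheet holding each canonical table, keyed by
    ``"patients"``, ``"visits"``, ``"resources"`` (the latter two optional —
    a workbook that only carries per-patient aggregates maps just
    ``"patients"`` and downstream stages consume pre-aggregated columns).
    Returns a dict of DataFrames with canonical headers applied.
    """
    column_map = column_map or {}
    out: dict[str, pd.DataFrame] = {}
    for key, sheet in sheet_map.items():
        frame = pd.read_excel(xlsx_path, sheet_name=sheet)
        out[key] = _apply_map(frame, column_map.get(key))
    return out


# ---------------------------------------------------------------------------
# cohort validation

@dataclass(frozen=True)
class Finding:
    patient_id: str
    code: str
    message: str


@dataclass
class ValidationReport:
    """Cohort-level invariant violations; empty iff all invariants hold."""

    findings: list[Finding] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.findings

    def codes(self) -> set[str]:
        return {f.code for f in self.findings}

    def to_json(self) -> str:
        return json.dumps([asdict(f) for f in self.findings], indent=2)

    def __str__(self) -> str:
        if self.empty:
            return "cohort valid: no findings"
        return "\n".join(f"[{f.code}] {f.patient_id}: {f.message}" for f in self.findings)


def validate_cohort(patients, visits, resources=()) -> ValidationReport:
    """Check cohort-level invariants; report, never raise.

    Findings: ``missing_baseline_visit`` (no time-0 visit),
    ``nonmonotone_visit_times`` (times not strictly increasing),
    ``negative_quantity``, ``no_visits``.
    Pure function: repeated calls on the same inputs yield equal reports.
    """
    findings: list[Finding] = []
    by_patient: dict[str, list[VisitRecord]] = {}
    for v in visits:
        by_patient.setdefault(v.patient_id, []).append(v)
    for p in patients:
        pvisits = sorted(by_patient.get(p.patient_id, []), key=lambda v: v.time)
        if not pvisits:
            findings.append(Finding(p.patient_id, "no_visits", "patient has no visits"))
            continue
        if pvisits[0].time != 0:
            findings.append(
                Finding(p.patient_id, "missing_baseline_visit",
                        f"first visit at month {pvisits[0].time}, expected 0")
            )
        raw_times = [v.time for v in by_patient[p.patient_id]]
        if any(t2 <= t1 for t1, t2 in zip(raw_times, raw_times[1:])):
            findings.append(
                Finding(p.patient_id, "nonmonotone_visit_times",
                        f"visit times not strictly increasing: {raw_times}")
            )
    for r in resources:
        if r.quantity < 0:  # unreachable via constructor; guards raw dicts
            findings.append(
                Finding(r.patient_id, "negative_quantity",
                        f"{r.category} quantity {r.quantity} < 0")
            )
    return ValidationReport(findings)
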