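"""Annual per-patient costing in reference-year euros.

Each consumed resource is costed as quantity x unit cost, CPI-adjusted to
the reference year.  Hospital admissions carry DRG tariffs with/without
complications and support the one-way sensitivity variants: forcing all
admissions to the with- or without-complication tariff, restricting to
admissions attributed to the ulcers or to ulcer pain, and per-diem costing
(length of stay x daily rate).  Ulcer-cleansing has no category: those
costs are structurally excluded (common to both arms and folded into visit
tariffs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

from .records import (
    ADMISSION,
    ANALGESIC_CATEGORIES,
    CPIIndex,
    ResourceUseRecord,
    UnitCostTable,
)

__all__ = [
    "CostVariant",
    "CostBreakdown",
    "DEFAULT_COST_CONFIG",
    "build_unit_cost_table",
    "build_cpi_index",
    "adjust_to_reference_year",
    "cost_admission",
    "annual_patient_cost",
    "cost_cohort",
]


class CostVariant(str, Enum):
    """Hospitalization-costing variant; exactly one active per costing run."""

    BASE_CASE = "base_case"
    DRG_ALL_COMPLICATIONS = "drg_all_complications"
    DRG_NO_COMPLICATIONS = "drg_no_complications"
    ADMISSIONS_ULCER_ONLY = "admissions_ulcer_only"
    ADMISSIONS_PAIN_ONLY = "admissions_pain_only"
    PER_DIEM = "per_diem"


# Default unit costs (2016 euros).  Consult/syringe/sevoflurane prices follow
# the published tariff schedule; DRG tariffs and per-diem rate are
# user-supplied in real analyses (single "default" diagnosis class here).
DEFAULT_COST_CONFIG: dict = {
    "unit_costs": {
        "sevoflurane_mL": 0.30,
        "syringe_10mL": 0.17,
        "opioid": 1.0,          # euros per OME-scaled daily unit; study used per-formulation prices
        "nonopioid": 1.0,
        "pc_sched_medical_first": 44.0,
        "pc_sched_medical_next": 18.0,
        "pc_sched_mednurse_first": 52.0,
        "pc_sched_mednurse_next": 23.0,
        "pc_sched_nurse": 21.0,
        "pc_nonsched_simple": 49.0,
        "pc_nonsched_observation": 86.0,
        "pc_nonsched_referral": 111.0,
        "hosp_sched_first": 114.0,
        "hosp_sched_next": 55.0,
        "hosp_nonsched_discharge": 144.0,
        "hosp_nonsched_admit": 392.0,
        "hyperbaric_session": 65.0,
    },
    "drg_with": {"default": 5000.0},
    "drg_without": {"default": 3000.0},
    "per_diem_rate": 400.0,
    "pharmacist_hourly_wage": 41.0,
    "syringes_per_hour": 200.0,
}


def build_unit_cost_table(config: Optional[dict] = None) -> UnitCostTable:
    """Assemble a :class:`UnitCostTable` from a config mapping.

    The syringe-filling labour cost is derived as
    ``pharmacist_hourly_wage / syringes_per_hour`` (e.g. 41 euros/h at 200
    syringes per hour gives 0.205 euros per fill).
    """
    cfg = dict(DEFAULT_COST_CONFIG if config is None else config)
    return UnitCostTable(
        unit_costs=dict(cfg.get("unit_costs", {})),
        drg_with=dict(cfg.get("drg_with", {})),
        drg_without=dict(cfg.get("drg_without", {})),
        per_diem_rate=float(cfg.get("per_diem_rate", 0.0)),
        pharmacist_hourly_wage=float(cfg.get("pharmacist_hourly_wage", 0.0)),
        syringes_per_hour=float(cfg.get("syringes_per_hour", 200.0)),
    )


def build_cpi_index(config: Optional[dict] = None) -> CPIIndex:
    """Assemble a :class:`CPIIndex`; identity index when no config given."""
    if config is None:
        return CPIIndex()
    return CPIIndex(
        index={int(k): float(v) for k, v in config.get("index", {}).items()},
        reference_year=int(config.get("reference_year", 2016)),
    )


def adjust_to_reference_year(amount: float, year: Optional[int], cpi: CPIIndex) -> float:
    """Express ``amount`` (euros of calendar ``year``) in reference-year euros."""
    return amount * cpi.factor(year)


def _admission_tariff(adm: ResourceUseRecord, table: UnitCostTable, use_complication: Optional[int]) -> float:
    source = table.drg_with if use_complication else table.drg_without
    if adm.diagnosis_class not in source:
        raise ValueError(f"no DRG tariff for diagnosis class {adm.diagnosis_class!r}")
    return source[adm.diagnosis_class]


def cost_admission(
    admission: ResourceUseRecord,
    table: UnitCostTable,
    variant: CostVariant = CostVariant.BASE_CASE,
) -> float:
    """Cost of one admission record (per unit quantity x quantity), unadjusted.

    Base case uses the record's complication flag to pick the DRG tariff;
    the drg_all/drg_no variants override that flag for every admission; the
    attribution variants return 0 for admissions outside the filter
    (attributions are nested: pain implies ulcer implies any); the per-diem
    variant prices length_of_stay x per_diem_rate instead of the DRG.
    """
    if admission.category != ADMISSION:
        raise ValueError(f"cost_admission got category {admission.category!r}")
    variant = CostVariant(variant)
    if variant is CostVariant.ADMISSIONS_ULCER_ONLY and admission.attribution not in ("ulcer", "pain"):
        return 0.0
    if variant is CostVariant.ADMISSIONS_PAIN_ONLY and admission.attribution != "pain":
        return 0.0
    if variant is CostVariant.PER_DIEM:
        if admission.length_of_stay is None:
            raise ValueError(
                f"per-diem costing needs length_of_stay (patient {admission.patient_id})"
            )
        return admission.quantity * admission.length_of_stay * table.per_diem_rate
    if variant is CostVariant.DRG_ALL_COMPLICATIONS:
        flag = 1
    elif variant is CostVariant.DRG_NO_COMPLICATIONS:
        flag = 0
    else:  # base case and attribution variants use the charted flag
        flag = admission.complication or 0
    return admission.quantity * _admission_tariff(admission, table, flag)


@dataclass
class CostBreakdown:
    """One patient's annual costs in reference-year euros, by category."""

    patient_id: str
    components: dict[str, float] = field(default_factory=dict)

    @property
    def total_analgesics(self) -> float:
        return sum(v for k, v in self.components.items() if k in ANALGESIC_CATEGORIES)

    @property
    def total_excluding_analgesics(self) -> float:
        return sum(v for k, v in self.components.items() if k not in ANALGESIC_CATEGORIES)

    @property
    def total(self) -> float:
        return sum(self.components.values())


def annual_patient_cost(
    resources: Sequence[ResourceUseRecord],
    table: UnitCostTable,
    cpi: Optional[CPIIndex] = None,
    variant: CostVariant = CostVariant.BASE_CASE,
) -> CostBreakdown:
    """Aggregate one patient's resources into a :class:`CostBreakdown`.

    Every component is ``sum(quantity x unit cost)`` CPI-adjusted to the
    reference year; admissions go through :func:`cost_admission` under the
    active variant.
    """
    cpi = cpi or CPIIndex()
    pids = {r.patient_id for r in resources}
    if len(pids) > 1:
        raise ValueError(f"resources span several patients: {sorted(pids)}")
    patient_id = next(iter(pids)) if pids else ""
    components: dict[str, float] = {}
    for r in resources:
        if r.category == ADMISSION:
            amount = cost_admission(r, table, variant)
        else:
            if r.category not in table.unit_costs:
                raise ValueError(f"no unit cost for category {r.category!r}")
            amount = r.quantity * table.unit_costs[r.category]
        components[r.category] = components.get(r.category, 0.0) + adjust_to_reference_year(
            amount, r.year, cpi
        )
    return CostBreakdown(patient_id=patient_id, components=components)


def cost_cohort(
    resources: Iterable[ResourceUseRecord],
    table: UnitCostTable,
    cpi: Optional[CPIIndex] = None,
    variant: CostVariant = CostVariant.BASE_CASE,
    patient_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-patient cost table (one row per patient, one column per category).

    ``patient_ids`` forces rows (all-zero breakdowns) for patients without
    any resource record.
    """
    by_patient: dict[str, list[ResourceUseRecord]] = {}
    for r in resources:
        by_patient.setdefault(r.patient_id, []).append(r)
    ids = list(patient_ids) if patient_ids is not None else sorted(by_patient)
    rows = []
    for pid in ids:
        bd = annual_patient_cost(by_patient.get(pid, []), table, cpi, variant)
        row = {"patient_id": pid, **bd.components}
        row["total_analgesics"] = bd.total_analgesics
        row["total_excluding_analgesics"] = bd.total_excluding_analgesics
        row["total"] = bd.total
        rows.append(row)
    frame = pd.DataFrame(rows).fillna(0.0)
    if not frame.empty:
        frame["patient_id"] = frame["patient_id"].astype(str)
    return frame
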