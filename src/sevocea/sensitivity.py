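"""Scenario definitions and the sensitivity-analysis suite.

Three scenario families, at most one active per scenario:

* one-way hospitalization-cost variants (re-cost admissions under a
  :class:`~sevocea.costing.CostVariant` and rebuild each patient's annual
  cost),
* subgroup exclusion (drop patients who died or underwent amputation
  before month 12),
* the extreme scenario (costs +25% for the intervention arm / -25% for the
  comparator, effectiveness -25% / +25%; the 25% is configuration, not
  code).

Each scenario gets a reproducible seed derived from the master seed and the
scenario name, so suite runs are repeatable without artificially
correlating scenarios.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import pandas as pd

from .bayes import AnalysisRow, MCMCConfig, PriorSpec, build_design, gibbs_sample
from .cea import CEASummary, summarize_cea
from .costing import CostVariant, annual_patient_cost
from .records import CPIIndex, PatientRecord, ResourceUseRecord, UnitCostTable

__all__ = [
    "Scenario",
    "ScenarioError",
    "DEFAULT_EXTREME_MULTIPLIERS",
    "standard_scenarios",
    "apply_scenario",
    "run_sensitivity_suite",
    "scenario_seed",
]

#: Extreme-scenario multipliers (worst case for the intervention arm).
DEFAULT_EXTREME_MULTIPLIERS: dict[str, float] = {
    "treated_cost": 1.25,
    "control_cost": 0.75,
    "treated_spid": 0.75,
    "control_spid": 1.25,
}


class ScenarioError(ValueError):
    """A scenario cannot be applied to the available inputs."""


@dataclass(frozen=True)
class Scenario:
    """One sensitivity scenario; the base case has every family inactive."""

    name: str
    cost_variant: Optional[CostVariant] = None
    exclude_events: bool = False
    extreme_multipliers: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        active = sum(
            [
                self.cost_variant is not None and self.cost_variant != CostVariant.BASE_CASE,
                self.exclude_events,
                self.extreme_multipliers is not None,
            ]
        )
        if active > 1:
            raise ValueError(f"scenario {self.name!r} activates more than one family")


def standard_scenarios() -> list[Scenario]:
    """The standard suite: base case, five one-way hospitalization variants,
    the event-exclusion subgroup, and the 25% extreme scenario."""
    return [
        Scenario("base_case"),
        Scenario("drg_all_complications", cost_variant=CostVariant.DRG_ALL_COMPLICATIONS),
        Scenario("drg_no_complications", cost_variant=CostVariant.DRG_NO_COMPLICATIONS),
        Scenario("admissions_ulcer_only", cost_variant=CostVariant.ADMISSIONS_ULCER_ONLY),
        Scenario("admissions_pain_only", cost_variant=CostVariant.ADMISSIONS_PAIN_ONLY),
        Scenario("per_diem", cost_variant=CostVariant.PER_DIEM),
        Scenario("exclude_death_amputation", exclude_events=True),
        Scenario("extreme_25pct", extreme_multipliers=dict(DEFAULT_EXTREME_MULTIPLIERS)),
    ]


def scenario_seed(master_seed: int, name: str) -> int:
    """Deterministic per-scenario seed: master seed + CRC32 of the name."""
    return (int(master_seed) + zlib.crc32(name.encode("utf-8"))) % (2**32)


def apply_scenario(
    rows: Sequence[AnalysisRow],
    scenario: Scenario,
    patients: Optional[Sequence[PatientRecord]] = None,
    resources: Optional[Sequence[ResourceUseRecord]] = None,
    unit_table: Optional[UnitCostTable] = None,
    cpi: Optional[CPIIndex] = None,
) -> list[AnalysisRow]:
    """Return the scenario's analysis rows; the input rows are never mutated.

    Cost-variant scenarios re-cost every patient from resource-level records
    (required — aggregate costs cannot be re-costed); the exclusion scenario
    needs the patient records' event flags; the extreme scenario only needs
    the rows themselves.  The base case returns a copy of the input.
    """
    if scenario.exclude_events:
        if patients is None:
            raise ScenarioError("exclusion scenario needs patient records (event flags)")
        events = {p.patient_id for p in patients if p.event_month is not None}
        return [r for r in rows if r.patient_id not in events]

    if scenario.extreme_multipliers is not None:
        m = scenario.extreme_multipliers
        out = []
        for r in rows:
            if r.treatment == 1:
                out.append(replace(r, annual_cost=r.annual_cost * m["treated_cost"],
                                   spid=r.spid * m["treated_spid"]))
            else:
                out.append(replace(r, annual_cost=r.annual_cost * m["control_cost"],
                                   spid=r.spid * m["control_spid"]))
        return out

    if scenario.cost_variant is not None and scenario.cost_variant != CostVariant.BASE_CASE:
        if resources is None or unit_table is None:
            raise ScenarioError(
                f"cost-variant scenario {scenario.name!r} needs resource-level "
                "records and a unit-cost table (cannot re-cost aggregates)"
            )
        by_patient: dict[str, list[ResourceUseRecord]] = {}
        for res in resources:
            by_patient.setdefault(res.patient_id, []).append(res)
        out = []
        for r in rows:
            bd = annual_patient_cost(
                by_patient.get(r.patient_id, []), unit_table, cpi, scenario.cost_variant
            )
            out.append(replace(r, annual_cost=bd.total))
        return out

    return list(rows)  # base case


def run_sensitivity_suite(
    rows: Sequence[AnalysisRow],
    scenarios: Sequence[Scenario],
    prior: Optional[PriorSpec] = None,
    mcmc: Optional[MCMCConfig] = None,
    patients: Optional[Sequence[PatientRecord]] = None,
    resources: Optional[Sequence[ResourceUseRecord]] = None,
    unit_table: Optional[UnitCostTable] = None,
    cpi: Optional[CPIIndex] = None,
    master_seed: int = 0,
    lambda_grid=None,
) -> tuple[dict[str, CEASummary], pd.DataFrame]:
    """Fit the model under every scenario and collate the CEA summaries.

    Each scenario runs a fresh MCMC chain on its own rows with its own
    derived seed.  Scenarios that fail to apply (e.g. a cost variant without
    resource records) are marked failed in the collated table and the suite
    continues.  Returns ``(per-scenario summaries, collated table)``.
    """
    prior = prior or PriorSpec()
    mcmc = mcmc or MCMCConfig()
    summaries: dict[str, CEASummary] = {}
    collated = []
    for sc in scenarios:
        try:
            sc_rows = apply_scenario(rows, sc, patients, resources, unit_table, cpi)
            md = build_design(sc_rows)
            cfg = replace(mcmc, seed=scenario_seed(master_seed, sc.name))
            draws = gibbs_sample(md, prior, cfg)
            comparator = md.X[md.X[:, -1] == 0]
            xbar = comparator.mean(axis=0) if len(comparator) else None
            summary = summarize_cea(draws, comparator_xbar=xbar, lambda_grid=lambda_grid)
            summaries[sc.name] = summary
            collated.append(
                {
                    "scenario": sc.name,
                    "n_patients": len(sc_rows),
                    "costs_ratio_mean": summary.costs_ratio["mean"],
                    "incremental_effectiveness_mean": summary.incremental_effectiveness["mean"],
                    "p_cheaper": summary.p_cheaper,
                    "p_more_effective": summary.p_more_effective,
                    "p_dominant": summary.p_dominant,
                    "status": "ok",
                }
            )
        except ScenarioError as exc:
            collated.append(
                {"scenario": sc.name, "n_patients": 0, "costs_ratio_mean": float("nan"),
                 "incremental_effectiveness_mean": float("nan"), "p_cheaper": float("nan"),
                 "p_more_effective": float("nan"), "p_dominant": float("nan"),
                 "status": f"failed: {exc}"}
            )
    return summaries, pd.DataFrame(collated)
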