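"""End-to-end orchestration: records -> outcomes -> costs -> fit -> CEA -> scenarios.

A single YAML-able config dict drives the run; every stage's numbers are
written as machine-readable CSV/JSON next to the figures, and the run log
records the master seed so re-runs are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from . import __version__
from .bayes import (
    AnalysisRow,
    MCMCConfig,
    PriorSpec,
    build_design,
    gibbs_sample,
    rows_to_frame,
    summarize_posterior,
)
from .cea import plot_ce_plane, plot_ceac, ce_plane, summarize_cea
from .costing import CostVariant, build_cpi_index, build_unit_cost_table, cost_cohort
from .outcomes import compute_outcomes
from .records import (
    CPIIndex,
    PatientRecord,
    ResourceUseRecord,
    UnitCostTable,
    VisitRecord,
    load_study_tables,
    validate_cohort,
    write_study_tables,
)
from .sensitivity import Scenario, standard_scenarios, run_sensitivity_suite
from .synthetic import SyntheticConfig, generate_cohort

__all__ = ["cohort_to_rows", "run_pipeline"]


def cohort_to_rows(
    patients: Sequence[PatientRecord],
    visits: Sequence[VisitRecord],
    resources: Sequence[ResourceUseRecord],
    unit_table: UnitCostTable,
    cpi: Optional[CPIIndex] = None,
    variant: CostVariant = CostVariant.BASE_CASE,
) -> list[AnalysisRow]:
    """Build per-patient analysis rows from the three raw record levels."""
    outcome_frame = compute_outcomes(patients, visits).set_index("patient_id")
    cost_frame = cost_cohort(
        resources, unit_table, cpi, variant, patient_ids=[p.patient_id for p in patients]
    ).set_index("patient_id")
    rows = []
    for p in patients:
        rows.append(
            AnalysisRow(
                patient_id=p.patient_id,
                treatment=p.group,
                aht=p.aht,
                ulcer_duration=p.ulcer_duration,
                ulcer_number=p.ulcer_number,
                ulcer_depth=p.ulcer_depth,
                ulcer_pain=p.baseline_pain,
                annual_cost=float(cost_frame.loc[p.patient_id, "total"]),
                spid=float(outcome_frame.loc[p.patient_id, "spid"]),
            )
        )
    return rows


def _scenarios_from_config(names: Optional[Sequence[str]]) -> list[Scenario]:
    available = {s.name: s for s in standard_scenarios()}
    if names is None:
        return list(available.values())
    unknown = [n for n in names if n not in available]
    if unknown:
        raise ValueError(f"unknown scenario(s): {', '.join(unknown)}")
    return [available[n] for n in names]


def run_pipeline(config: Mapping, outdir) -> dict:
    """Run the full analysis and write the report bundle under ``outdir``.

    Config keys (all optional unless noted):

    * ``synthetic``: mapping of :class:`SyntheticConfig` overrides — or
      ``inputs``: mapping with ``patients``/``visits``/``resources`` paths
      (one of the two is required);
    * ``unit_costs`` / ``cpi``: costing tables;
    * ``prior``: ``coef_prior_variance``, ``wishart_df``;
    * ``mcmc``: ``burn_in``, ``kept_iterations``, ``thinning``;
    * ``seed``: master seed (also seeds the MCMC);
    * ``scenarios``: list of scenario names (default: the full suite);
      ``run_scenarios``: false to skip the suite;
    * ``lambda_max`` / ``lambda_steps``: CEAC grid;
    * ``credible_level``, ``figures`` (default true).

    Returns a dict of output paths and headline numbers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    unit_table = build_unit_cost_table(config.get("unit_costs"))
    cpi = build_cpi_index(config.get("cpi"))

    if "inputs" in config:
        paths = config["inputs"]
        patients, visits, resources = load_study_tables(
            paths["patients"], paths["visits"], paths.get("resources"),
            column_map=config.get("column_map"),
        )
    elif "synthetic" in config or config.get("use_synthetic", False):
        overrides = dict(config.get("synthetic") or {})
        overrides.setdefault("seed", seed)
        bundle = generate_cohort(SyntheticConfig(**overrides), unit_table)
        patients, visits, resources = bundle.patients, bundle.visits, bundle.resources
        write_study_tables(
            patients, visits, resources,
            outdir / "patients.csv", outdir / "visits.csv", outdir / "resources.csv",
        )
        (outdir / "truth.json").write_text(json.dumps(bundle.truth, indent=2))
    else:
        raise ValueError("config needs either 'inputs' paths or a 'synthetic' section")

    report = validate_cohort(patients, visits, resources)
    (outdir / "validation.json").write_text(report.to_json())
    if not report.empty:
        raise ValueError(f"cohort failed validation:\n{report}")

    outcome_frame = compute_outcomes(patients, visits)
    outcome_frame.to_csv(outdir / "outcomes.csv", index=False)
    cost_frame = cost_cohort(
        resources, unit_table, cpi, patient_ids=[p.patient_id for p in patients]
    )
    cost_frame.to_csv(outdir / "cost_breakdown.csv", index=False)

    rows = cohort_to_rows(patients, visits, resources, unit_table, cpi)
    rows_to_frame(rows).to_csv(outdir / "analysis_rows.csv", index=False)

    prior_cfg = config.get("prior", {})
    prior = PriorSpec(
        coef_prior_variance=float(prior_cfg.get("coef_prior_variance", 1e5)),
        wishart_df=float(prior_cfg.get("wishart_df", 2.0)),
    )
    mcmc_cfg = config.get("mcmc", {})
    mcmc = MCMCConfig(
        burn_in=int(mcmc_cfg.get("burn_in", 10_000)),
        kept_iterations=int(mcmc_cfg.get("kept_iterations", 100_000)),
        thinning=int(mcmc_cfg.get("thinning", 1)),
        seed=seed,
    )
    level = float(config.get("credible_level", 0.95))

    md = build_design(rows)
    draws = gibbs_sample(md, prior, mcmc)
    summarize_posterior(draws, level).to_csv(outdir / "posterior_summary.csv")

    comparator = md.X[md.X[:, -1] == 0]
    xbar = comparator.mean(axis=0)
    grid = np.linspace(
        0.0, float(config.get("lambda_max", 2000.0)), int(config.get("lambda_steps", 101))
    )
    summary = summarize_cea(draws, comparator_xbar=xbar, lambda_grid=grid, credible_level=level)
    (outdir / "cea_summary.json").write_text(summary.to_json())
    summary.ceac.to_csv(outdir / "ceac.csv", index=False)
    ce_plane(draws).to_csv(outdir / "ce_plane.csv", index=False)
    if config.get("figures", True):
        plot_ce_plane(draws, outdir / "ce_plane.png")
        plot_ceac(summary.ceac, outdir / "ceac.png")

    result: dict = {
        "outdir": str(outdir),
        "n_patients": len(rows),
        "costs_ratio_mean": summary.costs_ratio["mean"],
        "incremental_effectiveness_mean": summary.incremental_effectiveness["mean"],
        "p_dominant": summary.p_dominant,
    }

    if config.get("run_scenarios", True):
        scenarios = _scenarios_from_config(config.get("scenarios"))
        summaries, collated = run_sensitivity_suite(
            rows, scenarios, prior, mcmc,
            patients=patients, resources=resources, unit_table=unit_table, cpi=cpi,
            master_seed=seed,
        )
        collated.to_csv(outdir / "scenarios.csv", index=False)
        for name, sc_summary in summaries.items():
            (outdir / f"cea_{name}.json").write_text(sc_summary.to_json())
        result["scenarios"] = {
            row["scenario"]: row["p_dominant"] for row in collated.to_dict("records")
        }

    log = {
        "package_version": __version__,
        "seed": seed,
        "mcmc": asdict(mcmc),
        "prior": {"coef_prior_variance": prior.coef_prior_variance,
                  "wishart_df": prior.wishart_df},
        "credible_level": level,
        "n_patients": len(rows),
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
    return result
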