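"""Synthetic study-shaped cohorts with known ground truth.

Two granularities:

* :func:`generate_analysis_rows` draws covariates and then (log annual
  cost, SPID) directly from the bivariate normal regression law — the
  model's own likelihood — returning rows plus the truth bundle;
* :func:`generate_cohort` additionally materializes the raw record levels
  (patients, visits, resources) *consistently* with each drawn (cost, SPID)
  pair: pain trajectories are built so that carry-forward + SPID reproduce
  the drawn SPID, and resource quantities are back-solved so that base-case
  costing reproduces the drawn annual cost.

Default true coefficients are round numbers of study-like magnitude; they
are synthetic defaults, not estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .bayes import (
    AnalysisRow,
    MCMCConfig,
    PriorSpec,
    build_design,
    gibbs_sample,
)
from .cea import dominance_probabilities
from .costing import build_unit_cost_table
from .records import (
    ADMISSION,
    PatientRecord,
    ResourceUseRecord,
    UnitCostTable,
    VisitRecord,
)

__all__ = [
    "SyntheticConfig",
    "CohortBundle",
    "generate_analysis_rows",
    "generate_cohort",
    "recovery_experiment",
]

DEFAULT_BETA_COST = np.array([7.6, 0.4, 0.02, 0.3, 1.0, 0.0, -0.7])
DEFAULT_BETA_EFF = np.array([-22.0, 1.5, 0.1, 0.6, 1.3, 4.5, 28.0])
DEFAULT_SIGMA = np.array([[0.9, -3.0], [-3.0, 120.0]])


@dataclass
class SyntheticConfig:
    """Generator parameters for a study-shaped cohort."""

    n_treated: int = 38
    n_control: int = 26
    # covariate generators
    p_aht: float = 0.73
    ulcer_duration_mu: float = 2.7    # lognormal log-mean, months
    ulcer_duration_sigma: float = 1.0
    ulcer_number_probs: tuple[float, ...] = (0.35, 0.25, 0.15, 0.10, 0.10, 0.05)  # counts 1..6
    p_depth: float = 0.28
    baseline_pain_mean: float = 6.8
    baseline_pain_sd: float = 1.5
    # regression truth
    beta_cost: np.ndarray = field(default_factory=lambda: DEFAULT_BETA_COST.copy())
    beta_eff: np.ndarray = field(default_factory=lambda: DEFAULT_BETA_EFF.copy())
    sigma: np.ndarray = field(default_factory=lambda: DEFAULT_SIGMA.copy())
    # raw-record generation
    death_rate: float = 0.125
    amputation_rate: float = 0.05
    visit_interval_months: float = 1.5
    integer_pain: bool = False  # True rounds visit pains to NRS integers
    sevoflurane_cost_share: float = 0.25  # treated arm only
    admission_cost_share: float = 0.5
    p_admission_complication: float = 0.4
    attribution_probs: tuple[float, float, float] = (0.6, 0.2, 0.2)  # any/ulcer/pain
    seed: int = 0

    def __post_init__(self) -> None:
        self.beta_cost = np.asarray(self.beta_cost, float)
        self.beta_eff = np.asarray(self.beta_eff, float)
        self.sigma = np.asarray(self.sigma, float)
        if self.beta_cost.shape != (7,) or self.beta_eff.shape != (7,):
            raise ValueError("coefficient vectors must have length 7")
        if self.sigma.shape != (2, 2):
            raise ValueError("sigma must be 2x2")
        if not np.allclose(self.sigma, self.sigma.T) or np.any(np.linalg.eigvalsh(self.sigma) <= 0):
            raise ValueError("sigma must be symmetric positive-definite")
        if self.n_treated < 2 or self.n_control < 2:
            raise ValueError("group sizes must be >= 2")
        for name in ("p_aht", "p_depth", "death_rate", "amputation_rate",
                     "p_admission_complication"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability, got {v}")


@dataclass
class CohortBundle:
    """Raw record levels plus the analysis rows and truth they encode."""

    patients: list[PatientRecord]
    visits: list[VisitRecord]
    resources: list[ResourceUseRecord]
    rows: list[AnalysisRow]
    truth: dict
    infeasible_resamples: int = 0


def _draw_covariates(config: SyntheticConfig, rng: np.random.Generator) -> list[dict]:
    n = config.n_treated + config.n_control
    treatment = np.array([1] * config.n_treated + [0] * config.n_control)
    probs = np.asarray(config.ulcer_number_probs, float)
    probs = probs / probs.sum()
    out = []
    for i in range(n):
        pain = float(np.clip(np.rint(rng.normal(config.baseline_pain_mean, config.baseline_pain_sd)), 0, 10))
        out.append(
            {
                "patient_id": f"P{i + 1:03d}",
                "treatment": int(treatment[i]),
                "aht": int(rng.random() < config.p_aht),
                "ulcer_duration": float(rng.lognormal(config.ulcer_duration_mu, config.ulcer_duration_sigma)),
                "ulcer_number": int(rng.choice(np.arange(1, len(probs) + 1), p=probs)),
                "ulcer_depth": int(rng.random() < config.p_depth),
                "ulcer_pain": pain,
            }
        )
    return out


def _design_vector(cov: dict) -> np.ndarray:
    return np.array(
        [1.0, cov["aht"], cov["ulcer_duration"], min(cov["ulcer_number"], 4),
         cov["ulcer_depth"], cov["ulcer_pain"], cov["treatment"]]
    )


def generate_analysis_rows(
    config: Optional[SyntheticConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[AnalysisRow], dict]:
    """Draw covariates and responses straight from the regression law.

    Returns ``(rows, truth)``; the truth bundle holds the coefficient
    vectors, the error covariance and the per-patient linear predictors.
    """
    config = config or SyntheticConfig()
    rng = rng or np.random.default_rng(config.seed)
    covariates = _draw_covariates(config, rng)
    chol = np.linalg.cholesky(config.sigma)
    rows, means = [], []
    for cov in covariates:
        x = _design_vector(cov)
        mu = np.array([x @ config.beta_cost, x @ config.beta_eff])
        resp = mu + chol @ rng.standard_normal(2)
        means.append(mu)
        rows.append(
            AnalysisRow(
                patient_id=cov["patient_id"],
                treatment=cov["treatment"],
                aht=cov["aht"],
                ulcer_duration=cov["ulcer_duration"],
                ulcer_number=cov["ulcer_number"],
                ulcer_depth=cov["ulcer_depth"],
                ulcer_pain=cov["ulcer_pain"],
                annual_cost=float(np.exp(resp[0])),
                spid=float(resp[1]),
            )
        )
    truth = {
        "beta_cost": config.beta_cost.tolist(),
        "beta_eff": config.beta_eff.tolist(),
        "sigma": config.sigma.tolist(),
        "linear_predictors": np.array(means).tolist(),
    }
    return rows, truth


def _spid_feasible(spid: float, baseline: float) -> bool:
    # constant post-baseline pain level p = baseline - spid/12 must be an NRS value
    p = baseline - spid / 12.0
    return 0.0 <= p <= 10.0


def _build_visits(
    cov: dict,
    spid: float,
    event_month: Optional[float],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> list[VisitRecord]:
    """Visit trajectory whose carry-forward SPID equals ``spid``.

    Pain drops at the first follow-up visit to the constant level
    ``baseline - spid/12`` and stays there; with every follow-up interval at
    that level, SPID telescopes to (baseline - level) x 12 regardless of the
    schedule, so the target is hit exactly (up to NRS rounding when
    ``integer_pain``).
    """
    pid, baseline = cov["patient_id"], cov["ulcer_pain"]
    level = baseline - spid / 12.0
    if config.integer_pain:
        level = float(np.clip(np.rint(level), 0, 10))
    end = min(12.0, event_month) if event_month is not None else 12.0
    visits = [VisitRecord(pid, 0.0, baseline)]
    t = config.visit_interval_months * (0.75 + 0.5 * rng.random())
    t = min(t, end * 0.5 if end < 12.0 else t)  # guarantee one follow-up before the event
    while t < end:
        visits.append(VisitRecord(pid, round(t, 3), level))
        t += config.visit_interval_months * (0.75 + 0.5 * rng.random())
    if len(visits) == 1:  # event very early: still need one follow-up
        visits.append(VisitRecord(pid, round(end * 0.5, 3), level))
    return visits


def _build_resources(
    cov: dict,
    cost: float,
    table: UnitCostTable,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> list[ResourceUseRecord]:
    """Resource records whose base-case costing totals ``cost`` exactly.

    Whole admissions are emitted while the admission share of the target
    covers a DRG tariff; the remainder is distributed over continuous
    categories with back-solved (fractional) quantities.
    """
    pid = cov["patient_id"]
    records: list[ResourceUseRecord] = []
    remaining = cost

    if cov["treatment"] == 1:
        sev_budget = cost * config.sevoflurane_cost_share
        # split the sevoflurane bundle over drug, syringes and filling labour
        ml_price = table.unit_costs["sevoflurane_mL"]
        syringe_price = table.unit_costs["syringe_10mL"]
        fill_price = table.unit_costs["syringe_fill"]
        ml = sev_budget * 0.9 / ml_price if ml_price > 0 else 0.0
        syringes = ml / 10.0  # one 10 mL syringe per 10 mL irrigated
        spent = ml * ml_price + syringes * (syringe_price + fill_price)
        scale = sev_budget / spent if spent > 0 else 0.0
        ml *= scale
        syringes *= scale
        records += [
            ResourceUseRecord(pid, "sevoflurane_mL", ml),
            ResourceUseRecord(pid, "syringe_10mL", syringes),
            ResourceUseRecord(pid, "syringe_fill", syringes),
        ]
        remaining -= ml * ml_price + syringes * (syringe_price + fill_price)

    adm_budget = cost * config.admission_cost_share
    attr_levels = np.array(["any", "ulcer", "pain"])
    attr_p = np.asarray(config.attribution_probs, float)
    attr_p = attr_p / attr_p.sum()
    while True:
        complication = int(rng.random() < config.p_admission_complication)
        tariff = (table.drg_with if complication else table.drg_without)["default"]
        if tariff <= 0 or adm_budget < tariff:
            break
        records.append(
            ResourceUseRecord(
                pid, ADMISSION, 1.0,
                attribution=str(rng.choice(attr_levels, p=attr_p)),
                complication=complication,
                length_of_stay=float(rng.integers(3, 15)),
            )
        )
        adm_budget -= tariff
        remaining -= tariff

    # remainder over continuous categories, proportions fixed
    spread = {
        "opioid": 0.25,
        "nonopioid": 0.10,
        "pc_sched_nurse": 0.20,
        "hosp_sched_next": 0.30,
        "pc_nonsched_simple": 0.15,
    }
    for category, share in spread.items():
        unit = table.unit_costs[category]
        if unit > 0:
            records.append(ResourceUseRecord(pid, category, remaining * share / unit))
    return records


def generate_cohort(
    config: Optional[SyntheticConfig] = None,
    unit_table: Optional[UnitCostTable] = None,
    max_resamples: int = 1000,
) -> CohortBundle:
    """Generate all three record levels consistent with drawn (cost, SPID).

    Responses whose SPID target is unattainable for the drawn baseline pain
    (the constant-level trajectory would leave the NRS range) are redrawn;
    the resample count is reported in the bundle.
    """
    config = config or SyntheticConfig()
    unit_table = unit_table or build_unit_cost_table()
    rng = np.random.default_rng(config.seed)
    covariates = _draw_covariates(config, rng)
    chol = np.linalg.cholesky(config.sigma)

    patients, visits, resources, rows = [], [], [], []
    resamples = 0
    for cov in covariates:
        x = _design_vector(cov)
        mu = np.array([x @ config.beta_cost, x @ config.beta_eff])
        for _ in range(max_resamples):
            resp = mu + chol @ rng.standard_normal(2)
            if _spid_feasible(resp[1], cov["ulcer_pain"]):
                break
            resamples += 1
        else:
            resp[1] = float(np.clip(resp[1], (cov["ulcer_pain"] - 10) * 12, cov["ulcer_pain"] * 12))
        cost, spid = float(np.exp(resp[0])), float(resp[1])

        death_month = amputation_month = None
        u = rng.random()
        if u < config.death_rate:
            death_month = float(np.round(rng.uniform(1.0, 12.0), 2))
        elif u < config.death_rate + config.amputation_rate:
            amputation_month = float(np.round(rng.uniform(1.0, 12.0), 2))

        patients.append(
            PatientRecord(
                patient_id=cov["patient_id"],
                group=cov["treatment"],
                aht=cov["aht"],
                ulcer_duration=cov["ulcer_duration"],
                ulcer_number=cov["ulcer_number"],
                ulcer_depth=cov["ulcer_depth"],
                baseline_pain=cov["ulcer_pain"],
                death_month=death_month,
                amputation_month=amputation_month,
            )
        )
        event = death_month if death_month is not None else amputation_month
        visits += _build_visits(cov, spid, event, config, rng)
        resources += _build_resources(cov, cost, unit_table, config, rng)
        rows.append(
            AnalysisRow(
                patient_id=cov["patient_id"],
                treatment=cov["treatment"],
                aht=cov["aht"],
                ulcer_duration=cov["ulcer_duration"],
                ulcer_number=cov["ulcer_number"],
                ulcer_depth=cov["ulcer_depth"],
                ulcer_pain=cov["ulcer_pain"],
                annual_cost=cost,
                spid=spid,
            )
        )
    truth = {
        "beta_cost": config.beta_cost.tolist(),
        "beta_eff": config.beta_eff.tolist(),
        "sigma": config.sigma.tolist(),
    }
    return CohortBundle(patients, visits, resources, rows, truth, resamples)


def recovery_experiment(
    config: Optional[SyntheticConfig] = None,
    replicates: int = 200,
    prior: Optional[PriorSpec] = None,
    mcmc: Optional[MCMCConfig] = None,
    credible_level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Parameter-recovery study for the Gibbs sampler.

    Per replicate: generate analysis rows, fit, and record the posterior
    mean, SD and equal-tailed CrI coverage of the two treatment
    coefficients, plus the dominance probability.  Returns one row per
    replicate; aggregate coverage should land near the nominal level.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    config = config or SyntheticConfig()
    prior = prior or PriorSpec()
    mcmc = mcmc or MCMCConfig(burn_in=1000, kept_iterations=20_000)
    true_b17 = float(config.beta_cost[-1])
    true_b27 = float(config.beta_eff[-1])
    lo = 100 * (1 - credible_level) / 2
    hi = 100 - lo
    master = np.random.SeedSequence(seed)
    data_seeds, fit_seeds = master.spawn(2)
    data_children = data_seeds.spawn(replicates)
    fit_children = fit_seeds.spawn(replicates)
    out = []
    for i in range(replicates):
        rng = np.random.default_rng(data_children[i])
        rows, _ = generate_analysis_rows(config, rng)
        md = build_design(rows)
        cfg = MCMCConfig(
            burn_in=mcmc.burn_in,
            kept_iterations=mcmc.kept_iterations,
            thinning=mcmc.thinning,
            seed=int(fit_children[i].generate_state(1)[0]),
        )
        draws = gibbs_sample(md, prior, cfg)
        b17 = draws.treatment_cost
        b27 = draws.treatment_eff
        _, _, p_dom = dominance_probabilities(draws)
        out.append(
            {
                "replicate": i,
                "b17_mean": float(b17.mean()),
                "b17_sd": float(b17.std(ddof=1)),
                "b17_covered": bool(np.percentile(b17, lo) <= true_b17 <= np.percentile(b17, hi)),
                "b27_mean": float(b27.mean()),
                "b27_sd": float(b27.std(ddof=1)),
                "b27_covered": bool(np.percentile(b27, lo) <= true_b27 <= np.percentile(b27, hi)),
                "p_dominant": p_dom,
            }
        )
    frame = pd.DataFrame(out)
    frame.attrs["true_b17"] = true_b17
    frame.attrs["true_b27"] = true_b27
    return frame
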