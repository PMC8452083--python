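import pytest

from sevocea.bayes import MCMCConfig, PriorSpec, build_design, gibbs_sample
from sevocea.costing import build_unit_cost_table
from sevocea.records import PatientRecord, ResourceUseRecord, VisitRecord
from sevocea.synthetic import SyntheticConfig, generate_analysis_rows, generate_cohort


@pytest.fixture(scope="session")
def unit_table():
    return build_unit_cost_table()


@pytest.fixture(scope="session")
def toy_cohort():
    """Three hand-built patients with visits and resources."""
    patients = [
        PatientRecord("A", 1, 1, 24.0, 2, 0, 8.0),
        PatientRecord("B", 1, 0, 6.0, 1, 1, 6.0, death_month=7.0),
        PatientRecord("C", 0, 1, 12.0, 5, 0, 7.0),
    ]
    visits = [
        VisitRecord("A", 0.0, 8.0), VisitRecord("A", 6.0, 3.0), VisitRecord("A", 12.0, 2.0),
        VisitRecord("B", 0.0, 6.0), VisitRecord("B", 4.0, 4.0),
        VisitRecord("C", 0.0, 7.0), VisitRecord("C", 5.0, 6.0), VisitRecord("C", 12.0, 6.0),
    ]
    resources = [
        ResourceUseRecord("A", "sevoflurane_mL", 300.0),
        ResourceUseRecord("A", "syringe_10mL", 30.0),
        ResourceUseRecord("A", "syringe_fill", 30.0),
        ResourceUseRecord("A", "hospital_admission", 1.0, attribution="pain",
                          complication=1, length_of_stay=10.0),
        ResourceUseRecord("B", "pc_sched_medical_first", 1.0),
        ResourceUseRecord("B", "opioid", 120.0),
        ResourceUseRecord("C", "hospital_admission", 2.0, attribution="ulcer",
                          complication=0, length_of_stay=5.0),
        ResourceUseRecord("C", "pc_sched_nurse", 10.0),
    ]
    return patients, visits, resources


@pytest.fixture(scope="session")
def synth_rows():
    """Study-shaped synthetic analysis rows with known truth (seed fixed)."""
    return generate_analysis_rows(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def synth_bundle(unit_table):
    """Full three-level synthetic cohort bundle."""
    return generate_cohort(SyntheticConfig(seed=12), unit_table)


@pytest.fixture(scope="session")
def fitted_draws(synth_rows):
    """One shared short-chain fit of the default synthetic dataset."""
    rows, _ = synth_rows
    md = build_design(rows)
    cfg = MCMCConfig(burn_in=500, kept_iterations=4000, seed=99)
    return gibbs_sample(md, PriorSpec(), cfg), md
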