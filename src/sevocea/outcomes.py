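"""Effectiveness outcomes: the SPID statistic, carry-forward, power, descriptives.

SPID (sum of pain intensity differences) accumulates, over every follow-up
visit, the difference between baseline pain (the time-0 NRS score) and the
visit's pain, weighted by the time elapsed since the previous visit,
measured in months over a 12-month horizon.  With month weights the
statistic ranges over [-120, 120]; higher means more cumulative relief.

Patients who died or lost the leg before month 12 have their last observed
pain carried forward to the end of the horizon before SPID is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import PatientRecord, VisitRecord

__all__ = [
    "OutcomeSet",
    "carry_forward_final_pain",
    "compute_spid",
    "pain_reduction_rate",
    "daily_ome",
    "posthoc_power",
    "compute_outcomes",
    "group_descriptives",
]

HORIZON_MONTHS = 12.0


@dataclass
class OutcomeSet:
    """Per-patient health outcomes over the follow-up year."""

    patient_id: str
    spid: float
    final_pain: float
    pain_reduction_rate: Optional[float]  # percent; None when baseline is 0
    completed_followup: bool
    healed: Optional[int] = None
    final_area: Optional[float] = None
    daily_ome: Optional[float] = None


def _sorted_visits(visits: Sequence[VisitRecord]) -> list[VisitRecord]:
    return sorted(visits, key=lambda v: v.time)


def carry_forward_final_pain(
    visits: Sequence[VisitRecord],
    patient: Optional[PatientRecord] = None,
    horizon_months: float = HORIZON_MONTHS,
) -> list[VisitRecord]:
    """Extend a visit sequence to the horizon by carrying the last pain forward.

    Observed visits are returned unchanged; if the last observed visit falls
    short of ``horizon_months`` a synthetic visit at the horizon with the
    last observed pain is appended.  This is the rule applied to patients
    whose follow-up was truncated by death or leg amputation.

    Raises ``ValueError`` on an empty sequence.
    """
    seq = _sorted_visits(visits)
    if not seq:
        raise ValueError("cannot carry forward an empty visit sequence")
    last = seq[-1]
    if last.time >= horizon_months:
        return seq
    return seq + [VisitRecord(last.patient_id, horizon_months, last.pain)]


def compute_spid(visits: Sequence[VisitRecord], horizon_months: float = HORIZON_MONTHS) -> float:
    """Time-weighted sum of pain intensity differences.

    ``spid = sum over follow-up visits v of (P0 - P_v) * (t_v - t_(v-1))``
    with ``P0`` the pain at the time-0 visit and ``t`` in months.  The visit
    sequence must start at time 0 and reach the horizon (apply
    :func:`carry_forward_final_pain` first for truncated follow-up).
    """
    seq = _sorted_visits(visits)
    if not seq:
        raise ValueError("no visits")
    if seq[0].time != 0:
        raise ValueError(f"no time-0 baseline visit (first visit at {seq[0].time})")
    if seq[-1].time < horizon_months:
        raise ValueError(
            f"visit sequence ends at month {seq[-1].time} < horizon {horizon_months}; "
            "apply carry_forward_final_pain first"
        )
    baseline = seq[0].pain
    spid = 0.0
    for prev, cur in zip(seq, seq[1:]):
        spid += (baseline - cur.pain) * (cur.time - prev.time)
    return spid


def pain_reduction_rate(baseline: float, final: float) -> Optional[float]:
    """Percent pain reduction, ``100 * (baseline - final) / baseline``.

    Undefined (returns None) when baseline is 0.
    """
    if baseline == 0:
        return None
    return 100.0 * (baseline - final) / baseline


def daily_ome(
    regimens: Iterable[tuple[str, float]],
    conversion_table: Mapping[str, float],
) -> float:
    """Total daily oral-morphine-equivalent dose in mg/day.

    ``regimens`` is an iterable of ``(opioid_name, mg_per_day)``;
    ``conversion_table`` maps opioid name to its OME factor (user supplied).
    """
    total = 0.0
    for name, dose in regimens:
        if name not in conversion_table:
            raise ValueError(f"no OME conversion factor for opioid {name!r}")
        total += dose * conversion_table[name]
    return total


def posthoc_power(
    mean_a: float,
    mean_b: float,
    common_sd: float,
    n_a: int,
    n_b: int,
    alpha: float = 0.05,
    two_sided: bool = True,
    method: str = "normal",
) -> float:
    """Post hoc power (percent) of a two-sample mean comparison.

    ``method="normal"`` uses the normal-approximation two-mean formula
    (matching the usual sample-size software); ``"noncentral_t"`` uses the
    exact noncentral-t power of the pooled two-sample t-test.  Returns an
    unrounded percent; report rounded to the nearest integer.
    """
    if common_sd <= 0:
        raise ValueError("common_sd must be > 0")
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 per group")
    se = common_sd * np.sqrt(1.0 / n_a + 1.0 / n_b)
    delta = abs(mean_a - mean_b) / se
    a = alpha / 2 if two_sided else alpha
    if method == "normal":
        z = stats.norm.ppf(1 - a)
        power = stats.norm.cdf(delta - z) + stats.norm.cdf(-delta - z)
    elif method == "noncentral_t":
        df = n_a + n_b - 2
        tcrit = stats.t.ppf(1 - a, df)
        power = 1 - stats.nct.cdf(tcrit, df, delta) + stats.nct.cdf(-tcrit, df, delta)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(100.0 * power)


def compute_outcomes(
    patients: Sequence[PatientRecord],
    visits: Sequence[VisitRecord],
    horizon_months: float = HORIZON_MONTHS,
) -> pd.DataFrame:
    """Per-patient outcome table: SPID, final pain, reduction rate.

    Applies the carry-forward rule per patient before computing SPID.
    """
    by_patient: dict[str, list[VisitRecord]] = {}
    for v in visits:
        by_patient.setdefault(v.patient_id, []).append(v)
    rows = []
    for p in patients:
        seq = carry_forward_final_pain(by_patient[p.patient_id], p, horizon_months)
        spid = compute_spid(seq, horizon_months)
        baseline = _sorted_visits(seq)[0].pain
        final = _sorted_visits(seq)[-1].pain
        rows.append(
            {
                "patient_id": p.patient_id,
                "group": p.group,
                "spid": spid,
                "final_pain": final,
                "pain_reduction_rate": pain_reduction_rate(baseline, final),
                "completed_followup": p.event_month is None,
                "died": p.death_month is not None,
                "amputated": p.amputation_month is not None,
            }
        )
    return pd.DataFrame(rows)


def _binary_test(table: np.ndarray) -> tuple[str, float]:
    # Fisher's exact test when any expected count <= 5, else chi-square.
    expected = stats.contingency.expected_freq(table)
    if (expected <= 5).any():
        return "fisher", float(stats.fisher_exact(table)[1])
    return "chi2", float(stats.chi2_contingency(table, correction=False)[1])


def group_descriptives(
    frame: pd.DataFrame,
    group_col: str = "group",
    continuous: Sequence[str] = (),
    binary: Sequence[str] = (),
) -> pd.DataFrame:
    """Two-group descriptive table with standard tests.

    Continuous variables: mean (SD) per group with a Mann-Whitney U rank
    test; binary variables: n (%) per group with chi-square, or Fisher's
    exact test when any expected cell count is below 5.
    """
    groups = sorted(frame[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    g1 = frame[frame[group_col] == groups[1]]
    g0 = frame[frame[group_col] == groups[0]]
    out = []
    for var in continuous:
        a = g1[var].dropna().to_numpy(float)
        b = g0[var].dropna().to_numpy(float)
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0  # degenerate identical samples
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided")[1])
        out.append(
            {"variable": var, "kind": "continuous", "test": "mannwhitney",
             "group1_mean": a.mean(), "group1_sd": a.std(ddof=1) if a.size > 1 else 0.0,
             "group0_mean": b.mean(), "group0_sd": b.std(ddof=1) if b.size > 1 else 0.0,
             "p_value": p}
        )
    for var in binary:
        a = g1[var].dropna().astype(int)
        b = g0[var].dropna().astype(int)
        table = np.array(
            [[int(a.sum()), int(len(a) - a.sum())],
             [int(b.sum()), int(len(b) - b.sum())]]
        )
        if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
            test, p = "degenerate", 1.0
        else:
            test, p = _binary_test(table)
        out.append(
            {"variable": var, "kind": "binary", "test": test,
             "group1_mean": 100.0 * a.mean(), "group1_sd": float(a.sum()),
             "group0_mean": 100.0 * b.mean(), "group0_sd": float(b.sum()),
             "p_value": p}
        )
    return pd.DataFrame(out)
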