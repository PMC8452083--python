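"""Cost-effectiveness outputs from posterior draws.

Because costs enter the regression on the log scale, the treatment effect
on costs is summarized as a *costs ratio* ``exp(b_cost_treatment)`` (the
intervention arm's expected cost divided by the comparator's), and the
relative incremental cost as ``(ratio - 1) x 100`` percent.  Euro-scale
incremental costs — needed for the ICER and the acceptability curve —
require a retransformation convention: by default the comparator arm's
expected cost is evaluated per draw as ``exp(xbar' beta_cost + sigma_cost/2)``
at the comparator covariate means (lognormal mean correction).  Dominance
probabilities are convention-free: the incremental cost's sign is the sign
of the treatment coefficient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .bayes import PosteriorDraws

__all__ = [
    "CEASummary",
    "costs_ratio",
    "incremental_effectiveness",
    "dominance_probabilities",
    "comparator_cost_reference",
    "incremental_cost_draws",
    "icer",
    "ceac",
    "ce_plane",
    "summarize_cea",
    "default_lambda_grid",
    "plot_ce_plane",
    "plot_ceac",
]

BaselineRef = Union[float, np.ndarray]


def _summary(samples: np.ndarray, level: float = 0.95) -> dict[str, float]:
    lo = 100 * (1 - level) / 2
    return {
        "mean": float(np.mean(samples)),
        "sd": float(np.std(samples, ddof=1)) if samples.size > 1 else 0.0,
        "lower": float(np.percentile(samples, lo)),
        "upper": float(np.percentile(samples, 100 - lo)),
    }


def costs_ratio(draws: PosteriorDraws, credible_level: float = 0.95) -> dict[str, float]:
    """Mean/SD/CrI of the per-draw costs ratio exp(treatment cost coefficient).

    Summaries are of the *transformed* draws (mean of exponentials, not the
    exponential of the mean).
    """
    return _summary(np.exp(draws.treatment_cost), credible_level)


def incremental_effectiveness(draws: PosteriorDraws, credible_level: float = 0.95) -> dict[str, float]:
    """Mean/SD/CrI of the treatment coefficient of the effectiveness equation."""
    return _summary(draws.treatment_eff, credible_level)


def dominance_probabilities(draws: PosteriorDraws) -> tuple[float, float, float]:
    """(p_cheaper, p_more_effective, p_dominant) as draw fractions.

    cheaper: cost treatment coefficient < 0; more effective: effectiveness
    treatment coefficient > 0; dominant: both jointly.
    """
    cheaper = draws.treatment_cost < 0
    effective = draws.treatment_eff > 0
    return (
        float(np.mean(cheaper)),
        float(np.mean(effective)),
        float(np.mean(cheaper & effective)),
    )


def comparator_cost_reference(draws: PosteriorDraws, comparator_xbar: np.ndarray) -> np.ndarray:
    """Per-draw expected comparator-arm cost in euros.

    Lognormal mean correction: ``exp(xbar' beta_cost + sigma_cost/2)`` with
    ``xbar`` the comparator-arm covariate means (treatment entry 0).
    """
    xbar = np.asarray(comparator_xbar, float)
    if xbar.shape != (draws.beta_cost.shape[1],):
        raise ValueError(f"comparator_xbar must have shape ({draws.beta_cost.shape[1]},)")
    return np.exp(draws.beta_cost @ xbar + 0.5 * draws.sigma[:, 0, 0])


def incremental_cost_draws(draws: PosteriorDraws, baseline_cost_reference: BaselineRef) -> np.ndarray:
    """Per-draw euro incremental cost: baseline x (ratio - 1)."""
    base = np.asarray(baseline_cost_reference, float)
    if np.any(base <= 0):
        raise ValueError("baseline cost reference must be positive")
    return base * (np.exp(draws.treatment_cost) - 1.0)


def icer(
    draws: PosteriorDraws,
    baseline_cost_reference: BaselineRef,
    credible_level: float = 0.95,
    dominance_threshold: float = 0.95,
) -> dict:
    """Per-draw ICER summary (euros per effectiveness unit).

    Draws with an exactly-zero effectiveness coefficient are excluded (count
    reported).  When the dominance probability exceeds
    ``dominance_threshold`` the summary is flagged: a ratio of a negative
    cost difference to a positive effect gain is not informative.
    """
    inc_cost = incremental_cost_draws(draws, baseline_cost_reference)
    eff = draws.treatment_eff
    nonzero = eff != 0.0
    excluded = int(np.sum(~nonzero))
    ratios = inc_cost[nonzero] / eff[nonzero]
    _, _, p_dom = dominance_probabilities(draws)
    out = _summary(ratios, credible_level)
    out["excluded_zero_effect_draws"] = excluded
    out["dominant"] = bool(p_dom > dominance_threshold)
    if out["dominant"]:
        out["note"] = "dominant - ICER not informative"
    return out


def default_lambda_grid(lambda_max: float = 2000.0, steps: int = 101) -> np.ndarray:
    """Willingness-to-pay grid, 0 to ``lambda_max`` euros per effectiveness unit."""
    return np.linspace(0.0, lambda_max, steps)


def ceac(
    draws: PosteriorDraws,
    lambda_grid: Sequence[float],
    baseline_cost_reference: BaselineRef,
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    ``CEAC(lambda)`` is the fraction of draws with positive incremental net
    benefit ``lambda x effect - incremental cost``.  At lambda 0 this equals
    the probability of being cheaper; for large lambda it tends to the
    probability of being more effective.
    """
    lambdas = np.asarray(lambda_grid, float)
    if np.any(lambdas < 0):
        raise ValueError("willingness-to-pay values must be non-negative")
    inc_cost = incremental_cost_draws(draws, baseline_cost_reference)
    eff = draws.treatment_eff
    probs = [float(np.mean(lam * eff - inc_cost > 0)) for lam in lambdas]
    return pd.DataFrame({"lambda": lambdas, "probability": probs})


def ce_plane(draws: PosteriorDraws) -> pd.DataFrame:
    """Per-draw cost-effectiveness plane points.

    x: incremental effectiveness draw; y: costs ratio draw.  Cost neutrality
    is the horizontal line y = 1 (a ratio, not a difference), recorded in
    ``frame.attrs["cost_neutral_y"]``.
    """
    frame = pd.DataFrame(
        {
            "incremental_effectiveness": draws.treatment_eff,
            "costs_ratio": np.exp(draws.treatment_cost),
        }
    )
    frame.attrs["cost_neutral_y"] = 1.0
    return frame


@dataclass
class CEASummary:
    """Headline cost-effectiveness outputs for one fitted model."""

    costs_ratio: dict[str, float]
    relative_incremental_cost_pct: float
    incremental_effectiveness: dict[str, float]
    p_cheaper: float
    p_more_effective: float
    p_dominant: float
    n_draws: int
    icer: Optional[dict] = None
    ceac: Optional[pd.DataFrame] = field(default=None, repr=False)

    def to_dict(self) -> dict:
        out = {
            "costs_ratio": self.costs_ratio,
            "relative_incremental_cost_pct": self.relative_incremental_cost_pct,
            "incremental_effectiveness": self.incremental_effectiveness,
            "p_cheaper": self.p_cheaper,
            "p_more_effective": self.p_more_effective,
            "p_dominant": self.p_dominant,
            "n_draws": self.n_draws,
            "icer": self.icer,
        }
        if self.ceac is not None:
            out["ceac"] = {
                "lambda": self.ceac["lambda"].tolist(),
                "probability": self.ceac["probability"].tolist(),
            }
        return out

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


def summarize_cea(
    draws: PosteriorDraws,
    comparator_xbar: Optional[np.ndarray] = None,
    baseline_cost_reference: Optional[BaselineRef] = None,
    lambda_grid: Optional[Sequence[float]] = None,
    credible_level: float = 0.95,
    dominance_threshold: float = 0.95,
) -> CEASummary:
    """Assemble the full :class:`CEASummary` from posterior draws.

    Euro-scale outputs (ICER, CEAC) need either ``comparator_xbar`` (default
    lognormal retransformation) or an explicit ``baseline_cost_reference``;
    with neither, those outputs are omitted and the convention-free parts
    are still returned.
    """
    ratio = costs_ratio(draws, credible_level)
    eff = incremental_effectiveness(draws, credible_level)
    p_cheaper, p_effective, p_dominant = dominance_probabilities(draws)
    baseline: Optional[BaselineRef] = baseline_cost_reference
    if baseline is None and comparator_xbar is not None:
        baseline = comparator_cost_reference(draws, comparator_xbar)
    icer_summary = None
    curve = None
    if baseline is not None:
        icer_summary = icer(draws, baseline, credible_level, dominance_threshold)
        grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
        curve = ceac(draws, grid, baseline)
    return CEASummary(
        costs_ratio=ratio,
        relative_incremental_cost_pct=float((ratio["mean"] - 1.0) * 100.0),
        incremental_effectiveness=eff,
        p_cheaper=p_cheaper,
        p_more_effective=p_effective,
        p_dominant=p_dominant,
        n_draws=draws.n_draws,
        icer=icer_summary,
        ceac=curve,
    )


# ---------------------------------------------------------------------------
# figures (headless; the data behind each figure is always exported as CSV)

def plot_ce_plane(draws: PosteriorDraws, path, max_points: int = 20_000) -> None:
    """Scatter of costs-ratio vs incremental-effectiveness draws."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    frame = ce_plane(draws)
    if len(frame) > max_points:
        frame = frame.iloc[:: len(frame) // max_points]
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(frame["incremental_effectiveness"], frame["costs_ratio"], s=2, alpha=0.25)
    ax.axhline(1.0, color="k", lw=0.8)
    ax.axvline(0.0, color="k", lw=0.8)
    ax.set_xlabel("Incremental effectiveness (SPID units)")
    ax.set_ylabel("Costs ratio")
    ax.set_title("Cost-effectiveness plane")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curve: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["lambda"], curve["probability"])
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("Willingness to pay (euros per SPID unit)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_title("Cost-effectiveness acceptability curve")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
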