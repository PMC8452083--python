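"""Bivariate Bayesian regression of (log annual cost, SPID) on six covariates.

The two equations share one design matrix

    [1, AHT, UlcerDuration, UlcerNumber (truncated at 4), UlcerDepth,
     UlcerPain, Treatment]

and a bivariate normal error with unknown 2x2 covariance.  Priors are
conditionally conjugate: independent N(0, 1e5 I7) on each equation's
coefficient vector and Wishart(df 2, I2) on the error *precision* matrix
(the standard BUGS-family parameterization).  Posterior sampling is a
two-block Gibbs sampler:

* coefficients | precision: 14-dimensional multivariate normal with
  precision ``Omega (x) X'X + (1/1e5) I``;
* precision | coefficients: Wishart with df ``2 + n`` and scale
  ``(I + E'E)^-1`` where ``E`` are current residuals.

Draws are reproducible bit-for-bit given (data, prior, config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DESIGN_COLUMNS",
    "AnalysisRow",
    "PriorSpec",
    "MCMCConfig",
    "ModelData",
    "PosteriorDraws",
    "SingularDesignError",
    "build_design",
    "gibbs_sample",
    "summarize_posterior",
    "rows_to_frame",
    "rows_from_frame",
]

DESIGN_COLUMNS = (
    "intercept",
    "aht",
    "ulcer_duration",
    "ulcer_number",
    "ulcer_depth",
    "ulcer_pain",
    "treatment",
)

#: Index of the treatment coefficient within each equation's 7-vector.
TREATMENT_IDX = 6

ULCER_NUMBER_CAP = 4


class SingularDesignError(ValueError):
    """The design matrix is rank deficient (collinear covariates)."""


@dataclass(frozen=True)
class AnalysisRow:
    """One patient's covariates plus annual cost (reference-year euros) and SPID."""

    patient_id: str
    treatment: int
    aht: int
    ulcer_duration: float
    ulcer_number: int
    ulcer_depth: int
    ulcer_pain: float
    annual_cost: float
    spid: float

    def __post_init__(self) -> None:
        if self.annual_cost <= 0:
            raise ValueError(
                f"annual_cost must be > 0 (log is taken); patient {self.patient_id} "
                f"has {self.annual_cost}"
            )


@dataclass
class PriorSpec:
    """Conditionally conjugate prior: diffuse normal coefficients, Wishart precision."""

    coef_prior_variance: float = 1e5  # scalar v in N(0, v I7) per equation
    wishart_df: float = 2.0
    wishart_scale: np.ndarray = field(default_factory=lambda: np.eye(2))

    def __post_init__(self) -> None:
        if self.coef_prior_variance <= 0:
            raise ValueError("coef_prior_variance must be > 0")
        if self.wishart_df < 2:
            raise ValueError("wishart_df must be >= 2 (matrix dimension)")
        self.wishart_scale = np.asarray(self.wishart_scale, float)
        if self.wishart_scale.shape != (2, 2):
            raise ValueError("wishart_scale must be 2x2")


@dataclass
class MCMCConfig:
    burn_in: int = 10_000
    kept_iterations: int = 100_000
    seed: int = 0
    thinning: int = 1
    chains: int = 1

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.kept_iterations < 1:
            raise ValueError("burn_in must be >= 0 and kept_iterations >= 1")
        if self.thinning < 1 or self.chains < 1:
            raise ValueError("thinning and chains must be >= 1")


@dataclass
class ModelData:
    """Design matrix and paired responses for the bivariate regression."""

    X: np.ndarray  # n x 7
    Y: np.ndarray  # n x 2; col 0 = log cost, col 1 = SPID
    patient_ids: list[str]
    columns: tuple[str, ...] = DESIGN_COLUMNS


@dataclass
class PosteriorDraws:
    """Retained MCMC draws: both coefficient vectors and the error covariance."""

    beta_cost: np.ndarray  # m x 7
    beta_eff: np.ndarray   # m x 7
    sigma: np.ndarray      # m x 2 x 2 (error covariance, inverse of precision draws)
    columns: tuple[str, ...] = DESIGN_COLUMNS

    @property
    def n_draws(self) -> int:
        return self.beta_cost.shape[0]

    @property
    def treatment_cost(self) -> np.ndarray:
        """Per-draw treatment coefficient of the cost equation (beta_17)."""
        return self.beta_cost[:, TREATMENT_IDX]

    @property
    def treatment_eff(self) -> np.ndarray:
        """Per-draw treatment coefficient of the effectiveness equation (beta_27)."""
        return self.beta_eff[:, TREATMENT_IDX]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"cost_{c}": self.beta_cost[:, i] for i, c in enumerate(self.columns)}
        cols.update({f"eff_{c}": self.beta_eff[:, i] for i, c in enumerate(self.columns)})
        cols["sigma_11"] = self.sigma[:, 0, 0]
        cols["sigma_12"] = self.sigma[:, 0, 1]
        cols["sigma_22"] = self.sigma[:, 1, 1]
        return pd.DataFrame(cols)


def build_design(rows: Sequence[AnalysisRow]) -> ModelData:
    """Stack analysis rows into the model's design matrix and response pair.

    Responses: column 0 is the natural log of annual cost, column 1 the
    untransformed SPID.  ``ulcer_number`` enters truncated at 4.
    """
    if not rows:
        raise ValueError("no analysis rows")
    for r in rows:
        if r.annual_cost <= 0:
            raise ValueError(f"non-positive annual cost for patient {r.patient_id}")
    X = np.array(
        [
            [
                1.0,
                r.aht,
                r.ulcer_duration,
                min(r.ulcer_number, ULCER_NUMBER_CAP),
                r.ulcer_depth,
                r.ulcer_pain,
                r.treatment,
            ]
            for r in rows
        ],
        dtype=float,
    )
    Y = np.array([[np.log(r.annual_cost), r.spid] for r in rows], dtype=float)
    return ModelData(X=X, Y=Y, patient_ids=[r.patient_id for r in rows])


def _check_full_rank(X: np.ndarray, columns: Sequence[str]) -> None:
    # Name near-degenerate columns via the R factor of a pivoted-free QR.
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = [columns[i] for i in range(len(diag)) if diag[i] <= tol]
    if bad:
        raise SingularDesignError(
            "design matrix is singular; offending column(s): " + ", ".join(bad)
        )


def _wishart_draw(df: float, scale_chol: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """2x2 Wishart draw via the Bartlett decomposition."""
    a11 = np.sqrt(rng.chisquare(df))
    a22 = np.sqrt(rng.chisquare(df - 1.0))
    a21 = rng.standard_normal()
    A = np.array([[a11, 0.0], [a21, a22]])
    LA = scale_chol @ A
    return LA @ LA.T


def _inv2(M: np.ndarray) -> np.ndarray:
    det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
    return np.array([[M[1, 1], -M[0, 1]], [-M[1, 0], M[0, 0]]]) / det


def _run_chain(
    X: np.ndarray,
    Y: np.ndarray,
    prior: PriorSpec,
    burn_in: int,
    kept: int,
    thinning: int,
    rng: np.random.Generator,
    fixed_precision: Optional[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    # The coefficient block's full-conditional precision is
    # Omega (x) X'X + c I.  With X'X = Q diag(lam) Q' fixed and
    # Omega = U diag(d) U' per iteration, this equals
    # (U (x) Q) diag(d_j lam_i + c) (U (x) Q)', so solving and sampling
    # reduce to p x 2 matrix products -- no 2p x 2p factorization per sweep.
    n, p = X.shape
    XtX = X.T @ X
    XtY = X.T @ Y
    prior_prec = 1.0 / prior.coef_prior_variance
    scale0_inv = _inv2(prior.wishart_scale)
    df_post = prior.wishart_df + n
    lam, Q = np.linalg.eigh(XtX)
    Qt = Q.T

    B = np.linalg.lstsq(X, Y, rcond=None)[0]  # p x 2 start at OLS
    n_out = (kept + thinning - 1) // thinning
    betas = np.empty((n_out, 2 * p))
    omegas = np.empty((n_out, 2, 2))
    out = 0
    for it in range(burn_in + kept):
        if fixed_precision is None:
            E = Y - X @ B
            S = _inv2(scale0_inv + E.T @ E)
            # S is SPD; 2x2 Cholesky in closed form
            l11 = np.sqrt(S[0, 0])
            l21 = S[1, 0] / l11
            l22 = np.sqrt(S[1, 1] - l21 * l21)
            S_chol = np.array([[l11, 0.0], [l21, l22]])
            Omega = _wishart_draw(df_post, S_chol, rng)
        else:
            Omega = fixed_precision
        d, U = np.linalg.eigh(Omega)
        denom = lam[:, None] * d[None, :] + prior_prec  # p x 2 spectrum of P
        G = Qt @ (XtY @ Omega) @ U  # rotated linear term
        Z = rng.standard_normal((p, 2))
        B = Q @ ((G / denom) + Z / np.sqrt(denom)) @ U.T
        k = it - burn_in
        if k >= 0 and k % thinning == 0:
            betas[out] = B.ravel(order="F")
            omegas[out] = Omega
            out += 1
    return betas[:out], omegas[:out]


def gibbs_sample(
    model_data: ModelData,
    prior: Optional[PriorSpec] = None,
    config: Optional[MCMCConfig] = None,
    fixed_precision: Optional[np.ndarray] = None,
) -> PosteriorDraws:
    """Run the two-block Gibbs sampler and return retained draws.

    ``fixed_precision`` freezes the error precision at a known matrix
    (skipping its update); used to validate the coefficient block against
    the known-variance conjugate closed form.
    """
    prior = prior or PriorSpec()
    config = config or MCMCConfig()
    X, Y = model_data.X, model_data.Y
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than covariates ({p})")
    _check_full_rank(X, model_data.columns)

    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    all_betas, all_omegas = [], []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        betas, omegas = _run_chain(
            X, Y, prior, config.burn_in, config.kept_iterations, config.thinning,
            rng, fixed_precision,
        )
        all_betas.append(betas)
        all_omegas.append(omegas)
    betas = np.concatenate(all_betas)
    omegas = np.concatenate(all_omegas)

    # invert the 2x2 precision draws vectorized
    det = omegas[:, 0, 0] * omegas[:, 1, 1] - omegas[:, 0, 1] * omegas[:, 1, 0]
    sigma = np.empty_like(omegas)
    sigma[:, 0, 0] = omegas[:, 1, 1] / det
    sigma[:, 1, 1] = omegas[:, 0, 0] / det
    sigma[:, 0, 1] = -omegas[:, 0, 1] / det
    sigma[:, 1, 0] = -omegas[:, 1, 0] / det

    return PosteriorDraws(
        beta_cost=betas[:, :p].copy(),
        beta_eff=betas[:, p:].copy(),
        sigma=sigma,
        columns=model_data.columns,
    )


def summarize_posterior(draws: PosteriorDraws, credible_level: float = 0.95) -> pd.DataFrame:
    """Posterior summary table: mean, SD, equal-tailed credible interval.

    Rows cover both equations' coefficients, the costs ratio
    ``exp(treatment coefficient of the cost equation)`` and the error
    covariance entries.
    """
    if draws.n_draws < 2:
        raise ValueError("need at least 2 draws to summarize")
    lo = 100 * (1 - credible_level) / 2
    hi = 100 - lo
    rows = []

    def add(name: str, samples: np.ndarray) -> None:
        rows.append(
            {
                "parameter": name,
                "mean": float(np.mean(samples)),
                "sd": float(np.std(samples, ddof=1)),
                "lower": float(np.percentile(samples, lo)),
                "upper": float(np.percentile(samples, hi)),
            }
        )

    for i, c in enumerate(draws.columns):
        add(f"cost_{c}", draws.beta_cost[:, i])
    add("cost_ratio", np.exp(draws.treatment_cost))
    for i, c in enumerate(draws.columns):
        add(f"eff_{c}", draws.beta_eff[:, i])
    add("sigma_11", draws.sigma[:, 0, 0])
    add("sigma_12", draws.sigma[:, 0, 1])
    add("sigma_22", draws.sigma[:, 1, 1])
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# row (de)serialization

_ROW_COLUMNS = (
    "patient_id", "treatment", "aht", "ulcer_duration", "ulcer_number",
    "ulcer_depth", "ulcer_pain", "annual_cost", "spid",
)


def rows_to_frame(rows: Sequence[AnalysisRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows], columns=list(_ROW_COLUMNS))


def rows_from_frame(frame: pd.DataFrame) -> list[AnalysisRow]:
    missing = [c for c in _ROW_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"analysis-row table missing column(s): {', '.join(missing)}")
    return [
        AnalysisRow(
            patient_id=str(r["patient_id"]),
            treatment=int(r["treatment"]),
            aht=int(r["aht"]),
            ulcer_duration=float(r["ulcer_duration"]),
            ulcer_number=int(r["ulcer_number"]),
            ulcer_depth=int(r["ulcer_depth"]),
            ulcer_pain=float(r["ulcer_pain"]),
            annual_cost=float(r["annual_cost"]),
            spid=float(r["spid"]),
        )
        for r in frame.to_dict("records")
    ]
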