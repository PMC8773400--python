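"""Grouped-binomial logistic trend models for daily reciprocity.

The daily reciprocity proportions of the two data sources (card network,
days 2-6; interview network, days 1-7) are modelled jointly as grouped
binomial observations

    logit(r) ~ dataset [+ day + day^2 [+ dataset x day + dataset x day^2]]

with trials equal to the daily directed-edge counts.  Nested fits are
compared by likelihood-ratio (deviance-difference) tests, and the dataset
effect is summarised as an odds ratio with a Wald interval.

The published day/day^2 coefficients are only determined up to the basis
chosen for the day polynomial, so the module exposes both a raw-power and
an orthonormal basis and the tests assert only basis-invariant quantities
(deviances, G^2, the dataset coefficient).  Fits go through statsmodels'
binomial GLM (IRLS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

Z_95 = 1.959963984540054


class ModelError(ValueError):
    pass


def build_model_matrix(
    observations: pd.DataFrame,
    degree: int = 2,
    interaction: bool = False,
    basis: str = "raw",
) -> pd.DataFrame:
    """Design matrix for the reciprocity trend models.

    Columns: intercept, dataset dummy (card = 1), ``degree`` polynomial
    terms in day, and optionally their interactions with the dummy.  With
    ``basis="orthonormal"`` the day terms are Gram-Schmidt orthonormalised
    (against the intercept and each other) over the observed rows; the
    column space is identical to the raw basis.
    """
    if degree not in (1, 2):
        raise ModelError("degree must be 1 or 2")
    if interaction and degree != 2:
        raise ModelError("interaction models require degree 2")
    if basis not in ("raw", "orthonormal"):
        raise ModelError(f"unknown basis {basis!r}")
    day = observations["day"].to_numpy(dtype=float)
    if np.ptp(day) == 0:
        raise ModelError("day values are constant; polynomial design is rank-deficient")
    ds = (observations["dataset"] == "card").to_numpy(dtype=float)

    powers = np.column_stack([day**p for p in range(1, degree + 1)])
    if basis == "orthonormal":
        q, _ = np.linalg.qr(
            np.column_stack([np.ones_like(day), powers])
        )
        powers = q[:, 1:] * np.sqrt(len(day))  # drop intercept direction
    X = {"intercept": np.ones_like(day), "dataset": ds}
    for p in range(degree):
        X[f"day^{p + 1}"] = powers[:, p]
    if interaction:
        for p in range(degree):
            X[f"dataset:day^{p + 1}"] = ds * powers[:, p]
    return pd.DataFrame(X, index=observations.index)


@dataclass(frozen=True)
class FittedModel:
    """A fitted grouped-binomial logistic model."""

    params: pd.Series
    bse: pd.Series
    deviance: float
    df_resid: int
    log_likelihood: float
    basis: str
    n_obs: int
    fitted_probs: np.ndarray

    @property
    def n_params(self) -> int:
        return len(self.params)


def fit_grouped_logistic(
    design: pd.DataFrame, observations: pd.DataFrame, basis: str = "raw"
) -> FittedModel:
    """Maximum-likelihood fit of reciprocated/total counts on a design.

    Deviance is measured against the saturated per-row model.  Raises on a
    rank-deficient design or non-convergence.
    """
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ModelError("design matrix is rank-deficient")
    endog = np.column_stack(
        [
            observations["reciprocated"].to_numpy(dtype=float),
            (observations["total"] - observations["reciprocated"]).to_numpy(dtype=float),
        ]
    )
    res = sm.GLM(endog, design, family=sm.families.Binomial()).fit(
        maxiter=100, tol=1e-10
    )
    if not res.converged:
        raise ModelError(f"IRLS did not converge: {res.fit_history}")
    mu = np.asarray(res.fittedvalues)
    if not ((mu > 0) & (mu < 1)).all():
        raise ModelError("fitted probabilities on the boundary (separation?)")
    return FittedModel(
        params=res.params,
        bse=res.bse,
        deviance=float(res.deviance),
        df_resid=int(res.df_resid),
        log_likelihood=float(res.llf),
        basis=basis,
        n_obs=len(observations),
        fitted_probs=mu,
    )


#: Model number -> (degree, interaction) per the nested trend-model suite.
MODEL_SPECS = {1: (1, False), 2: (2, False), 3: (2, True)}


def fit_model(
    observations: pd.DataFrame, model: int, basis: str = "raw"
) -> FittedModel:
    """Fit model 1 (linear), 2 (quadratic) or 3 (quadratic x dataset)."""
    if model not in MODEL_SPECS:
        raise ModelError(f"model must be one of {sorted(MODEL_SPECS)}")
    degree, interaction = MODEL_SPECS[model]
    design = build_model_matrix(observations, degree, interaction, basis)
    return fit_grouped_logistic(design, observations, basis=basis)


@dataclass(frozen=True)
class LikelihoodRatioTest:
    g2: float
    df: int
    p_value: float


def likelihood_ratio_test(
    model_small: FittedModel, model_large: FittedModel
) -> LikelihoodRatioTest:
    """Deviance-difference test of nested grouped-binomial fits."""
    if model_small.n_obs != model_large.n_obs:
        raise ModelError("models fitted on different observations")
    df = model_large.n_params - model_small.n_params
    if df <= 0 or model_small.deviance < model_large.deviance - 1e-8:
        raise ModelError("models are not nested small-within-large")
    g2 = max(model_small.deviance - model_large.deviance, 0.0)
    return LikelihoodRatioTest(
        g2=g2, df=df, p_value=float(scipy.stats.chi2.sf(g2, df)) if df else 1.0
    )


@dataclass(frozen=True)
class OddsRatio:
    odds_ratio: float
    ci_low: float
    ci_high: float
    z: float
    p_value: float


def dataset_odds_ratio(model: FittedModel) -> OddsRatio:
    """Wald summary of the dataset (card vs interview) dummy.

    The dummy is orthogonal to any day-basis change, so the odds ratio is
    basis-invariant.
    """
    if "dataset" not in model.params.index:
        raise ModelError("model has no dataset dummy")
    beta = float(model.params["dataset"])
    se = float(model.bse["dataset"])
    z = beta / se
    return OddsRatio(
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z_95 * se)),
        ci_high=float(np.exp(beta + Z_95 * se)),
        z=z,
        p_value=float(2 * scipy.stats.norm.sf(abs(z))),
    )
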