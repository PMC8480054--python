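"""Posterior-predictive intake quantification from biomarker-only data.

Given a fitted model, the intake of a new observation ``j`` with biomarkers
``y*_j`` is predicted by cycling deterministically through the stored
posterior parameter draws — the fit-once / predict-many workflow.  Each
predictive iteration:

1. takes the next stored draw of (alpha, beta, sigma2, theta2, gating),
2. computes the gating weights ``pi_d(y*_j)``,
3. samples the component ``c*_j`` from its exact marginal
   ``P(c* = d | y*) ∝ pi_d(y*) ∫ TN(z; x_d, theta_d^2) N(y* | z) dz``
   (the intake is integrated out analytically),
4. samples ``z*_j`` from its truncated-normal full conditional given
   ``c*_j``.

Collapsing the intake out of the label draw makes each iteration an exact,
independent draw from that parameter sample's predictive — a plain
conditional label draw given the previous ``z*`` is metastable when the
dose components are well separated, because switching modes would require a
many-sigma excursion of ``z*``.  Integrating over the stored parameter
draws is what lets the predictive distribution be multi-modal when the
biomarkers are consistent with more than one dose component.  The
prediction burn-in simply discards the first parameter draws consumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import log_ndtr

from .gating import GatingParameters, gating_probs_matrix
from .model_core import (BiomarkerOnlyData, MeasurementParams,
                         sample_truncated_normal)
from .sampler import FittedModel, _categorical_rows, summarize_chain

__all__ = ["PredictionResult", "predict_intakes",
           "predictive_distribution_export"]


@dataclass
class PredictionResult:
    """Posterior-predictive intake draws and per-observation summaries.

    ``draws`` has shape (retained iterations, n*); ``summaries`` holds the
    posterior-predictive median, SD and equal-tailed 95% credible interval
    for each observation.
    """

    draws: np.ndarray
    summaries: pd.DataFrame
    meta: dict

    @property
    def n_obs(self) -> int:
        return self.draws.shape[1]


def _gating_from_draw(model: FittedModel, idx: int) -> GatingParameters:
    return GatingParameters(
        thresholds=model.chains["zeta"][idx],
        coefficients=model.chains["w"][idx],
        center=np.asarray(model.meta["gating_center"], dtype=float),
        scale=np.asarray(model.meta["gating_scale"], dtype=float),
        link=model.meta.get("gating_link", "cauchit"),
    )


def _collapsed_component_weights(Y: np.ndarray, params: MeasurementParams,
                                 x: np.ndarray, theta2: np.ndarray):
    """Log marginal weight of each component with the intake integrated out.

    For component ``d``, ``∫_0^∞ TN(z; x_d, θ_d²) Π_p N(y_p; α_p + β_p z,
    σ_p²) dz`` has a closed form: completing the square in ``z`` leaves a
    Gaussian normalizer times the positive-half-line mass ``Φ(m_d √A_d)``.
    Per-observation constants common to all components are dropped.

    Returns ``(log_w, m, v)``: the (n, D) log weights, the (n, D)
    conditional means and the (D,) conditional variances of ``z`` given
    each component.
    """
    L = float(np.sum(params.beta ** 2 / params.sigma2))
    M = (Y - params.alpha) @ (params.beta / params.sigma2)      # (n,)
    A = L + 1.0 / theta2                                        # (D,)
    m = (M[:, None] + (x / theta2)[None, :]) / A[None, :]       # (n, D)
    log_w = (-log_ndtr(x / np.sqrt(theta2))
             - 0.5 * np.log(theta2) - 0.5 * x ** 2 / theta2
             - 0.5 * np.log(A))[None, :] \
        + 0.5 * A[None, :] * m ** 2 \
        + log_ndtr(m * np.sqrt(A)[None, :])
    return log_w, m, 1.0 / A


def predict_intakes(model: FittedModel, newdata: BiomarkerOnlyData,
                    niter: int = 2000, burnin: int = 500,
                    seed: Optional[int] = None) -> PredictionResult:
    """Predict latent intakes for biomarker-only observations.

    Parameters
    ----------
    model
        A previously fitted model (its retained chains drive prediction).
    newdata
        ``n* x P`` biomarker matrix with columns matching — and ordered as —
        the biomarkers the model was trained on.
    niter, burnin
        Predictive iterations and warm-up discards (``0 <= burnin < niter``).
    seed
        Seed for the predictive randomness; prediction is reproducible given
        (model, data, seed).
    """
    if not isinstance(newdata, BiomarkerOnlyData):
        newdata = BiomarkerOnlyData(np.asarray(newdata, dtype=float))
    if newdata.P != model.P:
        raise ValueError(
            f"newdata has {newdata.P} biomarker columns but the model was "
            f"fitted with P={model.P}; columns must match the training "
            "biomarkers in the same order")
    if model.n_draws == 0:
        raise ValueError("model has no retained chains to predict from")
    if not (0 <= burnin < niter):
        raise ValueError(f"require 0 <= burnin < niter, got burnin={burnin}, "
                         f"niter={niter}")
    rng = np.random.default_rng(seed)
    n_star = newdata.n
    S = model.n_draws
    x = model.dose_levels
    Y = newdata.biomarkers
    n_keep = niter - burnin
    draws = np.empty((n_keep, n_star))
    meta = {"niter": niter, "burnin": burnin, "seed": seed,
            "source_n_draws": S, "unit": model.meta.get("unit"),
            "dose_levels": x.tolist()}
    if n_star == 0:
        return PredictionResult(draws=draws,
                                summaries=_summaries_frame(draws, meta), meta=meta)

    for t in range(niter):
        idx = t % S
        params = MeasurementParams(model.chains["alpha"][idx],
                                   model.chains["beta"][idx],
                                   model.chains["sigma2"][idx])
        theta2 = model.chains["theta2"][idx]
        gating = _gating_from_draw(model, idx)
        log_pi = np.log(gating_probs_matrix(Y, gating, model.D))
        log_w, m, v = _collapsed_component_weights(Y, params, x, theta2)
        c = _categorical_rows(log_pi + log_w, rng)
        rows = np.arange(n_star)
        z = np.atleast_1d(sample_truncated_normal(m[rows, c],
                                                  np.sqrt(v[c]), rng))
        if t >= burnin:
            draws[t - burnin] = z
    return PredictionResult(draws=draws,
                            summaries=_summaries_frame(draws, meta), meta=meta)


def _summaries_frame(draws: np.ndarray, meta: dict) -> pd.DataFrame:
    rows = []
    for j in range(draws.shape[1]):
        med, sd, lo, hi = summarize_chain(draws[:, j])
        rows.append({"observation": j + 1, "median": med, "sd": sd,
                     "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows, columns=["observation", "median", "sd",
                                       "ci_low", "ci_high"])


def predictive_distribution_export(result: PredictionResult, observation: int):
    """Full predictive draw vector for one observation, with median and CI.

    The raw draws support histogramming of multi-modal predictive shapes;
    ``observation`` is a 0-based index into the prediction set.
    """
    if not 0 <= observation < result.n_obs:
        raise IndexError(f"observation index {observation} out of range "
                         f"(0..{result.n_obs - 1})")
    vec = result.draws[:, observation].copy()
    med, _, lo, hi = summarize_chain(vec)
    return vec, med, (lo, hi)
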