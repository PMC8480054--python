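"""MCMC estimation of the latent-intake model from intervention-study data.

The posterior is explored by a Gibbs sampler with conjugate full conditionals
for every block except two places where exactness requires extra care:

* the slope ``beta_p`` has a zero-truncated Gaussian prior, so the
  measurement block samples ``beta_p`` from its truncated marginal and then
  ``alpha_p`` from the exact Gaussian conditional given ``beta_p``;
* the component variance ``theta_d^2`` loses conjugacy through the
  zero-truncation normalizer ``Phi(x_d/theta_d)`` of its mixture component,
  so the inverse-gamma draw is used as an independence proposal and corrected
  by a Metropolis accept/reject step against the exact truncated-normal
  likelihood.  The correction is negligible whenever ``x_d >> theta_d``.

The gating model is updated by periodic penalized re-fit on the current
component labels (a modularized, "cut" update) rather than a full Bayesian
gating posterior; see :mod:`intakequant.gating`.

One sweep is: allocate labels -> (every ``gating_refit_every`` sweeps) refit
gating -> draw latent intakes -> draw measurement parameters -> draw
component variances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import log_ndtr

from .gating import GatingParameters, fit_gating, gating_probs_matrix, standardize_design
from .model_core import (ComponentParams, Hyperparameters, InterventionData,
                         MeasurementParams, sample_truncated_normal)

__all__ = ["ModelState", "FittedModel", "default_hyperparameters",
           "update_labels", "update_intakes", "update_measurement",
           "update_component_variances", "intake_conditional", "fit",
           "summarize_chain", "build_summary_table"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class ModelState:
    """One MCMC state: parameters, latent intakes and component labels."""

    params: MeasurementParams
    comp: ComponentParams
    gating: GatingParameters
    z: np.ndarray          # (n,), strictly positive latent intakes
    c: np.ndarray          # (n,), 0-based component labels

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.c = np.asarray(self.c, dtype=int)
        if np.any(self.z <= 0):
            raise ValueError("latent intakes must be strictly positive")
        if self.z.shape != self.c.shape:
            raise ValueError("z and c must have equal length")


@dataclass
class FittedModel:
    """Retained post-burn-in chains, posterior summaries and metadata.

    ``chains`` maps names (``alpha``, ``beta``, ``sigma2``, ``theta2``,
    ``zeta``, ``w``, ``z``) to arrays whose first axis indexes retained
    iterations.  ``summaries`` is a tidy table with one row per scalar
    quantity (posterior median, SD, equal-tailed 95% credible interval).
    """

    chains: dict
    summaries: pd.DataFrame
    meta: dict
    gating_template: GatingParameters = field(repr=False, default=None)

    @property
    def n_draws(self) -> int:
        return self.chains["alpha"].shape[0]

    @property
    def P(self) -> int:
        return self.chains["alpha"].shape[1]

    @property
    def D(self) -> int:
        return self.chains["theta2"].shape[1]

    @property
    def dose_levels(self) -> np.ndarray:
        return np.asarray(self.meta["dose_levels"], dtype=float)


def _per_biomarker_ols(x: np.ndarray, Y: np.ndarray):
    """Least-squares fit of each biomarker column on the regressor ``x``.

    Returns (intercepts, slopes, residual variances); a degenerate regressor
    (zero variance) yields zero slopes with a unit variance floor.
    """
    xm = x.mean()
    vx = float(np.var(x))
    ym = Y.mean(axis=0)
    if vx == 0.0:
        vx = 1.0
        slopes = np.zeros(Y.shape[1])
    else:
        slopes = ((x - xm) @ (Y - ym)) / (vx * x.shape[0])
    intercepts = ym - slopes * xm
    resid = Y - intercepts - np.outer(x, slopes)
    resid_var = np.mean(resid ** 2, axis=0)
    return intercepts, slopes, resid_var


def default_hyperparameters(data: InterventionData) -> Hyperparameters:
    """Data-driven prior defaults.

    Each biomarker is regressed on the assigned dose by least squares; the
    fitted intercept/slope become the prior means of ``alpha_p`` and
    ``beta_p`` (slope floored at a small positive value to respect the
    positivity constraint), with prior variances ten times the residual
    variance (floored at 1).  ``sigma_p^2 ~ IG(2, residual variance)`` and
    ``theta_d^2 ~ IG(2, (x_d/D)^2)``, centering each component's scale on a
    spread proportional to its dose.
    """
    a, b, rv = _per_biomarker_ols(data.quantities, data.biomarkers)
    prior_var = np.maximum(10.0 * rv, 1.0)
    return Hyperparameters(
        alpha_mean=a,
        alpha_var=prior_var,
        beta_mean=np.maximum(b, 1e-6),
        beta_var=prior_var,
        sigma2_shape=2.0,
        sigma2_scale=np.maximum(rv, 1e-8),
        theta2_shape=2.0,
        theta2_scale=(data.dose_levels / data.D) ** 2,
    )


def _log_tn_matrix(z: np.ndarray, dose_levels: np.ndarray,
                   theta2: np.ndarray) -> np.ndarray:
    """(n, D) matrix of log TN_(0,inf)(z_i; x_d, theta_d^2)."""
    sd = np.sqrt(theta2)
    u = (z[:, None] - dose_levels[None, :]) / sd[None, :]
    return (-0.5 * (_LOG_2PI + u ** 2) - np.log(sd)[None, :]
            - log_ndtr(dose_levels / sd)[None, :])


def _categorical_rows(logp: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per row from unnormalized log-probabilities."""
    logp = logp - logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(p.shape[0])
    return (p.cumsum(axis=1) < u[:, None]).sum(axis=1)


def update_labels(state: ModelState, data: InterventionData,
                  rng: np.random.Generator,
                  log_pi: Optional[np.ndarray] = None) -> np.ndarray:
    """Sample component labels: ``c_i ~ pi_d(y_i) TN(z_i; x_d, theta_d^2)``.

    Normalization is exact, carried out in log space to survive underflow.
    ``log_pi`` caches the (n, D) log gating probabilities; it is recomputed
    from the state's gating parameters when omitted.
    """
    if log_pi is None:
        log_pi = np.log(gating_probs_matrix(data.biomarkers, state.gating, data.D))
    logp = log_pi + _log_tn_matrix(state.z, data.dose_levels, state.comp.theta2)
    return _categorical_rows(logp, rng)


def intake_conditional(y: np.ndarray, params: MeasurementParams,
                       x_c: np.ndarray, theta2_c: np.ndarray):
    """Mean and variance of the Gaussian kernel of ``z``'s full conditional.

    With precision ``1/v = sum_p beta_p^2/sigma_p^2 + 1/theta_c^2`` and mean
    ``m = v (sum_p beta_p (y_p - alpha_p)/sigma_p^2 + x_c/theta_c^2)``; the
    draw itself is this normal truncated to the positive half-line.
    Vectorized over observations (rows of ``y``).
    """
    y = np.atleast_2d(y)
    prec = np.sum(params.beta ** 2 / params.sigma2) + 1.0 / theta2_c
    v = 1.0 / prec
    m = v * ((y - params.alpha) @ (params.beta / params.sigma2) + x_c / theta2_c)
    return m, v


def update_intakes(state: ModelState, data: InterventionData,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw latent intakes from their truncated-normal full conditional."""
    x_c = data.dose_levels[state.c]
    theta2_c = state.comp.theta2[state.c]
    m, v = intake_conditional(data.biomarkers, state.params, x_c, theta2_c)
    return sample_truncated_normal(m, np.sqrt(v), rng)


def update_measurement(state: ModelState, data: InterventionData,
                       hyper: Hyperparameters, rng: np.random.Generator
                       ) -> MeasurementParams:
    """Draw (alpha_p, beta_p, sigma_p^2) for every biomarker.

    (alpha, beta) follow the bivariate normal conditional of the regression
    of ``y_p`` on ``z`` under the stated priors; ``beta`` is sampled from its
    truncated marginal first, then ``alpha`` conditionally — exact under the
    positivity constraint.  ``sigma_p^2`` is conjugate inverse-gamma.
    """
    z = state.z
    n = z.shape[0]
    Y = data.biomarkers
    P = Y.shape[1]
    sz = z.sum()
    szz = float(z @ z)
    alpha = np.empty(P)
    beta = np.empty(P)
    sigma2 = np.empty(P)
    for p in range(P):
        s2 = state.params.sigma2[p]
        yp = Y[:, p]
        # posterior precision A and linear term b for (alpha, beta)
        A = np.array([[n / s2 + 1.0 / hyper.alpha_var[p], sz / s2],
                      [sz / s2, szz / s2 + 1.0 / hyper.beta_var[p]]])
        bvec = np.array([yp.sum() / s2 + hyper.alpha_mean[p] / hyper.alpha_var[p],
                         float(yp @ z) / s2 + hyper.beta_mean[p] / hyper.beta_var[p]])
        cov = np.linalg.inv(A)
        mu = cov @ bvec
        beta[p] = sample_truncated_normal(mu[1], np.sqrt(cov[1, 1]), rng)
        cm = mu[0] + cov[0, 1] / cov[1, 1] * (beta[p] - mu[1])
        cv = cov[0, 0] - cov[0, 1] ** 2 / cov[1, 1]
        alpha[p] = rng.normal(cm, np.sqrt(max(cv, 0.0)))
        ssr = float(np.sum((yp - alpha[p] - beta[p] * z) ** 2))
        shape = hyper.sigma2_shape + 0.5 * n
        scale = hyper.sigma2_scale[p] + 0.5 * ssr
        sigma2[p] = scale / rng.gamma(shape)
    return MeasurementParams(alpha, beta, sigma2)


def update_component_variances(state: ModelState, data: InterventionData,
                               hyper: Hyperparameters, rng: np.random.Generator
                               ) -> ComponentParams:
    """Draw ``theta_d^2`` via conjugate proposal + Metropolis correction.

    The inverse-gamma ``IG(shape + n_d/2, scale_d + SS_d/2)`` draw matches
    the Gaussian part of the truncated-normal likelihood exactly; the
    remaining factor ``Phi(x_d/theta_d)^{-n_d}`` enters through an
    independence Metropolis acceptance ratio.  Empty components draw from
    the prior.
    """
    theta2 = state.comp.theta2.copy()
    x = data.dose_levels
    for d in range(x.shape[0]):
        mask = state.c == d
        n_d = int(mask.sum())
        if n_d == 0:
            theta2[d] = hyper.theta2_scale[d] / rng.gamma(hyper.theta2_shape)
            continue
        ss = float(np.sum((state.z[mask] - x[d]) ** 2))
        shape = hyper.theta2_shape + 0.5 * n_d
        scale = hyper.theta2_scale[d] + 0.5 * ss
        proposal = scale / rng.gamma(shape)
        log_accept = n_d * (log_ndtr(x[d] / np.sqrt(theta2[d]))
                            - log_ndtr(x[d] / np.sqrt(proposal)))
        if np.log(rng.random()) < log_accept:
            theta2[d] = proposal
    return ComponentParams(theta2)


def summarize_chain(draws):
    """Posterior median, SD and equal-tailed 95% credible interval."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("cannot summarize an empty chain")
    lo, hi = np.quantile(draws, [0.025, 0.975])
    sd = float(np.std(draws, ddof=1)) if draws.size > 1 else 0.0
    return float(np.median(draws)), sd, float(lo), float(hi)


def build_summary_table(chains: dict, meta: dict) -> pd.DataFrame:
    """Tidy per-scalar summary table from retained chains."""
    rows = []
    P = chains["alpha"].shape[1]
    D = chains["theta2"].shape[1]

    def add(name, draws):
        med, sd, lo, hi = summarize_chain(draws)
        rows.append({"parameter": name, "median": med, "sd": sd,
                     "ci_low": lo, "ci_high": hi})

    for p in range(P):
        add(f"alpha_{p + 1}", chains["alpha"][:, p])
    for p in range(P):
        add(f"beta_{p + 1}", chains["beta"][:, p])
    for p in range(P):
        add(f"sigma_{p + 1}", np.sqrt(chains["sigma2"][:, p]))
    for d in range(D):
        add(f"theta_{d + 1}", np.sqrt(chains["theta2"][:, d]))
    for k in range(chains["zeta"].shape[1]):
        add(f"zeta_{k + 1}", chains["zeta"][:, k])
    for p in range(P):
        add(f"w_{p + 1}", chains["w"][:, p])
    if "z" in chains:
        for i in range(chains["z"].shape[1]):
            add(f"z_{i + 1}", chains["z"][:, i])
    return pd.DataFrame(rows, columns=["parameter", "median", "sd",
                                       "ci_low", "ci_high"])


def fit(data: InterventionData, niter: int = 5000, burnin: int = 1500,
        hyper: Optional[Hyperparameters] = None, gating_refit_every: int = 10,
        seed: Optional[int] = None, thin: int = 1,
        unit: Optional[str] = None, progress: bool = False) -> FittedModel:
    """Fit the full model by MCMC and return retained chains + summaries.

    Parameters
    ----------
    data
        Intervention-study data (doses + biomarkers).
    niter, burnin
        Total MCMC sweeps and the number discarded before summarizing
        (``0 <= burnin < niter``).
    hyper
        Prior hyperparameters; data-driven defaults when omitted.
    gating_refit_every
        Refit the gating model on current labels every this many sweeps
        (0 disables refitting; the initial fit is kept throughout).
    seed
        Seed for the random generator; fixing it makes the fit fully
        reproducible.
    thin
        Keep every ``thin``-th post-burn-in draw (1 = keep all).

    Initialization is deterministic: intakes at the assigned dose, labels at
    the dose index, measurement parameters from per-biomarker least squares
    on the dose, gating from a penalized fit on the initial labels.
    """
    if not isinstance(data, InterventionData):
        raise TypeError("data must be an InterventionData instance")
    if not (0 <= burnin < niter):
        raise ValueError(f"require 0 <= burnin < niter, got burnin={burnin}, "
                         f"niter={niter}")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    if hyper is None:
        hyper = default_hyperparameters(data)
    rng = np.random.default_rng(seed)
    n, P, D = data.n, data.P, data.D
    x = data.dose_levels

    a0, b0, rv0 = _per_biomarker_ols(data.quantities, data.biomarkers)
    params = MeasurementParams(a0, np.maximum(b0, 1e-6), np.maximum(rv0, 1e-8))
    comp = ComponentParams(hyper.theta2_scale.copy())
    c = data.dose_index.copy()
    z = data.quantities.astype(float).copy()
    standardization = standardize_design(data.biomarkers)
    gating = fit_gating(data.biomarkers, c, hyper.gating_penalty, D,
                        standardization=standardization)
    log_pi = np.log(gating_probs_matrix(data.biomarkers, gating, D))
    state = ModelState(params, comp, gating, z, c)

    n_keep = (niter - burnin + thin - 1) // thin
    if n_keep < 100:
        warnings.warn(f"only {n_keep} retained draws; posterior summaries "
                      "will be noisy", UserWarning, stacklevel=2)
    chains = {
        "alpha": np.empty((n_keep, P)), "beta": np.empty((n_keep, P)),
        "sigma2": np.empty((n_keep, P)), "theta2": np.empty((n_keep, D)),
        "zeta": np.empty((n_keep, max(D - 1, 0))), "w": np.empty((n_keep, P)),
        "z": np.empty((n_keep, n)),
    }
    kept = 0
    for t in range(1, niter + 1):
        state.c = update_labels(state, data, rng, log_pi)
        if gating_refit_every and t % gating_refit_every == 0:
            state.gating = fit_gating(data.biomarkers, state.c,
                                      hyper.gating_penalty, D,
                                      standardization=standardization)
            log_pi = np.log(gating_probs_matrix(data.biomarkers, state.gating, D))
        state.z = update_intakes(state, data, rng)
        state.params = update_measurement(state, data, hyper, rng)
        state.comp = update_component_variances(state, data, hyper, rng)
        if t > burnin and (t - burnin - 1) % thin == 0:
            chains["alpha"][kept] = state.params.alpha
            chains["beta"][kept] = state.params.beta
            chains["sigma2"][kept] = state.params.sigma2
            chains["theta2"][kept] = state.comp.theta2
            chains["zeta"][kept] = state.gating.thresholds
            chains["w"][kept] = state.gating.coefficients
            chains["z"][kept] = state.z
            kept += 1
        if progress and (t % max(niter // 10, 1) == 0):
            print(f"  sweep {t}/{niter}")
    assert kept == n_keep

    meta = {
        "dose_levels": x.tolist(), "n": n, "P": P, "D": D,
        "niter": niter, "burnin": burnin, "thin": thin,
        "seed": seed, "unit": unit or data.unit,
        "gating_center": standardization[0].tolist(),
        "gating_scale": standardization[1].tolist(),
        "gating_penalty": hyper.gating_penalty,
        "gating_link": gating.link,
    }
    summaries = build_summary_table(chains, meta)
    return FittedModel(chains=chains, summaries=summaries, meta=meta,
                       gating_template=state.gating)
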