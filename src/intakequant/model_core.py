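"""Core domain types and probability primitives for the latent-intake model.

The measurement model links ``P`` biomarker measurements to an unobserved,
continuous food intake ``z > 0`` through a factor-analytic regression

.. math::

    y_{p} = \\alpha_p + \\beta_p z + \\epsilon_{p}, \\qquad
    \\epsilon_{p} \\sim \\mathcal{N}(0, \\sigma_p^2),

while the latent intake carries a zero-truncated Gaussian-mixture prior whose
``D`` components are anchored at the dose levels administered in an
intervention (feeding) study:

.. math::

    z \\sim \\sum_{d=1}^{D} \\pi_d(\\mathbf{y})\\,
    \\mathcal{N}_{(0,\\infty)}(x_d, \\theta_d^2).

The slope (loading) parameters ``beta_p`` are constrained positive.  This
resolves the reflection non-identifiability inherent to one-factor models and
encodes the working assumption that a validated intake biomarker increases
with the consumed amount.  Biomarkers expected to *decrease* with intake
should be negated before fitting.

Everything downstream (Gibbs sampler, prediction) builds on the three
primitives defined here: the measurement log-likelihood, the mixture prior
log-density, and zero-truncated normal sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr, logsumexp

__all__ = [
    "InterventionData",
    "BiomarkerOnlyData",
    "MeasurementParams",
    "ComponentParams",
    "Hyperparameters",
    "loglik_measurement",
    "log_truncnorm_pdf",
    "log_prior_intake",
    "sample_truncated_normal",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def _as_float_array(x, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        if np.any(np.isnan(arr)):
            raise ValueError(f"{name} contains missing (NaN) values; impute or drop "
                             "them before fitting — the model does not handle missingness")
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class InterventionData:
    """Dose assignments and biomarker measurements from a feeding study.

    Parameters
    ----------
    quantities
        Administered food quantity per observation (length ``n``), in the
        user's unit of measure (grams by default).  Each value must equal one
        of the ``D`` distinct dose levels of the study design.
    biomarkers
        ``n x P`` matrix of biomarker measurements.  Units and biofluid are
        free; columns may be quantitative or relative measurements.

    Attributes
    ----------
    dose_levels
        The ``D`` distinct administered quantities, sorted increasing.
    dose_index
        For each observation, the 0-based index of its dose level.
    """

    quantities: np.ndarray
    biomarkers: np.ndarray
    unit: str = "grams"
    dose_levels: np.ndarray = field(init=False, repr=False)
    dose_index: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.quantities = _as_float_array(self.quantities, "quantities", 1)
        self.biomarkers = np.atleast_2d(_as_float_array(self.biomarkers, "biomarkers", 2))
        n = self.quantities.shape[0]
        if self.biomarkers.shape[0] != n:
            raise ValueError(
                f"biomarkers has {self.biomarkers.shape[0]} rows but quantities "
                f"has length {n}")
        if n == 0:
            raise ValueError("empty dataset")
        self.dose_levels, self.dose_index = np.unique(self.quantities,
                                                      return_inverse=True)
        if np.any(self.dose_levels <= 0):
            raise ValueError("all administered quantities must be strictly positive")
        if self.P < 1:
            raise ValueError("at least one biomarker column is required")
        if self.P == 1:
            warnings.warn(
                "only one biomarker supplied; the model is intended for panels "
                "of two or more biomarkers", UserWarning, stacklevel=2)

    @property
    def n(self) -> int:
        return self.quantities.shape[0]

    @property
    def P(self) -> int:
        return self.biomarkers.shape[1]

    @property
    def D(self) -> int:
        return self.dose_levels.shape[0]


@dataclass
class BiomarkerOnlyData:
    """Biomarker matrix for observations whose intake is to be predicted.

    Columns must match the biomarkers of the intervention study used to fit
    the model, in the same order.
    """

    biomarkers: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.biomarkers, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"biomarkers must be a 2-d matrix, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("biomarkers contain missing or non-finite values")
        self.biomarkers = arr

    @property
    def n(self) -> int:
        return self.biomarkers.shape[0]

    @property
    def P(self) -> int:
        return self.biomarkers.shape[1]


@dataclass
class MeasurementParams:
    """Per-biomarker intercepts ``alpha``, slopes ``beta`` and error
    variances ``sigma2`` of the measurement model."""

    alpha: np.ndarray
    beta: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = _as_float_array(self.alpha, "alpha", 1)
        self.beta = _as_float_array(self.beta, "beta", 1)
        self.sigma2 = _as_float_array(self.sigma2, "sigma2", 1)
        if not (self.alpha.shape == self.beta.shape == self.sigma2.shape):
            raise ValueError("alpha, beta, sigma2 must have equal length")
        if np.any(self.sigma2 <= 0):
            raise ValueError("sigma2 must be strictly positive")
        if np.any(self.beta <= 0):
            raise ValueError("beta must be strictly positive (positivity is the "
                             "model's identifiability constraint)")

    @property
    def P(self) -> int:
        return self.alpha.shape[0]


@dataclass
class ComponentParams:
    """Component variances ``theta2`` of the intake mixture prior, one per
    dose level."""

    theta2: np.ndarray

    def __post_init__(self) -> None:
        self.theta2 = _as_float_array(self.theta2, "theta2", 1)
        if np.any(self.theta2 <= 0):
            raise ValueError("theta2 must be strictly positive")

    @property
    def D(self) -> int:
        return self.theta2.shape[0]


@dataclass
class Hyperparameters:
    """Prior hyperparameters; defaults are data-driven (see
    :func:`intakequant.sampler.default_hyperparameters`) but every field may
    be overridden by the user.

    ``sigma2`` and ``theta2`` carry inverse-gamma ``IG(shape, scale)`` priors;
    ``alpha`` is Gaussian and ``beta`` a zero-truncated Gaussian.
    """

    alpha_mean: np.ndarray
    alpha_var: np.ndarray
    beta_mean: np.ndarray
    beta_var: np.ndarray
    sigma2_shape: float
    sigma2_scale: np.ndarray
    theta2_shape: float
    theta2_scale: np.ndarray
    gating_penalty: float = 0.1

    def __post_init__(self) -> None:
        self.alpha_mean = _as_float_array(self.alpha_mean, "alpha_mean", 1)
        self.alpha_var = _as_float_array(self.alpha_var, "alpha_var", 1)
        self.beta_mean = _as_float_array(self.beta_mean, "beta_mean", 1)
        self.beta_var = _as_float_array(self.beta_var, "beta_var", 1)
        self.sigma2_scale = _as_float_array(self.sigma2_scale, "sigma2_scale", 1)
        self.theta2_scale = _as_float_array(self.theta2_scale, "theta2_scale", 1)
        for name in ("alpha_var", "beta_var", "sigma2_scale", "theta2_scale"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be strictly positive")
        if self.sigma2_shape <= 0 or self.theta2_shape <= 0:
            raise ValueError("inverse-gamma shapes must be strictly positive")
        if self.gating_penalty < 0:
            raise ValueError("gating_penalty must be non-negative")


def loglik_measurement(y_row, z: float, params: MeasurementParams) -> float:
    """Log-likelihood of one observation's biomarker vector given intake.

    Returns ``sum_p log N(y_p; alpha_p + beta_p z, sigma_p^2)``.
    """
    y = _as_float_array(y_row, "y_row", 1)
    if y.shape[0] != params.P:
        raise ValueError(f"y_row has length {y.shape[0]}, expected {params.P}")
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    if z < 0:
        raise ValueError("z must be non-negative")
    resid = y - params.alpha - params.beta * z
    return float(-0.5 * np.sum(_LOG_2PI + np.log(params.sigma2)
                               + resid ** 2 / params.sigma2))


def log_truncnorm_pdf(z, mean, sd):
    """Log-density of ``N(mean, sd^2)`` truncated to ``(0, inf)``.

    The normalizer ``1 - Phi(-mean/sd) = Phi(mean/sd)`` is evaluated through
    ``log_ndtr`` so far-from-boundary components do not underflow.
    Broadcasts over array arguments.
    """
    z = np.asarray(z, dtype=float)
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("sd must be strictly positive")
    u = (z - mean) / sd
    out = -0.5 * (_LOG_2PI + u ** 2) - np.log(sd) - log_ndtr(mean / sd)
    return np.where(z > 0, out, -np.inf)


def log_prior_intake(z: float, weights, dose_levels, comp: ComponentParams) -> float:
    """Log-density of the zero-truncated Gaussian-mixture intake prior.

    ``log sum_d w_d TN_(0,inf)(z; x_d, theta_d^2)`` with each component
    normalized on the positive half-line.
    """
    if not np.isfinite(z) or z <= 0:
        raise ValueError("intake z must be a finite, strictly positive scalar")
    w = _as_float_array(weights, "weights", 1)
    x = _as_float_array(dose_levels, "dose_levels", 1)
    if w.shape != x.shape or w.shape[0] != comp.D:
        raise ValueError("weights, dose_levels and theta2 must have equal length")
    if abs(w.sum() - 1.0) > 1e-10 or np.any(w < 0):
        raise ValueError("weights must be a probability simplex")
    with np.errstate(divide="ignore"):
        logw = np.log(w)
    return float(logsumexp(logw + log_truncnorm_pdf(z, x, np.sqrt(comp.theta2))))


def _truncated_standard_normal(a: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draws from N(0,1) truncated to ``(a_i, inf)``, elementwise.

    Inverse-CDF sampling via the survival function, ``-ndtri(sf(a)(1-u))``,
    which stays accurate deep into either tail; when the truncation point
    sits more than 5 SDs above the mean the survival function is too small
    for the inverse CDF to resolve and we fall back to rejection from a
    shifted exponential (Robert's method).
    """
    from scipy.special import ndtr, ndtri

    a = np.asarray(a, dtype=float)
    out = np.empty_like(a)
    easy = a <= 5.0
    if easy.any():
        sf_a = ndtr(-a[easy])
        u = rng.random(int(easy.sum()))
        out[easy] = -ndtri(sf_a * (1.0 - u))
    hard = ~easy
    if hard.any():
        ah = a[hard]
        lam = 0.5 * (ah + np.sqrt(ah * ah + 4.0))
        vals = np.empty(ah.shape)
        pending = np.ones(ah.shape, dtype=bool)
        while pending.any():
            k = int(pending.sum())
            x = ah[pending] + rng.exponential(size=k) / lam[pending]
            accept = rng.random(k) <= np.exp(-0.5 * (x - lam[pending]) ** 2)
            idx = np.flatnonzero(pending)[accept]
            vals[idx] = x[accept]
            pending[idx] = False
        out[hard] = vals
    return out


def sample_truncated_normal(mean, sd, rng: np.random.Generator, size=None):
    """Draw from ``N(mean, sd^2)`` conditioned on ``(0, inf)``.

    ``mean`` and ``sd`` broadcast against each other (and against ``size``
    when given); every draw is strictly positive and reproducible given the
    generator state.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("sd must be strictly positive")
    shape = np.broadcast(mean, sd).shape if size is None else size
    a = np.broadcast_to(-mean / sd, shape)
    draws = np.broadcast_to(mean, shape) \
        + np.broadcast_to(sd, shape) * _truncated_standard_normal(a, rng)
    # u = 0 from the uniform generator maps to the truncation point itself;
    # nudge to the smallest positive normal to keep the support open
    tiny = np.finfo(float).tiny
    if draws.ndim == 0:
        return float(max(draws, tiny))
    return np.maximum(draws, tiny)
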