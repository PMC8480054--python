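"""Mixture-of-experts gating: observation-specific component weights.

The weight of mixture component ``d`` for observation ``i`` comes from a
cumulative-link (proportional-odds) ordinal regression of the component label
on the observation's own biomarkers:

    P(c_i <= d | y_i) = F(zeta_d - w' y_i_std),   d = 1, ..., D-1,

with strictly increasing cutpoints ``zeta_1 < ... < zeta_{D-1}`` and a single
coefficient vector ``w`` shared across cutpoints.  The default link ``F`` is
the Cauchit — the standard Cauchy CDF ``1/2 + arctan(u)/pi`` — whose heavy
tails keep far-outlying biomarker profiles from collapsing the weights onto a
single component; logit and probit are available as alternatives.

Biomarkers enter the gating design standardized (center/scale estimated on
the training data and stored for reuse at prediction) so the ridge penalty on
``w`` is unit-free.

Fitting maximizes the penalized ordinal log-likelihood with a deterministic
quasi-Newton optimizer; cutpoints are reparameterized as ``zeta_1`` plus
positive (log) increments so monotonicity holds at every iterate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import expit, logit as _sp_logit, ndtr, ndtri

__all__ = ["GatingParameters", "cauchit_cdf", "gating_probs",
           "gating_probs_matrix", "fit_gating", "penalized_ordinal_nll"]


def _cauchy_cdf(u):
    return 0.5 + np.arctan(u) / np.pi


def _cauchy_pdf(u):
    return 1.0 / (np.pi * (1.0 + u * u))


def _cauchy_ppf(q):
    return np.tan(np.pi * (np.asarray(q, dtype=float) - 0.5))


def _logistic_pdf(u):
    e = expit(u)
    return e * (1.0 - e)


def _norm_pdf(u):
    return np.exp(-0.5 * u * u) / np.sqrt(2.0 * np.pi)


# (cdf, pdf, ppf) per link, as plain vectorized callables for speed
_LINKS = {
    "cauchit": (_cauchy_cdf, _cauchy_pdf, _cauchy_ppf),
    "logit": (expit, _logistic_pdf, _sp_logit),
    "probit": (ndtr, _norm_pdf, ndtri),
}

_PROB_FLOOR = 1e-300


def cauchit_cdf(u):
    """Standard Cauchy CDF, ``1/2 + arctan(u)/pi``; the default gating link."""
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("cauchit_cdf requires finite input")
    out = 0.5 + np.arctan(u) / np.pi
    return float(out) if out.ndim == 0 else out


@dataclass
class GatingParameters:
    """Fitted gating model: cutpoints, coefficients and the standardization
    applied to the biomarker design."""

    thresholds: np.ndarray    # (D-1,), strictly increasing
    coefficients: np.ndarray  # (P,)
    center: np.ndarray        # (P,)
    scale: np.ndarray         # (P,), strictly positive
    link: str = "cauchit"

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float).reshape(-1)
        self.coefficients = np.asarray(self.coefficients, dtype=float).reshape(-1)
        self.center = np.asarray(self.center, dtype=float).reshape(-1)
        self.scale = np.asarray(self.scale, dtype=float).reshape(-1)
        if self.thresholds.size and np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")
        if np.any(self.scale <= 0):
            raise ValueError("standardization scale must be positive")
        if self.link not in _LINKS:
            raise ValueError(f"unknown link {self.link!r}; choose from {sorted(_LINKS)}")

    @property
    def D(self) -> int:
        return self.thresholds.shape[0] + 1

    @property
    def P(self) -> int:
        return self.coefficients.shape[0]

    def linear_predictor(self, y) -> np.ndarray:
        y = np.atleast_2d(np.asarray(y, dtype=float))
        if y.shape[1] != self.P:
            raise ValueError(f"expected {self.P} biomarker columns, got {y.shape[1]}")
        return ((y - self.center) / self.scale) @ self.coefficients


def gating_probs_matrix(y: np.ndarray, params: GatingParameters, D: int) -> np.ndarray:
    """Component probabilities for each row of ``y``; returns ``n x D``.

    Category probabilities are first differences of the cumulative link, with
    the last category taken as the complement so each row sums to one.
    """
    if D != params.D:
        raise ValueError(f"params encode D={params.D} components, requested D={D}")
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n = y.shape[0]
    if D == 1:
        return np.ones((n, 1))
    cdf = _LINKS[params.link][0]
    eta = params.linear_predictor(y)
    cum = cdf(params.thresholds[None, :] - eta[:, None])   # (n, D-1)
    probs = np.empty((n, D))
    probs[:, 0] = cum[:, 0]
    probs[:, 1:-1] = np.diff(cum, axis=1)
    probs[:, -1] = 1.0 - cum[:, -1]
    # a floor guards against floating-point zeros at extreme linear predictors
    np.clip(probs, _PROB_FLOOR, None, out=probs)
    probs /= probs.sum(axis=1, keepdims=True)
    return probs


def gating_probs(y_row, params: GatingParameters, D: int) -> np.ndarray:
    """Length-``D`` simplex of component weights for a single observation."""
    return gating_probs_matrix(np.atleast_2d(y_row), params, D)[0]


def _unpack(theta: np.ndarray, D: int, P: int):
    """theta = (zeta_1, log-increments delta_2..delta_{D-1}, w_1..w_P)."""
    zeta1 = theta[0]
    if D > 2:
        zeta = zeta1 + np.concatenate(([0.0], np.cumsum(np.exp(theta[1:D - 1]))))
    else:
        zeta = np.array([zeta1])
    w = theta[D - 1:]
    return zeta, w


def penalized_ordinal_nll(theta: np.ndarray, y_std: np.ndarray,
                          labels: np.ndarray, penalty: float, D: int,
                          link: str = "cauchit") -> float:
    """Negative penalized cumulative-link log-likelihood (objective only).

    Kept separate from the gradient-bearing fitter so tests can evaluate the
    objective through an independent code path.
    """
    zeta, w = _unpack(theta, D, y_std.shape[1])
    cdf = _LINKS[link][0]
    eta = y_std @ w
    ext = np.concatenate(([-np.inf], zeta, [np.inf]))
    upper = ext[labels + 1] - eta
    lower = ext[labels] - eta
    p = np.where(np.isinf(upper), 1.0, cdf(np.where(np.isinf(upper), 0.0, upper))) \
        - np.where(np.isinf(lower), 0.0, cdf(np.where(np.isinf(lower), 0.0, lower)))
    p = np.clip(p, _PROB_FLOOR, None)
    return float(-np.sum(np.log(p)) + penalty * np.dot(w, w))


def _nll_and_grad(theta, y_std, labels, penalty, D, link):
    P = y_std.shape[1]
    zeta, w = _unpack(theta, D, P)
    cdf, pdf, _ = _LINKS[link]
    eta = y_std @ w
    ext = np.concatenate(([-np.inf], zeta, [np.inf]))
    ui = labels + 1          # index of the upper cutpoint, D means +inf
    li = labels              # index of the lower cutpoint, 0 means -inf
    upper = ext[ui] - eta
    lower = ext[li] - eta
    Fu = np.where(ui == D, 1.0, cdf(np.where(ui == D, 0.0, upper)))
    Fl = np.where(li == 0, 0.0, cdf(np.where(li == 0, 0.0, lower)))
    fu = np.where(ui == D, 0.0, pdf(np.where(ui == D, 0.0, upper)))
    fl = np.where(li == 0, 0.0, pdf(np.where(li == 0, 0.0, lower)))
    p = np.clip(Fu - Fl, _PROB_FLOOR, None)
    nll = -np.sum(np.log(p)) + penalty * np.dot(w, w)

    inv_p = 1.0 / p
    # d nll / d zeta_k accumulated from obs where zeta_k is the upper/lower cut
    g_zeta = np.zeros(D - 1)
    np.add.at(g_zeta, np.clip(ui, 1, D - 1) - 1, np.where(ui < D, -fu * inv_p, 0.0))
    np.add.at(g_zeta, np.clip(li, 1, D - 1) - 1, np.where(li > 0, fl * inv_p, 0.0))
    # d nll / d eta = (fu - fl)/p ;  eta = y_std @ w
    g_eta = (fu - fl) * inv_p
    g_w = y_std.T @ g_eta + 2.0 * penalty * w

    grad = np.empty_like(theta)
    grad[0] = g_zeta.sum()
    if D > 2:
        inc = np.exp(theta[1:D - 1])
        # zeta_k depends on increments 2..k: reverse cumulative sum of g_zeta
        tail = np.cumsum(g_zeta[::-1])[::-1]
        grad[1:D - 1] = tail[1:] * inc
    grad[D - 1:] = g_w
    return nll, grad


def _null_thresholds(labels: np.ndarray, D: int, link: str) -> np.ndarray:
    """Cutpoints of the null (w = 0) model: link quantiles of the empirical
    cumulative label frequencies, clipped away from 0/1 and forced increasing."""
    ppf = _LINKS[link][2]
    counts = np.bincount(labels, minlength=D)
    cum = np.cumsum(counts)[:-1] / labels.shape[0]
    cum = np.clip(cum, 1e-3, 1.0 - 1e-3)
    zeta = ppf(cum)
    for k in range(1, zeta.shape[0]):   # repair ties from clipping
        if zeta[k] <= zeta[k - 1]:
            zeta[k] = zeta[k - 1] + 1e-6
    return zeta


def standardize_design(y: np.ndarray):
    """Center/scale for the gating design; constant columns get unit scale."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    center = y.mean(axis=0)
    scale = y.std(axis=0)
    scale[scale == 0] = 1.0
    return center, scale


def fit_gating(y: np.ndarray, labels: np.ndarray, penalty: float = 0.1,
               D: int | None = None, link: str = "cauchit",
               standardization=None) -> GatingParameters:
    """Fit the penalized cumulative-link gating model.

    Parameters
    ----------
    y
        ``n x P`` biomarker matrix (raw scale; standardized internally).
    labels
        Integer component labels, 0-based codes in ``0..D-1``.
    penalty
        Ridge weight on the coefficient vector (default 0.1); categories with
        no observations are handled by the penalty rather than an error.
    D
        Number of components; inferred as ``max(labels)+1`` when omitted.
    standardization
        Optional ``(center, scale)`` pair to reuse instead of re-estimating
        (the sampler keeps it fixed across refits).

    The optimizer is L-BFGS-B with an analytic gradient, always started from
    the null model, so the fit is deterministic given its inputs.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != y.shape[0]:
        raise ValueError("labels and y must have the same number of rows")
    if D is None:
        D = int(labels.max()) + 1
    if labels.min() < 0 or labels.max() >= D:
        raise ValueError(f"labels must lie in 0..{D - 1}")
    if y.shape[0] < D:
        raise ValueError("need at least as many observations as components")
    P = y.shape[1]
    if standardization is None:
        center, scale = standardize_design(y)
    else:
        center, scale = (np.asarray(a, dtype=float) for a in standardization)
    if D == 1:
        return GatingParameters(np.empty(0), np.zeros(P), center, scale, link)

    y_std = (y - center) / scale
    zeta0 = _null_thresholds(labels, D, link)
    theta0 = np.concatenate(([zeta0[0]],
                             np.log(np.diff(zeta0)) if D > 2 else [],
                             np.zeros(P)))
    res = optimize.minimize(
        _nll_and_grad, theta0, args=(y_std, labels, penalty, D, link),
        jac=True, method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    zeta, w = _unpack(res.x, D, P)
    return GatingParameters(zeta, w, center, scale, link)
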