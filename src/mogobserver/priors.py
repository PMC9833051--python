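"""Gaussian and mixture-of-Gaussians (MoG) algebra for Bayesian ideal observers.

An ideal observer combines a prior over stimulus values ``p(x)`` with a Gaussian
likelihood centered on a noisy internal measurement ``m`` (SD ``sigma``).  When the
prior is a mixture of ``C`` Gaussian components the posterior is again a mixture of
Gaussians whose component means are shrunk toward the prior component means and
whose mixing weights are re-adjusted by how compatible each component is with the
measurement.  This module implements that conjugate algebra exactly:

* :class:`MoGPrior` — the prior, components ``(w_i, nu_i, gamma_i)``.
* :func:`component_posterior_params` — per-component shrinkage ``alpha_i`` and
  offset ``nu_tilde_i`` (measurement independent).
* :func:`adjusted_weights` — measurement-dependent posterior weights
  ``w_tilde_i(m)``, computed in log space.
* :func:`posterior_mog` — the full posterior mixture :class:`PosteriorMoG`.

For ``C = 1`` every quantity reduces to the classic single-Gaussian observer:
posterior mean ``alpha*m + nu_tilde`` with ``alpha = gamma^2/(gamma^2+sigma^2)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "MoGPrior",
    "ObserverModel",
    "PosteriorMoG",
    "adjusted_weights",
    "component_posterior_params",
    "default_grid",
    "mog_pdf",
    "moment_matched_gaussian",
    "posterior_mog",
]

# Construction tolerances: weight sums within _RENORM_TOL of one are silently
# renormalized (round-tripped configs), larger deviations are rejected.
_WEIGHT_SUM_TOL = 1e-12
_RENORM_TOL = 1e-9


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass(frozen=True)
class MoGPrior:
    """A mixture-of-Gaussians prior ``p(x) = sum_i w_i N(nu_i, gamma_i^2)``.

    Parameters
    ----------
    weights : array-like of shape (C,)
        Nonnegative mixing weights summing to one.  Sums within 1e-9 of one are
        renormalized; anything further off raises ``ValueError``.
    means : array-like of shape (C,)
        Component means ``nu_i`` in stimulus units.
    sds : array-like of shape (C,)
        Component standard deviations ``gamma_i`` (strictly positive).
    """

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def __init__(self, weights, means, sds):
        w = _as_1d(weights, "weights")
        nu = _as_1d(means, "means")
        gamma = _as_1d(sds, "sds")
        if not (w.shape == nu.shape == gamma.shape):
            raise ValueError(
                f"component arrays must share a shape; got weights {w.shape}, "
                f"means {nu.shape}, sds {gamma.shape}"
            )
        if w.size < 1:
            raise ValueError("a prior needs at least one component")
        neg = np.nonzero(w < 0)[0]
        if neg.size:
            raise ValueError(f"weight of component {neg[0]} is negative ({w[neg[0]]})")
        bad = np.nonzero(gamma <= 0)[0]
        if bad.size:
            raise ValueError(f"sd of component {bad[0]} must be > 0, got {gamma[bad[0]]}")
        total = w.sum()
        if abs(total - 1.0) > _RENORM_TOL:
            raise ValueError(f"weights must sum to 1 (got {total!r})")
        if abs(total - 1.0) > _WEIGHT_SUM_TOL:
            w = w / total
        for name, arr in (("weights", w), ("means", nu), ("sds", gamma)):
            arr.flags.writeable = False
            object.__setattr__(self, name, arr)

    @property
    def n_components(self) -> int:
        return self.weights.size

    def pdf(self, x) -> np.ndarray | float:
        return mog_pdf(self, x)

    def mean(self) -> float:
        """Mixture mean ``sum_i w_i nu_i``."""
        return float(np.dot(self.weights, self.means))

    def variance(self) -> float:
        """Mixture variance ``sum_i w_i (gamma_i^2 + nu_i^2) - mean^2``."""
        m = self.mean()
        return float(np.dot(self.weights, self.sds**2 + self.means**2) - m**2)

    def sd(self) -> float:
        return float(np.sqrt(self.variance()))

    # --- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "components": [
                {"w": float(w), "nu": float(nu), "gamma": float(g)}
                for w, nu, g in zip(self.weights, self.means, self.sds)
            ]
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MoGPrior":
        comps = d["components"]
        return cls(
            weights=[c["w"] for c in comps],
            means=[c["nu"] for c in comps],
            sds=[c["gamma"] for c in comps],
        )


@dataclass(frozen=True)
class ObserverModel:
    """A prior plus per-condition measurement-noise SDs — the parameter vector.

    ``sigmas`` maps condition labels to likelihood SDs.  Observers used in tasks
    with a single noise level may use the default label ``"c1"``.
    """

    prior: MoGPrior
    sigmas: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        sig = dict(self.sigmas)
        for label, s in sig.items():
            if not (np.isfinite(s) and s > 0):
                raise ValueError(f"sigma for condition {label!r} must be > 0, got {s}")
        object.__setattr__(self, "sigmas", sig)

    @property
    def sigma(self) -> float:
        """The single noise SD; only valid for one-condition observers."""
        if len(self.sigmas) != 1:
            raise ValueError("observer has multiple conditions; index sigmas by label")
        return next(iter(self.sigmas.values()))

    def to_dict(self) -> dict:
        d = self.prior.to_dict()
        if len(self.sigmas) == 1:
            d["sigma"] = float(next(iter(self.sigmas.values())))
        else:
            d["sigmas"] = {k: float(v) for k, v in self.sigmas.items()}
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ObserverModel":
        prior = MoGPrior.from_dict(d)
        if "sigma" in d:
            sigmas = {"c1": float(d["sigma"])}
        else:
            sigmas = {k: float(v) for k, v in d["sigmas"].items()}
        return cls(prior=prior, sigmas=sigmas)

    @classmethod
    def from_json(cls, path) -> "ObserverModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _check_sigma(sigma: float) -> float:
    sigma = float(sigma)
    if not (np.isfinite(sigma) and sigma > 0):
        raise ValueError(f"sigma must be a positive finite real, got {sigma}")
    return sigma


def mog_pdf(prior: MoGPrior, x):
    """Mixture density ``sum_i w_i N(x; nu_i, gamma_i^2)``; vectorizes over ``x``."""
    x = np.asarray(x, dtype=float)
    dens = np.einsum(
        "i,...i->...",
        prior.weights,
        norm.pdf(x[..., None], loc=prior.means, scale=prior.sds),
    )
    return float(dens) if dens.ndim == 0 else dens


def component_posterior_params(prior: MoGPrior, sigma: float):
    """Per-component shrinkage factors and offsets, independent of the measurement.

    Returns ``(alpha, nu_tilde)`` with ``alpha_i = gamma_i^2 / (gamma_i^2 + sigma^2)``
    and ``nu_tilde_i = sigma^2 nu_i / (sigma^2 + gamma_i^2) = (1 - alpha_i) nu_i``.
    ``alpha_i`` is the fraction of the measurement retained in the posterior
    component mean; the remainder is pulled toward the prior component mean.
    """
    sigma = _check_sigma(sigma)
    g2 = prior.sds**2
    alpha = g2 / (g2 + sigma**2)
    nu_tilde = (sigma**2 / (sigma**2 + g2)) * prior.means
    return alpha, nu_tilde


def adjusted_weights(prior: MoGPrior, sigma: float, m: float) -> np.ndarray:
    """Posterior mixing weights ``w_tilde_i(m)``.

    Each prior weight is rescaled by the marginal compatibility of the component
    with the measurement, ``rho_i(m) = N(m; nu_i, gamma_i^2 + sigma^2)``, and the
    products ``v_i = w_i rho_i(m)`` are normalized to sum to one.  Computed in log
    space (log-sum-exp) so distant measurements do not underflow.
    """
    sigma = _check_sigma(sigma)
    m = float(m)
    with np.errstate(divide="ignore", over="ignore"):  # log 0 / far-tail overflow -> -inf
        log_v = np.log(prior.weights) + norm.logpdf(
            m, loc=prior.means, scale=np.sqrt(prior.sds**2 + sigma**2)
        )
    if not np.any(np.isfinite(log_v)):
        raise FloatingPointError(
            "all component scales v_i underflowed for measurement "
            f"m={m}; review the grid/support of the prior"
        )
    w = np.exp(log_v - logsumexp(log_v))
    return w / w.sum()


def adjusted_weights_grid(prior: MoGPrior, sigma: float, m_grid) -> np.ndarray:
    """Vectorized :func:`adjusted_weights` over a grid of measurements.

    Returns an array of shape ``(len(m_grid), C)``.
    """
    sigma = _check_sigma(sigma)
    m = np.asarray(m_grid, dtype=float)[:, None]
    with np.errstate(divide="ignore", over="ignore"):
        log_v = np.log(prior.weights) + norm.logpdf(
            m, loc=prior.means, scale=np.sqrt(prior.sds**2 + sigma**2)
        )
    bad = ~np.any(np.isfinite(log_v), axis=1)
    if np.any(bad):
        raise FloatingPointError(
            "all component scales v_i underflowed for some grid measurements; "
            "review the grid/support of the prior"
        )
    w = np.exp(log_v - logsumexp(log_v, axis=1, keepdims=True))
    return w / w.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class PosteriorMoG:
    """The posterior ``p(x|m)`` for a MoG prior and Gaussian likelihood.

    A mixture with adjusted weights ``w_tilde_i(m)``, component means
    ``alpha_i m + nu_tilde_i`` and component variances ``alpha_i sigma^2``.
    """

    m: float
    sigma: float
    weights: np.ndarray          # w_tilde_i(m)
    component_means: np.ndarray  # alpha_i m + nu_tilde_i
    component_sds: np.ndarray    # sqrt(alpha_i) sigma
    alphas: np.ndarray
    nu_tildes: np.ndarray

    @property
    def n_components(self) -> int:
        return self.weights.size

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        dens = np.einsum(
            "i,...i->...",
            self.weights,
            norm.pdf(x[..., None], loc=self.component_means, scale=self.component_sds),
        )
        return float(dens) if dens.ndim == 0 else dens

    def mean(self) -> float:
        """Posterior mean (the Bayesian least-squares estimate)."""
        return float(np.dot(self.weights, self.component_means))


def posterior_mog(prior: MoGPrior, sigma: float, m: float) -> PosteriorMoG:
    """Exact posterior mixture for measurement ``m`` under Gaussian noise ``sigma``."""
    sigma = _check_sigma(sigma)
    m = float(m)
    alpha, nu_tilde = component_posterior_params(prior, sigma)
    w_tilde = adjusted_weights(prior, sigma, m)
    return PosteriorMoG(
        m=m,
        sigma=sigma,
        weights=w_tilde,
        component_means=alpha * m + nu_tilde,
        component_sds=np.sqrt(alpha) * sigma,
        alphas=alpha,
        nu_tildes=nu_tilde,
    )


def moment_matched_gaussian(prior: MoGPrior) -> MoGPrior:
    """Best-fit single Gaussian to a mixture prior by moment matching.

    The returned one-component prior has the mixture's mean and variance:
    ``nu = sum w_i nu_i`` and ``gamma^2 = sum w_i (gamma_i^2 + nu_i^2) - nu^2``.
    """
    return MoGPrior(weights=[1.0], means=[prior.mean()], sds=[prior.sd()])


def default_grid(prior: MoGPrior, sigma: float, n: int = 2001) -> np.ndarray:
    """The package-wide grid convention for gridded densities.

    Uniform spacing, centered on the mixture mean, spanning +/- 8 times the larger
    of ``max_i(gamma_i + |nu_i|)`` and ``sigma``.
    """
    sigma = _check_sigma(sigma)
    center = prior.mean()
    half = 8.0 * max(float(np.max(prior.sds + np.abs(prior.means))), sigma)
    return np.linspace(center - half, center + half, n)
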