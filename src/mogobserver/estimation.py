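"""Point estimators and estimate distributions for the ideal observer.

The observer turns each noisy measurement ``m`` into an estimate through a
deterministic mapping ``T(m)``:

* Bayesian least squares (BLS, squared-error loss): the posterior mean,
  analytic for a MoG posterior.
* Maximum a posteriori (MAP, zero-one loss): the posterior mode, found
  numerically for mixtures (equal to BLS when the posterior is Gaussian).

Because measurements vary from trial to trial, estimates of a fixed stimulus
``x`` form an estimate distribution ``p(xhat|x)``.  Three routes are provided:

* ``exact_sg`` — the single-Gaussian closed form ``N(alpha x + nu_tilde,
  alpha^2 sigma^2)``;
* ``numeric``  — change of variables through a gridded estimator map ``T`` and
  its interpolated inverse (valid whenever ``T`` is strictly increasing);
* ``approx``   — the analytic Gaussian approximation obtained by freezing the
  posterior weights at their value for the expected measurement, ``w_tilde_i(x)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .priors import (
    MoGPrior,
    PosteriorMoG,
    adjusted_weights,
    adjusted_weights_grid,
    component_posterior_params,
    default_grid,
    posterior_mog,
)

__all__ = [
    "EstimateDistribution",
    "EstimatorMap",
    "approx_inverse",
    "bls_estimate",
    "bls_estimate_grid",
    "build_estimator_map",
    "estimate_distribution",
    "invert_estimator_map",
    "map_estimate",
]


def bls_estimate(posterior: PosteriorMoG) -> float:
    """Posterior mean ``sum_i w_tilde_i(m) (alpha_i m + nu_tilde_i)``."""
    return posterior.mean()


def bls_estimate_grid(prior: MoGPrior, sigma: float, m_grid) -> np.ndarray:
    """Vectorized BLS estimates over a grid of measurements."""
    m = np.asarray(m_grid, dtype=float)
    alpha, nu_tilde = component_posterior_params(prior, sigma)
    w = adjusted_weights_grid(prior, sigma, m)
    return np.einsum("ti,ti->t", w, alpha * m[:, None] + nu_tilde)


def map_estimate(posterior: PosteriorMoG, refine_tol: float = 1e-8) -> float:
    """Posterior mode by coarse grid scan plus local refinement.

    When the posterior has several equally high modes (a plateau or exact tie),
    the smallest maximizer is returned and a warning is emitted — a deterministic
    stand-in for a mode choice that would otherwise flip with infinitesimal
    measurement noise.
    """
    if refine_tol <= 0:
        raise ValueError("refine_tol must be positive")
    if posterior.n_components == 1:
        return posterior.mean()

    lo = float(np.min(posterior.component_means - 6 * posterior.component_sds))
    hi = float(np.max(posterior.component_means + 6 * posterior.component_sds))
    grid = np.linspace(lo, hi, 4001)
    dens = posterior.pdf(grid)

    # local maxima on the coarse grid, refined by bounded scalar minimization
    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:])
    idx = np.nonzero(interior)[0] + 1
    if idx.size == 0:
        idx = np.array([int(np.argmax(dens))])
    candidates = []
    for i in idx:
        a, b = grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]
        res = minimize_scalar(
            lambda x: -posterior.pdf(x),
            bounds=(a, b),
            method="bounded",
            options={"xatol": refine_tol},
        )
        candidates.append((float(res.x), float(-res.fun)))
    best = max(v for _, v in candidates)
    winners = sorted(x for x, v in candidates if v >= best * (1 - 1e-9))
    if len(winners) > 1:
        warnings.warn(
            "posterior has tied maxima; returning the smallest maximizer",
            RuntimeWarning,
            stacklevel=2,
        )
    return winners[0]


@dataclass(frozen=True)
class EstimatorMap:
    """Gridded estimator ``T(m)`` with an interpolated inverse.

    ``m_grid`` is strictly increasing; ``xhat_grid = T(m_grid)``.  The map is
    invertible by table lookup only when ``monotone_flag`` is true.
    """

    m_grid: np.ndarray
    xhat_grid: np.ndarray
    monotone_flag: bool
    estimator_kind: Literal["BLS", "MAP"]

    def to_text(self, path) -> None:
        """Two-column delimited dump (m, xhat) for inspection."""
        np.savetxt(
            path,
            np.column_stack([self.m_grid, self.xhat_grid]),
            header="m\txhat",
            delimiter="\t",
            comments="",
        )


def build_estimator_map(
    prior: MoGPrior,
    sigma: float,
    m_grid=None,
    estimator_kind: Literal["BLS", "MAP"] = "BLS",
) -> EstimatorMap:
    """Tabulate ``T(m)`` over a measurement grid.

    The default grid follows the package convention (:func:`~mogobserver.priors.default_grid`).
    """
    if m_grid is None:
        m_grid = default_grid(prior, sigma)
    m_grid = np.asarray(m_grid, dtype=float)
    if m_grid.ndim != 1 or m_grid.size < 2 or np.any(np.diff(m_grid) <= 0):
        raise ValueError("m_grid must be a strictly increasing 1-D array of length >= 2")
    if estimator_kind == "BLS":
        xhat = bls_estimate_grid(prior, sigma, m_grid)
    elif estimator_kind == "MAP":
        xhat = np.array(
            [map_estimate(posterior_mog(prior, sigma, m)) for m in m_grid]
        )
    else:
        raise ValueError(f"unknown estimator_kind {estimator_kind!r}")
    monotone = bool(np.all(np.diff(xhat) > 0))
    return EstimatorMap(
        m_grid=m_grid, xhat_grid=xhat, monotone_flag=monotone,
        estimator_kind=estimator_kind,
    )


def _inverse_derivative_table(emap: EstimatorMap) -> np.ndarray:
    # dT^-1/dxhat on the table: central differences of m w.r.t. xhat,
    # one-sided at the edges (np.gradient does exactly this).
    return np.gradient(emap.m_grid, emap.xhat_grid)


def invert_estimator_map(emap: EstimatorMap, xhat):
    """Numeric inverse ``m = T^-1(xhat)`` and its derivative ``dT^-1/dxhat``.

    Piecewise-linear interpolation of the inverted table; derivative by finite
    differences on the table.  Raises for non-monotone maps (use Monte-Carlo
    density estimation instead) and for ``xhat`` outside the tabulated range.
    """
    if not emap.monotone_flag:
        raise ValueError(
            "estimator map is not strictly increasing; the change-of-variables "
            "inverse is undefined — use a numeric (Monte-Carlo) density instead"
        )
    xhat_arr = np.asarray(xhat, dtype=float)
    lo, hi = emap.xhat_grid[0], emap.xhat_grid[-1]
    if np.any(xhat_arr < lo) or np.any(xhat_arr > hi):
        raise ValueError(
            f"estimate {xhat!r} outside the invertible range [{lo:.6g}, {hi:.6g}]"
        )
    m = np.interp(xhat_arr, emap.xhat_grid, emap.m_grid)
    deriv = np.interp(xhat_arr, emap.xhat_grid, _inverse_derivative_table(emap))
    if xhat_arr.ndim == 0:
        return float(m), float(deriv)
    return m, deriv


def approx_inverse(
    prior: MoGPrior,
    sigma: float,
    x: float,
    xhat,
    literal_offsets: bool = False,
):
    """Analytic approximate inverse of ``T`` with weights frozen at ``w_tilde_i(x)``.

    Approximating the measurement by its expected value ``E(m) = x`` inside the
    posterior weights makes ``T`` affine, hence invertible in closed form::

        m = (xhat - sum_i w_tilde_i(x) nu_tilde_i) / sum_i w_tilde_i(x) alpha_i
        dT^-1/dxhat = 1 / sum_i w_tilde_i(x) alpha_i

    ``literal_offsets=True`` substitutes the raw component means ``nu_i`` for the
    posterior offsets ``nu_tilde_i`` in the numerator (an alternative printed
    form); the default keeps the offsets consistent with the forward map.
    """
    alpha, nu_tilde = component_posterior_params(prior, sigma)
    w = adjusted_weights(prior, sigma, x)
    offsets = prior.means if literal_offsets else nu_tilde
    denom = float(np.dot(w, alpha))
    xhat_arr = np.asarray(xhat, dtype=float)
    m = (xhat_arr - float(np.dot(w, offsets))) / denom
    deriv = 1.0 / denom
    if xhat_arr.ndim == 0:
        return float(m), deriv
    return m, np.full_like(xhat_arr, deriv)


@dataclass(frozen=True)
class EstimateDistribution:
    """The distribution of estimates ``p(xhat|x)`` for a fixed stimulus.

    Either an analytic Gaussian (``form == "gaussian"``) or a gridded density
    obtained by change of variables through the estimator map
    (``form == "gridded"``, with a possibly non-uniform support grid).
    """

    form: Literal["gaussian", "gridded"]
    mean: float | None = None
    sd: float | None = None
    support: np.ndarray | None = None
    density: np.ndarray | None = None

    def pdf(self, xhat):
        if self.form == "gaussian":
            return norm.pdf(xhat, loc=self.mean, scale=self.sd)
        return np.interp(
            np.asarray(xhat, dtype=float), self.support, self.density,
            left=0.0, right=0.0,
        )

    def logpdf(self, xhat):
        if self.form == "gaussian":
            return norm.logpdf(xhat, loc=self.mean, scale=self.sd)
        with np.errstate(divide="ignore"):
            return np.log(self.pdf(xhat))

    def integral(self) -> float:
        if self.form == "gaussian":
            return 1.0
        return float(np.trapezoid(self.density, self.support))

    def moments(self) -> tuple[float, float]:
        """(mean, sd); exact for gaussian, trapezoid moments for gridded."""
        if self.form == "gaussian":
            return self.mean, self.sd
        z = self.integral()
        mu = float(np.trapezoid(self.support * self.density, self.support)) / z
        var = float(np.trapezoid((self.support - mu) ** 2 * self.density, self.support)) / z
        return mu, float(np.sqrt(var))


def estimate_distribution(
    prior: MoGPrior,
    sigma: float,
    x: float,
    method: Literal["exact_sg", "numeric", "approx"] = "numeric",
    m_grid=None,
) -> EstimateDistribution:
    """Distribution of BLS estimates of stimulus ``x`` under noise ``sigma``.

    ``exact_sg`` (single-Gaussian priors only): ``N(alpha x + nu_tilde, alpha^2 sigma^2)``.
    ``numeric``: density through the tabulated estimator map,
    ``p(xhat|x) = N(T^-1(xhat); x, sigma^2) |dT^-1/dxhat|``.
    ``approx``: Gaussian with frozen weights,
    ``N(sum_i w_i~(x)(alpha_i x + nu_i~), sigma^2 (sum_i w_i~(x) alpha_i)^2)``.
    """
    x = float(x)
    if method == "exact_sg":
        if prior.n_components != 1:
            raise ValueError("exact_sg requires a single-Gaussian prior (C = 1)")
        alpha, nu_tilde = component_posterior_params(prior, sigma)
        return EstimateDistribution(
            form="gaussian",
            mean=float(alpha[0] * x + nu_tilde[0]),
            sd=float(alpha[0] * sigma),
        )
    if method == "approx":
        alpha, nu_tilde = component_posterior_params(prior, sigma)
        w = adjusted_weights(prior, sigma, x)
        eff_alpha = float(np.dot(w, alpha))
        return EstimateDistribution(
            form="gaussian",
            mean=float(np.dot(w, alpha * x + nu_tilde)),
            sd=eff_alpha * float(sigma),
        )
    if method == "numeric":
        emap = build_estimator_map(prior, sigma, m_grid=m_grid, estimator_kind="BLS")
        if not emap.monotone_flag:
            raise ValueError(
                "estimator map is not strictly increasing; the numeric "
                "change-of-variables density is undefined for this observer"
            )
        m_inv = emap.m_grid
        deriv = _inverse_derivative_table(emap)
        density = norm.pdf(m_inv, loc=x, scale=sigma) * np.abs(deriv)
        return EstimateDistribution(form="gridded", support=emap.xhat_grid, density=density)
    raise ValueError(f"unknown method {method!r}")
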