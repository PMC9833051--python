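"""Forward simulation of ideal observers with arbitrary (gridded) priors.

These generators produce the synthetic trial tables used to validate the fitting
machinery: the generating observer can have a prior of any shape (e.g. Cauchy or
bimodal), while the fitted model approximates it with a Gaussian mixture.

* :func:`make_gridded_prior` — tabulated densities: Cauchy ``1 / (pi (1 + x^2))``
  (truncated to the grid and renormalized), the normalized sum of two Gaussians,
  or a user-supplied density.
* :func:`simulate_point_estimates` — stimulus drawn from the prior, measurement
  ``m = x + N(0, sigma^2)``, estimate looked up from a precomputed table of
  gridded-posterior means (BLS), interpolating between tabulated measurements.
* :func:`simulate_2afc` — measurement pairs pushed through the exact
  posterior-comparison decision rule.

All simulators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.special import ndtr
from scipy.stats import norm

from .datasets import EstimationDataset, TwoAFCDataset
from .priors import MoGPrior, adjusted_weights_grid, component_posterior_params
from .psychometric import TwoAFCObserver

__all__ = [
    "GriddedDensity",
    "make_gridded_prior",
    "simulate_2afc",
    "simulate_point_estimates",
]


@dataclass(frozen=True)
class GriddedDensity:
    """A density tabulated on a uniform grid, trapezoid-normalized to one."""

    x: np.ndarray
    density: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        d = np.asarray(self.density, dtype=float)
        if x.ndim != 1 or x.size < 3 or np.any(np.diff(x) <= 0):
            raise ValueError("grid must be a strictly increasing 1-D array")
        if d.shape != x.shape:
            raise ValueError("density and grid shapes differ")
        if np.any(d < 0):
            raise ValueError("density must be nonnegative everywhere")
        z = np.trapezoid(d, x)
        if z <= 0:
            raise ValueError("density integrates to zero on the grid")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "density", d / z)

    def pdf(self, x):
        return np.interp(np.asarray(x, dtype=float), self.x, self.density, left=0.0, right=0.0)

    def mean(self) -> float:
        return float(np.trapezoid(self.x * self.density, self.x))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Inverse-CDF sampling on the grid (piecewise-linear CDF)."""
        # cumulative trapezoid
        dx = np.diff(self.x)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * dx * (self.density[1:] + self.density[:-1]))])
        cdf /= cdf[-1]
        u = rng.uniform(size=n)
        return np.interp(u, cdf, self.x)


def make_gridded_prior(
    kind: Literal["cauchy", "bimodal_sum", "custom"],
    params: dict | None = None,
    grid=None,
) -> GriddedDensity:
    """Tabulate one of the reference prior shapes.

    ``cauchy``: ``scale`` (default 1), truncated to the grid and renormalized.
    ``bimodal_sum``: normalized sum of two Gaussians, ``means`` (default (-2, 2))
    and ``sds`` (default (1, 1)).
    ``custom``: ``params`` must carry ``density`` evaluated on ``grid``.
    """
    params = dict(params or {})
    if kind == "cauchy":
        scale = float(params.get("scale", 1.0))
        if grid is None:
            grid = np.linspace(-25 * scale, 25 * scale, 5001)
        grid = np.asarray(grid, dtype=float)
        dens = scale / (np.pi * (scale**2 + grid**2))
        return GriddedDensity(grid, dens)
    if kind == "bimodal_sum":
        means = params.get("means", (-2.0, 2.0))
        sds = params.get("sds", (1.0, 1.0))
        if grid is None:
            half = max(abs(m) + 5 * s for m, s in zip(means, sds))
            grid = np.linspace(-half, half, 4001)
        grid = np.asarray(grid, dtype=float)
        dens = sum(norm.pdf(grid, loc=m, scale=s) for m, s in zip(means, sds))
        return GriddedDensity(grid, dens)
    if kind == "custom":
        if grid is None or "density" not in params:
            raise ValueError("custom kind requires a grid and params['density']")
        return GriddedDensity(np.asarray(grid, dtype=float), np.asarray(params["density"], dtype=float))
    raise ValueError(f"unknown prior kind {kind!r}")


def _bls_table(prior: GriddedDensity, sigma: float, m_lo: float, m_hi: float, n: int = 1501):
    """Tabulate the gridded-posterior mean over a measurement grid.

    For each tabulated ``m`` the posterior is the pointwise product of the
    gridded prior and the Gaussian likelihood, normalized on the grid; its mean
    is the BLS estimate.  Computed in blocks to bound memory.
    """
    m_tab = np.linspace(m_lo, m_hi, n)
    x = prior.x
    xhat = np.empty(n)
    block = max(1, int(2e6 // x.size))
    for s in range(0, n, block):
        mm = m_tab[s:s + block, None]
        like = np.exp(-0.5 * ((mm - x[None, :]) / sigma) ** 2)
        post = like * prior.density[None, :]
        z = np.trapezoid(post, x, axis=1)
        xhat[s:s + block] = np.trapezoid(post * x[None, :], x, axis=1) / z
    return m_tab, xhat


def simulate_point_estimates(
    prior: GriddedDensity,
    sigma: float,
    n: int,
    seed: int | None = None,
    condition: str = "c1",
) -> EstimationDataset:
    """Simulate ``n`` point-estimation trials from a gridded-prior observer."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    x = prior.sample(n, rng)
    m = x + rng.normal(scale=sigma, size=n)
    m_tab, xhat_tab = _bls_table(prior, sigma, float(m.min()) - sigma, float(m.max()) + sigma)
    xhat = np.interp(m, m_tab, xhat_tab)
    return EstimationDataset(
        x=x,
        xhat=xhat,
        condition=np.full(n, condition, dtype=object),
        trial=np.arange(1, n + 1),
    )


def simulate_2afc(
    observer: TwoAFCObserver,
    design: Sequence[tuple[float, float]],
    seed: int | None = None,
    conditions: tuple[str, str] = ("c1", "c2"),
) -> TwoAFCDataset:
    """Simulate 2AFC responses for a list of ``(x1, x2)`` trials.

    Measurements are drawn from the two Gaussian measurement distributions and
    pushed through the exact decision rule (``P(x2 > x1 | m1, m2) > 1/2``,
    evaluated in closed form and vectorized over trials).
    """
    design = np.asarray(design, dtype=float)
    if design.ndim != 2 or design.shape[1] != 2 or design.shape[0] < 1:
        raise ValueError("design must be a nonempty sequence of (x1, x2) pairs")
    rng = np.random.default_rng(seed)
    x1, x2 = design[:, 0], design[:, 1]
    m1 = x1 + rng.normal(scale=observer.sigma1, size=x1.size)
    m2 = x2 + rng.normal(scale=observer.sigma2, size=x2.size)

    p = observer.prior
    a1, nt1 = component_posterior_params(p, observer.sigma1)
    a2, nt2 = component_posterior_params(p, observer.sigma2)
    w1 = adjusted_weights_grid(p, observer.sigma1, m1)
    w2 = adjusted_weights_grid(p, observer.sigma2, m2)
    mu1 = a1 * m1[:, None] + nt1
    mu2 = a2 * m2[:, None] + nt2
    v1 = a1 * observer.sigma1**2
    v2 = a2 * observer.sigma2**2
    z = (mu2[:, None, :] - mu1[:, :, None]) / np.sqrt(v1[None, :, None] + v2[None, None, :])
    exceed = np.einsum("ti,tj,tij->t", w1, w2, ndtr(z))
    response = (exceed > 0.5).astype(int)
    return TwoAFCDataset(
        x1=x1,
        x2=x2,
        condition1=np.full(x1.size, conditions[0], dtype=object),
        condition2=np.full(x1.size, conditions[1], dtype=object),
        response=response,
        trial=np.arange(1, x1.size + 1),
    )
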