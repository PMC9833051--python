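"""Two-alternative forced-choice (2AFC) behavior of the ideal observer.

On each trial the observer draws independent measurements ``m1 ~ N(x1, sigma1^2)``
and ``m2 ~ N(x2, sigma2^2)``, forms the two posteriors under a shared prior, and
answers "yes" (stimulus 2 larger) when ``P(x2 > x1 | m1, m2) > 1/2``.  Repeating
over trials traces out the psychometric function ``p("yes" | x1, x2)``.

Three routes to ``p("yes")`` are implemented:

* ``sg_analytic`` — the cumulative-normal closed form available when the prior is
  a single Gaussian (estimates are then Gaussian and their difference is too).
* ``numeric``     — exact for any MoG prior: the posterior-comparison decision rule
  is evaluated in closed form over a 2-D measurement grid and the joint measurement
  density is integrated over the "yes" region.
* ``mog_approx``  — the analytic MoG approximation: posterior weights frozen at the
  expected measurements ``w_tilde_i(x1)``, ``w_tilde_j(x2)``, which makes both
  estimate distributions Gaussian and yields a cumulative-normal expression.

Also provided: PSE (point of subjective equality) and psychometric slope, and the
perceptual bias ratio (the ratio of effective shrinkage factors for the two
stimuli; 1 means veridical perception).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr

from .priors import (
    MoGPrior,
    adjusted_weights,
    adjusted_weights_grid,
    component_posterior_params,
)

__all__ = [
    "PsychometricCurve",
    "TwoAFCObserver",
    "bias_ratio",
    "decision",
    "grid_convergence_gap",
    "p_yes",
    "posterior_exceedance",
    "pse_and_slope",
    "psychometric_curve",
]

_SQRT_2PI = float(np.sqrt(2.0 * np.pi))


@dataclass(frozen=True)
class TwoAFCObserver:
    """Shared prior plus per-stimulus measurement-noise SDs ``sigma1``, ``sigma2``."""

    prior: MoGPrior
    sigma1: float
    sigma2: float

    def __post_init__(self):
        for name in ("sigma1", "sigma2"):
            s = getattr(self, name)
            if not (np.isfinite(s) and s > 0):
                raise ValueError(f"{name} must be a positive finite real, got {s}")
        object.__setattr__(self, "sigma1", float(self.sigma1))
        object.__setattr__(self, "sigma2", float(self.sigma2))

    def swapped(self) -> "TwoAFCObserver":
        return TwoAFCObserver(self.prior, self.sigma2, self.sigma1)


def posterior_exceedance(observer: TwoAFCObserver, m1: float, m2: float) -> float:
    """``P(x2 > x1 | m1, m2)`` in closed form.

    Both posteriors are Gaussian mixtures, so the probability that a draw from
    posterior 2 exceeds an independent draw from posterior 1 is a double sum of
    normal CDFs over component pairs::

        sum_ij w_i~(m1) w_j~(m2) Phi((mu_j2 - mu_i1) / sqrt(s_i1^2 + s_j2^2))
    """
    p = observer.prior
    a1, nt1 = component_posterior_params(p, observer.sigma1)
    a2, nt2 = component_posterior_params(p, observer.sigma2)
    w1 = adjusted_weights(p, observer.sigma1, m1)
    w2 = adjusted_weights(p, observer.sigma2, m2)
    mu1 = a1 * float(m1) + nt1
    mu2 = a2 * float(m2) + nt2
    v1 = a1 * observer.sigma1**2
    v2 = a2 * observer.sigma2**2
    z = (mu2[None, :] - mu1[:, None]) / np.sqrt(v1[:, None] + v2[None, :])
    return float(np.einsum("i,j,ij->", w1, w2, ndtr(z)))


def decision(
    observer: TwoAFCObserver,
    m1: float,
    m2: float,
    approx: bool = False,
    x1: float | None = None,
    x2: float | None = None,
) -> int:
    """Binary 2AFC response for a measurement pair.

    Default rule: 1 iff ``P(x2 > x1 | m1, m2)`` strictly exceeds 1/2 (ties give 0).
    With ``approx=True`` the frozen-weight rule is used instead: the two BLS
    estimates are computed with posterior weights frozen at the stimulus values
    ``x1``, ``x2`` (which must then be supplied), and the response is 1 iff the
    stimulus-2 estimate is strictly larger.
    """
    if approx:
        if x1 is None or x2 is None:
            raise ValueError("the approximate decision rule needs x1 and x2")
        p = observer.prior
        a1, nt1 = component_posterior_params(p, observer.sigma1)
        a2, nt2 = component_posterior_params(p, observer.sigma2)
        w1 = adjusted_weights(p, observer.sigma1, x1)
        w2 = adjusted_weights(p, observer.sigma2, x2)
        e1 = float(np.dot(w1, a1 * m1 + nt1))
        e2 = float(np.dot(w2, a2 * m2 + nt2))
        return int(e2 > e1)
    return int(posterior_exceedance(observer, m1, m2) > 0.5)


# ---------------------------------------------------------------------------
# numeric path: decision boundary on a measurement grid, reusable across stimuli
# ---------------------------------------------------------------------------


class NumericTwoAFC:
    """Precomputed decision rule of an observer on a 2-D measurement grid.

    The exceedance ``P(x2 > x1 | m1, m2)`` is evaluated in closed form at every
    grid node; for each ``m1`` row the crossings of the 0.5 level along ``m2``
    are located by linear interpolation.  ``p("yes" | x1, x2)`` then only
    requires integrating the Gaussian measurement densities over the "yes"
    region: exact normal CDFs along ``m2``, trapezoid along ``m1``.  The
    boundary depends on the observer alone, so one instance serves a whole
    sweep of stimulus values (the grids must cover ``x +/- 6 sigma``).
    """

    def __init__(self, observer: TwoAFCObserver, m1_grid, m2_grid):
        self.observer = observer
        self.m1_grid = np.asarray(m1_grid, dtype=float)
        self.m2_grid = np.asarray(m2_grid, dtype=float)
        p = observer.prior
        a1, nt1 = component_posterior_params(p, observer.sigma1)
        a2, nt2 = component_posterior_params(p, observer.sigma2)
        w1 = adjusted_weights_grid(p, observer.sigma1, self.m1_grid)
        w2 = adjusted_weights_grid(p, observer.sigma2, self.m2_grid)
        mu1 = a1 * self.m1_grid[:, None] + nt1
        mu2 = a2 * self.m2_grid[:, None] + nt2
        v1 = a1 * observer.sigma1**2
        v2 = a2 * observer.sigma2**2
        n1, n2 = self.m1_grid.size, self.m2_grid.size
        E = np.zeros((n1, n2))
        for i in range(p.n_components):
            for j in range(p.n_components):
                z = (mu2[None, :, j] - mu1[:, None, i]) / np.sqrt(v1[i] + v2[j])
                E += (w1[:, i, None] * w2[None, :, j]) * ndtr(z)
        self._classify(E)

    def _classify(self, E: np.ndarray) -> None:
        m2 = self.m2_grid
        S = E > 0.5
        trans = np.diff(S.astype(np.int8), axis=1)
        n_trans = np.count_nonzero(trans, axis=1)
        # simple rows: monotone "no -> yes" along m2 with a single crossing
        self.cross = np.full(self.m1_grid.size, np.nan)
        simple = np.zeros(self.m1_grid.size, dtype=bool)
        all_yes = S.all(axis=1)
        all_no = ~S.any(axis=1)
        self.cross[all_yes] = -np.inf
        self.cross[all_no] = np.inf
        simple |= all_yes | all_no
        one = (n_trans == 1) & ~simple
        if np.any(one):
            rows = np.nonzero(one)[0]
            ks = np.argmax(trans[rows] != 0, axis=1)
            up = trans[rows, ks] == 1
            r_up, k_up = rows[up], ks[up]
            e0 = E[r_up, k_up]
            e1 = E[r_up, k_up + 1]
            self.cross[r_up] = m2[k_up] + (0.5 - e0) * (m2[k_up + 1] - m2[k_up]) / (e1 - e0)
            simple[r_up] = True
        # anything else (downward or multiple crossings): interval list per row
        self.simple = simple
        self.general_rows: dict[int, list[tuple[float, float]]] = {}
        for r in np.nonzero(~simple)[0]:
            intervals = []
            row = E[r]
            inside = bool(S[r, 0])
            start = -np.inf if inside else None
            for k in range(len(m2) - 1):
                if S[r, k] != S[r, k + 1]:
                    c = m2[k] + (0.5 - row[k]) * (m2[k + 1] - m2[k]) / (row[k + 1] - row[k])
                    if inside:
                        intervals.append((start, c))
                        inside = False
                    else:
                        start = c
                        inside = True
            if inside:
                intervals.append((start, np.inf))
            self.general_rows[r] = intervals

    def p_yes(self, x1: float, x2: float) -> float:
        obs = self.observer
        m1 = self.m1_grid
        f1 = np.exp(-0.5 * ((m1 - x1) / obs.sigma1) ** 2) / (obs.sigma1 * _SQRT_2PI)
        inner = np.zeros_like(m1)
        with np.errstate(invalid="ignore"):
            inner[self.simple] = ndtr((x2 - self.cross[self.simple]) / obs.sigma2)
        for r, intervals in self.general_rows.items():
            acc = 0.0
            for a, b in intervals:
                hi = 1.0 if np.isinf(b) else ndtr((b - x2) / obs.sigma2)
                lo = 0.0 if np.isinf(a) else ndtr((a - x2) / obs.sigma2)
                acc += hi - lo
            inner[r] = acc
        return float(np.clip(np.trapezoid(f1 * inner, m1), 0.0, 1.0))


def _numeric_engine(
    observer: TwoAFCObserver, x1: float, x2_lo: float, x2_hi: float, n_grid: int
) -> NumericTwoAFC:
    m1 = np.linspace(x1 - 6 * observer.sigma1, x1 + 6 * observer.sigma1, n_grid)
    m2 = np.linspace(x2_lo - 6 * observer.sigma2, x2_hi + 6 * observer.sigma2, n_grid)
    return NumericTwoAFC(observer, m1, m2)


def _sg_analytic_p_yes(observer: TwoAFCObserver, x1: float, x2: float) -> float:
    prior = observer.prior
    if prior.n_components != 1:
        raise ValueError("sg_analytic requires a single-Gaussian prior (C = 1)")
    a1, nt1 = component_posterior_params(prior, observer.sigma1)
    a2, nt2 = component_posterior_params(prior, observer.sigma2)
    num = a2[0] * x2 + nt2[0] - a1[0] * x1 - nt1[0]
    sd = np.sqrt(a1[0] ** 2 * observer.sigma1**2 + a2[0] ** 2 * observer.sigma2**2)
    return float(ndtr(num / sd))


def _mog_approx_stats(observer: TwoAFCObserver, x1: float, x2: float):
    prior = observer.prior
    a1, nt1 = component_posterior_params(prior, observer.sigma1)
    a2, nt2 = component_posterior_params(prior, observer.sigma2)
    w1 = adjusted_weights(prior, observer.sigma1, x1)
    w2 = adjusted_weights(prior, observer.sigma2, x2)
    mean1 = float(np.dot(w1, a1 * x1 + nt1))
    mean2 = float(np.dot(w2, a2 * x2 + nt2))
    sd = float(
        np.sqrt(
            observer.sigma1**2 * np.dot(w1, a1) ** 2
            + observer.sigma2**2 * np.dot(w2, a2) ** 2
        )
    )
    return mean1, mean2, sd


def _mog_approx_p_yes(observer: TwoAFCObserver, x1: float, x2: float) -> float:
    mean1, mean2, sd = _mog_approx_stats(observer, x1, x2)
    return float(ndtr((mean2 - mean1) / sd))


def _mog_approx_p_yes_batch(observer: TwoAFCObserver, x1, x2) -> np.ndarray:
    """Vectorized frozen-weight approximation over arrays of stimulus pairs."""
    prior = observer.prior
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    a1, nt1 = component_posterior_params(prior, observer.sigma1)
    a2, nt2 = component_posterior_params(prior, observer.sigma2)
    w1 = adjusted_weights_grid(prior, observer.sigma1, x1)
    w2 = adjusted_weights_grid(prior, observer.sigma2, x2)
    mean1 = np.einsum("ti,ti->t", w1, a1 * x1[:, None] + nt1)
    mean2 = np.einsum("tj,tj->t", w2, a2 * x2[:, None] + nt2)
    sd = np.sqrt(
        observer.sigma1**2 * (w1 @ a1) ** 2 + observer.sigma2**2 * (w2 @ a2) ** 2
    )
    return ndtr((mean2 - mean1) / sd)


Method = Literal["numeric", "sg_analytic", "mog_approx"]


def p_yes_batch(observer: TwoAFCObserver, x1, x2, method: Method) -> np.ndarray:
    """Vectorized ``p_yes`` over paired stimulus arrays (analytic methods only)."""
    if method == "sg_analytic":
        if observer.prior.n_components != 1:
            raise ValueError("sg_analytic requires a single-Gaussian prior (C = 1)")
        return np.clip(_mog_approx_p_yes_batch(observer, x1, x2), 0.0, 1.0)
    if method == "mog_approx":
        return np.clip(_mog_approx_p_yes_batch(observer, x1, x2), 0.0, 1.0)
    raise ValueError("p_yes_batch supports the analytic methods only")


def p_yes(
    observer: TwoAFCObserver,
    x1: float,
    x2: float,
    method: Method = "numeric",
    n_grid: int = 801,
) -> float:
    """Probability of responding "yes" (stimulus 2 judged larger) at ``(x1, x2)``."""
    x1, x2 = float(x1), float(x2)
    if method == "numeric":
        return _numeric_engine(observer, x1, x2, x2, n_grid).p_yes(x1, x2)
    if method == "sg_analytic":
        return float(np.clip(_sg_analytic_p_yes(observer, x1, x2), 0.0, 1.0))
    if method == "mog_approx":
        return float(np.clip(_mog_approx_p_yes(observer, x1, x2), 0.0, 1.0))
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class PsychometricCurve:
    """``p("yes")`` as a function of the comparison stimulus ``x2``."""

    x1: float
    x2_grid: np.ndarray
    p_yes: np.ndarray
    method: str

    def to_text(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack(
                [np.full_like(self.x2_grid, self.x1), self.x2_grid, self.p_yes]
            ),
            header=f"x1\tx2\tp_yes  (method={self.method})",
            delimiter="\t",
            comments="",
        )


def psychometric_curve(
    observer: TwoAFCObserver,
    x1: float,
    x2_values: Sequence[float],
    method: Method = "numeric",
    n_grid: int = 801,
) -> PsychometricCurve:
    """Evaluate ``p("yes")`` over an ``x2`` sweep (numeric boundary built once)."""
    x2_values = np.asarray(x2_values, dtype=float)
    if method == "numeric":
        engine = _numeric_engine(
            observer, x1, float(x2_values.min()), float(x2_values.max()), n_grid
        )
        p = np.array([engine.p_yes(x1, x2) for x2 in x2_values])
    else:
        p = np.array([p_yes(observer, x1, x2, method=method) for x2 in x2_values])
    return PsychometricCurve(x1=float(x1), x2_grid=x2_values, p_yes=p, method=method)


def pse_and_slope(
    observer: TwoAFCObserver,
    x1: float,
    method: Method = "numeric",
    n_grid: int = 801,
    bracket: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Point of subjective equality and psychometric slope at the PSE.

    The PSE is the root of ``p("yes") - 1/2`` in ``x2``, found by bisection to
    1e-6 stimulus units.  For the cumulative-normal methods the slope is the
    analytic ``1 / (sigma_diff sqrt(2 pi))``, the standard sensitivity metric
    expressed per unit of the estimate-difference mean; the numeric method
    returns the central-difference slope per unit ``x2`` (which differs from
    the analytic value by the factor ``d mu_diff / d x2``, the effective
    shrinkage of stimulus 2).
    """
    x1 = float(x1)
    sig = float(np.hypot(observer.sigma1, observer.sigma2))
    if bracket is None:
        span = 6.0 * sig + 2.0 * abs(x1) + 1.0
        bracket = (x1 - span, x1 + span)
    lo, hi = bracket

    if method == "numeric":
        engine = _numeric_engine(observer, x1, lo, hi, n_grid)
        f = lambda x2: engine.p_yes(x1, x2) - 0.5
    else:
        f = lambda x2: p_yes(observer, x1, x2, method=method) - 0.5

    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(
            "p_yes - 0.5 does not change sign on the search interval: "
            f"p({lo:.4g}) = {flo + 0.5:.4g}, p({hi:.4g}) = {fhi + 0.5:.4g}"
        )
    pse = float(brentq(f, lo, hi, xtol=1e-6))

    if method == "sg_analytic":
        a1, _ = component_posterior_params(observer.prior, observer.sigma1)
        a2, _ = component_posterior_params(observer.prior, observer.sigma2)
        sd = float(
            np.sqrt(a1[0] ** 2 * observer.sigma1**2 + a2[0] ** 2 * observer.sigma2**2)
        )
        slope = 1.0 / (sd * _SQRT_2PI)
    elif method == "mog_approx":
        _, _, sd = _mog_approx_stats(observer, x1, pse)
        slope = 1.0 / (sd * _SQRT_2PI)
    else:
        h = 1e-4 * max(1.0, abs(pse))
        slope = (f(pse + h) - f(pse - h)) / (2 * h)
    return pse, float(slope)


def bias_ratio(
    observer: TwoAFCObserver, x1: float, x2: float, squared: bool = False
) -> float:
    """Perceptual bias as the ratio of effective shrinkage factors.

    ``(sum_i w_i~(x1) alpha_i(sigma1)) / (sum_j w_j~(x2) alpha_j(sigma2))``;
    reduces to ``alpha1 / alpha2`` for a single-Gaussian prior and equals 1 for
    an unbiased configuration (``sigma1 = sigma2``, ``x1 = x2``).  The
    ``squared=True`` variant returns the ratio of the squared sums.
    """
    prior = observer.prior
    a1, _ = component_posterior_params(prior, observer.sigma1)
    a2, _ = component_posterior_params(prior, observer.sigma2)
    w1 = adjusted_weights(prior, observer.sigma1, x1)
    w2 = adjusted_weights(prior, observer.sigma2, x2)
    num = float(np.dot(w1, a1))
    den = float(np.dot(w2, a2))
    ratio = num / den
    return ratio**2 if squared else ratio


def grid_convergence_gap(
    observer: TwoAFCObserver, x1: float, x2: float, n_grid: int = 801
) -> float:
    """|p_yes at ``n_grid``  -  p_yes at doubled resolution| for the numeric path."""
    p_a = p_yes(observer, x1, x2, method="numeric", n_grid=n_grid)
    p_b = p_yes(observer, x1, x2, method="numeric", n_grid=2 * n_grid - 1)
    return abs(p_a - p_b)
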