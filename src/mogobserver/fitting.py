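"""Maximum-likelihood recovery of observer parameters from behavioral data.

The observable parameter vector is ``theta = {w_i, nu_i, gamma_i, sigma_c}``: the
prior mixture plus one measurement-noise SD per experimental condition.  The
negative log-likelihoods of point-estimation and 2AFC trial tables are exposed as
plain functions (:func:`nll_estimation`, :func:`nll_2afc`) and minimized by
multi-start numerical optimization over smooth unconstrained coordinates:
softmax-coded weights (first logit pinned at zero), log SDs, raw means.

Unrestricted mixtures are weakly identified, so two constrained prior
parameterizations are provided alongside ``free``:

* ``zero_mean`` — all component means pinned at zero with a fixed SD ladder;
  suits monotonically decaying, heavy-tailed priors (only the weights and the
  noise SDs are fitted, optionally the ladder itself).
* ``tiled``     — fixed, evenly spaced component means and SDs; only the weights
  are fitted, approximating arbitrary prior shapes including bimodal ones.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from .datasets import EstimationDataset, TwoAFCDataset
from .estimation import build_estimator_map, estimate_distribution, invert_estimator_map
from .priors import MoGPrior, ObserverModel, component_posterior_params, default_grid
from .psychometric import NumericTwoAFC, TwoAFCObserver, p_yes, p_yes_batch

__all__ = [
    "FitResult",
    "PriorParameterization",
    "fit_mle",
    "nll_2afc",
    "nll_estimation",
]

logger = logging.getLogger("mogobserver")

_LOG_FLOOR = np.log(1e-12)  # out-of-range estimates keep the objective finite
_P_CLIP = 1e-9


@dataclass(frozen=True)
class PriorParameterization:
    """Which observer parameters are free, and how the prior is constrained.

    Parameters
    ----------
    mode : {"free", "zero_mean", "tiled"}
        ``free`` fits weights, means, and SDs of every component; ``zero_mean``
        pins all means at zero and (by default) fixes the SDs to ``gammas``;
        ``tiled`` fixes both means and SDs and fits only the weights.
    n_components : int
    gammas, means : fixed component SDs / means where the mode requires them.
    fit_gammas : bool
        In ``zero_mean`` mode, optimize the SD ladder too.
    conditions : labels of the noise conditions; one ``sigma`` is fitted per label.
    """

    mode: Literal["free", "zero_mean", "tiled"]
    n_components: int
    gammas: tuple[float, ...] | None = None
    means: tuple[float, ...] | None = None
    fit_gammas: bool = False
    conditions: tuple[str, ...] = ("c1",)

    def __post_init__(self):
        if self.mode not in ("free", "zero_mean", "tiled"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.mode == "tiled":
            if self.gammas is None or self.means is None:
                raise ValueError("tiled mode requires fixed means and gammas")
            if self.fit_gammas:
                raise ValueError("tiled mode optimizes weights only")
        if self.mode == "zero_mean" and not self.fit_gammas and self.gammas is None:
            raise ValueError("zero_mean mode requires a gamma ladder unless fit_gammas")
        for name in ("gammas", "means"):
            v = getattr(self, name)
            if v is not None:
                v = tuple(float(u) for u in v)
                if len(v) != self.n_components:
                    raise ValueError(f"{name} must have n_components entries")
                object.__setattr__(self, name, v)
        object.__setattr__(self, "conditions", tuple(self.conditions))

    # --- layout of the unconstrained vector --------------------------------
    @property
    def _free_means(self) -> bool:
        return self.mode == "free"

    @property
    def _free_gammas(self) -> bool:
        return self.mode == "free" or (self.mode == "zero_mean" and self.fit_gammas)

    @property
    def n_params(self) -> int:
        c = self.n_components
        n = c - 1  # weight logits, first pinned at 0
        if self._free_gammas:
            n += c
        if self._free_means:
            n += c
        return n + len(self.conditions)

    def unpack(self, vector) -> ObserverModel:
        """Unconstrained vector -> constrained :class:`ObserverModel`."""
        v = np.asarray(vector, dtype=float)
        if v.size != self.n_params:
            raise ValueError(f"expected {self.n_params} parameters, got {v.size}")
        c = self.n_components
        k = 0
        logits = np.concatenate([[0.0], v[k:k + c - 1]])
        k += c - 1
        w = np.exp(logits - logits.max())
        w /= w.sum()
        if self._free_gammas:
            gammas = np.exp(v[k:k + c]); k += c
        else:
            gammas = np.asarray(self.gammas, dtype=float)
        if self._free_means:
            means = v[k:k + c]; k += c
        elif self.mode == "zero_mean":
            means = np.zeros(c)
        else:
            means = np.asarray(self.means, dtype=float)
        sigmas = {lab: float(np.exp(s)) for lab, s in zip(self.conditions, v[k:])}
        return ObserverModel(prior=MoGPrior(w, means, gammas), sigmas=sigmas)

    def pack(self, model: ObserverModel) -> np.ndarray:
        """Constrained model -> unconstrained vector (inverse of :meth:`unpack`)."""
        prior = model.prior
        if prior.n_components != self.n_components:
            raise ValueError("component count mismatch")
        logw = np.log(prior.weights)
        parts = [logw[1:] - logw[0]]
        if self._free_gammas:
            parts.append(np.log(prior.sds))
        if self._free_means:
            parts.append(prior.means)
        parts.append([np.log(model.sigmas[lab]) for lab in self.conditions])
        return np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in parts])

    def random_init(self, rng: np.random.Generator, scale: float = 1.0) -> np.ndarray:
        """A seeded random starting vector on the unconstrained coordinates."""
        c = self.n_components
        parts = [rng.normal(0.0, 1.0, size=c - 1)]
        if self._free_gammas:
            parts.append(np.log(scale * rng.uniform(0.3, 3.0, size=c)))
        if self._free_means:
            parts.append(rng.normal(0.0, scale, size=c))
        parts.append(np.log(scale * rng.uniform(0.2, 1.5, size=len(self.conditions))))
        return np.concatenate(parts)


# ---------------------------------------------------------------------------
# negative log-likelihoods
# ---------------------------------------------------------------------------


def _estimation_grid(prior: MoGPrior, sigma: float, data_x, data_xhat) -> np.ndarray:
    """Measurement grid for the numeric likelihood.

    Starts from the package grid convention and extends the span to cover the
    measurements compatible with the observed stimuli, while keeping the default
    grid *spacing* (a coarser table would smear sharp features of T and distort
    the change-of-variables density).  Estimates that T cannot reach on this
    span are handled by the floored penalty, not by stretching the grid.
    """
    base = default_grid(prior, sigma)
    spacing = base[1] - base[0]
    lo = min(base[0], float(np.min(data_x)) - 4 * sigma)
    hi = max(base[-1], float(np.max(data_x)) + 4 * sigma)
    n = min(int(np.ceil((hi - lo) / spacing)) + 1, 8001)
    return np.linspace(lo, hi, n)


def nll_estimation(
    data: EstimationDataset,
    model: ObserverModel,
    method: Literal["exact_sg", "numeric", "approx"] = "numeric",
) -> float:
    """Negative log-likelihood of point-estimation trials under an observer model.

    Sums ``-log p(xhat_t | x_t)`` over trials, grouped by condition.  The numeric
    path inverts the tabulated estimator map and applies the change-of-variables
    density (including the log-derivative term); estimates outside the invertible
    range contribute a floored log density of ``log(1e-12)`` and are counted in a
    log record rather than silently dropped.
    """
    total = 0.0
    n_out = 0
    for cond in data.conditions:
        if cond not in model.sigmas:
            raise ValueError(f"model has no sigma for condition {cond!r}")
        sigma = model.sigmas[cond]
        mask = data.condition == cond
        x, xhat = data.x[mask], data.xhat[mask]
        if method in ("exact_sg", "approx"):
            if method == "exact_sg" and model.prior.n_components != 1:
                raise ValueError("exact_sg requires a single-Gaussian prior (C = 1)")
            logp = np.array(
                [
                    estimate_distribution(model.prior, sigma, xi, method=method).logpdf(xh)
                    for xi, xh in zip(x, xhat)
                ]
            )
        elif method == "numeric":
            emap = build_estimator_map(
                model.prior, sigma, m_grid=_estimation_grid(model.prior, sigma, x, xhat)
            )
            if not emap.monotone_flag:
                raise ValueError(
                    "estimator map is not strictly increasing for condition "
                    f"{cond!r}; the numeric likelihood is undefined"
                )
            lo, hi = emap.xhat_grid[0], emap.xhat_grid[-1]
            inside = (xhat >= lo) & (xhat <= hi)
            logp = np.full(x.size, _LOG_FLOOR)
            if np.any(inside):
                m_inv, deriv = invert_estimator_map(emap, xhat[inside])
                logp[inside] = norm.logpdf(m_inv, loc=x[inside], scale=sigma) + np.log(
                    np.abs(deriv)
                )
            n_out += int(np.count_nonzero(~inside))
        else:
            raise ValueError(f"unknown method {method!r}")
        total -= float(np.sum(np.maximum(logp, _LOG_FLOOR)))
    if n_out:
        logger.warning(
            "%d estimate(s) outside the invertible range; log-density floored", n_out
        )
    return total


def nll_2afc(
    data: TwoAFCDataset,
    model: ObserverModel,
    method: Literal["numeric", "sg_analytic", "mog_approx"] = "mog_approx",
    n_grid: int = 801,
) -> float:
    """Bernoulli negative log-likelihood of 2AFC responses.

    ``-sum_t [T_t log p_yes + (1 - T_t) log(1 - p_yes)]`` with probabilities
    clipped to ``[1e-9, 1 - 1e-9]`` before the logs.  Trials are grouped by
    condition pair; the numeric path builds one decision boundary per pair.
    """
    probs = np.empty(data.n_trials)
    pairs = np.char.add(np.char.add(data.condition1.astype(str), "\x1f"), data.condition2.astype(str))
    for pair in np.unique(pairs):
        c1, c2 = pair.split("\x1f")
        for c in (c1, c2):
            if c not in model.sigmas:
                raise ValueError(f"model has no sigma for condition {c!r}")
        obs = TwoAFCObserver(model.prior, model.sigmas[c1], model.sigmas[c2])
        mask = pairs == pair
        x1, x2 = data.x1[mask], data.x2[mask]
        if method == "numeric":
            m1 = np.linspace(x1.min() - 6 * obs.sigma1, x1.max() + 6 * obs.sigma1, n_grid)
            m2 = np.linspace(x2.min() - 6 * obs.sigma2, x2.max() + 6 * obs.sigma2, n_grid)
            engine = NumericTwoAFC(obs, m1, m2)
            probs[mask] = [engine.p_yes(a, b) for a, b in zip(x1, x2)]
        else:
            probs[mask] = p_yes_batch(obs, x1, x2, method=method)
    probs = np.clip(probs, _P_CLIP, 1.0 - _P_CLIP)
    resp = data.response.astype(float)
    return float(-np.sum(resp * np.log(probs) + (1.0 - resp) * np.log1p(-probs)))


# ---------------------------------------------------------------------------
# multi-start maximum-likelihood fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of a multi-start maximum-likelihood fit."""

    model: ObserverModel
    nll: float
    per_start_nlls: list[float]
    converged: bool
    n_starts: int
    seed: int | None
    message: str
    params: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "nll": self.nll,
            "per_start_nlls": self.per_start_nlls,
            "converged": self.converged,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "message": self.message,
        }


def fit_mle(
    data: EstimationDataset | TwoAFCDataset,
    parameterization: PriorParameterization,
    method: str = "mog_approx",
    n_starts: int = 10,
    seed: int | None = None,
    x0: Sequence[float] | None = None,
    maxiter: int | None = None,
) -> FitResult:
    """Fit observer parameters by multi-start minimization of the relevant NLL.

    The objective (:func:`nll_estimation` for estimation data,
    :func:`nll_2afc` for 2AFC data) is minimized with Nelder-Mead on the smooth
    unconstrained coordinates, from ``n_starts`` seeded random initializations
    (plus ``x0`` if given).  The best start wins.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    is_2afc = isinstance(data, TwoAFCDataset)
    if is_2afc and len(parameterization.conditions) == 1:
        warnings.warn(
            "2AFC data with a single noise condition: the prior scale and sigma "
            "trade off and are not jointly identifiable; use two conditions of "
            "differing reliability",
            UserWarning,
            stacklevel=2,
        )
    missing = set(data.conditions) - set(parameterization.conditions)
    if missing:
        raise ValueError(f"parameterization lacks conditions {sorted(missing)}")

    if is_2afc:
        scale = float(np.std(np.concatenate([data.x1, data.x2]))) or 1.0

        def objective(v):
            try:
                return nll_2afc(data, parameterization.unpack(v), method=method)
            except (ValueError, FloatingPointError):
                return 1e12
    else:
        scale = float(np.std(data.x)) or 1.0

        def objective(v):
            try:
                return nll_estimation(data, parameterization.unpack(v), method=method)
            except (ValueError, FloatingPointError):
                return 1e12

    rng = np.random.default_rng(seed)
    starts = [] if x0 is None else [np.asarray(x0, dtype=float)]
    while len(starts) < n_starts:
        starts.append(parameterization.random_init(rng, scale=scale))

    options = {"xatol": 1e-6, "fatol": 1e-8}
    if maxiter is not None:
        options["maxiter"] = maxiter
    best = None
    per_start = []
    any_converged = False
    message = ""
    for v0 in starts:
        res = minimize(objective, v0, method="Nelder-Mead", options=options)
        per_start.append(float(res.fun))
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best, message = res, str(res.message)
    model = parameterization.unpack(best.x)
    return FitResult(
        model=model,
        nll=float(best.fun),
        per_start_nlls=per_start,
        converged=any_converged,
        n_starts=len(starts),
        seed=seed,
        message=message,
        params=np.asarray(best.x),
    )
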