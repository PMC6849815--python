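"""Time-simultaneous confidence bands for the cumulative baseline hazard.

Given a fitted Cox model and a multiplier-bootstrap ensemble, a level
``1 - alpha`` band for ``Lambda_0`` on an interval ``[t1, t2]`` is

    phi^{-1}[ phi{Lambda_hat(t)} -+ c*(alpha) / g_n(t) ],

where ``phi`` is the identity or the log transform and ``g_n`` a weight
function.  The supported weights are

    equal precision:  g(t) = sqrt(n) / sigma(t)        (id)
                      g(t) = sqrt(n) Lambda_hat(t) / sigma(t)   (log)
    Hall-Wellner:     g(t) = sqrt(n) / {1 + sigma^2(t)}          (id)
                      g(t) = sqrt(n) Lambda_hat(t) / {1 + sigma^2(t)}  (log)

with ``sigma^2(t)`` the bootstrap ensemble's empirical variance of
``sqrt(n){Lambda* - Lambda_hat}`` (its counterpart of the plug-in variance;
the plug-in estimator itself can be requested by passing the fit as the
variance source).  The critical value ``c*(alpha)`` is the empirical
``(1 - alpha)`` quantile across replicates of

    sup_{t in grid} g*(t) |Lambda*(t) - Lambda_hat(t)|

computed with the *untransformed* weight; the same critical value is reused
for the log-transformed band (the naive log-scale sup statistic is
numerically unstable, and the two are asymptotically equivalent).

The supremum grid is the set of event times inside ``[t1, t2]`` plus the two
endpoints: the deviation process is a step function, so its supremum is
attained there.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bootstrap import BootstrapEnsemble
from .cox import CoxFit
from .stepfun import StepFunction

__all__ = [
    "BandSpec", "ConfidenceBand", "weight", "critical_value",
    "build_band", "contains", "median_width", "band_grid",
]

_TRANSFORMS = ("identity", "log")
_WEIGHTS = ("equal_precision", "hall_wellner")


@dataclass(frozen=True)
class BandSpec:
    """Band configuration: interval, transform, weight type, level."""
    interval: tuple
    transform: str = "log"
    weight: str = "hall_wellner"
    alpha: float = 0.05

    def __post_init__(self):
        t1, t2 = self.interval
        if not (0 < t1 < t2):
            raise ValueError("need 0 < t1 < t2")
        if self.transform not in _TRANSFORMS:
            raise ValueError(f"transform must be one of {_TRANSFORMS}")
        if self.weight not in _WEIGHTS:
            raise ValueError(f"weight must be one of {_WEIGHTS}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class ConfidenceBand:
    """A simultaneous band on a time grid: lower(t) <= Lambda_0(t) <= upper(t)."""
    times: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    critical_value: float
    spec: BandSpec
    n_replicates: int = 0
    dropped: int = 0

    def width_at(self, t) -> np.ndarray:
        """Band width at arbitrary times (right-continuous step interpolation)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.clip(np.searchsorted(self.times, t, side="right") - 1, 0, None)
        return (self.upper - self.lower)[idx]

    def _evaluate_target(self, target):
        if callable(target):
            return np.asarray(target(self.times), dtype=float)
        raise TypeError("target must be callable (e.g. a StepFunction)")


def band_grid(event_times: np.ndarray, interval) -> np.ndarray:
    """Event times within the interval plus its endpoints, sorted unique."""
    t1, t2 = interval
    inside = event_times[(event_times >= t1) & (event_times <= t2)]
    grid = np.unique(np.concatenate([[t1], inside, [t2]]))
    return grid


def _sigma2(source, t) -> np.ndarray:
    """Variance function of sqrt(n)(Lambda_hat - Lambda_0) from fit or ensemble."""
    if isinstance(source, BootstrapEnsemble):
        return np.atleast_1d(source.variance_at(t))
    if isinstance(source, CoxFit):
        return np.atleast_1d(source.variance(t))
    raise TypeError("variance source must be a CoxFit or BootstrapEnsemble")


def _lambda_hat(source, t) -> np.ndarray:
    if isinstance(source, BootstrapEnsemble):
        return source.lambda_hat_at(t)
    return np.atleast_1d(source.breslow(t))


def weight(spec: BandSpec, source, t) -> np.ndarray:
    """Evaluate the band's weight function g_n(t) for the requested spec.

    ``source`` supplies the variance: a :class:`CoxFit` gives the plug-in
    ``sigma_hat^2``, a :class:`BootstrapEnsemble` its bootstrap counterpart.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    sigma2 = _sigma2(source, t)
    n = source.n
    if spec.weight == "equal_precision":
        bad = sigma2 <= 0
        if np.any(bad):
            raise ValueError(
                f"equal-precision weight undefined: sigma^2(t) = 0 at t = "
                f"{t[bad][0]:g}")
        g = np.sqrt(n) / np.sqrt(sigma2)
    else:
        g = np.sqrt(n) / (1.0 + sigma2)
    if spec.transform == "log":
        lam = _lambda_hat(source, t)
        bad = lam <= 0
        if np.any(bad):
            raise ValueError(
                f"log-transform weight undefined: Lambda_hat(t) = 0 at t = "
                f"{t[bad][0]:g}")
        g = g * lam
    return g


def _untransformed(spec: BandSpec) -> BandSpec:
    return BandSpec(spec.interval, "identity", spec.weight, spec.alpha)


def _quantile(values: np.ndarray, alpha: float) -> float:
    """Right-continuous inverted-ECDF quantile: order statistic ceil((1-a)B)."""
    values = np.sort(np.asarray(values, dtype=float))
    B = values.size
    if B == 0:
        raise ValueError("no values to take a quantile of")
    k = int(np.ceil((1.0 - alpha) * B))
    return float(values[max(k, 1) - 1])


def critical_value(ensemble: BootstrapEnsemble, fit: CoxFit,
                   spec: BandSpec) -> float:
    """(1-alpha) quantile of sup_t g*(t)|Lambda*(t) - Lambda_hat(t)| over replicates."""
    grid = band_grid(ensemble.times, spec.interval)
    if grid.size == 0:
        raise ValueError("empty supremum grid")
    g = weight(_untransformed(spec), ensemble, grid)
    star = ensemble.lambda_star_at(grid)            # (T, Bc)
    if star.shape[1] == 0:
        raise ValueError("no converged replicates in ensemble")
    hat = ensemble.lambda_hat_at(grid)
    sups = np.max(g[:, None] * np.abs(star - hat[:, None]), axis=0)
    return _quantile(sups, spec.alpha)


def build_band(fit: CoxFit, ensemble: BootstrapEnsemble,
               spec: BandSpec) -> ConfidenceBand:
    """Assemble the simultaneous band for Lambda_0 on the spec's interval."""
    grid = band_grid(ensemble.times, spec.interval)
    c = critical_value(ensemble, fit, spec)
    estimate = ensemble.lambda_hat_at(grid)
    g = weight(spec, ensemble, grid)
    if spec.transform == "identity":
        half = c / g
        lower = np.clip(estimate - half, 0.0, None)
        upper = estimate + half
    else:
        lower = estimate * np.exp(-c / g)
        upper = estimate * np.exp(c / g)
    return ConfidenceBand(grid, estimate, lower, upper, c, spec,
                          n_replicates=int(np.sum(ensemble.converged)),
                          dropped=ensemble.dropped)


def contains(band: ConfidenceBand, target) -> bool:
    """True iff lower(t) <= target(t) <= upper(t) at every grid time."""
    vals = band._evaluate_target(target)
    return bool(np.all((band.lower <= vals) & (vals <= band.upper)))


def median_width(bands, grid) -> np.ndarray:
    """Pointwise median of band widths across repetitions, on a common grid."""
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    widths = np.stack([b.width_at(grid) for b in bands], axis=0)
    return np.median(widths, axis=0)


# ----------------------------------------------------------------------
# Generic band core reused for plug-in functionals (survival, CIF, ...).
# ----------------------------------------------------------------------
def band_from_paths(times: np.ndarray, estimate: np.ndarray,
                    paths: np.ndarray, n: int, spec: BandSpec,
                    positive: bool = True) -> ConfidenceBand:
    """Band for any trajectory from its bootstrap replicate paths.

    ``paths`` has shape (T, B): one bootstrap realization of the trajectory
    per column.  The ensemble variance, sup-statistic critical value and band
    assembly mirror the cumulative-hazard band exactly.
    """
    times = np.asarray(times, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    dev = paths - estimate[:, None]
    if paths.shape[1] < 2:
        raise ValueError("need at least 2 replicate paths")
    sigma2 = n * np.var(dev, axis=1, ddof=1)
    if spec.weight == "equal_precision":
        if np.any(sigma2 <= 0):
            raise ValueError("equal-precision weight undefined: zero variance on grid")
        g = np.sqrt(n) / np.sqrt(sigma2)
    else:
        g = np.sqrt(n) / (1.0 + sigma2)
    sups = np.max(g[:, None] * np.abs(dev), axis=0)
    c = _quantile(sups, spec.alpha)
    if spec.transform == "identity":
        half = c / g
        lower = estimate - half
        upper = estimate + half
        if positive:
            lower = np.clip(lower, 0.0, None)
    else:
        if np.any(estimate <= 0):
            raise ValueError("log transform requires a positive estimate on the grid")
        gl = g * estimate
        lower = estimate * np.exp(-c / gl)
        upper = estimate * np.exp(c / gl)
    return ConfidenceBand(times, estimate, lower, upper, c, spec,
                          n_replicates=paths.shape[1])
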