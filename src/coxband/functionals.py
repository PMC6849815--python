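"""Plug-in functionals of (Lambda_hat, beta_hat) and their bootstrap uncertainty.

Because the multiplier bootstrap mimics the joint law of the parameter and
baseline estimators, any Hadamard-differentiable functional of the pair can
be bootstrapped by plugging each replicate (beta*, Lambda*) into the
functional.  Implemented here:

* covariate-conditional survival ``S(t|X) = exp{-Lambda_0(t) e^{X'beta}}``,
* restricted mean life ``Psi = int_0^tau S(s|X) ds = E{min(T, tau)|X}``
  (and differences between covariate profiles),
* the two-cause competing-risks cumulative incidence built from two
  cause-specific Cox fits whose bootstraps are resampled independently.

Symmetric confidence intervals use the (1-alpha) quantile of
``|Psi* - Psi_hat|`` across replicates; bands reuse the sup-statistic
machinery with the functional's replicate paths.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bands import BandSpec, ConfidenceBand, band_from_paths, band_grid
from .bootstrap import BootstrapEnsemble, MultiplierSpec, run_ensemble
from .cox import CoxFit, fit_beta
from .data import SurvivalSample
from .stepfun import StepFunction

__all__ = [
    "CovariateProfile", "CompetingRisksFit", "survival", "restricted_mean",
    "restricted_mean_difference", "functional_ci", "cumulative_incidence",
    "functional_band", "survival_path", "cumulative_incidence_path",
]


@dataclass(frozen=True)
class CovariateProfile:
    """Fixed covariate values at which to evaluate predictions."""
    X: np.ndarray

    def __init__(self, X):
        object.__setattr__(self, "X", np.atleast_1d(np.asarray(X, dtype=float)))


def _profile(X) -> np.ndarray:
    if isinstance(X, CovariateProfile):
        return X.X
    return np.atleast_1d(np.asarray(X, dtype=float))


def _risk_score(beta, X) -> float:
    return float(np.exp(np.clip(_profile(X) @ np.atleast_1d(beta), -700, 700)))


def survival(fit: CoxFit, X, t):
    """Predicted survival ``exp{-Lambda_hat(t) exp(X'beta_hat)}``."""
    return np.exp(-np.asarray(fit.breslow(t)) * _risk_score(fit.beta, X))


def restricted_mean(fit_or_theta, X, tau_r: float) -> float:
    """Restricted mean life ``int_0^tau_r exp{-Lambda_hat(s) e^{X'beta}} ds``.

    Accepts a :class:`CoxFit` or a ``(beta, cumhaz_step_function)`` pair.
    The survival step function is integrated exactly segment by segment.
    """
    beta, ch = _theta(fit_or_theta)
    risk = _risk_score(beta, X)
    keep = ch.times < tau_r
    cuts = np.concatenate([[0.0], ch.times[keep], [tau_r]])
    lam = np.concatenate([[0.0], ch.values[keep]])
    surv = np.exp(-lam * risk)
    return float(np.sum(np.diff(cuts) * surv))


def restricted_mean_difference(fit_or_theta, X1, X2, tau_r: float) -> float:
    """Difference in restricted mean life between two covariate profiles."""
    return (restricted_mean(fit_or_theta, X1, tau_r)
            - restricted_mean(fit_or_theta, X2, tau_r))


def _theta(obj):
    """Normalize a CoxFit / (beta, StepFunction) pair to (beta, stepfun)."""
    if isinstance(obj, CoxFit):
        return obj.beta, obj.breslow
    beta, ch = obj
    return np.atleast_1d(np.asarray(beta, dtype=float)), ch


def _replicate_thetas(ensembles):
    """Yield per-replicate theta tuples across one or more ensembles.

    Replicates are matched by column; only columns converged in every
    ensemble are used.
    """
    if isinstance(ensembles, BootstrapEnsemble):
        ensembles = (ensembles,)
    mask = np.logical_and.reduce([e.converged for e in ensembles])
    cols = np.flatnonzero(mask)
    for b in cols:
        yield tuple(
            (e.beta_star[b],
             StepFunction(e.times, np.diff(e.lambda_star[:, b], prepend=0.0)))
            for e in ensembles)


def functional_ci(ensembles, functional, alpha: float = 0.05,
                  min_replicates: int = 100):
    """Symmetric bootstrap confidence interval for a scalar functional.

    ``functional`` maps one theta tuple -- ``((beta, cumhaz), ...)``, one
    entry per ensemble -- to a float.  The interval is
    ``estimate -+ q*`` with ``q*`` the (1-alpha) empirical quantile of
    ``|Psi* - Psi_hat|`` over replicates.
    """
    from .bands import _quantile
    if isinstance(ensembles, BootstrapEnsemble):
        ensembles = (ensembles,)
    estimate = functional(tuple((e.fit.beta, e.fit.breslow) for e in ensembles))
    stars = np.array([functional(th) for th in _replicate_thetas(ensembles)])
    if stars.size < min_replicates:
        raise ValueError(
            f"only {stars.size} converged replicates; need >= {min_replicates}")
    q = _quantile(np.abs(stars - estimate), alpha)
    return float(estimate), (float(estimate - q), float(estimate + q))


# ----------------------------------------------------------------------
# Competing risks
# ----------------------------------------------------------------------
@dataclass
class CompetingRisksFit:
    """Two cause-specific Cox fits on the same subjects.

    Built from a dataset whose status codes are 0 (censored), 1 and 2: each
    cause-specific model treats the other cause's events as censorings.
    """
    fit1: CoxFit
    fit2: CoxFit

    @classmethod
    def from_codes(cls, ids, entry, exit, codes, covariates,
                   covariate_names=None) -> "CompetingRisksFit":
        codes = np.asarray(codes, dtype=int)
        if not np.all(np.isin(codes, (0, 1, 2))):
            raise ValueError("status codes must be in {0, 1, 2}")
        fits = []
        for cause in (1, 2):
            s = SurvivalSample(ids, entry, exit, (codes == cause).astype(int),
                               covariates, covariate_names=covariate_names)
            fits.append(fit_beta(s))
        return cls(*fits)

    def resample(self, B: int, spec: MultiplierSpec, approach: str = "direct",
                 increments: str = "dN"):
        """Independent multiplier bootstraps of the two cause-specific models."""
        if isinstance(spec.seed, np.random.SeedSequence):
            seeds = spec.seed.spawn(2)
        else:
            seeds = np.random.SeedSequence(spec.seed).spawn(2)
        out = []
        for fit, seed in zip((self.fit1, self.fit2), seeds):
            mspec = MultiplierSpec(law=spec.law, seed=seed)
            out.append(run_ensemble(fit._engine.sample, fit, B, mspec,
                                    approach=approach, increments=increments))
        return tuple(out)


def _cif_values(theta1, theta2, X, t) -> np.ndarray:
    """F1(t|X) summed over the jumps of Lambda_1 with left-limit survival."""
    beta1, ch1 = _theta(theta1)
    beta2, ch2 = _theta(theta2)
    a = _risk_score(beta1, X)
    b = _risk_score(beta2, X)
    u = ch1.times
    dL1 = ch1.increments
    lam1_left = np.concatenate([[0.0], ch1.values[:-1]]) if u.size else np.empty(0)
    lam2_left = ch2.left_limit(u)
    terms = np.exp(-lam1_left * a - lam2_left * b) * a * dL1
    csum = np.concatenate([[0.0], np.cumsum(terms)])
    t = np.atleast_1d(np.asarray(t, dtype=float))
    idx = np.searchsorted(u, t, side="right")
    return csum[idx]


def cumulative_incidence(crfit: CompetingRisksFit, X, t):
    """Cause-1 cumulative incidence ``F1(t|X)`` from the two cause-specific fits.

    ``F1(t|X) = sum_{u <= t} exp{-Lambda_1(u-) e^{X'b1} - Lambda_2(u-) e^{X'b2}}
    e^{X'b1} dLambda_1(u)``; nondecreasing in t and bounded by 1 in the
    continuous limit.
    """
    out = _cif_values(crfit.fit1, crfit.fit2, X, t)
    return out if np.ndim(t) else float(out[0])


# ----------------------------------------------------------------------
# Trajectory ("path") functionals and their bands
# ----------------------------------------------------------------------
def survival_path(X):
    """Path functional ``grid -> S(t|X)`` for use with :func:`functional_band`."""
    def path(thetas, grid):
        beta, ch = _theta(thetas[0])
        return np.exp(-np.asarray(ch(grid)) * _risk_score(beta, X))
    return path


def cumulative_incidence_path(X):
    """Path functional ``grid -> F1(t|X)`` from (cause-1, cause-2) thetas."""
    def path(thetas, grid):
        return _cif_values(thetas[0], thetas[1], X, grid)
    return path


def functional_band(ensembles, path_fn, interval, alpha: float = 0.05,
                    transform: str = "identity",
                    weight: str = "equal_precision",
                    grid=None) -> ConfidenceBand:
    """Simultaneous band for a trajectory functional of one or more fits.

    ``path_fn(thetas, grid)`` evaluates the trajectory for a theta tuple
    (one ``(beta, cumhaz)`` entry per ensemble).  The band reuses the
    cumulative-hazard machinery with the functional's replicate paths.
    """
    if isinstance(ensembles, BootstrapEnsemble):
        ensembles = (ensembles,)
    spec = BandSpec(tuple(interval), transform, weight, alpha)
    if grid is None:
        all_times = np.unique(np.concatenate([e.times for e in ensembles]))
        grid = band_grid(all_times, interval)
    grid = np.asarray(grid, dtype=float)
    estimate = np.asarray(
        path_fn(tuple((e.fit.beta, e.fit.breslow) for e in ensembles), grid),
        dtype=float)
    paths = np.stack([np.asarray(path_fn(th, grid), dtype=float)
                      for th in _replicate_thetas(ensembles)], axis=1)
    n = ensembles[0].n
    return band_from_paths(grid, estimate, paths, n, spec)
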