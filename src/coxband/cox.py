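"""Cox proportional hazards estimation in counting-process form.

The model for subject *i* is the multiplicative intensity

    lambda_i(t) = Y_i(t) lambda_0(t) exp{X_i(t)' beta_0},

with at-risk indicator ``Y_i``, baseline hazard ``lambda_0`` and regression
parameter ``beta_0``.  This module provides the partial-likelihood score and
information, a Newton solver for the maximum partial likelihood estimator
``beta_hat``, the Breslow estimator of the cumulative baseline hazard
``Lambda_0``, martingale residual increments, and the plug-in estimator of
the asymptotic variance of ``sqrt(n)(Lambda_hat - Lambda_0)``.

Tied event times follow the Breslow convention throughout: tied events share
one risk set and the Breslow estimator jumps by (number tied)/S0.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._engine import RiskSetEngine
from .data import SurvivalSample
from .stepfun import StepFunction

__all__ = [
    "RiskSetSums", "CoxFit", "FitError", "NoEventsError",
    "NonConvergenceError", "SingularInformationError",
    "risk_set_sums", "score", "information", "fit_beta", "breslow",
    "martingale_increments", "variance_estimate", "log_partial_likelihood",
]


class FitError(RuntimeError):
    """Base class for estimation failures."""


class NoEventsError(FitError):
    pass


class NonConvergenceError(FitError):
    def __init__(self, message, last_beta=None, score_norm=None):
        super().__init__(message)
        self.last_beta = last_beta
        self.score_norm = score_norm


class SingularInformationError(FitError):
    pass


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class RiskSetSums:
    """Risk-set sums at one time point.

    ``S0 = sum Y_i exp(X_i'beta)``, ``S1``/``S2`` the X-weighted analogues,
    ``E = S1/S0`` and ``V = S2/S0 - E E'``.  ``J`` indicates a nonempty risk
    set; when ``J`` is False, ``E`` and ``V`` are NaN (flagged, not raised).
    """
    t: float
    S0: float
    S1: np.ndarray
    S2: np.ndarray
    E: np.ndarray
    V: np.ndarray
    J: bool


def _engine(data) -> RiskSetEngine:
    if isinstance(data, RiskSetEngine):
        return data
    return RiskSetEngine(data)


def risk_set_sums(data: SurvivalSample, beta, t: float) -> RiskSetSums:
    """Compute S_k(t, beta), E(t, beta), V(t, beta) at a single time ``t``."""
    eng = _engine(data)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    S0, S1, S2 = eng.sums(beta, times=[float(t)], order=2)
    s0 = float(S0[0])
    if s0 > 0:
        E = S1[0] / s0
        V = S2[0] / s0 - np.outer(E, E)
        return RiskSetSums(float(t), s0, S1[0], S2[0], E, V, True)
    nanv = np.full(eng.p, np.nan)
    nanm = np.full((eng.p, eng.p), np.nan)
    return RiskSetSums(float(t), 0.0, S1[0], S2[0], nanv, nanm, False)


def score(data: SurvivalSample, beta) -> np.ndarray:
    """Partial-likelihood score ``U_tau(beta) = sum_events {X_e - E(t_e, beta)}``."""
    eng = _engine(data)
    if eng.n_events == 0:
        raise NoEventsError("no events in the data")
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    S0, S1, _ = eng.sums(beta, order=1)
    E = S1 / S0[:, None]
    return eng.event_X.sum(axis=0) - eng.ties @ E


def information(data: SurvivalSample, beta) -> np.ndarray:
    """Observed information ``I_tau(beta) = sum_events V(t_e, beta)`` (p x p, PSD)."""
    eng = _engine(data)
    if eng.n_events == 0:
        raise NoEventsError("no events in the data")
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    _, _, V = eng.e_and_v(beta)
    return np.einsum("k,kpq->pq", eng.ties, V)


def log_partial_likelihood(data: SurvivalSample, beta) -> float:
    """Breslow-ties log partial likelihood (up to an additive constant)."""
    eng = _engine(data)
    if eng.n_events == 0:
        raise NoEventsError("no events in the data")
    return eng.log_partial_likelihood(np.atleast_1d(np.asarray(beta, dtype=float)))


def breslow(data: SurvivalSample, beta) -> StepFunction:
    """Breslow estimator: jump (ties)/S0(u, beta) at each unique event time u.

    At ``beta = 0`` this is exactly the Nelson--Aalen estimator.  Event times
    with an empty risk set (possible under left truncation) get a zero jump.
    """
    eng = _engine(data)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    S0, _, _ = eng.sums(beta, order=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(S0 > 0, eng.ties / S0, 0.0)
    return StepFunction(eng.times, inc)


# ----------------------------------------------------------------------
@dataclass
class CoxFit:
    """A fitted Cox model: beta_hat, Breslow step function, information, variance.

    ``information`` is the unnormalized observed information ``I_tau(beta_hat)``.
    ``degenerate`` flags a fit whose information is singular (for example all
    covariates identical); such fits carry a valid Breslow estimator but no
    standard errors or variance function.
    """
    beta: np.ndarray
    breslow: StepFunction
    information: np.ndarray
    n: int
    iterations: int
    score_norm: float
    degenerate: bool
    covariate_names: tuple = ()
    _engine: RiskSetEngine = field(repr=False, default=None)
    # cached per-event-time quantities at beta_hat
    _s0: np.ndarray = field(repr=False, default=None)        # (K,)
    _E: np.ndarray = field(repr=False, default=None)         # (K, p)
    _dL: np.ndarray = field(repr=False, default=None)        # (K,) Breslow jumps
    _q: np.ndarray = field(repr=False, default=None)         # (K, p) cum E dL
    _mvar: np.ndarray = field(repr=False, default=None)      # (K,) cum ties/S0^2
    _info_inv: np.ndarray = field(repr=False, default=None)
    _ws: dict = field(repr=False, default_factory=dict)

    @property
    def p(self) -> int:
        return int(self.beta.size)

    @property
    def event_times(self) -> np.ndarray:
        return self.breslow.times

    @property
    def tau(self) -> float:
        return self._engine.sample.tau

    def _information_inverse(self) -> np.ndarray:
        if self.degenerate:
            raise SingularInformationError("fit is degenerate: singular information")
        if self._info_inv is None:
            self._info_inv = np.linalg.inv(self.information)
        return self._info_inv

    def std_errors(self) -> np.ndarray:
        """Model-based standard errors, sqrt(diag(I_tau^{-1}))."""
        return np.sqrt(np.diag(self._information_inverse()))

    def variance(self, t):
        """Plug-in variance ``sigma_hat^2(t)`` of ``sqrt(n)(Lambda_hat - Lambda_0)``.

        Derived from the asymptotic representation of the Breslow estimator:
        a martingale part ``n * sum_{u<=t} d_u / S0(u)^2`` plus the quadratic
        form ``q(t)' {I_tau/n}^{-1} q(t)`` with ``q(t) = sum_{u<=t} E(u) dLambda(u)``
        accounting for the estimation of beta.
        """
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        mart = np.where(idx >= 0, self._mvar[np.clip(idx, 0, None)], 0.0) * self.n
        q = np.where((idx >= 0)[..., None],
                     self._q[np.clip(idx, 0, None)], 0.0)
        if self.degenerate and np.max(np.abs(self._q)) == 0.0:
            # covariate-free limit: the beta-uncertainty term vanishes exactly
            quad = np.zeros(np.shape(mart))
        else:
            info_inv_n = self._information_inverse() * self.n  # (I/n)^{-1}
            quad = np.einsum("...p,pq,...q->...", q, info_inv_n, q)
        out = mart + quad
        return out if out.ndim else float(out)

    def report(self) -> dict:
        """Plain JSON-serializable fit summary."""
        out = {
            "n_subjects": self.n,
            "n_events": int(self._engine.n_events),
            "iterations": self.iterations,
            "score_norm": self.score_norm,
            "degenerate": self.degenerate,
            "coefficients": {},
        }
        ses = (self.std_errors() if not self.degenerate
               else np.full(self.p, np.nan))
        names = self.covariate_names or tuple(f"x{j+1}" for j in range(self.p))
        for j, name in enumerate(names):
            out["coefficients"][name] = {
                "beta": float(self.beta[j]),
                "se": float(ses[j]),
                "hazard_ratio": float(np.exp(self.beta[j])),
            }
        return out


def fit_beta(data: SurvivalSample, init=None, tol: float = 1e-9,
             max_iter: int = 50) -> CoxFit:
    """Newton--Raphson solver for the partial-likelihood score equation.

    Starts at ``init`` (default 0), iterates ``beta += I^{-1} U`` with
    step-halving whenever the log partial likelihood would decrease, and stops
    when ``||U||_inf < tol``.

    Raises
    ------
    NoEventsError
        If the data contain no events.
    SingularInformationError
        If a Newton step requires solving a singular information matrix while
        the score is still nonzero (e.g. collinear covariates).
    NonConvergenceError
        If ``max_iter`` is exhausted; carries the last iterate.
    """
    eng = _engine(data)
    if eng.n_events == 0:
        raise NoEventsError("no events in the data")
    p = eng.p
    beta = (np.zeros(p) if init is None
            else np.atleast_1d(np.asarray(init, dtype=float)).copy())
    sum_Xe = eng.event_X.sum(axis=0)

    iterations = 0
    converged = False
    for iterations in range(max_iter + 1):
        S0, E, V = eng.e_and_v(beta)
        if np.any(S0[eng.ties > 0] <= 0):
            raise FitError("empty risk set at an event time")
        U = sum_Xe - eng.ties @ E
        I = np.einsum("k,kpq->pq", eng.ties, V)
        unorm = float(np.max(np.abs(U)))
        if unorm < tol:
            converged = True
            break
        if not np.all(np.isfinite(I)) or np.linalg.cond(I) > 1e12:
            raise SingularInformationError(
                "singular information during Newton iteration "
                "(constant or collinear covariates within risk sets?)")
        try:
            delta = np.linalg.solve(I, U)
        except np.linalg.LinAlgError:
            raise SingularInformationError(
                "singular information during Newton iteration "
                "(constant or collinear covariates within risk sets?)")
        if not np.all(np.isfinite(delta)):
            raise SingularInformationError(
                "non-finite Newton step; information numerically singular")
        # step-halving: never accept a decrease of the log partial likelihood
        ll0 = eng.log_partial_likelihood(beta)
        step = delta
        for _ in range(30):
            if eng.log_partial_likelihood(beta + step) >= ll0 - 1e-12:
                break
            step = step / 2.0
        beta = beta + step

    if not converged:
        raise NonConvergenceError(
            f"Newton did not converge in {max_iter} iterations "
            f"(||U||_inf = {unorm:.3e})", last_beta=beta, score_norm=unorm)

    # assemble the fit with cached event-time quantities
    with np.errstate(divide="ignore", invalid="ignore"):
        dL = np.where(S0 > 0, eng.ties / S0, 0.0)
        mvar_inc = np.where(S0 > 0, eng.ties / S0 ** 2, 0.0)
    degenerate = False
    try:
        info_inv = np.linalg.inv(I)
        if not np.all(np.isfinite(info_inv)):
            degenerate = True
    except np.linalg.LinAlgError:
        degenerate = True

    fit = CoxFit(
        beta=beta,
        breslow=StepFunction(eng.times, dL),
        information=I,
        n=eng.sample.n_subjects,
        iterations=iterations,
        score_norm=unorm,
        degenerate=degenerate,
        covariate_names=eng.sample.covariate_names,
        _engine=eng,
        _s0=S0,
        _E=E,
        _dL=dL,
        _q=np.cumsum(E * dL[:, None], axis=0),
        _mvar=np.cumsum(mvar_inc),
        _info_inv=None if degenerate else info_inv,
    )
    return fit


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class MartingaleIncrements:
    """Estimated martingale increments dM_hat_i(u) at the unique event times.

    ``dM[k, i] = dN_i(u_k) - Y_i(u_k) exp(X_i(u_k)' beta_hat) dLambda_hat(u_k)``
    aggregated over the rows of subject i; columns follow ``subject_ids``.
    Rows sum to zero because the Breslow estimator solves the baseline score
    equation at each event time.
    """
    times: np.ndarray          # (K,)
    dM: np.ndarray             # (K, n_subjects)
    subject_ids: np.ndarray    # (n_subjects,)


def martingale_increments(data: SurvivalSample, fit: CoxFit) -> MartingaleIncrements:
    """Per-subject martingale residual increments at the event times of ``fit``."""
    eng = fit._engine if fit._engine is not None else _engine(data)
    sample = eng.sample
    row_to_subject, subject_ids = sample.subject_index()
    n = subject_ids.size
    K = eng.K
    at_risk = sample.at_risk(eng.times)                      # (K, m)
    w = np.exp(np.clip(sample.covariates @ fit.beta, -700, 700))  # (m,)
    dM_rows = -(at_risk * w[None, :]) * fit._dL[:, None]     # (K, m)
    dM_rows[eng.row_to_unique, eng.event_rows] += 1.0
    dM = np.zeros((K, n))
    np.add.at(dM.T, row_to_subject, dM_rows.T)
    return MartingaleIncrements(eng.times.copy(), dM, subject_ids)


def variance_estimate(fit: CoxFit, t, data: SurvivalSample | None = None):
    """Plug-in variance of ``sqrt(n){Lambda_hat(t) - Lambda_0(t)}`` (see CoxFit.variance)."""
    return fit.variance(t)
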