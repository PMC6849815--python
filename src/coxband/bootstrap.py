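"""Multiplier (wild) bootstrap for the Cox model.

Two resampling schemes are implemented, both driven by i.i.d. multipliers
``G_1..G_n`` with mean 0 and variance 1:

* ``approach="direct"`` -- direct resampling of the asymptotic representation:
  the bootstrap score ``U* = sum_i G_i int (X_i - E) dW_i`` and bootstrap
  information ``I* = sum_i G_i^2 int (X_i - E)(X_i - E)' dW_i`` define
  ``beta* = beta_hat + (I*)^{-1} U*`` in closed form, and the Breslow
  perturbation follows the same linearization.

* ``approach="score"`` -- the estimating-equation bootstrap: the score
  equations themselves are randomly reweighted and re-solved, i.e. ``beta*``
  solves ``sum_i (G_i + 1) int {X_i - E(., beta)} dN_i = 0`` (dN mode) and the
  bootstrap Breslow estimator is the reweighted Breslow formula evaluated at
  ``beta*``.  Because weights ``G_i + 1`` may be negative, individual
  replicates can fail to converge; these are flagged, dropped, and counted.

``increments`` selects the perturbed measure ``dW_i``: the counting-process
increments ``dN_i`` or the estimated martingale increments ``dM_hat_i``.

Ensembles are batch-vectorized across replicates: every replicate's Newton
iteration shares one risk-set-sum evaluation with a trailing batch axis.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cox import CoxFit, martingale_increments
from .data import SurvivalSample
from .stepfun import StepFunction

__all__ = [
    "MultiplierSpec", "BootstrapReplicate", "BootstrapEnsemble",
    "draw_multipliers", "bootstrap_score", "bootstrap_information",
    "direct_replicate", "score_replicate", "run_ensemble",
    "EnsembleError",
]

_LAWS = ("normal", "poisson", "exponential")
_APPROACHES = ("direct", "score")
_INCREMENTS = ("dN", "dM")


class EnsembleError(RuntimeError):
    """Raised when too large a fraction of replicates fails to converge."""


@dataclass(frozen=True)
class MultiplierSpec:
    """Multiplier law specification.

    ``law`` is one of ``normal`` (N(0,1), skewness 0), ``poisson``
    (Poi(1) - 1, skewness 1) or ``exponential`` (Exp(1) - 1, skewness 2);
    all have mean 0 and variance 1.  ``seed`` may be an int, a
    ``numpy.random.SeedSequence`` or a ``Generator``.
    """
    law: str = "normal"
    seed: object = None
    n: int | None = None

    def __post_init__(self):
        if self.law not in _LAWS:
            raise ValueError(f"unknown multiplier law {self.law!r}; "
                             f"choose from {_LAWS}")

    def rng(self) -> np.random.Generator:
        if isinstance(self.seed, np.random.Generator):
            return self.seed
        return np.random.default_rng(self.seed)


def _draw(rng: np.random.Generator, law: str, shape) -> np.ndarray:
    if law == "normal":
        return rng.standard_normal(shape)
    if law == "poisson":
        return rng.poisson(1.0, shape).astype(float) - 1.0
    if law == "exponential":
        return rng.exponential(1.0, shape) - 1.0
    raise ValueError(f"unknown multiplier law {law!r}")


def draw_multipliers(spec: MultiplierSpec, size=None) -> np.ndarray:
    """Draw i.i.d. centered unit-variance multipliers; reproducible under seed."""
    if size is None:
        if spec.n is None:
            raise ValueError("MultiplierSpec.n not set and no size given")
        size = spec.n
    return _draw(spec.rng(), spec.law, size)


# ----------------------------------------------------------------------
# Per-dataset workspace: everything beta-independent, cached on the fit.
# ----------------------------------------------------------------------
class _Workspace:
    def __init__(self, fit: CoxFit, increments: str):
        if increments not in _INCREMENTS:
            raise ValueError(f"increments must be one of {_INCREMENTS}")
        eng = fit._engine
        sample = eng.sample
        self.eng = eng
        self.fit = fit
        self.increments = increments
        self.K = eng.K
        self.d = eng.ties.astype(float)            # (K,)
        self.s0 = fit._s0                          # (K,)
        self.E = fit._E                            # (K, p)
        self.dL = fit._dL                          # (K,)
        self.q = fit._q                            # (K, p)
        self.p = eng.p
        row_to_subject, subject_ids = sample.subject_index()
        self.row_to_subject = row_to_subject
        self.n = subject_ids.size
        self.k_of_event = eng.row_to_unique        # (ne,)
        self.subj_of_event = row_to_subject[eng.event_rows]
        self.event_X = eng.event_X                 # (ne, p)
        self.sum_Xe = eng.event_X.sum(axis=0)      # (p,)

        n, p, K = self.n, self.p, self.K
        if increments == "dN":
            XmE = self.event_X - self.E[self.k_of_event]      # (ne, p)
            A = np.zeros((n, p))
            np.add.at(A, self.subj_of_event, XmE)
            R = np.zeros((n, p, p))
            np.add.at(R, self.subj_of_event,
                      XmE[:, :, None] * XmE[:, None, :])
            TX = np.zeros((n, p))
            np.add.at(TX, self.subj_of_event, self.event_X)
            self.Dsub = None
        else:
            mart = martingale_increments(sample, fit)
            Dsub = mart.dM                                    # (K, n) subject level
            # row-level matrix for covariate-weighted sums (time-dependent X)
            at_risk = sample.at_risk(eng.times)               # (K, m)
            w = np.exp(np.clip(sample.covariates @ fit.beta, -700, 700))
            D_rows = -(at_risk * w[None, :]) * self.dL[:, None]
            D_rows[self.k_of_event, eng.event_rows] += 1.0    # (K, m)
            X = sample.covariates                             # (m, p)
            colsum = D_rows.sum(axis=0)                       # (m,)
            TX_rows = X * colsum[:, None]                     # (m, p)
            ED = D_rows.T @ self.E                            # (m, p)
            A_rows = TX_rows - ED
            D2 = D_rows ** 2
            c0 = D2.sum(axis=0)                               # (m,)
            c1 = D2.T @ self.E                                # (m, p)
            c2 = np.einsum("km,kp,kq->mpq", D2, self.E, self.E)
            R_rows = (X[:, :, None] * X[:, None, :] * c0[:, None, None]
                      - X[:, :, None] * c1[:, None, :]
                      - c1[:, :, None] * X[:, None, :]
                      + c2)
            A = np.zeros((n, p))
            np.add.at(A, row_to_subject, A_rows)
            R = np.zeros((n, p, p))
            np.add.at(R, row_to_subject, R_rows)
            TX = np.zeros((n, p))
            np.add.at(TX, row_to_subject, TX_rows)
            self.Dsub = Dsub
        self.A = A      # (n, p): U* = A' G for both schemes at beta_hat
        self.R = R      # (n, p, p): I* = sum_i G_i^2 R_i
        self.TX = TX    # (n, p): G-weighted X-term of the reweighted score

    # -- G-dependent building blocks ----------------------------------
    def nu(self, G: np.ndarray) -> np.ndarray:
        """Reweighted event measure at the unique event times, shape (K, B).

        dN mode: ``nu_k = d_k + sum_{events at u_k} G_{subject}``;
        dM mode: ``nu_k = d_k + sum_i G_i dM_hat_i(u_k)``.
        """
        if self.increments == "dN":
            out = np.zeros((self.K, G.shape[1]))
            np.add.at(out, self.k_of_event, G[self.subj_of_event])
            return out + self.d[:, None]
        return self.Dsub @ G + self.d[:, None]

    def score_star(self, G: np.ndarray) -> np.ndarray:
        """Bootstrap score at beta_hat, shape (p, B)."""
        return self.A.T @ G

    def info_star(self, G: np.ndarray) -> np.ndarray:
        """Bootstrap information, shape (B, p, p)."""
        return np.einsum("ib,ipq->bpq", G ** 2, self.R)


def _workspace(fit: CoxFit, increments: str) -> _Workspace:
    ws = fit._ws.get(increments)
    if ws is None:
        ws = _Workspace(fit, increments)
        fit._ws[increments] = ws
    return ws


# ----------------------------------------------------------------------
@dataclass
class BootstrapReplicate:
    """One bootstrap realization (beta*, Lambda_0*)."""
    G: np.ndarray
    beta_star: np.ndarray
    breslow_star: StepFunction
    converged: bool
    approach: str
    increments: str


@dataclass
class BootstrapEnsemble:
    """B bootstrap replicates of (beta*, Lambda_0*) on the event-time grid.

    ``lambda_star`` holds the bootstrap Breslow values at the fit's unique
    event times (one column per replicate); ``converged`` masks the usable
    columns.  ``variance_at(t)`` is the empirical variance across converged
    replicates of ``sqrt(n){Lambda_0*(t) - Lambda_0_hat(t)}`` -- the
    bootstrap counterpart of the plug-in variance ``sigma_hat^2(t)``.
    """
    fit: CoxFit
    times: np.ndarray          # (K,)
    lambda_hat: np.ndarray     # (K,)
    beta_star: np.ndarray      # (B, p)
    lambda_star: np.ndarray    # (K, B)
    converged: np.ndarray      # (B,) bool
    G: np.ndarray              # (n, B)
    approach: str
    increments: str
    spec: MultiplierSpec

    @property
    def B(self) -> int:
        return int(self.converged.size)

    @property
    def n(self) -> int:
        return int(self.fit.n)

    @property
    def dropped(self) -> int:
        return int(np.sum(~self.converged))

    def _index(self, t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return t, np.searchsorted(self.times, t, side="right") - 1

    def lambda_hat_at(self, t) -> np.ndarray:
        t, idx = self._index(t)
        return np.where(idx >= 0, self.lambda_hat[np.clip(idx, 0, None)], 0.0)

    def lambda_star_at(self, t, converged_only: bool = True) -> np.ndarray:
        """Bootstrap Breslow values, shape (len(t), B_converged)."""
        t, idx = self._index(t)
        cols = self.lambda_star[:, self.converged] if converged_only else self.lambda_star
        out = np.zeros((t.size, cols.shape[1]))
        inside = idx >= 0
        out[inside] = cols[idx[inside]]
        return out

    def variance_at(self, t) -> np.ndarray:
        """Empirical variance of sqrt(n)(Lambda* - Lambda_hat) at times ``t``."""
        star = self.lambda_star_at(t)                       # (T, Bc)
        hat = self.lambda_hat_at(t)
        dev = star - hat[:, None]
        if dev.shape[1] < 2:
            return np.zeros(dev.shape[0])
        return self.n * np.var(dev, axis=1, ddof=1)

    def replicate(self, b: int) -> BootstrapReplicate:
        inc = np.diff(self.lambda_star[:, b], prepend=0.0)
        return BootstrapReplicate(
            G=self.G[:, b], beta_star=self.beta_star[b],
            breslow_star=StepFunction(self.times, inc),
            converged=bool(self.converged[b]),
            approach=self.approach, increments=self.increments)


# ----------------------------------------------------------------------
def bootstrap_score(data: SurvivalSample, fit: CoxFit, G,
                    increments: str = "dN") -> np.ndarray:
    """Multiplier bootstrap score ``U*_tau(beta_hat)``.

    dN mode: ``sum_i G_i sum_{events of i} {X_i - E(u, beta_hat)}``;
    dM mode: the same with dM_hat_i increments.  Identical for both
    resampling schemes (the reweighted score equation evaluated at beta_hat
    coincides with the direct perturbation).
    """
    ws = _workspace(fit, increments)
    G = np.asarray(G, dtype=float).reshape(-1, 1)
    return ws.score_star(G)[:, 0]


def bootstrap_information(data: SurvivalSample, fit: CoxFit, G,
                          increments: str = "dN") -> np.ndarray:
    """Multiplier bootstrap information ``I*_tau(beta_hat)`` (p x p, PSD).

    dN mode: ``sum_i G_i^2 sum_{events of i} (X_i - E)(X_i - E)'``; in dM mode
    the same quadratic form is reweighted with squared dM_hat increments.
    """
    ws = _workspace(fit, increments)
    G = np.asarray(G, dtype=float).reshape(-1, 1)
    return ws.info_star(G)[0]


# ----------------------------------------------------------------------
def _solve_batch(J: np.ndarray, U: np.ndarray):
    """Solve ``J[b] x[b] = U[b]`` for a (B,p,p)/(B,p) batch; mask singulars."""
    B, p = U.shape
    out = np.zeros((B, p))
    det = np.linalg.det(J)
    ok = np.isfinite(det) & (np.abs(det) > 0)
    if np.any(ok):
        try:
            out[ok] = np.linalg.solve(J[ok], U[ok][..., None])[..., 0]
        except np.linalg.LinAlgError:      # fall back to per-replicate solves
            for b in np.flatnonzero(ok):
                try:
                    out[b] = np.linalg.solve(J[b], U[b])
                except np.linalg.LinAlgError:
                    ok[b] = False
    bad = ~np.all(np.isfinite(out), axis=1)
    out[bad] = 0.0
    ok &= ~bad
    # a singular system with a vanishing right-hand side (e.g. G = 0) is
    # exactly solved by a zero step
    ok |= np.max(np.abs(U), axis=1) < 1e-12
    return out, ok


def _direct_batch(ws: _Workspace, G: np.ndarray):
    """Closed-form direct-resampling replicates for a (n, B) multiplier matrix."""
    fit = ws.fit
    U = ws.score_star(G)                                   # (p, B)
    Istar = ws.info_star(G)                                # (B, p, p)
    delta, ok = _solve_batch(Istar, U.T)                   # (B, p)
    beta_star = fit.beta[None, :] + delta
    # Breslow perturbation: -(beta*-beta)' q(t) + sum_i G_i int dW_i / S0
    if ws.increments == "dN":
        M = np.zeros((ws.K, G.shape[1]))
        contrib = G[ws.subj_of_event] / ws.s0[ws.k_of_event][:, None]
        np.add.at(M, ws.k_of_event, contrib)
    else:
        M = (ws.Dsub @ G) / ws.s0[:, None]
    gamma = np.cumsum(M, axis=0)                           # (K, B)
    lam_hat = fit.breslow.values
    lambda_star = lam_hat[:, None] - ws.q @ delta.T + gamma
    return beta_star, lambda_star, ok


def _score_batch(ws: _Workspace, G: np.ndarray, tol: float = 1e-8,
                 max_iter: int = 25, trust_radius: float = 1.0,
                 box: float = 5.0):
    """Newton-solved estimating-equation replicates for a (n, B) multiplier matrix.

    The reweighted score is ``U*_b(beta) = T_b - sum_k E(u_k, beta) nu_kb``
    with negative Jacobian ``sum_k V(u_k, beta) nu_kb``.  Steps are clipped to
    ``trust_radius`` in the sup norm and iterates confined to a +/- ``box``
    around beta_hat (divergent replicates hit the box and fail the final
    score-norm check, so they are flagged rather than overflowing).
    """
    fit = ws.fit
    eng = ws.eng
    p, K = ws.p, ws.K
    B = G.shape[1]
    nu = ws.nu(G)                                          # (K, B)
    Tconst = ws.sum_Xe[:, None] + ws.TX.T @ G              # (p, B)
    beta = np.repeat(fit.beta[None, :], B, axis=0)         # (B, p)
    lo, hi = fit.beta - box, fit.beta + box
    active = np.ones(B, dtype=bool)
    U = np.zeros((B, p))
    for _ in range(max_iter):
        S0, S1, S2 = eng.sums(beta, order=2)               # (K,B),(K,p,B),(K,p,p,B)
        with np.errstate(divide="ignore", invalid="ignore"):
            E = S1 / S0[:, None, :]                        # (K, p, B)
            V = S2 / S0[:, None, None, :] - E[:, :, None, :] * E[:, None, :, :]
        U = (Tconst - np.einsum("kb,kpb->pb", nu, E)).T    # (B, p)
        res = np.max(np.abs(U), axis=1)
        active = ~(res < tol) & np.all(np.isfinite(U), axis=1)
        if not np.any(active):
            break
        J = np.einsum("kb,kpqb->bpq", nu, V)               # (B, p, p)
        delta, ok = _solve_batch(J, U)
        # singular Jacobian with unconverged score: freeze (stays flagged)
        delta[~ok] = 0.0
        scale = np.max(np.abs(delta), axis=1)
        shrink = np.where(scale > trust_radius, trust_radius / np.maximum(scale, 1e-300), 1.0)
        delta *= shrink[:, None]
        beta_new = np.clip(beta + delta, lo[None, :], hi[None, :])
        beta[active] = beta_new[active]
    else:
        # final residual check after exhausting iterations
        S0, S1, _ = eng.sums(beta, order=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            E = S1 / S0[:, None, :]
        U = (Tconst - np.einsum("kb,kpb->pb", nu, E)).T
    converged = (np.max(np.abs(U), axis=1) < tol) & np.all(np.isfinite(beta), axis=1)
    # bootstrap Breslow: nu_k / S0(u_k, beta*) cumulated
    S0_star, _, _ = eng.sums(beta, order=0)                # (K, B)
    with np.errstate(divide="ignore", invalid="ignore"):
        dlam = np.where(S0_star > 0, nu / S0_star, 0.0)
    lambda_star = np.cumsum(dlam, axis=0)
    return beta, lambda_star, converged


def direct_replicate(data: SurvivalSample, fit: CoxFit, G,
                     increments: str = "dN") -> BootstrapReplicate:
    """One direct-resampling replicate for a given multiplier vector ``G``."""
    ws = _workspace(fit, increments)
    G = np.asarray(G, dtype=float).reshape(-1, 1)
    beta_star, lambda_star, ok = _direct_batch(ws, G)
    inc = np.diff(lambda_star[:, 0], prepend=0.0)
    return BootstrapReplicate(G[:, 0], beta_star[0],
                              StepFunction(ws.eng.times, inc),
                              bool(ok[0]), "direct", increments)


def score_replicate(data: SurvivalSample, fit: CoxFit, G,
                    increments: str = "dN", tol: float = 1e-8,
                    max_iter: int = 25) -> BootstrapReplicate:
    """One estimating-equation replicate for a given multiplier vector ``G``."""
    ws = _workspace(fit, increments)
    G = np.asarray(G, dtype=float).reshape(-1, 1)
    beta_star, lambda_star, ok = _score_batch(ws, G, tol=tol, max_iter=max_iter)
    inc = np.diff(lambda_star[:, 0], prepend=0.0)
    return BootstrapReplicate(G[:, 0], beta_star[0],
                              StepFunction(ws.eng.times, inc),
                              bool(ok[0]), "score", increments)


def run_ensemble(data: SurvivalSample, fit: CoxFit, B: int,
                 spec: MultiplierSpec, approach: str = "score",
                 increments: str = "dN", tol: float = 1e-8,
                 max_iter: int = 25,
                 max_dropped_frac: float = 0.2) -> BootstrapEnsemble:
    """Run B multiplier-bootstrap replicates (vectorized across the batch).

    Deterministic under ``spec.seed``: the (n, B) multiplier matrix is drawn
    in one call, replicate b being column b.  Nonconverged replicates are
    flagged and excluded from variance/critical-value computations; more than
    ``max_dropped_frac`` of them raises :class:`EnsembleError`.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if approach not in _APPROACHES:
        raise ValueError(f"approach must be one of {_APPROACHES}")
    ws = _workspace(fit, increments)
    G = _draw(spec.rng(), spec.law, (ws.n, B))
    if approach == "direct":
        beta_star, lambda_star, converged = _direct_batch(ws, G)
    else:
        beta_star, lambda_star, converged = _score_batch(
            ws, G, tol=tol, max_iter=max_iter)
    ens = BootstrapEnsemble(
        fit=fit, times=ws.eng.times.copy(), lambda_hat=fit.breslow.values.copy(),
        beta_star=beta_star, lambda_star=lambda_star, converged=converged,
        G=G, approach=approach, increments=increments, spec=spec)
    if ens.dropped > max_dropped_frac * B:
        raise EnsembleError(
            f"{ens.dropped}/{B} bootstrap replicates failed to converge; "
            "this signals model or data pathology")
    return ens
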