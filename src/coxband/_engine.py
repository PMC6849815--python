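"""Internal vectorized risk-set computations.

All estimation and resampling code reduces to the risk-set sums

    S_k(t, beta) = sum_rows X_row^{(k)} Y_row(t) exp(X_row' beta),  k = 0, 1, 2,

evaluated at the (unique) event times, possibly for a whole batch of beta
vectors at once (one per bootstrap replicate).  Rather than forming an
(events x rows) at-risk matrix per evaluation, the engine sorts rows once by
exit and by entry time and obtains each S_k at all query times from two
suffix cumulative sums and a searchsorted lookup, which is O(m log m) per
beta and vectorizes cleanly over a replicate batch.
"""
from __future__ import annotations

import numpy as np

_CLIP = 700.0  # exp() overflow guard on the linear predictor


def _suffix_sums(arr: np.ndarray) -> np.ndarray:
    """``out[j] = arr[j:].sum(axis=0)`` with a trailing zero row, shape (m+1, ...)."""
    out = np.zeros((arr.shape[0] + 1,) + arr.shape[1:], dtype=float)
    if arr.shape[0]:
        out[:-1] = np.cumsum(arr[::-1], axis=0)[::-1]
    return out


class RiskSetEngine:
    """Precomputed sort orders and event bookkeeping for one dataset."""

    def __init__(self, sample):
        self.sample = sample
        X = np.asarray(sample.covariates, dtype=float)
        self.X = X
        self.m, self.p = X.shape

        status = sample.status
        ev_rows = np.flatnonzero(status == 1)
        order = np.argsort(sample.exit[ev_rows], kind="stable")
        #: row indices of event rows, sorted by event time
        self.event_rows = ev_rows[order]
        #: per event row: time, covariate vector
        self.event_times_rows = sample.exit[self.event_rows]
        self.event_X = X[self.event_rows]
        #: unique event times, tie multiplicities, event-row -> unique index
        self.times, self.row_to_unique, self.ties = np.unique(
            self.event_times_rows, return_inverse=True, return_counts=True)
        self.K = int(self.times.size)
        self.n_events = int(self.event_rows.size)

        self.exit_order = np.argsort(sample.exit, kind="stable")
        self.exit_sorted = sample.exit[self.exit_order]
        self.X_exit = X[self.exit_order]
        self.has_entry = bool(np.any(sample.entry > 0))
        if self.has_entry:
            self.entry_order = np.argsort(sample.entry, kind="stable")
            self.entry_sorted = sample.entry[self.entry_order]
            self.X_entry = X[self.entry_order]
        # lookup positions of the unique event times
        self._pos_exit_ev = np.searchsorted(self.exit_sorted, self.times, side="left")
        if self.has_entry:
            self._pos_entry_ev = np.searchsorted(self.entry_sorted, self.times, side="left")

    # ------------------------------------------------------------------
    def _positions(self, times):
        if times is None:
            pos_exit = self._pos_exit_ev
            pos_entry = self._pos_entry_ev if self.has_entry else None
        else:
            t = np.atleast_1d(np.asarray(times, dtype=float))
            pos_exit = np.searchsorted(self.exit_sorted, t, side="left")
            pos_entry = (np.searchsorted(self.entry_sorted, t, side="left")
                         if self.has_entry else None)
        return pos_exit, pos_entry

    def sums(self, beta, times=None, order: int = 2):
        """Risk-set sums ``S0, S1, S2`` at ``times`` (default: unique event times).

        Parameters
        ----------
        beta
            Shape ``(p,)`` or ``(B, p)``; in the batch case results gain a
            trailing replicate axis.
        order
            Highest ``S_k`` to compute (0, 1 or 2).

        Returns
        -------
        ``S0`` with shape ``(T,)`` / ``(T, B)``; ``S1`` with shape ``(T, p)`` /
        ``(T, p, B)``; ``S2`` with shape ``(T, p, p)`` / ``(T, p, p, B)``.
        Entries of ``S1``/``S2`` are ``None`` beyond the requested order.
        """
        beta2 = np.atleast_2d(np.asarray(beta, dtype=float))  # (B, p)
        squeeze = np.ndim(beta) == 1
        pos_exit, pos_entry = self._positions(times)
        p = self.p

        def one_side(Xs, pos):
            w = np.exp(np.clip(Xs @ beta2.T, -_CLIP, _CLIP))  # (m, B)
            S0 = _suffix_sums(w)[pos]
            S1 = S2 = None
            if order >= 1:
                S1 = np.stack([_suffix_sums(w * Xs[:, d:d + 1])[pos]
                               for d in range(p)], axis=1)  # (T, p, B)
            if order >= 2:
                S2 = np.empty((S0.shape[0], p, p, beta2.shape[0]))
                for d in range(p):
                    for e in range(d, p):
                        s = _suffix_sums(w * (Xs[:, d] * Xs[:, e])[:, None])[pos]
                        S2[:, d, e] = s
                        S2[:, e, d] = s
            return S0, S1, S2

        S0, S1, S2 = one_side(self.X_exit, pos_exit)
        if self.has_entry:
            T0, T1, T2 = one_side(self.X_entry, pos_entry)
            S0 = S0 - T0
            if order >= 1:
                S1 = S1 - T1
            if order >= 2:
                S2 = S2 - T2
        if squeeze:
            S0 = S0[..., 0]
            S1 = S1[..., 0] if S1 is not None else None
            S2 = S2[..., 0] if S2 is not None else None
        return S0, S1, S2

    # ------------------------------------------------------------------
    def log_partial_likelihood(self, beta) -> float:
        """Breslow-ties log partial likelihood ``sum_e X_e'beta - sum_k d_k log S0``."""
        beta = np.asarray(beta, dtype=float)
        S0, _, _ = self.sums(beta, order=0)
        with np.errstate(divide="ignore"):
            logS0 = np.log(S0)
        return float((self.event_X @ beta).sum() - (self.ties * logS0).sum())

    def e_and_v(self, beta, times=None):
        """``E = S1/S0`` and ``V = S2/S0 - E E'`` at the query times (single beta)."""
        S0, S1, S2 = self.sums(beta, times=times, order=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            E = S1 / S0[:, None]
            V = S2 / S0[:, None, None] - E[:, :, None] * E[:, None, :]
        return S0, E, V
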