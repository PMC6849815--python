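"""Counting-process survival data.

A :class:`SurvivalSample` holds subject-level data in counting-process form:
one or more rows per subject, each describing a half-open at-risk interval
``(entry, exit]`` with a fixed covariate vector, and an event indicator that
may be 1 only on a subject's last interval.  This representation covers
right-censoring, left-truncation (delayed entry) and time-dependent
covariates (multiple rows per subject with disjoint intervals).

The at-risk convention is ``Y_i(t) = 1  iff  entry < t <= exit`` for some row
of subject *i*: a subject is not at risk at its own entry time.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["SurvivalSample", "DataError"]


class DataError(ValueError):
    """Raised when input rows violate the counting-process invariants."""


class SurvivalSample:
    """Validated counting-process dataset (the N_i, Y_i, X_i of the Cox model).

    Parameters
    ----------
    ids
        Integer subject identifier per row.
    entry, exit
        Interval endpoints per row; ``entry < exit``, half-open ``(entry, exit]``.
    status
        Event indicator in {0, 1} at ``exit``; at most one event row per
        subject and it must be the subject's chronologically last row.
    covariates
        ``(n_rows, p)`` array of finite covariate values, constant on each row's
        interval.
    covariate_names
        Optional column labels, defaults to ``x1..xp``.
    """

    def __init__(self, ids, entry, exit, status, covariates, covariate_names=None,
                 validate: bool = True):
        self.ids = np.asarray(ids, dtype=np.int64)
        self.entry = np.asarray(entry, dtype=float)
        self.exit = np.asarray(exit, dtype=float)
        self.status = np.asarray(status, dtype=np.int8)
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        self.covariates = cov
        if covariate_names is None:
            covariate_names = tuple(f"x{j + 1}" for j in range(cov.shape[1]))
        self.covariate_names = tuple(covariate_names)
        if validate:
            self._validate()

    # ------------------------------------------------------------------
    def _validate(self) -> None:
        m = self.ids.size
        for name, arr in (("entry", self.entry), ("exit", self.exit),
                          ("status", self.status)):
            if arr.shape != (m,):
                raise DataError(f"column '{name}' has wrong length")
        if self.covariates.shape[0] != m:
            raise DataError("covariate rows do not match id rows")
        if len(self.covariate_names) != self.covariates.shape[1]:
            raise DataError("covariate_names length mismatch")
        if not np.all(np.isfinite(self.entry)) or not np.all(np.isfinite(self.exit)):
            raise DataError("entry/exit times must be finite")
        if not np.all(np.isfinite(self.covariates)):
            bad = int(np.flatnonzero(~np.isfinite(self.covariates).all(axis=1))[0])
            raise DataError(f"non-finite covariate in row {bad}")
        if np.any(self.entry < 0):
            bad = int(np.flatnonzero(self.entry < 0)[0])
            raise DataError(f"negative entry time in row {bad}")
        bad_iv = self.entry >= self.exit
        if np.any(bad_iv):
            bad = int(np.flatnonzero(bad_iv)[0])
            raise DataError(f"entry >= exit in row {bad}")
        if not np.all(np.isin(self.status, (0, 1))):
            bad = int(np.flatnonzero(~np.isin(self.status, (0, 1)))[0])
            raise DataError(f"status outside {{0,1}} in row {bad}")
        # per-subject: disjoint intervals, event only on the last interval
        order = np.lexsort((self.entry, self.ids))
        sid = self.ids[order]
        same = sid[1:] == sid[:-1]
        if np.any(same):
            prev_exit = self.exit[order][:-1][same]
            next_entry = self.entry[order][1:][same]
            if np.any(next_entry < prev_exit - 1e-12):
                bad = int(order[1:][same][np.flatnonzero(next_entry < prev_exit - 1e-12)[0]])
                raise DataError(f"overlapping intervals for subject of row {bad}")
            ev_not_last = (self.status[order][:-1][same] == 1)
            if np.any(ev_not_last):
                bad = int(order[:-1][same][np.flatnonzero(ev_not_last)[0]])
                raise DataError(f"event row {bad} is not the subject's last interval")
        # at most one event per subject is implied by "event only on last row"

    # ------------------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return int(self.ids.size)

    @property
    def n_subjects(self) -> int:
        return int(np.unique(self.ids).size)

    @property
    def p(self) -> int:
        return int(self.covariates.shape[1])

    @property
    def tau(self) -> float:
        """Largest exit time on record (default terminal evaluation time)."""
        return float(self.exit.max())

    @property
    def n_events(self) -> int:
        return int(np.sum(self.status == 1))

    @property
    def event_times(self) -> np.ndarray:
        """Sorted unique event times."""
        return np.unique(self.exit[self.status == 1])

    def subject_index(self) -> tuple[np.ndarray, np.ndarray]:
        """Map rows to a dense 0..n_subjects-1 index.

        Returns ``(row_to_subject, subject_ids)`` where ``subject_ids`` is the
        sorted unique id vector.
        """
        subject_ids, row_to_subject = np.unique(self.ids, return_inverse=True)
        return row_to_subject, subject_ids

    def at_risk(self, t) -> np.ndarray:
        """Row-level at-risk indicator matrix ``Y(t)`` for times ``t``.

        Returns a boolean array of shape ``(len(t), n_rows)`` under the
        half-open convention ``entry < t <= exit``.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return (self.entry[None, :] < t[:, None]) & (t[:, None] <= self.exit[None, :])

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, covariate_cols=None) -> "SurvivalSample":
        """Build from a data frame with columns id, [entry,] time, status, x1..xp."""
        required = {"id", "time", "status"}
        missing = required - set(df.columns)
        if missing:
            raise DataError(f"missing required column(s): {sorted(missing)}")
        if covariate_cols is None:
            covariate_cols = [c for c in df.columns
                              if c not in ("id", "entry", "time", "status")]
        if not covariate_cols:
            raise DataError("no covariate columns found")
        entry = df["entry"].to_numpy(float) if "entry" in df.columns else np.zeros(len(df))
        try:
            cov = df[list(covariate_cols)].to_numpy(float)
            ids = df["id"].to_numpy(np.int64)
            time = df["time"].to_numpy(float)
            status = df["status"].to_numpy(float)
        except (TypeError, ValueError) as err:
            raise DataError(f"non-numeric field: {err}") from err
        if np.any(status != np.round(status)):
            raise DataError("status must be integral 0/1")
        return cls(ids, entry, time, status.astype(int), cov,
                   covariate_names=tuple(covariate_cols))

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame({"id": self.ids, "entry": self.entry,
                            "time": self.exit, "status": self.status})
        for j, name in enumerate(self.covariate_names):
            out[name] = self.covariates[:, j]
        return out
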