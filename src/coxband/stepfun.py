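"""Right-continuous step functions anchored at zero.

Cumulative hazards (Breslow, Nelson--Aalen) are step functions with
nonnegative increments; bootstrap perturbations of them are step functions
whose increments may have either sign.  Both are represented here.
"""
from __future__ import annotations

import numpy as np

__all__ = ["StepFunction"]


class StepFunction:
    """A cadlag step function ``t -> sum of increments at jump times <= t``.

    Parameters
    ----------
    times
        Strictly increasing jump times, all positive.
    increments
        Jump sizes at each time.  For a cumulative hazard these are
        nonnegative, but general (signed) increments are accepted so that
        bootstrap realizations can be carried in the same container.

    The function value is 0 on ``[0, times[0])``.
    """

    __slots__ = ("times", "increments", "values")

    def __init__(self, times, increments):
        times = np.atleast_1d(np.asarray(times, dtype=float))
        increments = np.atleast_1d(np.asarray(increments, dtype=float))
        if times.shape != increments.shape or times.ndim != 1:
            raise ValueError("times and increments must be 1-D and equally long")
        if times.size and (np.any(np.diff(times) <= 0) or times[0] <= 0):
            raise ValueError("jump times must be strictly increasing and positive")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(increments))):
            raise ValueError("jump times and increments must be finite")
        self.times = times
        self.increments = increments
        self.values = np.cumsum(increments)

    def __call__(self, t):
        """Evaluate right-continuously at scalar or array ``t``."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 0.0)
        return out if out.ndim else float(out)

    def left_limit(self, t):
        """Evaluate the left limit ``f(t-)`` at scalar or array ``t``."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="left") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 0.0)
        return out if out.ndim else float(out)

    @property
    def is_nondecreasing(self) -> bool:
        return bool(np.all(self.increments >= 0))

    def __len__(self) -> int:
        return int(self.times.size)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"StepFunction({len(self)} jumps on [{self.times[0] if len(self) else 0}, {self.times[-1] if len(self) else 0}])"
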