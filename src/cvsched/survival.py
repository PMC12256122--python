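"""Right-continuous step functions for survival curves and exact integrals."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InputError


@dataclass
class StepSurvival:
    """A piecewise-constant survival function on ``[origin, end]``.

    ``S(t) = 1`` for ``origin <= t < knots[0]`` and ``S(t) = values[j]`` for
    ``knots[j] <= t < knots[j+1]`` (right-continuous).  ``knots`` are the jump
    locations (e.g. event ages), strictly increasing.
    """

    origin: float
    end: float
    knots: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.knots.shape != self.values.shape:
            raise InputError("knots and values must have equal length")
        if len(self.knots) and np.any(np.diff(self.knots) <= 0):
            raise InputError("knots must be strictly increasing")
        if self.end < self.origin:
            raise InputError("end must be >= origin")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if len(self.knots) == 0:
            out = np.ones_like(t)
        else:
            idx = np.searchsorted(self.knots, t, side="right") - 1
            out = np.where(idx < 0, 1.0, self.values[np.clip(idx, 0, None)])
        return float(out) if out.ndim == 0 else out

    def integrate(self, a: float, b: float, power: float = 1.0) -> float:
        """Exact integral of ``S(t)**power`` over ``[a, b]``."""
        if b < a:
            raise InputError("integration bounds must satisfy a <= b")
        inner = self.knots[(self.knots > a) & (self.knots < b)]
        edges = np.concatenate(([a], inner, [b]))
        lengths = np.diff(edges)
        vals = self(edges[:-1])
        return float(np.sum(np.asarray(vals) ** power * lengths))

    @classmethod
    def from_cumhaz(cls, origin: float, end: float,
                    times: np.ndarray, cumhaz: np.ndarray,
                    log_hr: float = 0.0) -> "StepSurvival":
        """Build ``S(t) = exp(-Lambda(t) * exp(log_hr))`` from a baseline
        cumulative hazard given at absolute times."""
        times = np.asarray(times, dtype=float)
        cumhaz = np.asarray(cumhaz, dtype=float)
        keep = (times > origin) & (times <= end)
        return cls(origin=origin, end=end, knots=times[keep],
                   values=np.exp(-cumhaz[keep] * np.exp(log_hr)))
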