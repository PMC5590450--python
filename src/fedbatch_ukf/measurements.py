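"""Container for the online off-gas measurement series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class MeasurementSeries:
    """Time series of cumulative off-gas signals (cOUR, cCPR).

    Times are in hours and strictly increasing; the cumulative signals are
    in model units.  ``source`` optionally records where the series was
    read from.
    """

    times: np.ndarray
    cOUR: np.ndarray
    cCPR: np.ndarray
    source: str | None = field(default=None, compare=False)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        o = np.asarray(self.cOUR, dtype=float)
        c = np.asarray(self.cCPR, dtype=float)
        if not (t.shape == o.shape == c.shape) or t.ndim != 1:
            raise ValueError("times, cOUR, cCPR must be equal-length 1-d")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("measurement times must be strictly increasing")
        if not np.all(np.isfinite(t)):
            raise ValueError("measurement times must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "cOUR", o)
        object.__setattr__(self, "cCPR", c)

    def __len__(self) -> int:
        return self.times.size

    def values(self) -> np.ndarray:
        """Signals stacked as an (n, 2) array, columns (cOUR, cCPR)."""
        return np.column_stack([self.cOUR, self.cCPR])
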