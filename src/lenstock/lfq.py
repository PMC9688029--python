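"""Length-frequency table container.

Binned fork-length counts by sampling month are the common currency of the
growth and mortality analyses: ELEFAN restructures them, the catch curve pools
them. Bins are uniform, left-closed right-open [lower, lower + width), labelled
by their lower edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LengthFrequencyTable"]


def _to_month(d) -> pd.Period:
    p = pd.Period(d, freq="M") if not isinstance(d, pd.Period) else d.asfreq("M")
    return p


@dataclass
class LengthFrequencyTable:
    """Fork-length counts on a uniform length grid, one column per month.

    Parameters
    ----------
    bin_lower : array of float
        Lower edges (cm) of the length bins; strictly increasing, uniform step.
    dates : sequence
        Sampling months (anything ``pd.Period(freq='M')`` accepts).
    counts : 2-D array, shape (n_bins, n_dates)
        Non-negative counts.
    """

    bin_lower: np.ndarray
    dates: list = field(default_factory=list)
    counts: np.ndarray = None

    def __post_init__(self):
        self.bin_lower = np.asarray(self.bin_lower, dtype=float)
        self.dates = [_to_month(d) for d in self.dates]
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_lower.ndim != 1 or self.bin_lower.size == 0:
            raise ValueError("bin_lower must be a non-empty 1-D array")
        if self.bin_lower.size > 1:
            steps = np.diff(self.bin_lower)
            if np.any(steps <= 0):
                raise ValueError("bin lower edges must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
                raise ValueError("bin widths must be uniform")
        if self.counts.shape != (self.bin_lower.size, len(self.dates)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"({self.bin_lower.size} bins, {len(self.dates)} dates)"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(~np.isfinite(self.counts)):
            raise ValueError("counts must be finite")

    @property
    def bin_width(self) -> float:
        if self.bin_lower.size > 1:
            return float(self.bin_lower[1] - self.bin_lower[0])
        return float(getattr(self, "_width", 5.0))

    def set_width(self, w: float) -> None:
        # only meaningful for single-bin tables where width is not inferable
        self._width = float(w)

    @property
    def midpoints(self) -> np.ndarray:
        return self.bin_lower + 0.5 * self.bin_width

    @property
    def n_bins(self) -> int:
        return self.bin_lower.size

    @property
    def n_dates(self) -> int:
        return len(self.dates)

    def date_fracs(self) -> np.ndarray:
        """Sampling dates as decimal years at mid-month."""
        return np.array([p.year + (p.month - 0.5) / 12.0 for p in self.dates])

    def pooled(self) -> np.ndarray:
        """Counts summed over dates (catch-curve input)."""
        return self.counts.sum(axis=1)

    def total(self) -> float:
        return float(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long tidy frame with columns date, length_lower, count."""
        rows = []
        for j, d in enumerate(self.dates):
            for i, lo in enumerate(self.bin_lower):
                rows.append((str(d), lo, self.counts[i, j]))
        return pd.DataFrame(rows, columns=["date", "length_lower", "count"])

    def copy(self) -> "LengthFrequencyTable":
        out = LengthFrequencyTable(
            self.bin_lower.copy(), list(self.dates), self.counts.copy()
        )
        if hasattr(self, "_width"):
            out.set_width(self._width)
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, LengthFrequencyTable):
            return NotImplemented
        return (
            np.array_equal(self.bin_lower, other.bin_lower)
            and self.dates == other.dates
            and np.array_equal(self.counts, other.counts)
        )
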