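"""Quantiles, PTA curves, bias and percent-achieving statistics.

PTA at a target T is the fraction of the simulated population whose index
value is at least T, so PTA 90% corresponds to the population 10% quantile.
Quantiles use linear interpolation between order statistics (numpy's
default), and target attainment is the inclusive ``>=``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PTACurve",
    "BiasReport",
    "quantile",
    "pta_curve",
    "bias_percent",
    "percent_achieving",
]

#: Hours per day, for the secondary unit column of exported curves.
HOURS_PER_DAY = 24.0


def _values(sample) -> np.ndarray:
    """Accept an IndexSample-like object (``.values``) or a bare array."""
    arr = np.asarray(getattr(sample, "values", sample), dtype=float)
    if arr.ndim != 1:
        raise ValueError("sample must be one-dimensional")
    return arr


@dataclass(frozen=True)
class PTACurve:
    """PTA as a function of the target index value (days).

    ``pta[j]`` is the fraction of the population with value >= ``targets[j]``;
    non-increasing in the target by construction.
    """

    targets: np.ndarray
    pta: np.ndarray

    def to_frame(self, hours: bool = True) -> pd.DataFrame:
        """Two-column (or three with ``hours``) table for CSV export."""
        d = {"target_days": self.targets}
        if hours:
            d["target_hours"] = self.targets * HOURS_PER_DAY
        d["pta"] = self.pta
        return pd.DataFrame(d)


@dataclass(frozen=True)
class BiasReport:
    """Relative bias (in %) of a scaled quantile against its reference."""

    ref_q: float
    scaled_q: float
    bias_percent: float

    @classmethod
    def from_quantiles(cls, scaled_q: float, ref_q: float) -> "BiasReport":
        return cls(ref_q=ref_q, scaled_q=scaled_q,
                   bias_percent=bias_percent(scaled_q, ref_q))


def quantile(sample, q: float) -> float:
    """Empirical q-quantile with linear interpolation between order statistics."""
    if not (0 < q < 1):
        raise ValueError(f"quantile level must lie in (0, 1), got {q}")
    arr = _values(sample)
    if arr.size < 2:
        raise ValueError("sample must contain at least 2 values")
    return float(np.quantile(arr, q))


def pta_curve(sample, targets) -> PTACurve:
    """PTA of ``sample`` at each target: (# values >= target)/n.

    ``targets`` must be sorted ascending and positive.
    """
    t = np.asarray(targets, dtype=float)
    if t.size == 0:
        raise ValueError("targets must be non-empty")
    if np.any(t <= 0):
        raise ValueError("targets must be positive")
    if np.any(np.diff(t) < 0):
        raise ValueError("targets must be sorted ascending")
    arr = np.sort(_values(sample))
    # count of values >= target via a right-bisect on the sorted sample
    n_below = np.searchsorted(arr, t, side="left")
    pta = 1.0 - n_below / arr.size
    return PTACurve(targets=t, pta=pta)


def bias_percent(scaled_q: float, ref_q: float) -> float:
    """100 * (scaled_q - ref_q) / ref_q."""
    if not (ref_q > 0):
        raise ValueError(f"reference quantile must be positive, got {ref_q}")
    return 100.0 * (scaled_q - ref_q) / ref_q


def percent_achieving(sample, target: float) -> float:
    """Percentage of the population with index value >= ``target`` (inclusive)."""
    if not (target > 0):
        raise ValueError(f"target must be positive, got {target}")
    arr = _values(sample)
    return 100.0 * float(np.mean(arr >= target))
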