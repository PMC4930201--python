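"""Cumulative-sums (CuSUM) detection of the most prominent shift in the mean.

Each series is standardised (subtract the mean, divide by the population
standard deviation) and the running sum of the standardised values is
plotted against time.  A persistent deviation from the long-term mean
appears as a persistent slope; the turning point of the curve — the global
extremum of |CuSUM| — marks the last year of the old regime, so the shift
year reported is the following observed year.  Standardisation makes the
detected year invariant to affine rescaling of the series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ShiftReport", "cusum_curve", "detect_shift"]


@dataclass
class ShiftReport:
    name: str
    years: np.ndarray          # observed (non-missing) years
    curve: np.ndarray          # cumulative sum of standardised values
    shift_year: int | None
    direction: str             # "+" or "-"
    magnitude: float           # post-shift mean minus pre-shift mean (raw units)


def cusum_curve(series: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative sum of standardised values over the observed years.

    Missing years are skipped, not interpolated.  Returns (years, curve);
    the final curve value is ~0 because z-scores sum to zero.
    """
    s = series.dropna()
    if len(s) < 3:
        raise ValueError("need at least 3 non-missing values")
    x = s.to_numpy(dtype=float)
    sd = float(np.std(x))  # population convention (divisor n)
    if sd == 0.0:
        raise ValueError("constant series has no shift to detect")
    z = (x - float(np.mean(x))) / sd
    return s.index.to_numpy(), np.cumsum(z)


def detect_shift(series: pd.Series, name: str = "") -> ShiftReport:
    """Locate the most prominent mean shift of an annual series.

    The shift index is the global extremum of |CuSUM| (earliest year on
    ties); the reported shift year is the first observed year of the new
    regime, and the direction is the sign of (post-shift mean - pre-shift
    mean) of the raw values.
    """
    years, curve = cusum_curve(series)
    x = series.dropna().to_numpy(dtype=float)
    k = int(np.argmax(np.abs(curve)))  # argmax takes the earliest maximum
    if k + 1 < len(years):
        shift_year = int(years[k + 1])
    else:
        shift_year = None
    before = x[: k + 1]
    after = x[k + 1 :]
    magnitude = float(np.mean(after) - np.mean(before)) if after.size else 0.0
    direction = "+" if magnitude >= 0 else "-"
    return ShiftReport(
        name=name or (series.name or ""),
        years=years,
        curve=curve,
        shift_year=shift_year,
        direction=direction,
        magnitude=magnitude,
    )
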