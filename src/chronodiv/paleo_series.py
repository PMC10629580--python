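"""Paleoclimate proxy curves: representation, Tukey smoothing, interpolation.

A proxy series (delta-18-O, CO2, sea level, ...) is a pair of vectors
(ages in My before present, values in proxy units).  Before a proxy enters
a correlation or an environment-dependent rate function it is smoothed
with Tukey's compound running-median smoother and linearly interpolated
onto the target age grid; both steps live here so every consumer applies
the same preprocessing.

The smoother implemented is the classic 3RS3R compound: running medians
of 3 repeated to convergence (3R), splitting of two-point flat extrema
with the median end-value rule (S), then 3R again, the whole cycle
iterated to a fixed point.  Endpoints are copied.  Iterating to a fixed
point makes the smoother idempotent, and because every replacement is a
median of values already present, output values never leave the input
range.  Extrapolation beyond the covered age span clamps to the nearest
knot: proxies are undefined outside their coverage and clamping is
explicit and monotone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DataError


@dataclass(frozen=True)
class PaleoSeries:
    """(age, value) proxy curve with ages strictly increasing, present = 0."""

    ages: np.ndarray
    values: np.ndarray
    unit: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "values", values)
        if ages.ndim != 1 or values.ndim != 1 or len(ages) != len(values):
            raise DataError("ages and values must be 1-D vectors of equal length")
        if len(ages) < 2:
            raise DataError("a proxy series needs at least 2 points")
        if np.any(ages < 0):
            raise DataError("proxy ages must be >= 0 (My before present)")
        if np.any(np.diff(ages) <= 0):
            raise DataError("proxy ages must be strictly increasing")
        if not (np.all(np.isfinite(ages)) and np.all(np.isfinite(values))):
            raise DataError("proxy series contains non-finite entries")

    def __len__(self) -> int:
        return len(self.ages)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.ages[0]), float(self.ages[-1])


def read_series_csv(path: str, unit: str = "", name: str = "") -> PaleoSeries:
    """Read a proxy CSV with header ``age_mya,value``."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "age_mya" not in cols or "value" not in cols:
        raise DataError(f"{path}: expected columns 'age_mya,value', got {list(df.columns)}")
    df = df.sort_values(cols["age_mya"], kind="stable")
    return PaleoSeries(
        ages=df[cols["age_mya"]].to_numpy(float),
        values=df[cols["value"]].to_numpy(float),
        unit=unit,
        name=name or path,
    )


def write_series_csv(series: PaleoSeries, path: str) -> None:
    pd.DataFrame({"age_mya": series.ages, "value": series.values}).to_csv(
        path, index=False
    )


# ----------------------------------------------------------------------
def _median3_pass(v: np.ndarray) -> np.ndarray:
    """One running-median-of-3 pass, endpoints copied."""
    out = v.copy()
    if len(v) >= 3:
        stacked = np.stack([v[:-2], v[1:-1], v[2:]])
        out[1:-1] = np.median(stacked, axis=0)
    return out


def _repeat_median3(v: np.ndarray, max_iter: int = 1000) -> np.ndarray:
    for _ in range(max_iter):
        nxt = _median3_pass(v)
        if np.array_equal(nxt, v):
            return v
        v = nxt
    return v


def _split_two_flats(v: np.ndarray) -> np.ndarray:
    """Tukey's S step: break two-point flat local extrema.

    For a mesa/valley v[i] == v[i+1] strictly above/below both neighbours,
    each flat value is re-estimated with the median end-value rule from its
    own side (median of the value, its neighbour, and the linear
    extrapolant through the two points beyond it).  Medians of in-range
    values stay in range.
    """
    out = v.copy()
    n = len(v)
    for i in range(1, n - 2):
        if v[i] != v[i + 1]:
            continue
        left, right = v[i - 1], v[i + 2]
        is_mesa = left < v[i] and right < v[i]
        is_valley = left > v[i] and right > v[i]
        if not (is_mesa or is_valley):
            continue
        if i >= 2:
            out[i] = np.median([v[i], v[i - 1], 3 * v[i - 1] - 2 * v[i - 2]])
        if i + 3 < n:
            out[i + 1] = np.median([v[i + 1], v[i + 2], 3 * v[i + 2] - 2 * v[i + 3]])
    return out


def tukey_smooth(series: PaleoSeries, max_cycles: int = 50) -> PaleoSeries:
    """Tukey 3RS3R compound running-median smoother (idempotent).

    Raises
    ------
    DataError
        If the series has fewer than 3 points.
    """
    if len(series) < 3:
        raise DataError("Tukey smoothing needs at least 3 points")
    v = series.values.astype(float).copy()
    for _ in range(max_cycles):
        smoothed = _repeat_median3(v)
        smoothed = _split_two_flats(smoothed)
        smoothed = _repeat_median3(smoothed)
        if np.array_equal(smoothed, v):
            break
        v = smoothed
    return replace(series, values=v)


def interpolate_series(series: PaleoSeries, ages: np.ndarray) -> np.ndarray:
    """Piecewise-linear values at query ages; exact at knots; clamped to
    the nearest knot value outside the covered span."""
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        return np.empty(0)
    if np.any(ages < 0):
        raise DataError("query ages must be >= 0")
    # np.interp clamps to end values by default
    return np.interp(ages, series.ages, series.values)


def smooth_if_possible(series: PaleoSeries) -> PaleoSeries:
    """Tukey smooth when the series is long enough; a 2-point series has
    nothing to smooth and passes through unchanged."""
    return series if len(series) < 3 else tukey_smooth(series)


def smooth_and_interpolate(series: PaleoSeries, ages: np.ndarray) -> np.ndarray:
    """The shared preprocessing convention: Tukey smooth, then linear
    interpolation onto ``ages``."""
    return interpolate_series(smooth_if_possible(series), ages)
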