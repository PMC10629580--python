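"""Detrended cross-correlation analysis (DCCA) between rate-through-time
curves and paleoclimate proxies, and the ensemble-level significance test.

DCCA is the correlation analogue of detrended fluctuation analysis: both
series are integrated into profiles, the profiles are cut into
overlapping boxes of fixed length, each box is detrended by an ordinary
least-squares line, and the coefficient is

    rho = F2_xy / (F_x * F_y)

where F2_xy averages the residual cross-products over boxes and F_x, F_y
are the corresponding root-mean detrended variances.  rho lies in [-1, 1]
by the Cauchy-Schwarz inequality, equals +1 for identical (up to positive
affine maps) series, and -1 for sign-flipped ones.  It is preferred over
plain Pearson correlation for rate and climate curves because both are
strongly autocorrelated over short spans.

The ensemble test mirrors how a posterior of rate curves is compared with
a proxy: one coefficient per posterior draw, the proxy smoothed and
interpolated onto the ensemble's own age grid first, then a one-sample
Wilcoxon signed-rank test of the coefficient distribution against zero.
Posterior draws are correlated, so the p-value is descriptive rather than
a calibrated error rate; the mean coefficient is the headline quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .errors import DataError
from .paleo_series import PaleoSeries, smooth_and_interpolate


@dataclass(frozen=True)
class RTTEnsemble:
    """Posterior samples x age-grid matrix of speciation rates."""

    ages: np.ndarray
    rates: np.ndarray  # (n_samples, n_ages)
    source: str = ""

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        rates = np.atleast_2d(np.asarray(self.rates, dtype=float))
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "rates", rates)
        if rates.ndim != 2 or rates.shape[1] != len(ages):
            raise DataError("rates must be (n_samples, n_ages)")
        if rates.shape[0] < 1:
            raise DataError("ensemble needs at least one sample")
        if np.any(rates < 0):
            raise DataError("speciation rates must be >= 0")
        if np.any(np.diff(ages) <= 0):
            raise DataError("ensemble age grid must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.rates.shape[0]

    def mean_curve(self) -> np.ndarray:
        return self.rates.mean(axis=0)

    def restrict(self, max_age: float) -> "RTTEnsemble":
        mask = self.ages <= max_age
        if mask.sum() < 2:
            raise DataError(f"fewer than 2 grid ages at or below {max_age} My")
        return RTTEnsemble(self.ages[mask], self.rates[:, mask], self.source)


def read_rtt_csv(path: str, burnin_frac: float = 0.0) -> RTTEnsemble:
    """Read an ensemble CSV: column ``sample_id`` then one column per grid
    age (column names are the ages in My).  ``burnin_frac`` drops that
    leading fraction of rows."""
    df = pd.read_csv(path)
    if df.columns[0] != "sample_id":
        raise DataError(f"{path}: first column must be 'sample_id'")
    try:
        ages = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise DataError(f"{path}: rate columns must be named by age") from exc
    rates = df.iloc[:, 1:].to_numpy(float)
    if not 0.0 <= burnin_frac < 1.0:
        raise DataError("burnin_frac must be in [0, 1)")
    n_drop = int(round(burnin_frac * len(rates)))
    if n_drop:
        rates = rates[n_drop:]
    if len(rates) == 0:
        raise DataError("burn-in removal left no samples")
    return RTTEnsemble(ages, rates, source=path)


def write_rtt_csv(ens: RTTEnsemble, path: str) -> None:
    df = pd.DataFrame(ens.rates, columns=[f"{a:.6g}" for a in ens.ages])
    df.insert(0, "sample_id", np.arange(ens.n_samples))
    df.to_csv(path, index=False)


@dataclass(frozen=True)
class DCCAResult:
    coefficients: np.ndarray
    mean: float
    p_value: float
    box_size: int

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "p": self.p_value,
            "n_samples": int(len(self.coefficients)),
            "box_size": int(self.box_size),
        }


# ----------------------------------------------------------------------
def _detrended_residuals(profiles: np.ndarray, box_size: int) -> np.ndarray:
    """OLS-line residuals of every overlapping box of each profile row.

    profiles: (n_series, N) -> residuals (n_series, n_boxes, box_size).
    The projection matrix is shared by every box, so this is one einsum.
    """
    t = np.arange(box_size, dtype=float)
    X = np.column_stack([np.ones(box_size), t])
    # residual maker M = I - X (X'X)^-1 X'
    M = np.eye(box_size) - X @ np.linalg.solve(X.T @ X, X.T)
    windows = sliding_window_view(profiles, box_size, axis=-1)  # (s, n_boxes, box)
    return windows @ M.T


def dcca_coefficient(x: np.ndarray, y: np.ndarray, box_size: int) -> float:
    """DCCA rho between two equally-gridded series at one box scale."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("series must be 1-D and of equal length")
    if box_size < 4:
        raise DataError("box size must be >= 4")
    if len(x) < box_size:
        raise DataError(f"series length {len(x)} shorter than box size {box_size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("DCCA undefined for a constant series")
    coeffs = dcca_many(x[None, :], y, box_size)
    return float(coeffs[0])


def dcca_many(rows: np.ndarray, y: np.ndarray, box_size: int) -> np.ndarray:
    """Vectorized DCCA of many series (rows) against one series y."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    y = np.asarray(y, dtype=float)
    profiles_x = np.cumsum(rows - rows.mean(axis=1, keepdims=True), axis=1)
    profile_y = np.cumsum(y - y.mean())
    res_x = _detrended_residuals(profiles_x, box_size)
    res_y = _detrended_residuals(profile_y[None, :], box_size)[0]
    f2x = np.mean(res_x**2, axis=(1, 2))
    f2y = float(np.mean(res_y**2))
    f2xy = np.mean(res_x * res_y[None, :, :], axis=(1, 2))
    denom = np.sqrt(f2x * f2y)
    if f2y == 0 or np.any(f2x == 0):
        raise DataError("DCCA undefined: a detrended profile has zero variance")
    return f2xy / denom


def default_box_size(n: int) -> int:
    """Mid-range default scale: floor(N/4), floored at the minimum of 4."""
    return max(4, n // 4)


def ensemble_climate_test(
    ens: RTTEnsemble,
    proxy: PaleoSeries,
    box_size: int | None = None,
    wilcoxon_variant: str = "signed_rank",
) -> DCCAResult:
    """One DCCA coefficient per posterior rate curve against the proxy,
    with a rank-based test of the coefficient distribution against zero.

    The proxy is Tukey-smoothed then interpolated onto the ensemble grid
    (the enforced preprocessing order).  ``wilcoxon_variant`` selects the
    one-sample signed-rank test (default) or a two-sample rank-sum test
    against a zero vector.
    """
    n_grid = len(ens.ages)
    if box_size is None:
        box_size = default_box_size(n_grid)
    if n_grid < box_size:
        raise DataError(
            f"ensemble grid ({n_grid}) shorter than the DCCA box size ({box_size})"
        )
    proxy_on_grid = smooth_and_interpolate(proxy, ens.ages)
    coeffs = dcca_many(ens.rates, proxy_on_grid, box_size)
    mean = float(np.mean(coeffs))
    if len(coeffs) < 2 or np.ptp(coeffs) == 0 and coeffs[0] == 0:
        p = 1.0
    elif wilcoxon_variant == "signed_rank":
        p = float(stats.wilcoxon(coeffs, alternative="two-sided").pvalue)
    elif wilcoxon_variant == "rank_sum":
        p = float(stats.ranksums(coeffs, np.zeros_like(coeffs)).pvalue)
    else:
        raise DataError(f"unknown wilcoxon variant {wilcoxon_variant!r}")
    return DCCAResult(coefficients=coeffs, mean=mean, p_value=p, box_size=box_size)
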