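"""Binding-curve construction and Hill fitting.

Per-cell records (normalized dot intensity vs estimated free concentration)
are binned into fixed-width concentration windows; the bin medians, weighted
by bin occupancy, are fit with

    I(C) = I_max * C^n / (Kd^n + C^n)

by bounded nonlinear least squares.  Standard errors come from the fit
covariance (scaled by the residual variance).  Also provides the internal
consistency check that saturated dot intensity is linear in the operator
repeat number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "HillFitResult",
    "LinearityResult",
    "KdLowerBoundWarning",
    "bin_cells",
    "fit_hill",
    "hill_curve",
    "linearity_check",
]


class KdLowerBoundWarning(UserWarning):
    """The data never reach half of the fitted saturation level."""


@dataclass
class HillFitResult:
    """Fitted Hill parameters with covariance-based standard errors."""

    kd: float           # nM
    hill_n: float
    i_max: float        # normalized intensity at saturation
    se_kd: float
    se_n: float
    se_imax: float
    n_cells: int
    bin_width: float    # nM
    n_bins: int

    def __post_init__(self):
        if self.kd <= 0 or self.hill_n <= 0:
            raise ValueError("fitted kd and hill_n must be positive")


@dataclass
class LinearityResult:
    pearson_r: float
    slope: float        # intensity per operator repeat
    intercept: float


def hill_curve(conc, i_max: float, kd: float, n: float):
    """Hill binding curve; safe at ``conc == 0`` (returns 0)."""
    c = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(c > 0, (kd / np.where(c > 0, c, 1.0)) ** n, np.inf)
    return i_max / (1.0 + ratio)


def bin_cells(
    records: pd.DataFrame,
    bin_width: float = 100.0,
    conc_column: str = "free_conc_est",
    intensity_column: str = "occupancy_est",
) -> pd.DataFrame:
    """Bin usable, undiscarded cells into half-open concentration windows.

    Bins are ``[k*w, (k+1)*w)``; empty bins are omitted.  Each row reports
    the median concentration, the median normalized intensity, its 5th and
    95th percentiles, and the cell count.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    df = records
    if "usable" in df:
        df = df[df["usable"]]
    if "discarded" in df:
        df = df[~df["discarded"]]
    # occupancy > 1.05 is unphysical for a single array (replicated pair the
    # bright-dot filter could not cut in a sparse bin) — leave it out.
    if "occupancy_outlier" in df:
        df = df[~df["occupancy_outlier"].astype(bool)]
    df = df.dropna(subset=[conc_column, intensity_column])
    if len(df) == 0:
        raise ValueError("no usable records to bin")
    k = np.floor(df[conc_column].to_numpy() / bin_width).astype(int)
    rows = []
    for bin_index in sorted(set(k)):
        sel = df[k == bin_index]
        inten = sel[intensity_column].to_numpy()
        rows.append(
            {
                "bin_left": bin_index * bin_width,
                "bin_right": (bin_index + 1) * bin_width,
                "conc_median": float(np.median(sel[conc_column])),
                "intensity_median": float(np.median(inten)),
                "intensity_p5": float(np.percentile(inten, 5)),
                "intensity_p95": float(np.percentile(inten, 95)),
                "count": int(len(sel)),
            }
        )
    binned = pd.DataFrame(rows)
    if len(binned) < 2:
        raise ValueError("all cells fall in a single concentration bin; curve unfittable")
    return binned


def fit_hill(
    conc: Union[pd.DataFrame, Sequence[float]],
    intensity: Optional[Sequence[float]] = None,
    weights: Optional[Sequence[float]] = None,
    *,
    n_cells: Optional[int] = None,
    bin_width: float = float("nan"),
) -> HillFitResult:
    """Weighted least-squares Hill fit of a binned binding curve.

    Accepts either the DataFrame from :func:`bin_cells` or explicit
    ``(conc, intensity, weights)`` arrays.  Initialization: ``Kd0`` at the
    concentration where the curve crosses half its maximum, ``n0 = 2``;
    bounds ``Kd in (1e-3, 1e5) nM``, ``n in (0.2, 10)``.  Warns via
    :class:`KdLowerBoundWarning` when the data never reach half the fitted
    saturation level, in which case the fitted Kd is only a lower bound.
    """
    if isinstance(conc, pd.DataFrame):
        binned = conc
        x = binned["conc_median"].to_numpy(dtype=float)
        y = binned["intensity_median"].to_numpy(dtype=float)
        w = binned["count"].to_numpy(dtype=float)
        if n_cells is None:
            n_cells = int(binned["count"].sum())
    else:
        x = np.asarray(conc, dtype=float)
        y = np.asarray(intensity, dtype=float)
        w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
        if n_cells is None:
            n_cells = int(round(w.sum()))
    if len(x) < 3:
        raise ValueError("need at least 3 bins to fit three parameters")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")

    imax0 = float(y.max())
    if imax0 <= 0:
        raise ValueError("all intensities are zero; nothing to fit")
    above = x[y >= imax0 / 2]
    kd0 = float(above.min()) if len(above) else float(np.median(x))
    kd0 = min(max(kd0, 1e-2), 9e4)
    p0 = (imax0, kd0, 2.0)
    bounds = ([1e-6, 1e-3, 0.2], [max(10.0 * imax0, 10.0), 1e5, 10.0])
    sigma = 1.0 / np.sqrt(w)
    try:
        popt, pcov = curve_fit(
            hill_curve,
            x,
            y,
            p0=p0,
            sigma=sigma,
            absolute_sigma=False,
            bounds=bounds,
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"Hill fit failed to converge (p0={p0}, {len(x)} bins, "
            f"x range {x.min():.3g}-{x.max():.3g} nM): {exc}"
        ) from exc
    i_max, kd, n = (float(v) for v in popt)
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    se_imax, se_kd, se_n = (float(v) if np.isfinite(v) else float("inf") for v in perr)
    if float(y.max()) < 0.5 * i_max:
        warnings.warn(
            "data never reach half of the fitted saturation level; "
            "the fitted Kd is a lower bound",
            KdLowerBoundWarning,
        )
    return HillFitResult(
        kd=kd,
        hill_n=n,
        i_max=i_max,
        se_kd=se_kd,
        se_n=se_n,
        se_imax=se_imax,
        n_cells=int(n_cells),
        bin_width=float(bin_width),
        n_bins=len(x),
    )


def linearity_check(
    repeat_counts: Sequence[float], saturated_intensities: Sequence[float]
) -> LinearityResult:
    """Pearson correlation and slope of saturated dot intensity vs array size."""
    reps = np.asarray(repeat_counts, dtype=float)
    inten = np.asarray(saturated_intensities, dtype=float)
    if len(reps) < 3:
        raise ValueError("need at least 3 array sizes")
    if np.std(reps) == 0 or np.std(inten) == 0:
        raise ValueError("zero variance in inputs; correlation undefined")
    r, _ = stats.pearsonr(reps, inten)
    slope, intercept = np.polyfit(reps, inten, 1)
    return LinearityResult(pearson_r=float(r), slope=float(slope), intercept=float(intercept))
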