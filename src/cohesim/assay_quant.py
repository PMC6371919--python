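"""Quantification of the phosphate-release ATPase assay.

A coupled colorimetric assay reports inorganic phosphate release as
absorbance at 360 nm.  Absorbance is converted to phosphate concentration
through a KH2PO4 standard curve (ordinary least squares), and the hydrolysis
rate is the slope of the linear phase of the reaction — by convention the
first 10 minutes — divided by the standard-curve slope, giving µM phosphate
per minute.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StandardCurve",
    "AbsorbanceSeries",
    "RateEstimate",
    "fit_phosphate_standard_curve",
    "atpase_rate",
]


@dataclass(frozen=True)
class StandardCurve:
    """Linear phosphate standard: AU = slope * µM + intercept."""

    slope: float  # AU per µM phosphate
    intercept: float  # AU
    fit_residual: float = 0.0  # root-mean-square AU


@dataclass
class AbsorbanceSeries:
    """Absorbance (AU at 360 nm) sampled at strictly increasing times (min)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class RateEstimate:
    rate: float  # µM phosphate per minute
    window: tuple[float, float]  # minutes used for the fit
    r_squared: float


def fit_phosphate_standard_curve(
    concentrations: Sequence[float], absorbances: Sequence[float]
) -> StandardCurve:
    """Ordinary least-squares line through (µM, AU) standard points."""
    conc = np.asarray(concentrations, dtype=float)
    au = np.asarray(absorbances, dtype=float)
    if conc.shape != au.shape or conc.ndim != 1:
        raise ValueError("concentrations and absorbances must match in length")
    if np.unique(conc).size < 2:
        raise ValueError("degenerate curve: need at least 2 distinct concentrations")
    fit = stats.linregress(conc, au)
    resid = au - (fit.slope * conc + fit.intercept)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        fit_residual=float(np.sqrt(np.mean(resid**2))),
    )


def atpase_rate(
    series: AbsorbanceSeries,
    curve: StandardCurve,
    window_minutes: float = 10.0,
    baseline: AbsorbanceSeries | None = None,
) -> RateEstimate:
    """Hydrolysis rate from the slope of the linear phase.

    Fits AU vs time over [0, ``window_minutes``] by least squares and divides
    the slope by ``curve.slope`` to obtain µM phosphate/min.  If a no-protein
    ``baseline`` series is given, its rate over the same window is subtracted
    (off by default).
    """
    if curve.slope <= 0:
        raise ValueError("standard curve slope must be positive")
    mask = series.times <= window_minutes
    t = series.times[mask]
    y = series.values[mask]
    if t.size < 3:
        raise ValueError(
            f"window too sparse: {t.size} points within [0, {window_minutes}] min"
        )
    fit = stats.linregress(t, y)
    rate = float(fit.slope) / curve.slope
    if baseline is not None:
        rate -= atpase_rate(baseline, curve, window_minutes).rate
    r2 = float(fit.rvalue**2) if np.std(y) > 0 else 1.0
    return RateEstimate(
        rate=rate,
        window=(float(t[0]), float(min(window_minutes, series.times[-1]))),
        r_squared=r2,
    )
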