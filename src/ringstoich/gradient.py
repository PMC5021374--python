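"""Rate-zonal gradient analysis: mass calibration, peak detection, oligomer calls.

Fractions are numbered 1..n bottom-to-top, so heavier species peak at
*smaller* indices.  Over a narrow mass range, peak fraction is well
approximated as linear in log10(mass); two or more marker proteins of known
mass anchor that line.  Detected profile peaks are converted to apparent
masses and snapped to the nearest integer multiple of the subunit mass to
call monomer/dimer/higher oligomer states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "GradientProfile",
    "MarkerSet",
    "CalibrationFit",
    "Peak",
    "OligomerAssignment",
    "calibrate",
    "predict_fraction",
    "predict_mass",
    "detect_peaks",
    "assign_oligomer_states",
]

DEFAULT_N_FRACTIONS = 31


@dataclass(frozen=True)
class GradientProfile:
    """Fluorescence intensity per fraction, indices contiguous from 1."""

    fraction: tuple[int, ...]
    intensity: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.fraction)
        if n == 0:
            raise ValueError("empty profile")
        if len(self.intensity) != n:
            raise ValueError("fraction and intensity lengths differ")
        if tuple(self.fraction) != tuple(range(1, n + 1)):
            raise ValueError("fraction indices must be contiguous from 1")
        if any(i < 0 for i in self.intensity):
            raise ValueError("intensities must be nonnegative")

    @classmethod
    def from_intensities(cls, intensity: Sequence[float]) -> "GradientProfile":
        return cls(tuple(range(1, len(intensity) + 1)), tuple(float(v) for v in intensity))


@dataclass(frozen=True)
class MarkerSet:
    """Calibration anchors: (mass in kDa, observed peak fraction)."""

    markers: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.markers) < 2:
            raise ValueError("need at least 2 markers to calibrate")
        masses = [m for m, _ in self.markers]
        if any(m <= 0 for m in masses):
            raise ValueError("marker masses must be positive")
        if len(set(masses)) != len(masses):
            raise ValueError("marker masses must be distinct")


@dataclass(frozen=True)
class CalibrationFit:
    """Line peak_fraction = slope * log10(mass kDa) + intercept."""

    slope: float
    intercept: float
    residuals: tuple[float, ...] = ()


@dataclass(frozen=True)
class Peak:
    fraction: float  # refined, real-valued, 1-based
    height: float


@dataclass(frozen=True)
class OligomerAssignment:
    peak: Peak
    order: int | None  # None = unassigned within tolerance
    mass_kda: float


def calibrate(markers: MarkerSet) -> CalibrationFit:
    """Least-squares fit of peak fraction on log10(mass); exact for 2 markers."""
    x = np.log10([m for m, _ in markers.markers])
    y = np.array([f for _, f in markers.markers])
    slope, intercept = np.polyfit(x, y, 1)
    residuals = y - (slope * x + intercept)
    return CalibrationFit(float(slope), float(intercept), tuple(residuals))


def predict_fraction(mass_kda: float, fit: CalibrationFit) -> float:
    """Expected peak fraction for a species of the given mass."""
    if mass_kda <= 0:
        raise ValueError("mass must be positive")
    return fit.slope * math.log10(mass_kda) + fit.intercept


def predict_mass(fraction: float, fit: CalibrationFit) -> float:
    """Inverse of :func:`predict_fraction`: apparent mass at a peak fraction."""
    if fit.slope == 0:
        raise ValueError("degenerate calibration (zero slope)")
    return 10.0 ** ((fraction - fit.intercept) / fit.slope)


def _parabolic_refine(y: np.ndarray, i: int) -> tuple[float, float]:
    """3-point parabola vertex around index i; returns (offset, height)."""
    if i == 0 or i == len(y) - 1:
        return 0.0, float(y[i])
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return 0.0, float(y[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    height = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta
    return float(delta), float(height)


def detect_peaks(
    profile: GradientProfile,
    smoothing_window: int = 3,
    min_prominence: float = 0.1,
) -> "list[Peak]":
    """Moving-average smoothing, prominence-filtered maxima, parabolic refinement.

    ``min_prominence`` is a fraction of the smoothed profile's maximum.
    Returns peaks sorted by fraction index; a flat (all-equal) profile yields
    an empty list.
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be a positive odd integer")
    y = np.asarray(profile.intensity, dtype=float)
    if smoothing_window >= len(y):
        raise ValueError("smoothing_window must be smaller than the profile")
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        # reflect-pad so edge fractions keep a full-width average
        pad = smoothing_window // 2
        ypad = np.pad(y, pad, mode="edge")
        y = np.convolve(ypad, kernel, mode="valid")
    ymax = y.max()
    if ymax <= 0 or np.ptp(y) == 0:
        return []
    idx, _ = find_peaks(y, prominence=min_prominence * ymax)
    peaks = []
    for i in idx:
        delta, height = _parabolic_refine(y, i)
        peaks.append(Peak(fraction=float(profile.fraction[i]) + delta, height=height))
    return sorted(peaks, key=lambda pk: pk.fraction)


def assign_oligomer_states(
    peaks: Sequence[Peak],
    fit: CalibrationFit,
    subunit_mass: float,
    tolerance: float = 0.1,
) -> "list[OligomerAssignment]":
    """Call each peak's oligomer order from its calibrated apparent mass.

    The order is the nearest integer multiple ``n`` of ``subunit_mass`` whose
    mass lies within relative ``tolerance`` of the apparent mass; peaks
    outside tolerance are flagged unassigned (order None), never fatal.
    """
    if subunit_mass <= 0:
        raise ValueError("subunit mass must be positive")
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    out = []
    for pk in peaks:
        mass = predict_mass(pk.fraction, fit)
        n = max(1, round(mass / subunit_mass))
        rel_err = abs(mass - n * subunit_mass) / (n * subunit_mass)
        out.append(
            OligomerAssignment(
                peak=pk,
                order=n if rel_err <= tolerance else None,
                mass_kda=mass,
            )
        )
    return out
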