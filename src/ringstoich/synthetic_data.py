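"""Seeded generators for titration datasets and gradient profiles.

The generators emit data with exactly the statistical structure the
inference modules assume: Poisson plaque counts whose mean follows the
chosen ring model's activity curve, and 31-fraction gradient traces built
as Gaussian peaks on a log-mass calibration line plus truncated Gaussian
noise.  Each design carries its own seed and round-trips deterministically.

Defaults mirror the titration experiment this package models: mutant
fractions 0 to 0.9 in steps of 0.1, three replicates, and a control
(p = 0) expectation of 500 plaque counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .assembly_model import DimerRule, RingModel, relative_activity
from .gradient import (
    DEFAULT_N_FRACTIONS,
    CalibrationFit,
    GradientProfile,
    MarkerSet,
    calibrate,
    predict_fraction,
)
from .inference import TitrationDataset, TitrationRow

__all__ = [
    "DEFAULT_P_GRID",
    "TitrationDesign",
    "GradientDesign",
    "simulate_titration",
    "simulate_gradient_profile",
]

DEFAULT_P_GRID = tuple(round(0.1 * i, 1) for i in range(10))  # 0.0 .. 0.9


@dataclass(frozen=True)
class TitrationDesign:
    """Design of a simulated mutant-titration assembly assay."""

    truth: RingModel
    rule: DimerRule = DimerRule()
    p_grid: tuple[float, ...] = DEFAULT_P_GRID
    n_replicates: int = 3
    control_mean: float = 500.0
    scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if 0.0 not in self.p_grid:
            raise ValueError("p_grid must include the p = 0 control")
        if any(not 0.0 <= p <= 1.0 for p in self.p_grid):
            raise ValueError("p_grid values must lie in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.control_mean <= 0:
            raise ValueError("control_mean must be positive")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


@dataclass(frozen=True)
class GradientDesign:
    """Design of a simulated gradient fractionation trace.

    ``species`` lists (mass kDa, relative abundance); peak centers come from
    the calibration, widths are a common Gaussian s.d. in fraction units.
    """

    species: tuple[tuple[float, float], ...]
    calibration: CalibrationFit | MarkerSet
    peak_width: float = 1.2
    noise_sd: float = 0.05
    n_fractions: int = DEFAULT_N_FRACTIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for _, a in self.species):
            raise ValueError("species abundances must be positive")
        if any(m <= 0 for m, _ in self.species):
            raise ValueError("species masses must be positive")
        if self.peak_width <= 0:
            raise ValueError("peak_width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_fractions < 2:
            raise ValueError("need at least 2 fractions")

    @property
    def fit(self) -> CalibrationFit:
        if isinstance(self.calibration, MarkerSet):
            return calibrate(self.calibration)
        return self.calibration


def simulate_titration(design: TitrationDesign) -> TitrationDataset:
    """Draw Poisson plaque counts with mean control_mean * scale * A(p).

    The returned dataset records the generating model in ``truth`` so
    recovery studies can score themselves.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    import warnings as _warnings

    for p in design.p_grid:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # p = 1 no-dimer convention
            a = relative_activity(p, design.truth, design.rule)
        mean = design.control_mean * design.scale * a
        counts = rng.poisson(mean, size=design.n_replicates)
        rows.append(
            TitrationRow(
                p=float(p),
                counts=tuple(int(c) for c in counts),
                scales=(design.scale,) * design.n_replicates,
            )
        )
    return TitrationDataset(tuple(rows), truth=design.truth)


def simulate_gradient_profile(design: GradientDesign) -> GradientProfile:
    """Sum of calibrated Gaussian peaks plus zero-truncated Gaussian noise."""
    fit = design.fit
    fractions = np.arange(1, design.n_fractions + 1, dtype=float)
    intensity = np.zeros_like(fractions)
    for mass, abundance in design.species:
        center = predict_fraction(mass, fit)
        if not 1.0 <= center <= design.n_fractions:
            raise ValueError(
                f"species of {mass} kDa predicts peak at fraction {center:.2f}, "
                f"outside [1, {design.n_fractions}]"
            )
        intensity += abundance * np.exp(
            -0.5 * ((fractions - center) / design.peak_width) ** 2
        )
    if design.noise_sd > 0:
        rng = np.random.default_rng(design.seed)
        intensity = intensity + rng.normal(0.0, design.noise_sd, size=len(fractions))
    intensity = np.clip(intensity, 0.0, None)
    return GradientProfile.from_intensities(intensity)
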