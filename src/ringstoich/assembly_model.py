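"""Closed-form activity curves for rings assembled from a wild-type/mutant pool.

A ring motor built from ``z`` subunits is "poisoned" when it contains at
least ``K`` inactive (mutant) subunits.  If subunits are drawn independently
from a pool with mutant fraction ``p``, the probability that a ring remains
active is the cumulative binomial

    A(p) = sum_{m=0}^{K-1} C(z, m) p^m (1 - p)^(z - m),

the classical one-hit poisoning model used to read ring stoichiometry off a
mutant-titration inhibition curve.  A second assembly mode covers asymmetric
rings seeded by one preformed noncovalent dimer plus ``z - 2`` independent
monomers, where dimer formation itself requires at least one partner with an
intact arginine finger (mutant-mutant dimers never form), as observed for the
phi29 packaging ATPase gp16.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import binom

__all__ = [
    "AssemblyMode",
    "RingModel",
    "SubunitPool",
    "DimerRule",
    "NoDimerError",
    "relative_activity_random",
    "relative_activity_dimer_seeded",
    "relative_activity",
    "dimer_type_distribution",
    "activity_curve",
]


class AssemblyMode(str, enum.Enum):
    """How a ring is assembled from the subunit pool."""

    RANDOM = "random"
    DIMER_SEEDED = "dimer_seeded"


class NoDimerError(ValueError):
    """Raised when an all-mutant pool cannot seed any dimer."""


@dataclass(frozen=True)
class RingModel:
    """Structural hypothesis for the ring: subunit count, blocking number, mode.

    Parameters
    ----------
    z
        Number of subunits in the ring (z >= 1; z >= 2 for dimer-seeded mode).
    k
        Blocking number: the minimum count of mutant subunits that
        inactivates the ring.  ``k = 1`` is single-poison blocking.  ``k > z``
        is allowed as a degenerate hypothesis whose activity is identically 1.
    mode
        Assembly mode, :class:`AssemblyMode` or its string value.
    """

    z: int
    k: int = 1
    mode: AssemblyMode = AssemblyMode.RANDOM

    def __post_init__(self) -> None:
        if self.z < 1:
            raise ValueError(f"z must be >= 1, got {self.z}")
        if self.k < 1:
            raise ValueError(f"blocking number k must be >= 1, got {self.k}")
        object.__setattr__(self, "mode", AssemblyMode(self.mode))
        if self.mode is AssemblyMode.DIMER_SEEDED and self.z < 2:
            raise ValueError("dimer-seeded assembly requires z >= 2")


@dataclass(frozen=True)
class SubunitPool:
    """A mixing pool characterized by its mutant fraction ``p``."""

    p: float

    def __post_init__(self) -> None:
        _check_fraction(self.p)


@dataclass(frozen=True)
class DimerRule:
    """Whether dimer formation requires an arginine-finger donor.

    With ``requires_donor`` (the behaviour seen for the gp16 arginine-finger
    mutant), a dimer forms only when at least one partner carries an intact
    finger, so mutant-mutant dimers have probability zero.
    """

    requires_donor: bool = True


# number of mutant subunits each dimer class contributes to the ring
_DIMER_MUTANTS = {"WW": 0, "WM": 1, "MM": 2}


def _check_fraction(p: float) -> None:
    if not 0.0 <= p <= 1.0 or math.isnan(p):
        raise ValueError(f"mutant fraction must lie in [0, 1], got {p}")


def _binom_cdf_below(k: int, n: int, p: float) -> float:
    """P(X < k) for X ~ Binomial(n, p); 0 for k <= 0, 1 for k > n."""
    if k <= 0:
        return 0.0
    if k > n:
        return 1.0
    return float(binom.cdf(k - 1, n, p))


def relative_activity_random(p: float, model: RingModel) -> float:
    """Active-ring probability under independent (random) assembly.

    Returns P(ring contains fewer than ``model.k`` mutants) when each of the
    ``model.z`` subunits is mutant independently with probability ``p``.
    """
    if model.mode is not AssemblyMode.RANDOM:
        raise ValueError("model.mode must be 'random'")
    _check_fraction(p)
    return _binom_cdf_below(model.k, model.z, p)


def dimer_type_distribution(p: float, rule: DimerRule) -> dict[str, float]:
    """Distribution over unordered dimer compositions at mutant fraction ``p``.

    Pair classes are WW (both wild type), WM (mixed) and, only when the rule
    does not demand a donor, MM.  Under ``requires_donor`` the MM class is
    excluded and the remaining probabilities are renormalized:
    WW = (1-p)/(1+p), WM = 2p/(1+p).

    Raises
    ------
    NoDimerError
        If ``p == 1`` while ``rule.requires_donor`` — an all-mutant pool
        cannot seed any ring.
    """
    _check_fraction(p)
    ww = (1.0 - p) ** 2
    wm = 2.0 * p * (1.0 - p)
    mm = p**2
    if not rule.requires_donor:
        return {"WW": ww, "WM": wm, "MM": mm}
    total = ww + wm
    if total == 0.0:
        raise NoDimerError("all-mutant pool: no dimer can form with requires_donor")
    return {"WW": ww / total, "WM": wm / total}


def relative_activity_dimer_seeded(
    p: float, model: RingModel, rule: DimerRule = DimerRule()
) -> float:
    """Active-ring probability for dimer-seeded assembly.

    The ring is one dimer drawn from :func:`dimer_type_distribution` plus
    ``z - 2`` independent monomers at pool frequency ``p``; the ring is
    active iff its total mutant count is below ``model.k``.  For single-poison
    blocking (k = 1) on a hexamer this is ``[(1-p)/(1+p)] * (1-p)**4``.

    At ``p == 1`` with a donor-requiring rule no dimer forms; by convention
    the activity is 0 and a warning is emitted.
    """
    if model.mode is not AssemblyMode.DIMER_SEEDED:
        raise ValueError("model.mode must be 'dimer_seeded'")
    _check_fraction(p)
    try:
        dist = dimer_type_distribution(p, rule)
    except NoDimerError:
        warnings.warn(
            "p = 1: no dimers form under the donor rule; activity is 0",
            stacklevel=2,
        )
        return 0.0
    return sum(
        weight * _binom_cdf_below(model.k - _DIMER_MUTANTS[kind], model.z - 2, p)
        for kind, weight in dist.items()
    )


def relative_activity(
    p: float, model: RingModel, rule: DimerRule = DimerRule()
) -> float:
    """Mode-dispatching activity: random or dimer-seeded per ``model.mode``."""
    if model.mode is AssemblyMode.RANDOM:
        return relative_activity_random(p, model)
    return relative_activity_dimer_seeded(p, model, rule)


def activity_curve(
    model: RingModel,
    p_grid: "list[float]",
    rule: DimerRule = DimerRule(),
) -> pd.DataFrame:
    """Tabulate A(p) over ``p_grid`` (input order preserved).

    Returns a two-column DataFrame ``(p, activity)`` suitable for CSV export.
    """
    rows = [(float(p), relative_activity(p, model, rule)) for p in p_grid]
    return pd.DataFrame(rows, columns=["p", "activity"])
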