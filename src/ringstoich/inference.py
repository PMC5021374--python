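"""Maximum-likelihood stoichiometry inference from mutant-titration counts.

The virion-assembly readout is a plaque count, modelled as Poisson with mean
``A0 * scale * A(p)`` where ``A0`` is the expected control count per unit
scale (the p = 0 baseline) and ``A(p)`` the model activity curve.  The
structural hypothesis (z, K, assembly mode) lives on an integer grid; each
cell is profiled over ``A0`` in closed form, and the winner is chosen by AIC
with a deterministic tie-break.  Bootstrap confidence intervals resample
titration rows (stratified to always retain a control row).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import poisson

from .assembly_model import AssemblyMode, DimerRule, RingModel, relative_activity

__all__ = [
    "TitrationRow",
    "TitrationDataset",
    "FitResult",
    "loglik",
    "profile_A0",
    "fit_stoichiometry",
    "bootstrap_ci",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class TitrationRow:
    """One mutant fraction with its replicate plaque counts and scales."""

    p: float
    counts: tuple[int, ...]
    scales: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"mutant fraction must lie in [0, 1], got {self.p}")
        if len(self.counts) == 0:
            raise ValueError("row needs at least one replicate count")
        if len(self.counts) != len(self.scales):
            raise ValueError("counts and scales must have equal length")
        if any(c < 0 or c != int(c) for c in self.counts):
            raise ValueError("counts must be nonnegative integers")
        if any(s <= 0 for s in self.scales):
            raise ValueError("scales must be positive")


@dataclass(frozen=True)
class TitrationDataset:
    """Rows of (p, replicate counts, scales); fitting requires a p = 0 row.

    ``truth`` optionally records the generating model for recovery studies.
    """

    rows: tuple[TitrationRow, ...]
    truth: RingModel | None = None

    def __post_init__(self) -> None:
        if len(self.rows) == 0:
            raise ValueError("dataset has no rows")

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[float, Sequence[int], Sequence[float] | float]],
        truth: RingModel | None = None,
    ) -> "TitrationDataset":
        """Build from (p, counts, scale-or-scales) tuples; scalar scale is broadcast."""
        rows = []
        for p, counts, scale in records:
            counts = tuple(int(c) for c in counts)
            if np.isscalar(scale):
                scales = (float(scale),) * len(counts)
            else:
                scales = tuple(float(s) for s in scale)
            rows.append(TitrationRow(float(p), counts, scales))
        return cls(tuple(rows), truth=truth)

    @property
    def has_control(self) -> bool:
        return any(row.p == 0.0 for row in self.rows)

    def require_control(self) -> None:
        if not self.has_control:
            raise ValueError(
                "dataset lacks a p = 0 control row; baseline A0 is unidentifiable"
            )


@dataclass(frozen=True)
class FitResult:
    """Selected ring hypothesis with the full grid's likelihood bookkeeping."""

    z_hat: int
    k_hat: int
    mode_hat: AssemblyMode
    a0_hat: float
    loglik_table: dict[tuple[int, int, str], float]
    criterion_table: dict[tuple[int, int, str], float]
    ci: dict[str, tuple[float, float]] | None = None

    @property
    def model(self) -> RingModel:
        return RingModel(self.z_hat, self.k_hat, self.mode_hat)

    def to_dict(self) -> dict:
        return {
            "z_hat": self.z_hat,
            "k_hat": self.k_hat,
            "mode_hat": self.mode_hat.value,
            "a0_hat": self.a0_hat,
            "loglik_table": [
                {"z": z, "k": k, "mode": mode, "loglik": ll}
                for (z, k, mode), ll in sorted(self.loglik_table.items())
            ],
            "criterion_table": [
                {"z": z, "k": k, "mode": mode, "aic": v}
                for (z, k, mode), v in sorted(self.criterion_table.items())
            ],
            "ci": self.ci,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _activities(data: TitrationDataset, model: RingModel, rule: DimerRule) -> np.ndarray:
    import warnings as _warnings

    with _warnings.catch_warnings():
        # the p = 1 no-dimer convention (activity 0) is expected during grid scans
        _warnings.simplefilter("ignore")
        return np.array([relative_activity(row.p, model, rule) for row in data.rows])


def loglik(
    data: TitrationDataset,
    model: RingModel,
    a0: float,
    rule: DimerRule = DimerRule(),
    background: float = 0.0,
) -> float:
    """Poisson log-likelihood of the dataset under (model, A0).

    Each replicate count contributes ``log Poisson(count | mu)`` with
    ``mu = scale * (a0 * A(p) + background)``.  With ``background = 0`` a
    positive count at A(p) = 0 yields ``-inf``; a zero count there
    contributes 0.
    """
    if a0 <= 0:
        raise ValueError("A0 must be positive")
    if background < 0:
        raise ValueError("background rate must be nonnegative")
    activities = _activities(data, model, rule)
    total = 0.0
    for row, a in zip(data.rows, activities):
        for count, scale in zip(row.counts, row.scales):
            mu = scale * (a0 * a + background)
            if mu == 0.0:
                if count > 0:
                    return NEG_INF
                continue  # Poisson(0 | 0) = 1
            total += float(poisson.logpmf(count, mu))
    return total


def profile_A0(
    data: TitrationDataset,
    model: RingModel,
    rule: DimerRule = DimerRule(),
) -> float:
    """Closed-form Poisson MLE of the baseline: sum(counts) / sum(scale * A(p)).

    Rows with A(p) = 0 carry no information about A0 and are excluded.
    """
    activities = _activities(data, model, rule)
    num = 0.0
    den = 0.0
    for row, a in zip(data.rows, activities):
        if a <= 0.0:
            continue
        num += sum(row.counts)
        den += a * sum(row.scales)
    if den == 0.0:
        raise ValueError("no row with positive model activity; A0 undefined")
    return num / den


def _grid_cells(
    z_range: tuple[int, int], modes: Sequence[AssemblyMode]
) -> "list[RingModel]":
    z_lo, z_hi = z_range
    if z_lo < 1 or z_hi < z_lo:
        raise ValueError(f"invalid z range {z_range}")
    cells = []
    for z in range(z_lo, z_hi + 1):
        for k in range(1, z + 1):
            for mode in modes:
                if mode is AssemblyMode.DIMER_SEEDED and z < 2:
                    continue
                cells.append(RingModel(z, k, mode))
    return cells


def fit_stoichiometry(
    data: TitrationDataset,
    z_range: tuple[int, int] = (1, 12),
    modes: Sequence[AssemblyMode | str] = (AssemblyMode.RANDOM,),
    rule: DimerRule = DimerRule(),
    background: float = 0.0,
    complexity_penalty: float = 0.0,
) -> FitResult:
    """Exhaustive ML grid search over z in z_range, K in 1..z, mode in modes.

    Each cell's baseline is profiled via :func:`profile_A0`; cells are ranked
    by AIC with 2 effective parameters each, plus an optional
    ``complexity_penalty * (z + K)`` term guarding against integer
    overfitting.  Ties break deterministically toward smallest z, then
    smallest K, then random mode before dimer-seeded.
    """
    data.require_control()
    modes = [AssemblyMode(m) for m in modes]
    best: tuple | None = None
    loglik_table: dict[tuple[int, int, str], float] = {}
    criterion_table: dict[tuple[int, int, str], float] = {}
    best_a0 = float("nan")
    for model in _grid_cells(z_range, modes):
        try:
            a0 = profile_A0(data, model, rule)
        except ValueError:
            ll = NEG_INF
            a0 = float("nan")
        else:
            ll = loglik(data, model, a0, rule, background)
        key = (model.z, model.k, model.mode.value)
        loglik_table[key] = ll
        aic = 2 * 2 - 2 * ll + complexity_penalty * (model.z + model.k)
        criterion_table[key] = aic
        # lexicographic preference implements the tie-break
        rank = (aic, model.z, model.k, 0 if model.mode is AssemblyMode.RANDOM else 1)
        if best is None or rank < best[0]:
            best = (rank, model)
            best_a0 = a0
    assert best is not None
    if math.isinf(best[0][0]) and best[0][0] > 0:
        raise ValueError("every grid cell has zero likelihood; no fit possible")
    winner = best[1]
    return FitResult(
        z_hat=winner.z,
        k_hat=winner.k,
        mode_hat=winner.mode,
        a0_hat=best_a0,
        loglik_table=loglik_table,
        criterion_table=criterion_table,
    )


def bootstrap_ci(
    data: TitrationDataset,
    n_boot: int,
    seed: int,
    alpha: float = 0.05,
    **fit_kwargs,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap intervals for z_hat and K_hat.

    Resamples titration rows with replacement, stratified into control
    (p = 0) and non-control strata so every replicate keeps a control row,
    then refits.  Reproducible for a fixed seed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    data.require_control()
    rng = np.random.default_rng(seed)
    controls = [r for r in data.rows if r.p == 0.0]
    others = [r for r in data.rows if r.p != 0.0]
    z_samples = np.empty(n_boot, dtype=int)
    k_samples = np.empty(n_boot, dtype=int)
    for b in range(n_boot):
        picked = [controls[i] for i in rng.integers(len(controls), size=len(controls))]
        if others:
            picked += [others[i] for i in rng.integers(len(others), size=len(others))]
        fit = fit_stoichiometry(TitrationDataset(tuple(picked)), **fit_kwargs)
        z_samples[b] = fit.z_hat
        k_samples[b] = fit.k_hat
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    return {
        "z": tuple(np.percentile(z_samples, [lo, hi])),
        "k": tuple(np.percentile(k_samples, [lo, hi])),
    }
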