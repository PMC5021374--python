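"""CSV/JSON readers and writers for the package's file dialects.

Dialects (header required, UTF-8, dot decimal):

* titration:  ``mutant_fraction, replicate, count, scale``
* profile:    ``fraction, intensity``
* markers:    ``mass_kda, peak_fraction``

Readers reject files whose headers differ from the dialect — no silent
column guessing.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .gradient import GradientProfile, MarkerSet
from .inference import TitrationDataset, TitrationRow

__all__ = [
    "read_titration_csv",
    "write_titration_csv",
    "read_profile_csv",
    "write_profile_csv",
    "read_markers_csv",
    "write_json",
]

TITRATION_COLUMNS = ["mutant_fraction", "replicate", "count", "scale"]
PROFILE_COLUMNS = ["fraction", "intensity"]
MARKER_COLUMNS = ["mass_kda", "peak_fraction"]


class DialectError(ValueError):
    """A file's header does not match the documented dialect."""


def _read_checked(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DialectError(f"{path}: empty file") from exc
    if list(df.columns) != list(columns):
        raise DialectError(
            f"{path}: header {list(df.columns)} does not match the "
            f"required columns {list(columns)}"
        )
    return df


def read_titration_csv(path: str | Path) -> TitrationDataset:
    """Load a titration table, grouping replicates by mutant fraction."""
    df = _read_checked(path, TITRATION_COLUMNS)
    if df.empty:
        raise DialectError(f"{path}: no data rows")
    rows = []
    for p, grp in df.groupby("mutant_fraction", sort=True):
        grp = grp.sort_values("replicate")
        rows.append(
            TitrationRow(
                p=float(p),
                counts=tuple(int(c) for c in grp["count"]),
                scales=tuple(float(s) for s in grp["scale"]),
            )
        )
    return TitrationDataset(tuple(rows))


def write_titration_csv(data: TitrationDataset, path: str | Path) -> None:
    records = []
    for row in data.rows:
        for rep, (count, scale) in enumerate(zip(row.counts, row.scales), start=1):
            records.append((row.p, rep, count, scale))
    pd.DataFrame(records, columns=TITRATION_COLUMNS).to_csv(path, index=False)


def read_profile_csv(path: str | Path) -> GradientProfile:
    df = _read_checked(path, PROFILE_COLUMNS)
    df = df.sort_values("fraction")
    return GradientProfile(
        tuple(int(f) for f in df["fraction"]),
        tuple(float(v) for v in df["intensity"]),
    )


def write_profile_csv(profile: GradientProfile, path: str | Path) -> None:
    pd.DataFrame(
        {"fraction": profile.fraction, "intensity": profile.intensity}
    ).to_csv(path, index=False)


def read_markers_csv(path: str | Path) -> MarkerSet:
    df = _read_checked(path, MARKER_COLUMNS)
    return MarkerSet(
        tuple((float(m), float(f)) for m, f in zip(df["mass_kda"], df["peak_fraction"]))
    )


def write_json(obj: dict, path: str | Path | None) -> str:
    """Serialize to pretty JSON; write to ``path`` unless it is None."""
    text = json.dumps(obj, indent=2, sort_keys=False)
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text
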