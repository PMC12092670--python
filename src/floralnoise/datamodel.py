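"""Domain types and CSV I/O for per-nucleus fluorescence tables.

A *bud* is one floral meristem; every quantified nucleus carries 3-D
coordinates in the bud frame (origin at the bud center, x lateral,
y abaxial, z apical; micrometers), an optional distance to the bud surface,
and one or more fluorescence channels in arbitrary units.

The on-disk schema is a plain UTF-8 comma-separated file::

    bud_id,stage,treatment,x_um,y_um,z_um,depth_um,<channel...>

``depth_um`` and ``treatment`` are optional (treatment defaults to
``"none"``); every remaining non-coordinate column is treated as a
fluorescence channel. A ``column_map`` argument lets callers ingest tables
with other header names without rewriting files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import StudyConfig

#: canonical floral stages; the stage field is open (e.g. "1-file" .. "4-file")
CANONICAL_STAGES = ("1a", "1b", "2a", "2b", "2c")

REQUIRED_COLUMNS = ("bud_id", "stage", "x_um", "y_um", "z_um")
OPTIONAL_COLUMNS = ("treatment", "depth_um")
COORD_COLUMNS = ("x_um", "y_um", "z_um")


class SchemaError(ValueError):
    """A required column is missing or a channel name clashes."""


class RowError(ValueError):
    """A data row holds a non-numeric or invalid value; cites the line."""


@dataclass(frozen=True)
class NucleusRecord:
    """One quantified nucleus."""

    bud_id: str
    stage: str
    x: float
    y: float
    z: float
    depth: float | None
    signals: Mapping[str, float]


@dataclass
class BudTable:
    """All quantified nuclei of one bud, with stage/treatment metadata.

    ``data`` holds one row per nucleus with columns ``x_um, y_um, z_um``,
    optionally ``depth_um``, plus one column per fluorescence channel.
    """

    bud_id: str
    stage: str
    data: pd.DataFrame
    channels: tuple[str, ...]
    treatment: str = "none"

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        missing = [c for c in COORD_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"bud {self.bud_id!r}: missing columns {missing}")
        missing_ch = [c for c in self.channels if c not in self.data.columns]
        if missing_ch:
            raise SchemaError(f"bud {self.bud_id!r}: missing channels {missing_ch}")

    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def has_depth(self) -> bool:
        return "depth_um" in self.data.columns

    @property
    def records(self) -> Iterator[NucleusRecord]:
        for _, row in self.data.iterrows():
            yield NucleusRecord(
                bud_id=self.bud_id,
                stage=self.stage,
                x=float(row["x_um"]),
                y=float(row["y_um"]),
                z=float(row["z_um"]),
                depth=float(row["depth_um"]) if self.has_depth else None,
                signals={ch: float(row[ch]) for ch in self.channels},
            )

    def signal(self, channel: str) -> np.ndarray:
        if channel not in self.channels:
            raise SchemaError(f"bud {self.bud_id!r}: no channel {channel!r}")
        return self.data[channel].to_numpy(dtype=float)

    def with_data(self, data: pd.DataFrame, channels: Sequence[str] | None = None) -> "BudTable":
        return BudTable(
            bud_id=self.bud_id,
            stage=self.stage,
            data=data.reset_index(drop=True),
            channels=tuple(channels) if channels is not None else self.channels,
            treatment=self.treatment,
        )

    def equals(self, other: "BudTable", rtol: float = 1e-9) -> bool:
        if (self.bud_id, self.stage, self.treatment, self.channels) != (
            other.bud_id, other.stage, other.treatment, other.channels
        ):
            return False
        if self.has_depth != other.has_depth or len(self.data) != len(other.data):
            return False
        cols = list(COORD_COLUMNS) + (["depth_um"] if self.has_depth else []) + list(self.channels)
        a = self.data[cols].to_numpy(dtype=float)
        b = other.data[cols].to_numpy(dtype=float)
        return bool(np.allclose(a, b, rtol=rtol, atol=0.0))


def validate_bud_table(table: BudTable) -> list[str]:
    """Check the type invariants; returns violations instead of raising.

    Each violation names the offending record index (0-based) and rule.
    """
    violations: list[str] = []
    if table.n_records < 1:
        violations.append("table: must contain at least one record")
        return violations
    if not table.channels:
        violations.append("table: channel set is empty")
    if len(set(table.channels)) != len(table.channels):
        violations.append("table: channel names must be unique")
    if any(not str(c) for c in table.channels):
        violations.append("table: channel names must be nonempty")
    for col in table.data.columns:
        if col not in COORD_COLUMNS and col != "depth_um" and col not in table.channels:
            violations.append(
                f"table: column {col!r} not in declared channel set (channel-set mismatch)"
            )

    coords = table.data[list(COORD_COLUMNS)].to_numpy(dtype=float)
    bad = np.nonzero(~np.isfinite(coords).all(axis=1))[0]
    for i in bad:
        violations.append(f"record {i}: coordinates must be finite")
    for ch in table.channels:
        if ch not in table.data.columns:
            continue
        sig = table.data[ch].to_numpy(dtype=float)
        for i in np.nonzero(~np.isfinite(sig))[0]:
            violations.append(f"record {i}: signal {ch!r} must be finite")
        finite = np.isfinite(sig)
        for i in np.nonzero(finite & (sig < 0))[0]:
            violations.append(f"record {i}: signal {ch!r} violates signal >= 0")
    return violations


def _resolve_columns(columns: Sequence[str], column_map: Mapping[str, str] | None) -> list[str]:
    if not column_map:
        return list(columns)
    inverse = {v: k for k, v in column_map.items()}
    return [inverse.get(c, c) for c in columns]


def read_nucleus_csv(
    path: str | Path,
    config: StudyConfig | None = None,
    column_map: Mapping[str, str] | None = None,
) -> list[BudTable]:
    """Read a long-format per-nucleus CSV into one :class:`BudTable` per bud.

    Parameters
    ----------
    path : path
        CSV file following the package schema (see module docstring).
    config : StudyConfig, optional
        Unused for parsing; accepted so pipeline stages share one signature.
    column_map : mapping, optional
        Maps schema names to the file's actual header names, e.g.
        ``{"x_um": "Position X"}``, for ingesting foreign exports.

    Row order within a bud is preserved; buds are returned in order of first
    appearance.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    raw.columns = _resolve_columns(raw.columns, column_map)

    for col in REQUIRED_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    channel_cols = [
        c for c in raw.columns if c not in REQUIRED_COLUMNS and c not in OPTIONAL_COLUMNS
    ]
    if not channel_cols:
        raise SchemaError(f"{path.name}: no fluorescence channel column found")

    numeric_cols = list(COORD_COLUMNS) + channel_cols
    if "depth_um" in raw.columns:
        numeric_cols.append("depth_um")
    parsed = {}
    for col in numeric_cols:
        values = pd.to_numeric(raw[col], errors="coerce")
        bad = values.isna() & raw[col].notna()
        if col == "depth_um":
            bad = bad & (raw[col].str.strip() != "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise RowError(
                f"{path.name}, line {line}: non-numeric value "
                f"{raw[col][bad.idxmax()]!r} in column {col!r}"
            )
        if col != "depth_um" and values.isna().any():
            line = int(values.isna().idxmax()) + 2
            raise RowError(f"{path.name}, line {line}: missing value in column {col!r}")
        parsed[col] = values.astype(float)
    for col in channel_cols:
        neg = parsed[col] < 0
        if neg.any():
            line = int(neg.idxmax()) + 2
            raise RowError(
                f"{path.name}, line {line}: negative signal in channel {col!r}"
            )

    frame = pd.DataFrame(parsed)
    frame.insert(0, "bud_id", raw["bud_id"].astype(str))
    frame.insert(1, "stage", raw["stage"].astype(str))
    frame.insert(
        2,
        "treatment",
        raw["treatment"].fillna("none").astype(str) if "treatment" in raw.columns
        else "none",
    )
    if "depth_um" in frame.columns and frame["depth_um"].isna().all():
        frame = frame.drop(columns=["depth_um"])

    tables: list[BudTable] = []
    for bud_id in frame["bud_id"].unique():
        sub = frame[frame["bud_id"] == bud_id]
        stages = sub["stage"].unique()
        if len(stages) != 1:
            raise SchemaError(
                f"{path.name}: bud {bud_id!r} carries multiple stages {list(stages)}"
            )
        treatments = sub["treatment"].unique()
        if len(treatments) != 1:
            raise SchemaError(
                f"{path.name}: bud {bud_id!r} carries multiple treatments {list(treatments)}"
            )
        cols = [c for c in sub.columns if c not in ("bud_id", "stage", "treatment")]
        tables.append(
            BudTable(
                bud_id=str(bud_id),
                stage=str(stages[0]),
                treatment=str(treatments[0]),
                data=sub[cols].reset_index(drop=True),
                channels=tuple(channel_cols),
            )
        )
    return tables


def write_nucleus_csv(tables: Sequence[BudTable], path: str | Path) -> None:
    """Write bud tables to the package CSV schema (UTF-8, "." decimal).

    Column order is deterministic: metadata, coordinates, depth (if any bud
    carries it), then channels in the order declared by the first table.
    An empty sequence yields a header-only file with the base schema.
    """
    path = Path(path)
    if not tables:
        header = ",".join(REQUIRED_COLUMNS[:2] + ("treatment",) + COORD_COLUMNS)
        path.write_text(header + "\n", encoding="utf-8")
        return

    channels = tables[0].channels
    for t in tables[1:]:
        if t.channels != channels:
            raise SchemaError(
                f"cannot serialize buds with differing channel sets: "
                f"{channels} vs {t.channels} (bud {t.bud_id!r})"
            )
    any_depth = any(t.has_depth for t in tables)
    frames = []
    for t in tables:
        frame = t.data.copy()
        if any_depth and not t.has_depth:
            frame["depth_um"] = np.nan
        frame.insert(0, "bud_id", t.bud_id)
        frame.insert(1, "stage", t.stage)
        frame.insert(2, "treatment", t.treatment)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    cols = ["bud_id", "stage", "treatment", *COORD_COLUMNS]
    if any_depth:
        cols.append("depth_um")
    cols.extend(channels)
    out[cols].to_csv(path, index=False, encoding="utf-8")
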