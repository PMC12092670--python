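"""Radial registration and tiling of buds into a shared coordinate system.

Buds differ in size, so per-bud x/y coordinates are normalized by the 80th
percentile (configurable) of the radial coordinate r = sqrt(x^2 + y^2),
computed with linear interpolation between order statistics
(h = (n-1)p/100 + 1; NumPy "linear", identical to R's default quantile
type 7). The percentile is computed on the full bud *before* any
discarding, since the discard rule references the same percentile. Nuclei
with r greater than ``discard_multiplier`` times that percentile are then
discarded (outliers / neighboring-tissue carry-over). The z coordinate is
neither normalized nor tiled; it is carried through untouched.

Normalized coordinates are binned into square tiles anchored at the
origin, half-open and lower-inclusive: tile index (i, j) =
(floor(x_norm/w), floor(y_norm/w)), so a coordinate exactly on a boundary
belongs to the higher tile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import ConfigError, StudyConfig
from .datamodel import BudTable


class DegenerateBudError(ValueError):
    """All nuclei sit on the central axis; no radial scale exists."""


@dataclass
class RegisteredBud:
    """A bud in normalized coordinates with tile assignments.

    ``data`` extends the bud's nucleus table with ``x_norm``, ``y_norm``,
    ``r_norm``, ``tile_i``, ``tile_j`` columns (retained nuclei only).
    """

    bud_id: str
    stage: str
    treatment: str
    p80_radius: float
    n_discarded: int
    data: pd.DataFrame
    channels: tuple[str, ...]

    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def tiles(self) -> list[tuple[int, int]]:
        return sorted(
            set(zip(self.data["tile_i"].astype(int), self.data["tile_j"].astype(int)))
        )


def tile_index(x_norm, y_norm, binwidth: float):
    """Half-open lower-inclusive tile assignment in normalized coordinates."""
    if binwidth <= 0:
        raise ConfigError(f"binwidth must be > 0, got {binwidth}")
    i = np.floor(np.asarray(x_norm, dtype=float) / binwidth).astype(int)
    j = np.floor(np.asarray(y_norm, dtype=float) / binwidth).astype(int)
    return i, j


def register_bud(bud: BudTable, config: StudyConfig | None = None) -> RegisteredBud:
    """Normalize a bud's x/y coordinates and apply the radial discard rule.

    Raises
    ------
    DegenerateBudError
        If every nucleus lies on the z axis (zero radial scale).
    ValueError
        If the bud is empty.
    """
    config = config or StudyConfig()
    if bud.n_records < 1:
        raise ValueError(f"bud {bud.bud_id!r} is empty")
    if bud.n_records == 1:
        warnings.warn(
            f"bud {bud.bud_id!r} has a single nucleus; its radius defines the scale",
            stacklevel=2,
        )

    x = bud.data["x_um"].to_numpy(dtype=float)
    y = bud.data["y_um"].to_numpy(dtype=float)
    r = np.hypot(x, y)
    p80 = float(np.percentile(r, config.radial_percentile))
    if p80 <= 0.0:
        raise DegenerateBudError(
            f"bud {bud.bud_id!r}: radial percentile is zero (all nuclei on the axis)"
        )

    keep = r <= config.discard_multiplier * p80
    n_discarded = int((~keep).sum())

    data = bud.data.loc[keep].reset_index(drop=True).copy()
    data["x_norm"] = x[keep] / p80
    data["y_norm"] = y[keep] / p80
    data["r_norm"] = r[keep] / p80
    data["tile_i"], data["tile_j"] = tile_index(
        data["x_norm"], data["y_norm"], config.binwidth
    )
    return RegisteredBud(
        bud_id=bud.bud_id,
        stage=bud.stage,
        treatment=bud.treatment,
        p80_radius=p80,
        n_discarded=n_discarded,
        data=data,
        channels=bud.channels,
    )


def assign_tiles(registered: RegisteredBud, binwidth: float) -> RegisteredBud:
    """Re-assign tile indices with a different binwidth (in place semantics
    on a copy); registration must already be done."""
    data = registered.data.copy()
    data["tile_i"], data["tile_j"] = tile_index(data["x_norm"], data["y_norm"], binwidth)
    return RegisteredBud(
        bud_id=registered.bud_id,
        stage=registered.stage,
        treatment=registered.treatment,
        p80_radius=registered.p80_radius,
        n_discarded=registered.n_discarded,
        data=data,
        channels=registered.channels,
    )


def register_cohort(
    buds: Sequence[BudTable], config: StudyConfig | None = None
) -> list[RegisteredBud]:
    return [register_bud(b, config) for b in buds]


def registered_to_frame(buds: Sequence[RegisteredBud]) -> pd.DataFrame:
    """Long-format table of registered nuclei across buds (for CSV export)."""
    frames = []
    for b in buds:
        frame = b.data.copy()
        frame.insert(0, "bud_id", b.bud_id)
        frame.insert(1, "stage", b.stage)
        frame.insert(2, "treatment", b.treatment)
        frames.append(frame)
    if not frames:
        return pd.DataFrame(
            columns=["bud_id", "stage", "treatment", "x_um", "y_um", "z_um",
                     "x_norm", "y_norm", "r_norm", "tile_i", "tile_j"]
        )
    return pd.concat(frames, ignore_index=True)
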