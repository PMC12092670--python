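"""Per-bud pattern heatmaps and cross-bud mean/CV summary heatmaps.

A *pattern heatmap* describes how one bud distributes a reporter's signal
over the tile grid: the arithmetic mean signal of the nuclei in each
occupied tile, normalized so tile values sum to one. Unoccupied tiles are
missing data, not zeros — pooling zeros would deflate means and inflate CV
at the bud rim. Because of the normalization, pattern heatmaps are
invariant to uniform rescaling of a bud's signals, which makes buds imaged
at different gains comparable.

A *summary heatmap* pools the pattern heatmaps of all buds of one stage:
per tile, the number of contributing buds, mean, sample SD (n-1
denominator) and CV = SD/mean across buds. Tiles contributed by fewer than
``min_buds_per_tile`` (default 3) buds are dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import StudyConfig
from .datamodel import BudTable, SchemaError
from .registration import RegisteredBud

logger = logging.getLogger(__name__)

Tile = tuple[int, int]


@dataclass
class PatternHeatmap:
    """One bud's normalized tile pattern for one channel."""

    bud_id: str
    stage: str
    channel: str
    values: dict[Tile, float]

    def to_frame(self) -> pd.DataFrame:
        tiles = sorted(self.values)
        return pd.DataFrame(
            {
                "bud_id": self.bud_id,
                "stage": self.stage,
                "channel": self.channel,
                "tile_i": [t[0] for t in tiles],
                "tile_j": [t[1] for t in tiles],
                "value": [self.values[t] for t in tiles],
            }
        )


@dataclass
class SummaryHeatmap:
    """Cross-bud per-tile mean/SD/CV for one stage and channel.

    ``table`` columns: tile_i, tile_j, n_buds, mean, sd, cv. ``cv`` is NaN
    where the cross-bud mean is zero (estimator undefined); such tiles are
    excluded from :meth:`cv_values`.
    """

    stage: str
    channel: str
    table: pd.DataFrame

    @property
    def tiles(self) -> list[Tile]:
        return list(zip(self.table["tile_i"].astype(int), self.table["tile_j"].astype(int)))

    def cv_values(self) -> pd.DataFrame:
        out = self.table.dropna(subset=["cv"])
        return out[["tile_i", "tile_j", "cv"]].reset_index(drop=True)


def make_ratio_channel(
    bud: BudTable, numerator: str, denominator: str, new_name: str
) -> BudTable:
    """Add a per-nucleus ratio channel (e.g. mDII/DII auxin perception).

    Nuclei with a zero denominator are excluded from the output table; the
    exclusion count is logged.
    """
    for ch in (numerator, denominator):
        if ch not in bud.channels:
            raise SchemaError(f"bud {bud.bud_id!r}: missing channel {ch!r}")
    if new_name in bud.channels:
        raise SchemaError(f"bud {bud.bud_id!r}: channel {new_name!r} already exists")

    den = bud.data[denominator].to_numpy(dtype=float)
    keep = den != 0.0
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info(
            "bud %s: excluded %d nuclei with zero %s for ratio channel %s",
            bud.bud_id, n_excluded, denominator, new_name,
        )
    data = bud.data.loc[keep].reset_index(drop=True).copy()
    data[new_name] = data[numerator].to_numpy(dtype=float) / data[denominator].to_numpy(dtype=float)
    return bud.with_data(data, channels=bud.channels + (new_name,))


def bud_pattern_heatmap(registered: RegisteredBud, channel: str) -> PatternHeatmap:
    """Tile-mean signal of one bud, normalized to the bud's total.

    An all-zero bud yields all-zero tiles with a warning (no normalization
    is possible).
    """
    if channel not in registered.channels:
        raise SchemaError(f"bud {registered.bud_id!r}: no channel {channel!r}")
    grouped = registered.data.groupby(["tile_i", "tile_j"], sort=True)[channel].mean()
    total = float(grouped.sum())
    if total == 0.0:
        warnings.warn(
            f"bud {registered.bud_id!r}: total {channel!r} signal is zero; "
            "pattern left unnormalized (all zeros)",
            stacklevel=2,
        )
        values = {(int(i), int(j)): 0.0 for (i, j) in grouped.index}
    else:
        values = {(int(i), int(j)): float(v) / total for (i, j), v in grouped.items()}
    return PatternHeatmap(
        bud_id=registered.bud_id, stage=registered.stage, channel=channel, values=values
    )


def summary_heatmaps(
    patterns: Sequence[PatternHeatmap], config: StudyConfig | None = None
) -> SummaryHeatmap:
    """Pool same-stage pattern heatmaps into per-tile n/mean/SD/CV.

    Statistics run over the buds that *have* each tile; tiles with fewer
    than ``min_buds_per_tile`` contributing buds are dropped.
    """
    config = config or StudyConfig()
    if not patterns:
        raise ValueError("summary_heatmaps requires at least one pattern heatmap")
    stages = {p.stage for p in patterns}
    channels = {p.channel for p in patterns}
    if len(stages) != 1 or len(channels) != 1:
        raise ValueError(
            f"pattern heatmaps must share stage and channel, got stages={stages}, "
            f"channels={channels}"
        )
    stage, channel = stages.pop(), channels.pop()

    per_tile: dict[Tile, list[float]] = {}
    for p in patterns:
        for tile, value in p.values.items():
            per_tile.setdefault(tile, []).append(value)

    rows = []
    for tile in sorted(per_tile):
        vals = np.asarray(per_tile[tile], dtype=float)
        n = len(vals)
        if n < config.min_buds_per_tile:
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        cv = sd / mean if mean > 0 else np.nan
        rows.append((tile[0], tile[1], n, mean, sd, cv))
    table = pd.DataFrame(
        rows, columns=["tile_i", "tile_j", "n_buds", "mean", "sd", "cv"]
    )
    return SummaryHeatmap(stage=stage, channel=channel, table=table)


def cv_by_stage(summaries: Mapping[str, SummaryHeatmap]) -> pd.DataFrame:
    """Long table (stage, tile_i, tile_j, cv) across stages.

    One row per retained tile with a defined CV; feeds the stagewise
    permutation comparisons.
    """
    frames = []
    for stage in summaries:
        cv = summaries[stage].cv_values()
        if len(cv):
            cv = cv.copy()
            cv.insert(0, "stage", stage)
            frames.append(cv)
    if not frames:
        return pd.DataFrame(columns=["stage", "tile_i", "tile_j", "cv"])
    return pd.concat(frames, ignore_index=True)


def plot_summary_heatmap(summary: SummaryHeatmap, column: str = "cv", ax=None):
    """Render a summary heatmap column (``mean`` or ``cv``) on a tile grid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = summary.table.dropna(subset=[column])
    if len(t) == 0:
        return ax
    i0, i1 = int(t["tile_i"].min()), int(t["tile_i"].max())
    j0, j1 = int(t["tile_j"].min()), int(t["tile_j"].max())
    grid = np.full((j1 - j0 + 1, i1 - i0 + 1), np.nan)
    for _, row in t.iterrows():
        grid[int(row["tile_j"]) - j0, int(row["tile_i"]) - i0] = row[column]
    im = ax.imshow(grid, origin="lower", extent=(i0, i1 + 1, j0, j1 + 1))
    ax.set_xlabel("tile i")
    ax.set_ylabel("tile j")
    ax.set_title(f"{summary.channel} {column}, stage {summary.stage}")
    ax.figure.colorbar(im, ax=ax)
    return ax
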