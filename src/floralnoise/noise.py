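"""Dual-reporter extrinsic/intrinsic noise decomposition.

Two reporters c1, c2 driven by identical promoters in the same cell
separate cell-to-cell variability into a correlated (extrinsic) and an
uncorrelated (intrinsic) component via the moment estimators

    eta2_ext = (<c1 c2> - <c1><c2>) / (<c1><c2>)
    eta2_int = <(c1 - c2)^2> / (2 <c1><c2>)

where angle brackets average over the pooled cells. The companion total

    eta2_tot = ((<c1^2> + <c2^2>)/2 - <c1><c2>) / (<c1><c2>)

satisfies eta2_tot = eta2_ext + eta2_int as an algebraic identity. These
are plug-in estimators with no bias correction; the raw eta2_ext may be
negative in finite samples (it is a covariance estimate) and is reported
unclamped, with eta values defined as sqrt(max(eta2, 0)) and a negativity
flag.

Pooling all cells of all positions and stages folds deterministic
positional/stage differences in mean expression into the extrinsic
component. Conditioning on tile position and stage —
eta2 | (x, y, s), estimated from all cells at one tile in all buds of one
stage — removes that deterministic part and isolates stochastic
cell-level noise.

The module also provides a statsmodels-style entry point:
:class:`DualReporterNoise` is built from cell data and `.fit()` returns a
:class:`DualReporterNoiseResults` with estimates, bootstrap confidence
intervals and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import StudyConfig
from .datamodel import SchemaError
from .registration import RegisteredBud

Tile = tuple[int, int]


class UndefinedNoiseError(ValueError):
    """Estimator undefined: fewer than two cells or a zero channel mean."""


@dataclass(frozen=True)
class NoiseEstimate:
    """One noise decomposition with its grouping key.

    ``eta2_ext`` may be negative (finite-sample covariance); ``eta_ext``
    and ``eta_int`` are square roots of the zero-clamped eta2 values.
    """

    eta2_ext: float
    eta2_int: float
    eta2_tot: float
    eta_ext: float
    eta_int: float
    n_cells: int
    key: str | tuple = "pooled"
    mean_sum_signal: float | None = None
    mean_c1: float | None = None
    mean_c2: float | None = None
    flags: tuple[str, ...] = ()


def pooled_noise(
    c1: Sequence[float] | np.ndarray,
    c2: Sequence[float] | np.ndarray,
    key: str | tuple = "pooled",
    flags: tuple[str, ...] = (),
) -> NoiseEstimate:
    """Plug-in dual-reporter noise over a pool of cells.

    Requires at least two cells and strictly positive channel means.
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    if c1.shape != c2.shape or c1.ndim != 1:
        raise ValueError("c1 and c2 must be 1-D arrays of equal length")
    n = c1.size
    if n < 2:
        raise UndefinedNoiseError(f"need at least 2 cells, got {n}")
    m1 = float(c1.mean())
    m2 = float(c2.mean())
    if m1 <= 0 or m2 <= 0:
        raise UndefinedNoiseError(
            f"channel means must be > 0, got <c1>={m1}, <c2>={m2}"
        )
    denom = m1 * m2
    cross = float(np.mean(c1 * c2))
    sq = (float(np.mean(c1 * c1)) + float(np.mean(c2 * c2))) / 2.0
    eta2_ext = (cross - denom) / denom
    eta2_int = float(np.mean((c1 - c2) ** 2)) / (2.0 * denom)
    eta2_tot = (sq - denom) / denom
    out_flags = tuple(flags)
    if eta2_ext < 0:
        out_flags = out_flags + ("eta2_ext_negative",)
    return NoiseEstimate(
        eta2_ext=eta2_ext,
        eta2_int=eta2_int,
        eta2_tot=eta2_tot,
        eta_ext=math.sqrt(max(eta2_ext, 0.0)),
        eta_int=math.sqrt(max(eta2_int, 0.0)),
        n_cells=n,
        key=key,
        mean_sum_signal=float(np.mean(c1 + c2)),
        mean_c1=m1,
        mean_c2=m2,
        flags=out_flags,
    )


def aggregate_noise(estimates: Sequence[NoiseEstimate],
                    key: str | tuple = "aggregate") -> NoiseEstimate | None:
    """Combine bin-level estimates into one by pooling their moment sums.

    Ratio-of-sums: each bin contributes n * (numerator moment) and
    n * <c1><c2> to a single ratio, so high-signal, well-populated bins
    dominate and the aggregate is far more stable than averaging the
    per-bin ratios. Reduces to the bin estimate itself for a single bin.
    """
    ests = [e for e in estimates if e.mean_c1 is not None and e.mean_c2 is not None]
    if not ests:
        return None
    den = sum(e.n_cells * e.mean_c1 * e.mean_c2 for e in ests)
    num_ext = sum(e.n_cells * e.eta2_ext * e.mean_c1 * e.mean_c2 for e in ests)
    num_int = sum(e.n_cells * e.eta2_int * e.mean_c1 * e.mean_c2 for e in ests)
    ext = num_ext / den
    intr = num_int / den
    n_total = int(sum(e.n_cells for e in ests))
    return NoiseEstimate(
        eta2_ext=ext,
        eta2_int=intr,
        eta2_tot=ext + intr,
        eta_ext=math.sqrt(max(ext, 0.0)),
        eta_int=math.sqrt(max(intr, 0.0)),
        n_cells=n_total,
        key=key,
    )


@dataclass
class NoiseMap:
    """Per-tile conditional noise estimates for one stage."""

    stage: str
    channels: tuple[str, str]
    estimates: dict[Tile, NoiseEstimate]

    @property
    def tiles(self) -> list[Tile]:
        return sorted(self.estimates)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tile in self.tiles:
            e = self.estimates[tile]
            rows.append(
                {
                    "stage": self.stage,
                    "tile_i": tile[0],
                    "tile_j": tile[1],
                    "n_cells": e.n_cells,
                    "eta2_ext": e.eta2_ext,
                    "eta2_int": e.eta2_int,
                    "eta2_tot": e.eta2_tot,
                    "eta_ext": e.eta_ext,
                    "eta_int": e.eta_int,
                    "mean_sum_signal": e.mean_sum_signal,
                    "flags": ";".join(e.flags),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["stage", "tile_i", "tile_j", "n_cells", "eta2_ext", "eta2_int",
                     "eta2_tot", "eta_ext", "eta_int", "mean_sum_signal", "flags"],
        )

    def aggregate(self) -> NoiseEstimate | None:
        """Pooled-moment (ratio-of-sums) aggregate over the tiles."""
        return aggregate_noise(
            list(self.estimates.values()), key=(self.stage, "aggregate")
        )


def conditional_noise_map(
    cohort: Sequence[RegisteredBud],
    channels: tuple[str, str],
    config: StudyConfig | None = None,
) -> NoiseMap:
    """Noise conditioned on tile position within one developmental stage.

    Cells from all buds of the stage are pooled per tile; tiles with fewer
    than ``min_cells_per_noise_bin`` cells, or with a zero channel mean,
    are dropped.
    """
    config = config or StudyConfig()
    if not cohort:
        raise ValueError("conditional_noise_map requires at least one bud")
    stages = {b.stage for b in cohort}
    if len(stages) != 1:
        raise ValueError(f"cohort must share one stage, got {stages}")
    stage = stages.pop()
    c1_name, c2_name = channels
    for b in cohort:
        for ch in channels:
            if ch not in b.channels:
                raise SchemaError(f"bud {b.bud_id!r}: missing channel {ch!r}")

    pooled = pd.concat(
        [b.data[["tile_i", "tile_j", c1_name, c2_name]] for b in cohort],
        ignore_index=True,
    )
    estimates: dict[Tile, NoiseEstimate] = {}
    for (i, j), group in pooled.groupby(["tile_i", "tile_j"], sort=True):
        if len(group) < config.min_cells_per_noise_bin:
            continue
        try:
            est = pooled_noise(
                group[c1_name].to_numpy(),
                group[c2_name].to_numpy(),
                key=(int(i), int(j), stage),
            )
        except UndefinedNoiseError:
            continue
        estimates[(int(i), int(j))] = est
    if not estimates:
        import warnings

        warnings.warn(
            f"stage {stage!r}: no tile meets the {config.min_cells_per_noise_bin}-cell "
            "minimum; noise map is empty",
            stacklevel=2,
        )
    return NoiseMap(stage=stage, channels=(c1_name, c2_name), estimates=estimates)


def intrinsic_noise_by_depth(
    cells: pd.DataFrame,
    channels: tuple[str, str],
    config: StudyConfig | None = None,
    depth_column: str = "depth_um",
    bin_edges: Sequence[float] | None = None,
) -> list[NoiseEstimate]:
    """Intrinsic noise of expressing cells, binned by distance to surface.

    Cells are first filtered to expressing cells
    (max(c1, c2) > ``expressing_threshold``); only intrinsic noise is
    meaningful under that filter, because omitting non-expressing cells
    biases the extrinsic (covariance) component downward. The extrinsic
    estimate is still computed but flagged ``biased-expressing-filter``.

    Bins default to fixed ``depth_binwidth``-wide intervals from zero;
    explicit ``bin_edges`` override. Bins with fewer than
    ``min_cells_per_noise_bin`` cells are skipped.
    """
    config = config or StudyConfig()
    c1_name, c2_name = channels
    for col in (depth_column, c1_name, c2_name):
        if col not in cells.columns:
            raise SchemaError(f"cells table missing column {col!r}")
    c1 = cells[c1_name].to_numpy(dtype=float)
    c2 = cells[c2_name].to_numpy(dtype=float)
    depth = cells[depth_column].to_numpy(dtype=float)
    expressing = np.maximum(c1, c2) > config.expressing_threshold
    if not expressing.any():
        import warnings

        warnings.warn("no expressing cells above threshold; no depth bins", stacklevel=2)
        return []
    c1, c2, depth = c1[expressing], c2[expressing], depth[expressing]

    if bin_edges is None:
        top = math.ceil(depth.max() / config.depth_binwidth) + 1
        bin_edges = [k * config.depth_binwidth for k in range(int(top) + 1)]
    edges = np.asarray(bin_edges, dtype=float)
    idx = np.digitize(depth, edges) - 1

    out: list[NoiseEstimate] = []
    for b in range(len(edges) - 1):
        mask = idx == b
        if mask.sum() < config.min_cells_per_noise_bin:
            continue
        try:
            est = pooled_noise(
                c1[mask], c2[mask],
                key=("depth", float(edges[b]), float(edges[b + 1])),
                flags=("eta2_ext_biased_expressing_filter",),
            )
        except UndefinedNoiseError:
            continue
        out.append(est)
    return out


def noise_signal_relation(noise_map: NoiseMap) -> tuple[pd.DataFrame, dict]:
    """Per-tile noise vs mean summed signal, with OLS slope and Pearson r.

    With fewer than 3 tiles the table is still emitted but no fit is
    computed. A constant noise column yields slope 0 and r = 0 by
    convention (the correlation is undefined).
    """
    table = noise_map.to_frame()[
        ["stage", "tile_i", "tile_j", "n_cells", "mean_sum_signal", "eta_ext", "eta_int"]
    ]
    fits: dict[str, dict] = {}
    if len(table) >= 3:
        x = table["mean_sum_signal"].to_numpy(dtype=float)
        for noise_col in ("eta_ext", "eta_int"):
            y = table[noise_col].to_numpy(dtype=float)
            if np.ptp(y) == 0.0 or np.ptp(x) == 0.0:
                fits[noise_col] = {"slope": 0.0, "intercept": float(y.mean()), "r": 0.0}
                continue
            res = sps.linregress(x, y)
            fits[noise_col] = {
                "slope": float(res.slope),
                "intercept": float(res.intercept),
                "r": float(res.rvalue),
            }
    return table, fits


# ---------------------------------------------------------------------------
# Model / Results layer


class DualReporterNoise:
    """Dual-reporter noise model for a population of cells.

    Parameters
    ----------
    cells : DataFrame
        One row per cell with the two reporter columns, and (for
        conditional decomposition) ``tile_i``, ``tile_j``, ``stage``
        columns as produced by the registration stage.
    channels : (str, str)
        Names of the two reporter columns.
    config : StudyConfig, optional

    Examples
    --------
    >>> model = DualReporterNoise.from_dataframe(df, channels=("c1", "c2"))
    >>> res = model.fit(seed=0)
    >>> print(res.summary())
    """

    def __init__(
        self,
        cells: pd.DataFrame,
        channels: tuple[str, str],
        config: StudyConfig | None = None,
    ) -> None:
        self.config = config or StudyConfig()
        self.channels = tuple(channels)
        for ch in self.channels:
            if ch not in cells.columns:
                raise SchemaError(f"cells table missing channel {ch!r}")
        self.cells = cells.reset_index(drop=True)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        channels: tuple[str, str],
        config: StudyConfig | None = None,
    ) -> "DualReporterNoise":
        return cls(data, channels=channels, config=config)

    @classmethod
    def from_cohort(
        cls,
        cohort: Sequence[RegisteredBud],
        channels: tuple[str, str],
        config: StudyConfig | None = None,
    ) -> "DualReporterNoise":
        """Build from registered buds (enables conditional decomposition)."""
        frames = []
        for b in cohort:
            f = b.data[["tile_i", "tile_j", *channels]].copy()
            f.insert(0, "stage", b.stage)
            f.insert(0, "bud_id", b.bud_id)
            frames.append(f)
        return cls(pd.concat(frames, ignore_index=True), channels=channels, config=config)

    @property
    def has_conditioning(self) -> bool:
        return {"tile_i", "tile_j", "stage"}.issubset(self.cells.columns)

    def fit(self, seed: int | None = None, n_bootstrap: int | None = None
            ) -> "DualReporterNoiseResults":
        """Estimate pooled (and, when possible, conditional) noise.

        ``seed`` drives the bootstrap; when None, the config seed is used.
        ``n_bootstrap`` overrides the config bootstrap depth (0 disables).
        """
        from .stats import bootstrap_pairs

        c1 = self.cells[self.channels[0]].to_numpy(dtype=float)
        c2 = self.cells[self.channels[1]].to_numpy(dtype=float)
        pooled = pooled_noise(c1, c2)

        n_boot = self.config.n_bootstrap if n_bootstrap is None else n_bootstrap
        boot_ci = None
        if n_boot:
            boot_ci = bootstrap_pairs(
                c1, c2,
                lambda a, b: (pooled_noise(a, b).eta2_ext, pooled_noise(a, b).eta2_int),
                n_boot=n_boot,
                seed=self.config.seed if seed is None else seed,
            )

        conditional: dict[str, NoiseMap] = {}
        if self.has_conditioning:
            for stage, group in self.cells.groupby("stage", sort=True):
                estimates: dict[Tile, NoiseEstimate] = {}
                for (i, j), tile_group in group.groupby(["tile_i", "tile_j"], sort=True):
                    if len(tile_group) < self.config.min_cells_per_noise_bin:
                        continue
                    try:
                        estimates[(int(i), int(j))] = pooled_noise(
                            tile_group[self.channels[0]].to_numpy(),
                            tile_group[self.channels[1]].to_numpy(),
                            key=(int(i), int(j), stage),
                        )
                    except UndefinedNoiseError:
                        continue
                conditional[str(stage)] = NoiseMap(
                    stage=str(stage), channels=self.channels, estimates=estimates
                )
        return DualReporterNoiseResults(
            model=self, pooled=pooled, conditional=conditional, bootstrap_ci=boot_ci
        )


@dataclass
class DualReporterNoiseResults:
    """Fitted dual-reporter noise decomposition.

    Attributes
    ----------
    pooled : NoiseEstimate
        Decomposition over all cells regardless of position/stage.
    conditional : dict stage -> NoiseMap
        Tile-conditioned decompositions (empty when the input carried no
        tile/stage columns).
    bootstrap_ci : dict or None
        Percentile 95% CIs for the pooled (eta2_ext, eta2_int).
    """

    model: DualReporterNoise
    pooled: NoiseEstimate
    conditional: Mapping[str, NoiseMap]
    bootstrap_ci: Mapping[str, tuple[float, float]] | None = None

    def conditional_frame(self) -> pd.DataFrame:
        frames = [m.to_frame() for m in self.conditional.values() if m.estimates]
        if not frames:
            return NoiseMap(stage="", channels=self.model.channels, estimates={}).to_frame()
        return pd.concat(frames, ignore_index=True)

    def conditional_aggregate(self) -> NoiseEstimate | None:
        """Pooled-moment aggregate eta2 over all (tile, stage) bins."""
        ests = [e for m in self.conditional.values() for e in m.estimates.values()]
        return aggregate_noise(ests, key="conditional-aggregate")

    def summary(self) -> str:
        """Plain-text summary table of the decomposition."""
        lines = []
        p = self.pooled
        lines.append("Dual-reporter noise decomposition")
        lines.append("=" * 54)
        lines.append(f"channels: {self.model.channels[0]}, {self.model.channels[1]}")
        lines.append(f"n cells (pooled): {p.n_cells}")
        lines.append("")
        lines.append(f"{'':<22}{'eta^2':>12}{'eta':>12}")
        lines.append(f"{'pooled extrinsic':<22}{p.eta2_ext:>12.4f}{p.eta_ext:>12.4f}")
        lines.append(f"{'pooled intrinsic':<22}{p.eta2_int:>12.4f}{p.eta_int:>12.4f}")
        lines.append(f"{'pooled total':<22}{p.eta2_tot:>12.4f}{math.sqrt(max(p.eta2_tot, 0.0)):>12.4f}")
        if self.bootstrap_ci:
            lo, hi = self.bootstrap_ci["eta2_ext"]
            lines.append(f"  eta2_ext 95% CI: [{lo:.4f}, {hi:.4f}]")
            lo, hi = self.bootstrap_ci["eta2_int"]
            lines.append(f"  eta2_int 95% CI: [{lo:.4f}, {hi:.4f}]")
        agg = self.conditional_aggregate()
        if agg is not None:
            lines.append("")
            n_bins = sum(len(m.estimates) for m in self.conditional.values())
            lines.append(
                f"conditional on (tile, stage): {n_bins} bins, {agg.n_cells} cells"
            )
            lines.append(f"{'cond. extrinsic':<22}{agg.eta2_ext:>12.4f}{agg.eta_ext:>12.4f}")
            lines.append(f"{'cond. intrinsic':<22}{agg.eta2_int:>12.4f}{agg.eta_int:>12.4f}")
        if p.flags:
            lines.append("")
            lines.append(f"flags: {', '.join(p.flags)}")
        return "\n".join(lines)
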