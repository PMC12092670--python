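"""Study-level configuration shared by every pipeline stage.

The defaults encode the analysis conventions used throughout the package:
0.25-wide tiles in normalized bud coordinates, normalization by the 80th
percentile of the radial coordinate, a 1.3x radial discard rule, tiles kept
only when at least 3 buds contribute, and resampling depths of 100,000
permutations / 10,000 bootstrap draws.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates its documented domain."""


@dataclass(frozen=True)
class StudyConfig:
    """Container for every tunable analysis parameter.

    Parameters
    ----------
    binwidth : float
        Tile edge length in normalized (dimensionless) bud coordinates.
    radial_percentile : float
        Percentile of the per-bud radial coordinate used as the
        normalization scale, in percent.
    discard_multiplier : float
        Nuclei with radius greater than ``discard_multiplier`` times the
        normalization scale are discarded.
    min_buds_per_tile : int
        Minimum number of contributing buds for a tile to enter the
        cross-bud summary heatmaps.
    min_cells_per_noise_bin : int
        Minimum pooled cell count for a (tile, stage) or depth bin to
        receive a noise estimate.
    expressing_threshold : float
        Fluorescence threshold (arbitrary units) above which a cell counts
        as expressing, used by the depth-binned intrinsic-noise analysis.
    depth_binwidth : float
        Width in micrometers of the distance-to-surface bins.
    n_permutations, n_bootstrap : int
        Monte-Carlo depths for the resampling statistics.
    seed : int
        Master seed for every stochastic routine.
    channel_roles : mapping
        Optional mapping from a role name (e.g. ``"c1"``, ``"c2"``,
        ``"ratio_num"``) to a channel column name.
    """

    binwidth: float = 0.25
    radial_percentile: float = 80.0
    discard_multiplier: float = 1.3
    min_buds_per_tile: int = 3
    min_cells_per_noise_bin: int = 5
    expressing_threshold: float = 0.0
    depth_binwidth: float = 3.0
    n_permutations: int = 100_000
    n_bootstrap: int = 10_000
    seed: int = 0
    channel_roles: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.binwidth > 0:
            raise ConfigError(f"binwidth must be > 0, got {self.binwidth}")
        if not 0 < self.radial_percentile < 100:
            raise ConfigError(
                f"radial_percentile must lie in (0, 100), got {self.radial_percentile}"
            )
        if self.discard_multiplier < 1:
            raise ConfigError(
                f"discard_multiplier must be >= 1, got {self.discard_multiplier}"
            )
        for name in ("min_buds_per_tile", "min_cells_per_noise_bin",
                     "n_permutations", "n_bootstrap"):
            value = getattr(self, name)
            if int(value) != value or value < 1:
                raise ConfigError(f"{name} must be a count >= 1, got {value!r}")
        if self.depth_binwidth <= 0:
            raise ConfigError(f"depth_binwidth must be > 0, got {self.depth_binwidth}")

    def replace(self, **kwargs) -> "StudyConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channel_roles"] = dict(self.channel_roles)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a flat mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def content_hash(self) -> str:
        """Stable hex digest of the configuration, recorded in run reports."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode("utf-8")
        return hashlib.sha256(payload).hexdigest()[:16]
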