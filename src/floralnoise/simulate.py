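"""Synthetic floral-meristem generator with separable, known noise sources.

Emulates per-nucleus dual-reporter tables from the upper (above-equator)
dome of a bud. Each cell i on the dome receives a deterministic mean

    mu_i = floor + baseline + sum of focus Gaussians + sum of patch Gaussians

evaluated in normalized bud coordinates, then two reporter signals

    c_{i,r} = mu_i * E_i * I_{i,r} + m_{i,r},    r in {1, 2}

where E_i = exp(N(0, sigma_ext^2)) is shared by both reporters of a cell
(extrinsic noise), I_{i,r} = exp(N(0, sigma_int^2)) is drawn independently
per reporter (intrinsic noise), and m_{i,r} >= 0 is half-normal measurement
noise with scale sigma_meas (truncation at zero keeps signals nonnegative).

The lognormal construction gives closed-form dual-reporter noise
(see :func:`closed_form_noise`), so estimator recovery can be tested
against analytic truth. Perturbation scenarios modify geometry/model the
way the corresponding wet-lab treatments change the tissue: cell-number
reduction (microtubule / cell-cycle inhibitors), spatially uniform
induction (exogenous auxin flooding), and a zero-biology bead control that
isolates measurement error.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import ConfigError
from .datamodel import BudTable

GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))

PLACEMENT_RULES = ("uniform-cap", "fibonacci-cap", "cluster")

#: Per-stage default geometry: dome radius (um) and upper-epidermis cell
#: count. Counts grow ~60 -> ~400 from the youngest to the oldest stage,
#: an order-of-magnitude choice consistent with meristem growth.
STAGE_GEOMETRY: dict[str, tuple[float, int]] = {
    "1a": (22.0, 60),
    "1b": (26.0, 100),
    "2a": (30.0, 160),
    "2b": (34.0, 260),
    "2c": (38.0, 400),
}

#: Default per-stage bud counts for a simulated cohort (observed cohort sizes).
STAGE_BUD_COUNTS: dict[str, int] = {"1a": 22, "1b": 14, "2a": 17, "2b": 10, "2c": 8}


class ScenarioError(ConfigError):
    """Unknown perturbation scenario name."""


@dataclass(frozen=True)
class MeristemGeometry:
    """Dome geometry of one bud: radius (um), cell count, placement rule."""

    dome_radius: float
    n_cells: int
    placement_rule: str = "uniform-cap"

    def __post_init__(self) -> None:
        if self.dome_radius <= 0:
            raise ConfigError(f"dome_radius must be > 0, got {self.dome_radius}")
        if self.n_cells < 1:
            raise ConfigError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.placement_rule not in PLACEMENT_RULES:
            raise ConfigError(
                f"placement_rule must be one of {PLACEMENT_RULES}, got {self.placement_rule!r}"
            )

    @classmethod
    def for_stage(cls, stage: str, placement_rule: str = "uniform-cap") -> "MeristemGeometry":
        if stage not in STAGE_GEOMETRY:
            raise ConfigError(f"no default geometry for stage {stage!r}")
        radius, n = STAGE_GEOMETRY[stage]
        return cls(dome_radius=radius, n_cells=n, placement_rule=placement_rule)


@dataclass(frozen=True)
class Focus:
    """A deterministic Gaussian expression focus in normalized coordinates."""

    x: float
    y: float
    amplitude: float
    width: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ConfigError("focus amplitude must be >= 0")
        if self.width <= 0:
            raise ConfigError("focus width must be > 0")


def four_sepal_foci(distance: float = 0.8, amplitude: float = 120.0,
                    width: float = 0.2) -> tuple[Focus, ...]:
    """Four incipient-sepal maxima at (+-d, 0) and (0, +-d)."""
    return (
        Focus(+distance, 0.0, amplitude, width),
        Focus(-distance, 0.0, amplitude, width),
        Focus(0.0, +distance, amplitude, width),
        Focus(0.0, -distance, amplitude, width),
    )


def two_lateral_foci(distance: float = 0.8, amplitude: float = 120.0,
                     width: float = 0.2) -> tuple[Focus, ...]:
    """Two lateral incipient-sepal maxima at (+-d, 0)."""
    return (
        Focus(+distance, 0.0, amplitude, width),
        Focus(-distance, 0.0, amplitude, width),
    )


@dataclass(frozen=True)
class ExpressionModel:
    """Generative parameters for the dual-reporter expression field.

    ``sigma_ext`` and ``sigma_int`` are standard deviations on the log
    scale of the shared (extrinsic) and per-reporter (intrinsic) lognormal
    factors. ``sigma_meas`` is the scale of the additive half-normal
    measurement noise in fluorescence units. ``patch_rate`` is the expected
    number of random stochastic patches per bud (young-stage behaviour);
    patch centers are uniform in the unit disk of normalized coordinates.

    ``quantize_binwidth``, when set, evaluates the deterministic pattern at
    tile centers of the registration grid (tiles of that binwidth in
    coordinates normalized by the ``quantize_percentile``-th percentile of
    the realized radial coordinate), so the mean is exactly constant within
    every downstream tile. Used for exact conditioning tests.
    """

    baseline: float = 20.0
    foci: tuple[Focus, ...] = ()
    patch_rate: float = 0.0
    patch_amplitude: float = 120.0
    patch_width: float = 0.2
    sigma_ext: float = 0.3
    sigma_int: float = 0.6
    sigma_meas: float = 0.0
    floor: float = 0.0
    quantize_binwidth: float | None = None
    quantize_percentile: float = 80.0

    def __post_init__(self) -> None:
        for name in ("baseline", "patch_rate", "patch_amplitude",
                     "sigma_ext", "sigma_int", "sigma_meas", "floor"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.patch_width <= 0:
            raise ConfigError("patch_width must be > 0")
        if self.quantize_binwidth is not None and self.quantize_binwidth <= 0:
            raise ConfigError("quantize_binwidth must be > 0 when set")

    @classmethod
    def for_stage(cls, stage: str, **overrides) -> "ExpressionModel":
        """Stage-appropriate pattern: random patches at stage 1, two
        lateral foci at stage 2a, four sepal foci at stages 2b/2c."""
        if stage in ("1a", "1b"):
            pattern = dict(foci=(), patch_rate=3.0)
        elif stage == "2a":
            pattern = dict(foci=two_lateral_foci(), patch_rate=1.0)
        elif stage in ("2b", "2c"):
            pattern = dict(foci=four_sepal_foci(), patch_rate=0.0)
        else:
            pattern = dict(foci=(), patch_rate=0.0)
        pattern.update(overrides)
        return cls(**pattern)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth sidecar for one simulated bud."""

    bud_id: str
    stage: str
    sigma_ext: float
    sigma_int: float
    sigma_meas: float
    eta2_ext_true: float
    eta2_int_true: float
    patch_centers: tuple[tuple[float, float], ...]
    seed: int


def closed_form_noise(sigma_ext: float, sigma_int: float) -> tuple[float, float]:
    """Analytic dual-reporter noise of the lognormal generative model.

    For c_r = mu * E * I_r with E ~ lognormal(0, sigma_ext) shared and
    I_r ~ lognormal(0, sigma_int) independent per reporter (no measurement
    noise, constant mu), the moment identities give

        eta2_ext = exp(sigma_ext^2) - 1
        eta2_int = exp(sigma_ext^2) * (exp(sigma_int^2) - 1)
    """
    if sigma_ext < 0 or sigma_int < 0:
        raise ValueError("noise SDs must be >= 0")
    e = math.exp(sigma_ext ** 2)
    return e - 1.0, e * (math.exp(sigma_int ** 2) - 1.0)


def _place_cells(geometry: MeristemGeometry, rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Place nuclei on the upper hemisphere x^2+y^2+z^2 = R^2, z >= 0.

    uniform-cap samples uniformly by area (z ~ U[0, R] is exact for a
    sphere); fibonacci-cap is a deterministic spiral lattice; cluster puts
    every "nucleus" at the apex (bead control).
    """
    R = geometry.dome_radius
    n = geometry.n_cells
    if geometry.placement_rule == "uniform-cap":
        z = rng.uniform(0.0, R, size=n)
        phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    elif geometry.placement_rule == "fibonacci-cap":
        z = (np.arange(n) + 0.5) / n * R
        phi = np.arange(n) * GOLDEN_ANGLE
    else:  # cluster
        return np.zeros(n), np.zeros(n), np.full(n, R)
    rho = np.sqrt(np.maximum(R ** 2 - z ** 2, 0.0))
    return rho * np.cos(phi), rho * np.sin(phi), z


def _pattern_mean(model: ExpressionModel, xn: np.ndarray, yn: np.ndarray,
                  patches: Sequence[tuple[float, float]]) -> np.ndarray:
    mu = np.full(xn.shape, model.floor + model.baseline, dtype=float)
    for f in model.foci:
        mu += f.amplitude * np.exp(
            -((xn - f.x) ** 2 + (yn - f.y) ** 2) / (2.0 * f.width ** 2)
        )
    for (px, py) in patches:
        mu += model.patch_amplitude * np.exp(
            -((xn - px) ** 2 + (yn - py) ** 2) / (2.0 * model.patch_width ** 2)
        )
    return mu


def generate_bud(
    geometry: MeristemGeometry,
    model: ExpressionModel,
    stage: str,
    bud_id: str,
    seed: int,
    channels: tuple[str, str] = ("c1", "c2"),
    with_depth: bool = False,
) -> tuple[BudTable, SimulationTruth]:
    """Simulate one bud; returns the nucleus table and its truth sidecar.

    Reproducible: identical arguments yield identical outputs (PCG64
    generator seeded with ``seed``; a fixed draw order is part of the
    contract).
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    x, y, z = _place_cells(geometry, rng)
    n = geometry.n_cells

    # realized stochastic patches (young-stage behaviour)
    n_patches = int(rng.poisson(model.patch_rate)) if model.patch_rate > 0 else 0
    patch_r = np.sqrt(rng.uniform(0.0, 1.0, size=n_patches))
    patch_phi = rng.uniform(0.0, 2.0 * math.pi, size=n_patches)
    patches = tuple(
        (float(r * math.cos(p)), float(r * math.sin(p)))
        for r, p in zip(patch_r, patch_phi)
    )

    if model.quantize_binwidth is not None:
        # mirror the registration stage: percentile-normalize the realized
        # radii, then evaluate the pattern at tile centers so mu is exactly
        # constant within every downstream tile
        r = np.hypot(x, y)
        scale = float(np.percentile(r, model.quantize_percentile))
        if scale <= 0:
            scale = geometry.dome_radius
        w = model.quantize_binwidth
        xn = (np.floor(x / scale / w) + 0.5) * w
        yn = (np.floor(y / scale / w) + 0.5) * w
    else:
        xn = x / geometry.dome_radius
        yn = y / geometry.dome_radius
    mu = _pattern_mean(model, xn, yn, patches)

    ext = np.exp(rng.normal(0.0, model.sigma_ext, size=n)) if model.sigma_ext > 0 else np.ones(n)
    signals = {}
    for ch in channels:
        intr = np.exp(rng.normal(0.0, model.sigma_int, size=n)) if model.sigma_int > 0 else np.ones(n)
        c = mu * ext * intr
        if model.sigma_meas > 0:
            c = c + np.abs(rng.normal(0.0, model.sigma_meas, size=n))
        signals[ch] = c

    frame = pd.DataFrame({"x_um": x, "y_um": y, "z_um": z})
    if with_depth:
        frame["depth_um"] = np.zeros(n)
    for ch in channels:
        frame[ch] = signals[ch]

    eta2_ext, eta2_int = closed_form_noise(model.sigma_ext, model.sigma_int)
    truth = SimulationTruth(
        bud_id=bud_id,
        stage=stage,
        sigma_ext=model.sigma_ext,
        sigma_int=model.sigma_int,
        sigma_meas=model.sigma_meas,
        eta2_ext_true=eta2_ext,
        eta2_int_true=eta2_int,
        patch_centers=patches,
        seed=seed,
    )
    table = BudTable(bud_id=bud_id, stage=stage, data=frame, channels=tuple(channels))
    return table, truth


def derive_bud_seed(master_seed: int, stage: str, index: int) -> int:
    """Deterministic per-bud substream seed, independent across buds.

    Mixes the master seed with a CRC of the stage label and the bud index
    through SeedSequence, so changing one stage's bud count leaves every
    other bud's realization unchanged.
    """
    ss = np.random.SeedSequence(
        [int(master_seed) % (2 ** 31), zlib.crc32(stage.encode("utf-8")), int(index)]
    )
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def generate_cohort(
    n_buds: Mapping[str, int],
    geometry: Mapping[str, MeristemGeometry] | MeristemGeometry | None,
    model: Mapping[str, ExpressionModel] | ExpressionModel | None,
    seed: int,
    channels: tuple[str, str] = ("c1", "c2"),
) -> list[tuple[BudTable, SimulationTruth]]:
    """Simulate a cohort of buds across stages with per-bud substreams.

    ``geometry``/``model`` may be a single object (applied to all stages),
    a per-stage mapping, or None to use the stage defaults.
    """
    out: list[tuple[BudTable, SimulationTruth]] = []
    for stage in n_buds:
        count = int(n_buds[stage])
        if count < 0:
            raise ConfigError(f"bud count for stage {stage!r} must be >= 0")
        if isinstance(geometry, Mapping):
            geo = geometry[stage]
        elif geometry is None:
            geo = MeristemGeometry.for_stage(stage)
        else:
            geo = geometry
        if isinstance(model, Mapping):
            mod = model[stage]
        elif model is None:
            mod = ExpressionModel.for_stage(stage)
        else:
            mod = model
        for k in range(count):
            bud_id = f"{stage}_bud{k:03d}"
            bud_seed = derive_bud_seed(seed, stage, k)
            out.append(generate_bud(geo, mod, stage, bud_id, bud_seed, channels=channels))
    return out


def truth_frame(truths: Sequence[SimulationTruth]) -> pd.DataFrame:
    """Long-format truth sidecar table (one row per bud)."""
    return pd.DataFrame(
        {
            "bud_id": [t.bud_id for t in truths],
            "stage": [t.stage for t in truths],
            "sigma_ext": [t.sigma_ext for t in truths],
            "sigma_int": [t.sigma_int for t in truths],
            "sigma_meas": [t.sigma_meas for t in truths],
            "eta2_ext_true": [t.eta2_ext_true for t in truths],
            "eta2_int_true": [t.eta2_int_true for t in truths],
            "n_patches": [len(t.patch_centers) for t in truths],
            "seed": [t.seed for t in truths],
        }
    )


#: Cell-number retain factors implied by the reported treatment effects:
#: the microtubule inhibitor removes 59% of upper-epidermis cells, the
#: cell-cycle inhibitor 33%.
ORYZALIN_RETAIN = 0.41
HYDROXYUREA_RETAIN = 0.67

SCENARIOS = ("mock", "oryzalin", "hydroxyurea", "2,4-D", "beads")
_SCENARIO_ALIASES = {"24d": "2,4-D", "2,4-d": "2,4-D", "24-d": "2,4-D"}


def apply_perturbation(
    scenario: str,
    geometry: MeristemGeometry,
    model: ExpressionModel,
    retain_factor: float | None = None,
    induction_level: float = 120.0,
    bead_sigma_meas: float = 5.0,
) -> tuple[MeristemGeometry, ExpressionModel]:
    """Transform (geometry, model) according to a perturbation scenario.

    - ``oryzalin``: scale n_cells by ``retain_factor`` (default 0.41).
    - ``hydroxyurea``: scale n_cells by ``retain_factor`` (default 0.67).
    - ``2,4-D``: deterministic pattern replaced by a spatially uniform
      elevated baseline; noise parameters untouched.
    - ``beads``: co-located cluster with all biological noise off and
      measurement noise on (instrument-error control).
    - ``mock``: identity.
    """
    name = _SCENARIO_ALIASES.get(scenario.lower(), scenario)
    if name not in SCENARIOS:
        raise ScenarioError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if name == "mock":
        return geometry, model
    if name in ("oryzalin", "hydroxyurea"):
        factor = retain_factor if retain_factor is not None else (
            ORYZALIN_RETAIN if name == "oryzalin" else HYDROXYUREA_RETAIN
        )
        if not 0 < factor <= 1:
            raise ConfigError(f"retain_factor must lie in (0, 1], got {factor}")
        n = max(1, round(geometry.n_cells * factor))
        return replace(geometry, n_cells=n), model
    if name == "2,4-D":
        return geometry, replace(
            model, foci=(), patch_rate=0.0, baseline=induction_level
        )
    # beads
    return (
        replace(geometry, placement_rule="cluster"),
        replace(
            model,
            foci=(),
            patch_rate=0.0,
            sigma_ext=0.0,
            sigma_int=0.0,
            sigma_meas=model.sigma_meas if model.sigma_meas > 0 else bead_sigma_meas,
        ),
    )
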