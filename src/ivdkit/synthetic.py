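"""Synthetic data generators with planted ground truth.

Every downstream stage of the pipeline (cytokine screening, correlation
networks, micro-CT morphometry, cyclic-compression mechanics, glucose
tolerance) can be exercised on data produced here, with the true structure
returned alongside so tests can score recovery.

Generators are pure functions of ``(spec, seed)``: the same arguments give
bit-identical output, and no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GroupDesign",
    "CorrelationStructure",
    "Solid",
    "DiscPhantomSpec",
    "LoadingProtocol",
    "PanelTruth",
    "DiscVolume",
    "MaskSet",
    "LoadingTrace",
    "META_COLS",
    "generate_cytokine_panel",
    "generate_disc_volume",
    "generate_loading_trace",
    "generate_gtt_series",
]

#: Leading non-cytokine columns of a wide panel table.
META_COLS = ["animal_id", "group", "replicate"]

#: The 45-plex mouse cytokine panel used as the default cytokine name space.
PANEL_45PLEX = [
    "CCL2", "CCL3", "CCL4", "CCL5", "CCL11", "CCL12", "CCL17", "CCL20",
    "CCL21", "CCL22", "CSF1", "CSF2", "CSF3", "IL-1a", "IL-1b", "IL-2",
    "IL-3", "IL-4", "IL-5", "IL-6", "IL-7", "IL-9", "IL-10", "IL-11",
    "IL-12A", "IL-12B", "IL-13", "IL-15", "IL-16", "IL-17", "CXCL1",
    "CXCL2", "CXCL5", "CXCL9", "CXCL10", "CX3CL1", "IFN-g", "IFN-b1",
    "TNF-a", "LIF", "VEGF", "EPO", "TIMP-1", "IL-12p40", "IL-12p70",
]


@dataclass(frozen=True)
class GroupDesign:
    """Experimental group layout of a multiplex cytokine study.

    Defaults mirror a four-group diabetic mouse study: db/+ and db/db
    littermates, chow+vehicle controls, and STZ-HFD diabetic animals, with
    the small per-group sample sizes typical of such work (3, 3, 3, 9).
    """

    groups: tuple[str, ...] = ("db/+", "db/db", "Con+Veh", "STZ-HFD")
    n_per_group: tuple[int, ...] = (3, 3, 3, 9)
    pseudoreplicates_per_animal: int = 2

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("group labels must be unique")
        if len(self.n_per_group) != len(self.groups):
            raise ValueError("n_per_group must match groups")
        if any(n < 2 for n in self.n_per_group):
            raise ValueError("every group needs n >= 2")
        if self.pseudoreplicates_per_animal < 1:
            raise ValueError("pseudoreplicates_per_animal must be >= 1")


@dataclass(frozen=True)
class CorrelationStructure:
    """Planted correlation and effect structure of a synthetic panel.

    Cytokine log-concentrations follow a latent-factor model: a shared
    factor per block plus an independent term, giving Pearson correlation
    ``within_block_r`` inside a block and ``between_block_r`` across blocks
    on the log scale (diluted by ``noise_sd``).  Group-specific fold
    multipliers shift block means; missingness is left-censored at the
    ``missing_rate`` quantile, emulating out-of-range multiplex readings.

    ``noise_sd`` is independent log-scale noise added on top of the
    unit-variance factor structure (attenuating correlations by a factor
    ``1/(1+noise_sd**2)``); ``replicate_sd`` is the small technical
    log-scale noise separating pseudo-replicates of one animal.
    """

    blocks: Mapping[str, tuple[str, ...]]
    within_block_r: float = 0.9
    between_block_r: float = 0.0
    upregulated: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    missing_rate: float = 0.0
    noise_sd: float = 0.1
    replicate_sd: float = 0.05
    base_sigma: float = 0.4

    def __post_init__(self) -> None:
        names = self.cytokines()
        if len(names) != len(set(names)):
            raise ValueError("blocks must partition cytokines disjointly")
        if not 0 <= self.within_block_r < 1:
            raise ValueError("within_block_r must be in [0, 1)")
        if not 0 <= self.between_block_r < self.within_block_r:
            raise ValueError("need 0 <= between_block_r < within_block_r")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_sd < 0 or self.replicate_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        for group, mult in self.upregulated.items():
            for cyt, m in mult.items():
                if m <= 0:
                    raise ValueError(
                        f"fold multiplier for {cyt!r} in {group!r} must be > 0"
                    )
                if cyt not in names:
                    raise ValueError(f"unknown cytokine {cyt!r} in upregulated")

    def cytokines(self) -> list[str]:
        return [c for block in self.blocks.values() for c in block]


def two_block_structure(
    n_per_block: int = 6,
    within_block_r: float = 0.9,
    between_block_r: float = 0.0,
    **kwargs,
) -> CorrelationStructure:
    """Convenience two-module structure over the first panel cytokines."""
    names = PANEL_45PLEX[: 2 * n_per_block]
    blocks = {"A": tuple(names[:n_per_block]), "B": tuple(names[n_per_block:])}
    return CorrelationStructure(
        blocks=blocks,
        within_block_r=within_block_r,
        between_block_r=between_block_r,
        **kwargs,
    )


@dataclass(frozen=True)
class PanelTruth:
    """Ground truth planted into a synthetic cytokine panel."""

    blocks: Mapping[str, tuple[str, ...]]
    fold_multipliers: Mapping[str, Mapping[str, float]]
    flagged: pd.DataFrame  # boolean, same shape/index as the panel's cytokines
    animal_log_values: pd.DataFrame  # latent per-animal log concentrations


def generate_cytokine_panel(
    design: GroupDesign,
    structure: CorrelationStructure,
    seed: int,
) -> tuple[pd.DataFrame, PanelTruth]:
    """Simulate a wide multiplex cytokine panel with planted structure.

    Returns a DataFrame with one row per (animal, pseudo-replicate) —
    columns ``animal_id, group, replicate`` then one column per cytokine,
    concentrations in pg/ml with out-of-range entries as NaN — and the
    :class:`PanelTruth` describing what was planted.

    Concentrations are log-normal: block-correlated latent factors set the
    animal-level log value, technical noise separates replicates, and
    censoring flags the lowest ``missing_rate`` fraction of each cytokine's
    readings (multiplex assays lose the low end of their dynamic range).
    """
    rng = np.random.default_rng(seed)
    cytokines = structure.cytokines()
    n_cyt = len(cytokines)
    block_of = {c: b for b, members in structure.blocks.items() for c in members}
    block_ids = list(structure.blocks)

    # per-cytokine baseline concentrations, log-uniform across 10-500 pg/ml
    baseline = 10.0 ** rng.uniform(1.0, np.log10(500.0), size=n_cyt)

    rows: list[dict] = []
    animal_logs: list[dict] = []
    r_b = structure.between_block_r
    r_w = structure.within_block_r
    # factor loadings giving corr r_w within a block, r_b across blocks
    a_global = np.sqrt(r_b)
    a_block = np.sqrt(r_w - r_b)
    a_indiv = np.sqrt(1.0 - r_w)

    for group, n in zip(design.groups, design.n_per_group):
        mult = structure.upregulated.get(group, {})
        for i in range(n):
            animal = f"{group}-{i + 1}"
            g = rng.standard_normal()
            zb = {b: rng.standard_normal() for b in block_ids}
            eps = rng.standard_normal(n_cyt)
            extra = structure.noise_sd * rng.standard_normal(n_cyt)
            log_vals = {}
            for j, cyt in enumerate(cytokines):
                latent = a_global * g + a_block * zb[block_of[cyt]] + a_indiv * eps[j]
                log_vals[cyt] = (
                    np.log(baseline[j] * mult.get(cyt, 1.0))
                    + structure.base_sigma * (latent + extra[j])
                )
            animal_logs.append({"animal_id": animal, "group": group, **log_vals})
            for rep in range(1, design.pseudoreplicates_per_animal + 1):
                tech = structure.replicate_sd * rng.standard_normal(n_cyt)
                row = {"animal_id": animal, "group": group, "replicate": rep}
                for j, cyt in enumerate(cytokines):
                    row[cyt] = float(np.exp(log_vals[cyt] + tech[j]))
                rows.append(row)

    panel = pd.DataFrame(rows, columns=META_COLS + cytokines)
    values = panel[cytokines]

    # left-censoring: flag the lowest missing_rate quantile per cytokine
    flagged = pd.DataFrame(False, index=panel.index, columns=cytokines)
    if structure.missing_rate > 0:
        limits = values.quantile(structure.missing_rate)
        flagged = values.lt(limits)
        panel[cytokines] = values.where(~flagged)

    truth = PanelTruth(
        blocks=dict(structure.blocks),
        fold_multipliers={g: dict(m) for g, m in structure.upregulated.items()},
        flagged=flagged,
        animal_log_values=pd.DataFrame(animal_logs),
    )
    return panel, truth


# ---------------------------------------------------------------------------
# disc phantoms


@dataclass(frozen=True)
class Solid:
    """Axis-aligned parametric solid on the voxel grid.

    ``kind`` is one of ``ellipsoid`` (semi-axes = ``radii``), ``cylinder``
    (axis along the stack direction, half-height ``radii[0]``, elliptical
    cross-section ``radii[1:]``) or ``box`` (half-extents = ``radii``).
    ``center`` and ``radii`` are in voxel units, order (slice, row, col).
    """

    kind: str
    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.kind not in ("ellipsoid", "cylinder", "box"):
            raise ValueError(f"unknown solid kind {self.kind!r}")
        if any(r <= 0 for r in self.radii):
            raise ValueError("radii must be positive")

    def contains(self, z: np.ndarray, y: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Boolean membership of voxel-center coordinates."""
        dz = (z - self.center[0]) / self.radii[0]
        dy = (y - self.center[1]) / self.radii[1]
        dx = (x - self.center[2]) / self.radii[2]
        if self.kind == "ellipsoid":
            return dz * dz + dy * dy + dx * dx <= 1.0
        if self.kind == "cylinder":
            return (np.abs(dz) <= 1.0) & (dy * dy + dx * dx <= 1.0)
        return (np.abs(dz) <= 1.0) & (np.abs(dy) <= 1.0) & (np.abs(dx) <= 1.0)

    def volume(self) -> float:
        """Analytic volume in voxel^3."""
        a, b, c = self.radii
        if self.kind == "ellipsoid":
            return 4.0 / 3.0 * np.pi * a * b * c
        if self.kind == "cylinder":
            return 2.0 * a * np.pi * b * c
        return 8.0 * a * b * c


@dataclass(frozen=True)
class DiscPhantomSpec:
    """Contrast-enhanced micro-CT phantom of a disc with a bright NP core.

    Default geometry emulates a mouse coccygeal disc scanned at 10 µm voxel
    size: a flattened disc envelope with a roughly centred nucleus pulposus
    (NP) occupying ~15% of the disc volume.  The contrast agent partitions
    into the proteoglycan-rich NP, so ``np_intensity`` must exceed
    ``disc_intensity``, which must exceed ``background_intensity``.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 10.0  # µm
    disc_geometry: Solid = Solid("ellipsoid", (31.5, 31.5, 31.5), (14.0, 26.0, 26.0))
    np_geometry: Solid = Solid("ellipsoid", (31.5, 31.5, 31.5), (8.0, 13.0, 13.0))
    disc_intensity: float = 100.0
    np_intensity: float = 200.0
    background_intensity: float = 20.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if not (
            self.np_intensity >= self.disc_intensity > self.background_intensity
        ):
            raise ValueError(
                "need np_intensity >= disc_intensity > background_intensity"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class DiscVolume:
    """3D intensity grid; axis 0 is the transverse (stack) direction."""

    data: np.ndarray
    voxel_size: float  # µm

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("volume must be 3D")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")


@dataclass(frozen=True)
class MaskSet:
    """Whole-disc and NP binary masks over the same grid as the volume."""

    disc: np.ndarray
    np_: np.ndarray

    def __post_init__(self) -> None:
        if self.disc.shape != self.np_.shape:
            raise ValueError("masks must share a shape")
        if np.any(self.np_ & ~self.disc):
            raise ValueError("NP mask must lie inside the disc mask")

    @property
    def npvf(self) -> float:
        """NP volume fraction implied by the masks."""
        return float(self.np_.sum()) / float(self.disc.sum())


def generate_disc_volume(
    spec: DiscPhantomSpec, seed: int
) -> tuple[DiscVolume, MaskSet]:
    """Voxelize a disc phantom and return it with exact ground-truth masks.

    Voxels take the intensity of the innermost solid containing their
    center; Gaussian noise of SD ``spec.noise_sd`` is added on top.  The
    returned masks are the exact voxelizations, so the true NP volume
    fraction and NP/disc intensity ratio are computable from them.
    """
    rng = np.random.default_rng(seed)
    z, y, x = np.meshgrid(
        *(np.arange(s, dtype=float) for s in spec.grid_shape), indexing="ij"
    )
    disc = spec.disc_geometry.contains(z, y, x)
    np_mask = spec.np_geometry.contains(z, y, x)
    if not np_mask.any():
        raise ValueError("NP geometry contains no voxels")
    if np.any(np_mask & ~disc) or np_mask.sum() >= disc.sum():
        raise ValueError("NP geometry must lie strictly inside the disc geometry")

    vol = np.full(spec.grid_shape, spec.background_intensity, dtype=float)
    vol[disc] = spec.disc_intensity
    vol[np_mask] = spec.np_intensity
    if spec.noise_sd > 0:
        vol = vol + spec.noise_sd * rng.standard_normal(spec.grid_shape)
    return DiscVolume(vol, spec.voxel_size), MaskSet(disc, np_mask)


# ---------------------------------------------------------------------------
# cyclic compression traces


@dataclass(frozen=True)
class LoadingProtocol:
    """Sinusoidal compression protocol.

    Defaults follow a standard murine functional-spine-unit test: 1 Hz,
    20 cycles, 35 µm displacement amplitude, 0.03 N preload.
    """

    frequency: float = 1.0  # Hz
    n_cycles: int = 20
    amplitude: float = 35.0  # µm
    stiffness: float = 0.01  # N/µm
    phase_delta: float = 0.1  # rad, loss angle
    preload: float = 0.03  # N
    sample_rate: float = 100.0  # Hz
    noise_sd: float = 0.0  # N

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.n_cycles < 1:
            raise ValueError("need at least 1 cycle")
        if self.sample_rate < 20 * self.frequency:
            raise ValueError("sample_rate must be >= 20x frequency (aliasing guard)")
        if not 0 <= self.phase_delta < np.pi / 2:
            raise ValueError("phase_delta must be in [0, pi/2)")
        if self.amplitude <= 0 or self.stiffness <= 0:
            raise ValueError("amplitude and stiffness must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class LoadingTrace:
    """Sampled time / displacement / force record of one cyclic test."""

    time: np.ndarray  # s
    displacement: np.ndarray  # µm
    force: np.ndarray  # N
    frequency: float  # nominal Hz
    amplitude: float  # nominal µm

    def __post_init__(self) -> None:
        n = len(self.time)
        if len(self.displacement) != n or len(self.force) != n:
            raise ValueError("trace arrays must have equal length")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")


def generate_loading_trace(protocol: LoadingProtocol, seed: int) -> LoadingTrace:
    """Simulate a phase-lagged sinusoidal compression trace.

    Displacement ``x(t) = X0 sin(2πft)``; force
    ``F(t) = preload + k X0 sin(2πft + δ) + noise``, where ``k`` is the
    stiffness and ``δ`` the planted loss angle.  The record spans exactly
    ``n_cycles`` periods.
    """
    rng = np.random.default_rng(seed)
    n = int(round(protocol.n_cycles * protocol.sample_rate / protocol.frequency))
    t = np.arange(n) / protocol.sample_rate
    w = 2 * np.pi * protocol.frequency
    x = protocol.amplitude * np.sin(w * t)
    f = (
        protocol.preload
        + protocol.stiffness * protocol.amplitude * np.sin(w * t + protocol.phase_delta)
        + protocol.noise_sd * rng.standard_normal(n)
    )
    return LoadingTrace(t, x, f, protocol.frequency, protocol.amplitude)


def generate_gtt_series(
    baseline: float,
    peaks: Sequence[float],
    seed: int = 0,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Blood-glucose series of a glucose tolerance test.

    ``baseline`` is the fasted reading at t=0 and ``peaks`` the readings at
    30, 60 and 90 min post bolus (mg/dl).  Returns a DataFrame with
    ``time_h`` (0, 0.5, 1.0, 1.5) and ``glucose_mg_dl`` columns; optional
    Gaussian measurement noise is seeded and clipped to stay positive.
    """
    if len(peaks) != 3:
        raise ValueError("expected 3 post-bolus readings (30/60/90 min)")
    glucose = np.array([baseline, *peaks], dtype=float)
    if np.any(glucose <= 0):
        raise ValueError("glucose values must be positive")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        glucose = np.clip(glucose + noise_sd * rng.standard_normal(4), 1.0, None)
    return pd.DataFrame({"time_h": [0.0, 0.5, 1.0, 1.5], "glucose_mg_dl": glucose})
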