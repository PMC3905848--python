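"""Synthetic multi-channel z-stack generator with ground truth.

Renders seeded, annotated 3D stacks of single nuclei containing
ionizing-radiation-induced foci whose per-channel geometry follows a
:class:`~irif3d.phenotypes.PhenotypeSpec`: solid spheres early or in G1,
hollow 53BP1/FK2 shells with an RPA core spot once the devoid core has
formed in late G2, and the intermediate states of the knockdown conditions.

The generator emulates *deconvolved* microscopy data: rendered geometry is
convolved with a small residual point-spread function, resampled with
Poisson photon statistics and Gaussian read noise.  Nuclei are flattened
ellipsoids (adherent-cell geometry); the cell-cycle marker channel is
pan-nuclear with a phase-dependent amplitude.

All randomness flows from one integer seed; nucleus ``i`` draws from the
stream ``default_rng([seed, i])`` so a fixed seed reproduces the dataset
bit for bit regardless of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np
from scipy import ndimage as ndi

from .grids import (
    DEFAULT_ROLES,
    ROLE_CYCLE,
    VoxelGrid,
)
from .phenotypes import (
    KnockdownCondition,
    PhenotypeSpec,
    condition_label,
    resolve_phenotype,
)

GEOMETRY_KINDS = ("solid_sphere", "hollow_shell", "core_spot", "broad_solid_with_dip")

#: Residual intensity level (fraction of amplitude) inside the central dip
#: of a ``broad_solid_with_dip`` geometry.
DIP_LEVEL = 0.5


class GeometryError(ValueError):
    """Focus geometry does not fit inside the target grid."""


@dataclass(frozen=True)
class FocusGeometry:
    """One focus structure in one channel, in physical µm.

    ``centre`` is ``(z, y, x)``.  ``inner_radius`` is the shell lumen or
    central-dip radius and must be 0 for solid kinds.
    """

    kind: str
    outer_radius: float
    inner_radius: float = 0.0
    amplitude: float = 1.0
    centre: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.kind not in GEOMETRY_KINDS:
            raise ValueError(f"unknown geometry kind {self.kind!r}")
        if not (0.0 <= self.inner_radius <= self.outer_radius):
            raise ValueError("need 0 <= inner_radius <= outer_radius")
        if self.kind in ("solid_sphere", "core_spot") and self.inner_radius != 0:
            raise ValueError(f"{self.kind} must have inner_radius == 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")

    @property
    def support_volume(self) -> float:
        """Analytic volume (µm³) of the region carrying signal.

        Shells exclude the lumen: (4/3)π(R³ − r³).  Solid kinds (including
        the dipped solid, whose core still carries signal) use the full
        sphere volume.
        """
        inner = self.inner_radius if self.kind == "hollow_shell" else 0.0
        return 4.0 / 3.0 * math.pi * (self.outer_radius**3 - inner**3)


@dataclass(frozen=True)
class GroundTruthRecord:
    """Ground truth for one focus in one channel."""

    nucleus_id: int
    focus_id: int
    channel_role: str
    geometry: FocusGeometry
    condition: str

    @property
    def true_volume(self) -> float:
        return self.geometry.support_volume


@dataclass
class SimulationConfig:
    """Parameters of the synthetic microscope and specimen.

    Lengths in µm.  ``psf_sigma`` is ``(z, xy)``; the defaults are small
    because the generator stands in for deconvolved stacks.
    ``noise_poisson_scale`` is photons per intensity unit (0 disables shot
    noise); ``noise_gaussian_sd`` is additive read noise.
    """

    n_nuclei: int = 8
    foci_per_nucleus_mean: float = 10.0
    psf_sigma: tuple[float, float] = (0.12, 0.05)
    noise_gaussian_sd: float = 6.0
    noise_poisson_scale: float = 2.0
    seed: int = 0
    nucleus_radius: float = 6.0
    nucleus_z_radius: float = 2.8
    voxel_size: tuple[float, float, float] = (0.2, 0.1, 0.1)
    base_focus_radius: float = 0.6
    background_level: float = 15.0
    cycle_amplitude: dict = field(default_factory=lambda: {"G1": 8.0, "G2": 80.0})
    radius_jitter: float = 0.07
    min_separation_factor: float = 2.5
    pad: float = 0.5

    def __post_init__(self):
        for name in ("noise_gaussian_sd", "noise_poisson_scale", "foci_per_nucleus_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(s < 0 for s in self.psf_sigma):
            raise ValueError("psf_sigma must be >= 0")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        vz, vy, vx = self.voxel_size
        nz = int(round(2 * (self.nucleus_z_radius + self.pad) / vz))
        ny = int(round(2 * (self.nucleus_radius + self.pad) / vy))
        nx = int(round(2 * (self.nucleus_radius + self.pad) / vx))
        return nz, ny, nx


# -- rendering -------------------------------------------------------------

def render_focus(grid: VoxelGrid, geometry: FocusGeometry, channel_role: str) -> VoxelGrid:
    """Add one focus structure to a channel, in place; returns the grid.

    A voxel belongs to the structure iff its centre lies in the geometric
    support.  Raises :class:`GeometryError` if the support extends beyond
    the stack.
    """
    ch = grid.channel(channel_role)  # raises ChannelError for unknown roles
    cz, cy, cx = geometry.centre
    extent = grid.extent
    for c, r, e in zip((cz, cy, cx), (geometry.outer_radius,) * 3, extent):
        if c - r < 0 or c + r > e:
            raise GeometryError(
                f"geometry (centre {geometry.centre}, R={geometry.outer_radius}) "
                f"outside grid extent {extent}"
            )
    if geometry.outer_radius == 0:
        return grid

    vz, vy, vx = grid.voxel_size
    # bounding box of the support, in voxel indices
    lo = [max(0, int((c - geometry.outer_radius) / v)) for c, v in zip(geometry.centre, grid.voxel_size)]
    hi = [
        min(n, int((c + geometry.outer_radius) / v) + 2)
        for c, v, n in zip(geometry.centre, grid.voxel_size, grid.shape)
    ]
    zz = (np.arange(lo[0], hi[0]) + 0.5) * vz - cz
    yy = (np.arange(lo[1], hi[1]) + 0.5) * vy - cy
    xx = (np.arange(lo[2], hi[2]) + 0.5) * vx - cx
    d2 = (
        zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
    )
    box = ch[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    outer = d2 <= geometry.outer_radius**2
    if geometry.kind == "hollow_shell":
        support = outer & (d2 > geometry.inner_radius**2)
        box[support] += geometry.amplitude
    elif geometry.kind == "broad_solid_with_dip":
        dip = d2 <= geometry.inner_radius**2
        box[outer & ~dip] += geometry.amplitude
        box[dip] += geometry.amplitude * DIP_LEVEL
    else:  # solid_sphere, core_spot
        box[outer] += geometry.amplitude
    return grid


def apply_psf_and_noise(
    grid: VoxelGrid,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> VoxelGrid:
    """Blur with the per-axis PSF, then Poisson-resample, then add clipped
    Gaussian read noise.  With all parameters zero the grid is returned
    unchanged (as a copy).  Blur conserves total intensity away from
    borders.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out = grid.copy()
    data = out.data
    sz, sxy = config.psf_sigma
    if sz > 0 or sxy > 0:
        vz, vy, vx = grid.voxel_size
        sigmas = (sz / vz, sxy / vy, sxy / vx)
        for c in range(data.shape[0]):
            data[c] = ndi.gaussian_filter(data[c], sigma=sigmas, mode="nearest")
    if config.noise_poisson_scale > 0:
        scale = config.noise_poisson_scale
        data[:] = rng.poisson(np.clip(data, 0, None) * scale).astype(data.dtype) / scale
    if config.noise_gaussian_sd > 0:
        data += rng.normal(0.0, config.noise_gaussian_sd, size=data.shape).astype(data.dtype)
        np.clip(data, 0, None, out=data)
    return out


# -- nucleus assembly ------------------------------------------------------

def _ellipsoid_mask(shape, voxel_size, centre, semi_axes) -> np.ndarray:
    zz = (np.arange(shape[0]) + 0.5) * voxel_size[0] - centre[0]
    yy = (np.arange(shape[1]) + 0.5) * voxel_size[1] - centre[1]
    xx = (np.arange(shape[2]) + 0.5) * voxel_size[2] - centre[2]
    q = (
        (zz[:, None, None] / semi_axes[0]) ** 2
        + (yy[None, :, None] / semi_axes[1]) ** 2
        + (xx[None, None, :] / semi_axes[2]) ** 2
    )
    return q <= 1.0


def _place_centres(
    rng: np.random.Generator,
    n: int,
    semi_axes: tuple[float, float, float],
    centre: tuple[float, float, float],
    min_sep: float,
    max_attempts: int = 400,
) -> list[tuple[float, float, float]]:
    """Sample focus centres uniformly inside an ellipsoid, rejecting pairs
    closer than ``min_sep`` (Euclidean µm).  Foci that cannot be placed
    after ``max_attempts`` draws are dropped."""
    placed: list[np.ndarray] = []
    a = np.asarray(semi_axes)
    c = np.asarray(centre)
    for _ in range(n):
        for _ in range(max_attempts):
            u = rng.uniform(-1.0, 1.0, size=3)
            if (u**2).sum() > 1.0:
                continue
            p = c + u * a
            if all(np.linalg.norm(p - q) >= min_sep for q in placed):
                placed.append(p)
                break
    return [tuple(p) for p in placed]


def render_nucleus(
    nucleus_id: int,
    condition: KnockdownCondition,
    spec: PhenotypeSpec,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[VoxelGrid, list[GroundTruthRecord]]:
    """Render one noisy nucleus stack plus its ground-truth records."""
    grid = VoxelGrid.empty(config.grid_shape, config.voxel_size, DEFAULT_ROLES)
    centre = tuple(e / 2 for e in grid.extent)
    semi = (config.nucleus_z_radius, config.nucleus_radius, config.nucleus_radius)
    nucleus = _ellipsoid_mask(grid.shape, grid.voxel_size, centre, semi)

    # pan-nuclear signal: marker-channel background plus the phase-dependent
    # cell-cycle marker
    for role in grid.channel_roles:
        if role == ROLE_CYCLE:
            grid.channel(role)[nucleus] += config.cycle_amplitude[condition.phase]
        else:
            grid.channel(role)[nucleus] += config.background_level

    # focus reference radius: enlargement multiplies measured (filled)
    # volume, so the radius scales with its cube root
    ref_radius = config.base_focus_radius * spec.enlargement ** (1.0 / 3.0)
    templates = {r: t for r, t in spec.channel_geometries.items() if t is not None}
    max_outer = max((t.outer_rel for t in templates.values()), default=1.0) * ref_radius
    margin = max_outer * 1.1 + 0.15
    placeable = tuple(max(s - margin, 0.1) for s in semi)

    n_foci = int(rng.poisson(config.foci_per_nucleus_mean))
    centres = _place_centres(
        rng, n_foci, placeable, centre, config.min_separation_factor * max_outer
    )

    records: list[GroundTruthRecord] = []
    for fid, fc in enumerate(centres):
        jitter = 1.0 + config.radius_jitter * rng.uniform(-1.0, 1.0)
        for role, tmpl in templates.items():
            if tmpl.prob < 1.0 and rng.uniform() >= tmpl.prob:
                continue
            outer = tmpl.outer_rel * ref_radius * jitter
            geom = FocusGeometry(
                kind=tmpl.kind,
                outer_radius=outer,
                inner_radius=tmpl.inner_frac * outer,
                amplitude=tmpl.amplitude,
                centre=fc,
            )
            render_focus(grid, geom, role)
            records.append(
                GroundTruthRecord(
                    nucleus_id=nucleus_id,
                    focus_id=fid,
                    channel_role=role,
                    geometry=geom,
                    condition=condition_label(condition),
                )
            )
    noisy = apply_psf_and_noise(grid, config, rng)
    return noisy, records


def iter_condition_nuclei(
    condition: KnockdownCondition,
    config: SimulationConfig,
) -> Iterator[tuple[VoxelGrid, list[GroundTruthRecord]]]:
    """Yield ``(stack, ground_truth)`` per nucleus, one at a time.

    Memory-friendly form of :func:`generate_condition_dataset`; nucleus ``i``
    is drawn from ``default_rng([seed, i])``.
    """
    spec = resolve_phenotype(condition)
    for i in range(config.n_nuclei):
        rng = np.random.default_rng([config.seed, i])
        yield render_nucleus(i, condition, spec, config, rng)


def generate_condition_dataset(
    condition: KnockdownCondition,
    config: SimulationConfig,
) -> tuple[list[VoxelGrid], list[GroundTruthRecord]]:
    """Render the full dataset for one condition (all nuclei in memory)."""
    stacks: list[VoxelGrid] = []
    truth: list[GroundTruthRecord] = []
    for stack, records in iter_condition_nuclei(condition, config):
        stacks.append(stack)
        truth.extend(records)
    return stacks, truth


def with_seed(config: SimulationConfig, seed: int, n_nuclei: Optional[int] = None) -> SimulationConfig:
    """Copy a config with a new seed (and optionally nucleus count)."""
    kwargs = {"seed": int(seed)}
    if n_nuclei is not None:
        kwargs["n_nuclei"] = int(n_nuclei)
    return replace(config, **kwargs)
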