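"""Line-profile quantification of focus architecture.

Fluorescence intensity is sampled along lines through a focus centre in
its centroid z-plane, averaged over several in-plane orientations and
normalized per channel.  From the averaged profile we classify the
distribution as *bipolar* (two peaks flanking a central trough — the
signature of a devoid core) or *monopolar*, and measure:

- **clearance** — the distance between the two peaks of a bipolar profile;
- **outer width** — the distance between the outer edges of the peaks at
  50% of the respective peak intensity (full width at half maximum for a
  monopolar profile).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import find_peaks as _scipy_find_peaks

from .grids import VoxelGrid
from .quantify import FocusRegion


class ProfileError(ValueError):
    pass


class ProfileBorderError(ProfileError):
    """Profile line would leave the stack (focus too close to the border)."""


@dataclass
class IntensityProfile:
    """Sampled intensities along a line through a focus centre.

    ``positions`` are µm, symmetric about 0 at the centroid and uniformly
    spaced; ``intensities`` has shape ``(C, P)`` and each channel with any
    signal is normalized to unit maximum along the line.
    """

    positions: np.ndarray
    intensities: np.ndarray
    channel_roles: tuple[str, ...]
    sd: Optional[np.ndarray] = None
    n_cells_averaged: int = 1

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.channel_roles), self.positions.size):
            raise ValueError("intensities must be (n_channels, n_positions)")
        steps = np.diff(self.positions)
        if self.positions.size > 1 and (
            np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6)
        ):
            raise ValueError("positions must be strictly increasing and uniform")

    @property
    def step(self) -> float:
        return float(self.positions[1] - self.positions[0])

    def channel(self, role: str) -> np.ndarray:
        try:
            return self.intensities[self.channel_roles.index(role)]
        except ValueError:
            raise ProfileError(f"no channel {role!r} in profile") from None


@dataclass
class ProfileMetrics:
    """Polarity call and derived distances for one channel's profile."""

    channel_role: str
    polarity: str  # "bipolar" | "monopolar" | "undetected"
    peak_positions: list = field(default_factory=list)
    clearance: Optional[float] = None  # µm, bipolar only
    outer_width: Optional[float] = None  # µm
    trough_ratio: Optional[float] = None  # trough / mean peak intensity
    centre_intensity: Optional[float] = None  # normalized intensity at 0


@dataclass
class ProfileParams:
    length_um: float = 4.0
    n_orientations: int = 8
    min_prominence: float = 0.2
    trough_ratio_max: float = 0.8
    smooth_window: int = 3


def _normalize(intensities: np.ndarray) -> np.ndarray:
    out = intensities.astype(float).copy()
    for c in range(out.shape[0]):
        m = out[c].max()
        if m > 0:
            out[c] /= m
    return out


# -- extraction & averaging ------------------------------------------------

def extract_profile(
    stack: VoxelGrid,
    focus: FocusRegion,
    length_um: float = 4.0,
    n_orientations: int = 8,
) -> IntensityProfile:
    """Sample all channels along in-plane lines through the focus centroid.

    ``n_orientations`` evenly spaced orientations in the centroid z-plane
    are sampled by trilinear interpolation at a step equal to the smaller
    in-plane voxel size, averaged, then normalized per channel.
    """
    vz, vy, vx = stack.voxel_size
    step = min(vy, vx)
    half = int(round((length_um / 2) / step))
    positions = np.arange(-half, half + 1) * step

    cz, cy, cx = focus.centroid  # µm
    # voxel-index coordinates of the physical points (centre convention)
    zc = cz / vz - 0.5
    nz, ny, nx = stack.shape
    thetas = np.pi * np.arange(n_orientations) / n_orientations
    ys = (cy + positions[None, :] * np.sin(thetas)[:, None]) / vy - 0.5
    xs = (cx + positions[None, :] * np.cos(thetas)[:, None]) / vx - 0.5
    zs = np.full_like(ys, zc)
    if (
        zs.min() < 0 or zs.max() > nz - 1
        or ys.min() < 0 or ys.max() > ny - 1
        or xs.min() < 0 or xs.max() > nx - 1
    ):
        raise ProfileBorderError(
            f"profile of length {length_um} µm through {focus.centroid} "
            "leaves the stack"
        )
    coords = np.vstack([zs.ravel(), ys.ravel(), xs.ravel()])
    acc = np.empty((stack.n_channels, positions.size))
    for c in range(stack.n_channels):
        sampled = ndi.map_coordinates(stack.data[c], coords, order=1)
        acc[c] = sampled.reshape(n_orientations, positions.size).mean(axis=0)
    return IntensityProfile(
        positions=positions,
        intensities=_normalize(acc),
        channel_roles=stack.channel_roles,
    )


def resample_profile(profile: IntensityProfile, positions: np.ndarray) -> IntensityProfile:
    """Linearly resample a profile onto a new common position grid."""
    positions = np.asarray(positions, dtype=float)
    out = np.vstack(
        [np.interp(positions, profile.positions, row) for row in profile.intensities]
    )
    return IntensityProfile(
        positions=positions,
        intensities=_normalize(out),
        channel_roles=profile.channel_roles,
        n_cells_averaged=profile.n_cells_averaged,
    )


def average_profiles(profiles: Sequence[IntensityProfile]) -> IntensityProfile:
    """Pointwise mean ± SD over profiles sharing one position grid.

    Profiles must already be centred and on a common grid (use
    :func:`resample_profile` first if not); the average is re-normalized to
    unit channel maxima, with the SD scaled by the same factor.
    """
    if not profiles:
        raise ProfileError("average_profiles requires at least one profile")
    ref = profiles[0]
    for p in profiles[1:]:
        if p.positions.size != ref.positions.size or not np.allclose(
            p.positions, ref.positions
        ):
            raise ProfileError("profiles are on mismatched grids; resample first")
        if p.channel_roles != ref.channel_roles:
            raise ProfileError("profiles have mismatched channel roles")
    block = np.stack([p.intensities for p in profiles])  # (N, C, P)
    mean = block.mean(axis=0)
    sd = block.std(axis=0, ddof=0)
    scale = np.where(mean.max(axis=1, keepdims=True) > 0, mean.max(axis=1, keepdims=True), 1.0)
    return IntensityProfile(
        positions=ref.positions.copy(),
        intensities=mean / scale,
        sd=sd / scale,
        channel_roles=ref.channel_roles,
        n_cells_averaged=sum(p.n_cells_averaged for p in profiles),
    )


# -- peaks and metrics -----------------------------------------------------

def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    ypad = np.pad(y, pad, mode="edge")
    return np.convolve(ypad, kernel, mode="valid")


def find_profile_peaks(
    profile: IntensityProfile,
    channel_role: str,
    min_prominence: float = 0.2,
    smooth_window: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Local maxima of the lightly smoothed profile with prominence at
    least ``min_prominence`` × channel maximum; endpoints are never peaks.

    Returns ``(positions_um, heights)`` sorted by position.
    """
    if not 0 < min_prominence < 1:
        raise ValueError("min_prominence must be in (0, 1)")
    y = _smooth(profile.channel(channel_role), smooth_window)
    top = y.max()
    if top <= 0:
        return np.array([]), np.array([])
    idx, _props = _scipy_find_peaks(y, prominence=min_prominence * top)
    return profile.positions[idx], y[idx]


def _half_crossing(positions, y, peak_idx, half, direction) -> Optional[float]:
    """Walk outward from a peak to the first crossing below ``half``,
    linearly interpolated; None if the profile never drops below."""
    i = peak_idx
    n = len(y)
    while 0 <= i + direction < n:
        j = i + direction
        if y[j] <= half:
            # interpolate between i and j
            if y[i] == y[j]:
                return float(positions[j])
            t = (y[i] - half) / (y[i] - y[j])
            return float(positions[i] + t * (positions[j] - positions[i]))
        i = j
    return None


def outer_width(
    profile: IntensityProfile,
    channel_role: str,
    params: Optional[ProfileParams] = None,
) -> float:
    """Distance between the outer edges of the peaks at 50% intensity.

    For a bipolar profile this spans from the 50% crossing outside the left
    peak (at half the *left* peak height) to the crossing outside the right
    peak (at half the *right* peak height).  For a single peak it reduces
    to the full width at half maximum.  Crossings are linearly
    interpolated between samples.
    """
    params = params or ProfileParams()
    y = _smooth(profile.channel(channel_role), params.smooth_window)
    pos, heights = find_profile_peaks(
        profile, channel_role, params.min_prominence, params.smooth_window
    )
    if pos.size == 0:
        raise ProfileError(f"no peak in channel {channel_role!r}; width undefined")
    left_idx = int(np.argmin(np.abs(profile.positions - pos[0])))
    right_idx = int(np.argmin(np.abs(profile.positions - pos[-1])))
    xl = _half_crossing(profile.positions, y, left_idx, heights[0] / 2, -1)
    xr = _half_crossing(profile.positions, y, right_idx, heights[-1] / 2, +1)
    if xl is None or xr is None:
        raise ProfileError("profile does not fall below 50% within its extent")
    return float(xr - xl)


def classify_polarity(
    profile: IntensityProfile,
    channel_role: str,
    params: Optional[ProfileParams] = None,
) -> ProfileMetrics:
    """Classify a channel profile as bipolar or monopolar and fill metrics.

    Bipolar requires exactly two detected peaks separated by at least two
    grid steps with a central trough no higher than ``trough_ratio_max``
    of the mean peak height; the clearance is then the inter-peak
    distance.  With no detectable peak the polarity is "undetected" and
    all metrics are absent.
    """
    params = params or ProfileParams()
    pos, heights = find_profile_peaks(
        profile, channel_role, params.min_prominence, params.smooth_window
    )
    if pos.size == 0:
        return ProfileMetrics(channel_role=channel_role, polarity="undetected")

    y = _smooth(profile.channel(channel_role), params.smooth_window)
    centre = float(y[int(np.argmin(np.abs(profile.positions)))])
    try:
        width = outer_width(profile, channel_role, params)
    except ProfileError:
        # e.g. a pan-nuclear channel that never drops below half maximum
        width = None

    trough_ratio = None
    if pos.size >= 2:
        i0 = int(np.argmin(np.abs(profile.positions - pos[0])))
        i1 = int(np.argmin(np.abs(profile.positions - pos[-1])))
        trough = float(y[i0 : i1 + 1].min())
        trough_ratio = trough / float(heights.mean())

    separation = float(pos[-1] - pos[0]) if pos.size >= 2 else 0.0
    if (
        pos.size == 2
        and separation >= 2 * profile.step
        and trough_ratio is not None
        and trough_ratio <= params.trough_ratio_max
    ):
        return ProfileMetrics(
            channel_role=channel_role,
            polarity="bipolar",
            peak_positions=[float(p) for p in pos],
            clearance=separation,
            outer_width=width,
            trough_ratio=trough_ratio,
            centre_intensity=centre,
        )
    main = float(pos[int(np.argmax(heights))])
    return ProfileMetrics(
        channel_role=channel_role,
        polarity="monopolar",
        peak_positions=[main],
        clearance=None,
        outer_width=width,
        trough_ratio=trough_ratio,
        centre_intensity=centre,
    )


# -- 3D cross-check --------------------------------------------------------

def core_shell_score_3d(
    stack: VoxelGrid,
    focus: FocusRegion,
    channel_role: str,
    core_fraction: float = 0.4,
) -> float:
    """3D devoid-core score: 1 − (mean core intensity / mean shell
    intensity) over the filled focus mask, clipped to [0, 1].

    The core is the region within ``core_fraction`` of the focus
    equivalent radius of the centroid; the shell is the rest of the focus.
    Approaches 1 for an ideal hollow shell and 0 for a uniform solid.
    """
    coords_um = (focus.coords + 0.5) * np.asarray(stack.voxel_size)
    d = np.linalg.norm(coords_um - np.asarray(focus.centroid), axis=1)
    r_eq = (3.0 * focus.volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    core = d <= core_fraction * r_eq
    shell = ~core
    if core.sum() < 4 or shell.sum() < 4:
        raise ProfileError("focus too small for a core/shell decomposition")
    ch = stack.channel(channel_role)
    vals = ch[tuple(focus.coords.T)]
    shell_mean = float(vals[shell].mean())
    if shell_mean <= 0:
        return 0.0
    score = 1.0 - float(vals[core].mean()) / shell_mean
    return float(np.clip(score, 0.0, 1.0))
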