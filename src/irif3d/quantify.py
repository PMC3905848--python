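"""Nucleus segmentation, phase calling, 3D focus detection and the
IQR-based valid-range rule for focus volumes.

Foci are detected per nucleus on a top-hat background-subtracted channel
thresholded at background mean + k·SD, labelled in 3D, and hole-filled so
that a hollow shell and its lumen count as ONE focus whose volume is the
filled region — an enlarged focus is one object with internal structure.

The "maximum valid value" of a set of volumes is the largest datum still
within 1.5 interquartile ranges above the upper quartile (Tukey's upper
fence), the rule used to discard abnormally large values caused by focus
clumping and resolution limits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .grids import ROLE_CYCLE, ROLE_RPA, VoxelGrid


@dataclass
class DetectionParams:
    """Tunable segmentation constants (lengths in µm, sizes in voxels)."""

    k_sd: float = 3.0
    min_focus_voxels: int = 27
    rpa_min_focus_voxels: int = 15  # RPA core spots are far smaller than IRIF
    tophat_size_um: tuple[float, float, float] = (2.2, 2.5, 2.5)
    nucleus_smooth_sigma_um: float = 0.5
    min_nucleus_volume_um3: float = 20.0
    max_nucleus_volume_um3: float = 650.0
    phase_threshold: float = 40.0

    def min_voxels_for(self, channel_role: str) -> int:
        if channel_role == ROLE_RPA:
            return self.rpa_min_focus_voxels
        return self.min_focus_voxels


@dataclass
class NucleusRecord:
    """One segmented nucleus: mask, cycle-marker level and phase call."""

    nucleus_id: int
    mask: np.ndarray  # boolean (Z, Y, X)
    mean_cycle_marker: float
    phase: Optional[str] = None

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class FocusRegion:
    """One segmented focus (filled region) in one channel."""

    focus_id: int
    nucleus_id: int
    channel_role: str
    coords: np.ndarray  # (N, 3) integer voxel indices (z, y, x)
    centroid: tuple[float, float, float]  # (z, y, x) µm
    volume: float  # µm³

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[tuple(self.coords.T)] = True
        return m


@dataclass
class VolumeSummary:
    """Per-condition volume statistics with the IQR valid-range rule."""

    volumes: np.ndarray
    median: float
    minimum: float
    max_valid: float
    n_excluded: int


# -- nuclei ----------------------------------------------------------------

def segment_nuclei(
    stack: VoxelGrid,
    params: Optional[DetectionParams] = None,
    nuclear_role: str = ROLE_CYCLE,
) -> list[NucleusRecord]:
    """Segment nuclei on the (pan-nuclear) cycle-marker channel.

    Otsu threshold on the smoothed channel, 3D connected components, then
    volume window filtering: components below ``min_nucleus_volume_um3``
    are debris, components above ``max_nucleus_volume_um3`` are merged
    (touching) nuclei and are excluded rather than split.
    """
    params = params or DetectionParams()
    ch = stack.channel(nuclear_role)  # ChannelError if absent
    if not np.any(ch > 0):
        return []
    sigma = tuple(params.nucleus_smooth_sigma_um / v for v in stack.voxel_size)
    smooth = ndi.gaussian_filter(np.asarray(ch, dtype=np.float32), sigma=sigma)
    thr = threshold_otsu(smooth)
    mask = smooth > thr
    labels, n = ndi.label(mask)
    records: list[NucleusRecord] = []
    nucleus_id = 0
    for lab in range(1, n + 1):
        comp = labels == lab
        vol = comp.sum() * stack.voxel_volume
        if vol < params.min_nucleus_volume_um3 or vol > params.max_nucleus_volume_um3:
            continue
        records.append(
            NucleusRecord(
                nucleus_id=nucleus_id,
                mask=comp,
                mean_cycle_marker=float(ch[comp].mean()),
            )
        )
        nucleus_id += 1
    return records


def classify_phase(
    nucleus: NucleusRecord,
    stack: VoxelGrid,
    threshold: Optional[float] = None,
    params: Optional[DetectionParams] = None,
) -> str:
    """G2 iff mean cycle-marker intensity within the nucleus mask exceeds
    the (config) threshold, mirroring marker-positive visual scoring."""
    if threshold is None:
        threshold = (params or DetectionParams()).phase_threshold
    mean = float(stack.channel(ROLE_CYCLE)[nucleus.mask].mean())
    nucleus.mean_cycle_marker = mean
    phase = "G2" if mean > threshold else "G1"
    nucleus.phase = phase
    return phase


# -- foci ------------------------------------------------------------------

def _background_stats(values: np.ndarray, k: float) -> tuple[float, float]:
    """Robust background mean/SD via median and MAD, so the bright focus
    voxels (a minority of the nucleus) cannot inflate the estimate."""
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med, 1.4826 * mad


def _fill_holes(mask: np.ndarray) -> np.ndarray:
    """Close shell lumina: fill per z-slice (ring cross-sections), then in 3D."""
    out = np.empty_like(mask)
    for z in range(mask.shape[0]):
        out[z] = ndi.binary_fill_holes(mask[z])
    return ndi.binary_fill_holes(out)


def detect_foci(
    stack: VoxelGrid,
    nucleus: NucleusRecord,
    channel_role: str,
    params: Optional[DetectionParams] = None,
) -> list[FocusRegion]:
    """Detect foci of one channel inside one nucleus.

    Top-hat background subtraction, threshold at background mean + k·SD
    (statistics over the nucleus mask), hole closing so shells label as one
    filled object, 3D connected components, minimum-size filter.
    """
    params = params or DetectionParams()
    ch = np.asarray(stack.channel(channel_role), dtype=np.float32)
    size = tuple(
        max(3, int(round(t / v)) | 1)  # odd window, >= 3 voxels
        for t, v in zip(params.tophat_size_um, stack.voxel_size)
    )
    tophat = ndi.white_tophat(ch, size=size)
    inside = tophat[nucleus.mask]
    bg_mean, bg_sd = _background_stats(inside, params.k_sd)
    thr = float(bg_mean + params.k_sd * bg_sd)
    fg = (tophat > thr) & nucleus.mask
    if not fg.any():
        return []
    fg = _fill_holes(fg) & nucleus.mask
    labels, n = ndi.label(fg)
    min_vox = params.min_voxels_for(channel_role)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)
    bboxes = ndi.find_objects(labels)
    regions: list[FocusRegion] = []
    fid = 0
    for lab in range(1, n + 1):
        if sizes[lab] < min_vox:
            continue
        box = bboxes[lab - 1]
        offset = np.array([s.start for s in box])
        coords = np.argwhere(labels[box] == lab) + offset
        centroid = tuple(
            float(c) for c in (coords.mean(axis=0) + 0.5) * np.asarray(stack.voxel_size)
        )
        regions.append(
            FocusRegion(
                focus_id=fid,
                nucleus_id=nucleus.nucleus_id,
                channel_role=channel_role,
                coords=coords,
                centroid=centroid,
                volume=coords.shape[0] * stack.voxel_volume,
            )
        )
        fid += 1
    return regions


def count_foci(
    stack: VoxelGrid,
    nucleus: NucleusRecord,
    channel_role: str,
    params: Optional[DetectionParams] = None,
) -> int:
    """Number of detected foci (e.g. γH2AX or RPA focus enumeration)."""
    return len(detect_foci(stack, nucleus, channel_role, params))


# -- volume statistics -----------------------------------------------------

def max_valid_value(values: Sequence[float]) -> float:
    """Highest datum within 1.5 IQR of the upper quartile.

    Quartiles use linear interpolation of order statistics; the fence is
    Q3 + 1.5·(Q3 − Q1) and the result is ``max{v : v <= fence}`` (always
    defined for a nonempty sample, since the median never exceeds the
    fence).
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("max_valid_value requires a nonempty sample")
    q1, q3 = np.quantile(v, [0.25, 0.75])
    fence = q3 + 1.5 * (q3 - q1)
    return float(v[v <= fence].max())


def volume_summary(regions: Iterable[Union[FocusRegion, float]]) -> VolumeSummary:
    """Summarize focus volumes: median, minimum, IQR-rule maximum valid
    value, and the count of excluded (above-fence) values.

    Accepts :class:`FocusRegion` objects or raw volumes in µm³.
    """
    volumes = np.asarray(
        [r.volume if isinstance(r, FocusRegion) else float(r) for r in regions],
        dtype=float,
    )
    if volumes.size == 0:
        raise ValueError("volume_summary requires at least one focus")
    mv = max_valid_value(volumes)
    return VolumeSummary(
        volumes=volumes,
        median=float(np.median(volumes)),
        minimum=float(volumes.min()),
        max_valid=mv,
        n_excluded=int((volumes > mv).sum()),
    )
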