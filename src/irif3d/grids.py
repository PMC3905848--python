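"""Multi-channel 3D voxel grids with physical voxel sizes and channel roles.

A :class:`VoxelGrid` is the in-memory representation of one imaged field
(typically a single nucleus): a ``(C, Z, Y, X)`` array of non-negative
fluorescence intensities, the physical voxel size in micrometres, and one
role label per channel naming the protein/stain the channel reports
(53BP1, conjugated ubiquitin via the FK2 antibody, RPA, γH2AX, BRCA1, and
a pan-nuclear cell-cycle marker).

Coordinates are physical micrometres with the origin at the stack corner;
voxel ``i`` along an axis owns the half-open interval ``[i*s, (i+1)*s)``
and its centre sits at ``(i + 0.5) * s``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: Canonical channel role labels.
ROLE_53BP1 = "53BP1"
ROLE_FK2 = "FK2"
ROLE_RPA = "RPA"
ROLE_GH2AX = "gH2AX"
ROLE_BRCA1 = "BRCA1"
ROLE_CYCLE = "cycle"

DEFAULT_ROLES: tuple[str, ...] = (
    ROLE_53BP1,
    ROLE_FK2,
    ROLE_RPA,
    ROLE_GH2AX,
    ROLE_BRCA1,
    ROLE_CYCLE,
)


class ChannelError(KeyError):
    """Raised when a channel role is missing from a grid."""


@dataclass
class VoxelGrid:
    """A multi-channel 3D image stack with physical metadata.

    Parameters
    ----------
    data
        Intensities, shape ``(C, Z, Y, X)``, all values >= 0.
    voxel_size
        Physical voxel size ``(z, y, x)`` in micrometres, all > 0.
    channel_roles
        One unique role label per channel, in channel order.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_roles: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"data must be (C, Z, Y, X), got shape {self.data.shape}")
        self.voxel_size = tuple(float(s) for s in self.voxel_size)
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel_size must be three positive values, got {self.voxel_size}")
        self.channel_roles = tuple(self.channel_roles)
        if len(self.channel_roles) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_roles)} roles for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_roles)) != len(self.channel_roles):
            raise ValueError(f"channel roles must be unique, got {self.channel_roles}")
        if self.data.size and float(self.data.min()) < 0:
            raise ValueError("intensities must be non-negative")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial shape ``(Z, Y, X)`` in voxels."""
        return self.data.shape[1:]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        vz, vy, vx = self.voxel_size
        return vz * vy * vx

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical extent ``(z, y, x)`` of the stack in µm."""
        return tuple(n * s for n, s in zip(self.shape, self.voxel_size))

    def axis_centres(self, axis: int) -> np.ndarray:
        """Physical centre coordinates of voxels along one spatial axis (µm)."""
        n = self.shape[axis]
        return (np.arange(n) + 0.5) * self.voxel_size[axis]

    # -- channel access -----------------------------------------------------
    def channel_index(self, role: str) -> int:
        try:
            return self.channel_roles.index(role)
        except ValueError:
            raise ChannelError(
                f"channel role {role!r} not in grid (has {self.channel_roles})"
            ) from None

    def has_channel(self, role: str) -> bool:
        return role in self.channel_roles

    def channel(self, role: str) -> np.ndarray:
        """Return a (Z, Y, X) view of one channel."""
        return self.data[self.channel_index(role)]

    # -- construction -------------------------------------------------------
    @classmethod
    def empty(
        cls,
        shape: Sequence[int],
        voxel_size: Sequence[float],
        channel_roles: Sequence[str] = DEFAULT_ROLES,
        dtype=np.float32,
    ) -> "VoxelGrid":
        data = np.zeros((len(channel_roles), *shape), dtype=dtype)
        return cls(data, tuple(voxel_size), tuple(channel_roles))

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(self.data.copy(), self.voxel_size, self.channel_roles)
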