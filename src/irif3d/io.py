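"""Stack and table I/O.

Stacks are written as plain multi-page TIFF (axes ``CZYX``) with a JSON
sidecar of the same stem carrying the physical metadata a bare TIFF
cannot: voxel size, channel roles, and optional annotations (condition
label, nucleus id).  Reading requires the sidecar; a stack without voxel
size metadata is an error, never a guess.

Tables are CSV with a header row; units are embedded in the column names
(``_um``, ``_um3``).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
import tifffile

from .grids import VoxelGrid
from .quantify import FocusRegion
from .simulate import GroundTruthRecord

TRUTH_COLUMNS = [
    "nucleus_id",
    "focus_id",
    "channel",
    "kind",
    "outer_um",
    "inner_um",
    "cx",
    "cy",
    "cz",
    "true_volume_um3",
    "condition",
]


class MetadataError(ValueError):
    pass


def _sidecar_path(path: Union[str, Path]) -> Path:
    return Path(path).with_suffix(".json")


def write_stack(path: Union[str, Path], grid: VoxelGrid, **annotations) -> Path:
    """Write a stack as TIFF + JSON sidecar; returns the TIFF path."""
    path = Path(path)
    tifffile.imwrite(
        path, np.asarray(grid.data, dtype=np.float32), photometric="minisblack"
    )
    meta = {
        "voxel_size_um": list(grid.voxel_size),
        "channel_roles": list(grid.channel_roles),
        "axes": "CZYX",
    }
    meta.update(annotations)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path: Union[str, Path]) -> tuple[VoxelGrid, dict]:
    """Read a TIFF + sidecar stack; returns ``(grid, annotations)``."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(f"no metadata sidecar {sidecar} for {path}")
    meta = json.loads(sidecar.read_text())
    for key in ("voxel_size_um", "channel_roles"):
        if key not in meta:
            raise MetadataError(f"sidecar {sidecar} missing {key!r}")
    data = tifffile.imread(path)
    if data.ndim == 3:  # single channel stored without the channel axis
        data = data[None]
    if data.ndim != 4:
        raise MetadataError(f"stack {path} is {data.ndim}D; expected (C, Z, Y, X)")
    if data.shape[0] != len(meta["channel_roles"]):
        raise MetadataError(
            f"{len(meta['channel_roles'])} roles for {data.shape[0]} channels in {path}"
        )
    grid = VoxelGrid(
        data=data,
        voxel_size=tuple(meta["voxel_size_um"]),
        channel_roles=tuple(meta["channel_roles"]),
    )
    extra = {k: v for k, v in meta.items() if k not in ("voxel_size_um", "channel_roles", "axes")}
    return grid, extra


# -- tables ----------------------------------------------------------------

def truth_to_frame(records: Iterable[GroundTruthRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        cz, cy, cx = r.geometry.centre
        rows.append(
            {
                "nucleus_id": r.nucleus_id,
                "focus_id": r.focus_id,
                "channel": r.channel_role,
                "kind": r.geometry.kind,
                "outer_um": r.geometry.outer_radius,
                "inner_um": r.geometry.inner_radius,
                "cx": cx,
                "cy": cy,
                "cz": cz,
                "true_volume_um3": r.true_volume,
                "condition": r.condition,
            }
        )
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def foci_to_frame(
    regions: Iterable[FocusRegion],
    condition: Optional[str] = None,
) -> pd.DataFrame:
    rows = []
    for f in regions:
        cz, cy, cx = f.centroid
        row = {
            "nucleus_id": f.nucleus_id,
            "focus_id": f.focus_id,
            "channel": f.channel_role,
            "volume_um3": f.volume,
            "cx": cx,
            "cy": cy,
            "cz": cz,
        }
        if condition is not None:
            row["condition"] = condition
        rows.append(row)
    cols = ["nucleus_id", "focus_id", "channel", "volume_um3", "cx", "cy", "cz"]
    if condition is not None:
        cols.append("condition")
    return pd.DataFrame(rows, columns=cols)


def profile_to_frame(profile, condition: Optional[str] = None) -> pd.DataFrame:
    """Long-format per-position profile table (position_um, channel, mean, sd, n)."""
    rows = []
    for c, role in enumerate(profile.channel_roles):
        for i, pos in enumerate(profile.positions):
            rows.append(
                {
                    "condition": condition,
                    "position_um": float(pos),
                    "channel": role,
                    "mean": float(profile.intensities[c, i]),
                    "sd": float(profile.sd[c, i]) if profile.sd is not None else np.nan,
                    "n": profile.n_cells_averaged,
                }
            )
    return pd.DataFrame(rows)


def metrics_to_frame(metrics: dict, condition: Optional[str] = None) -> pd.DataFrame:
    """Per-channel profile metrics table."""
    rows = []
    for role, m in metrics.items():
        rows.append(
            {
                "condition": condition,
                "channel": role,
                "polarity": m.polarity,
                "clearance_um": m.clearance,
                "outer_width_um": m.outer_width,
                "trough_ratio": m.trough_ratio,
                "centre_intensity": m.centre_intensity,
            }
        )
    frame = pd.DataFrame(rows)
    for col in ("clearance_um", "outer_width_um", "trough_ratio", "centre_intensity"):
        frame[col] = frame[col].astype(float)
    return frame
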