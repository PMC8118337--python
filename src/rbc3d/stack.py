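"""Voxel stacks: the raw unit of 3D confocal imaging data.

Arrays are stored z-slowest (``intensities[z, y, x]``), so a multi-page
TIFF maps directly onto the first axis.  Physical voxel sizes are kept in
nanometres in (x, y, z) order.  Voxel centres sit at ``(i + 0.5) * pitch``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import tifffile

log = logging.getLogger(__name__)

DEFAULT_VOXEL_NM = (110.0, 110.0, 300.0)


class StackFormatError(ValueError):
    """Raised for unreadable or structurally inconsistent stack files."""


@dataclass
class VoxelStack:
    intensities: np.ndarray  # (nz, ny, nx), non-negative
    voxel_size_xyz: tuple[float, float, float]  # nm

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise StackFormatError("intensities must be a 3D array")
        vs = tuple(float(v) for v in self.voxel_size_xyz)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise StackFormatError("voxel sizes must be three positive lengths")
        if not np.isfinite(self.intensities).all():
            raise StackFormatError("intensities must be finite")
        self.voxel_size_xyz = vs

    @property
    def shape_xyz(self) -> tuple[int, int, int]:
        nz, ny, nx = self.intensities.shape
        return nx, ny, nz

    @property
    def n_planes(self) -> int:
        return self.intensities.shape[0]

    def copy(self) -> "VoxelStack":
        return VoxelStack(self.intensities.copy(), self.voxel_size_xyz)


def save_stack(path, stack: VoxelStack, spec_sidecar: dict | None = None) -> None:
    """Write a multi-page TIFF; voxel size goes into the image description.

    If *spec_sidecar* is given, a ``<path>.json`` ground-truth sidecar is
    written next to the TIFF.
    """
    meta = {"voxel_size_xyz_nm": list(stack.voxel_size_xyz)}
    tifffile.imwrite(
        str(path),
        np.asarray(stack.intensities, dtype=np.float32),
        photometric="minisblack",
        description=json.dumps(meta),
    )
    if spec_sidecar is not None:
        sidecar = str(path) + ".json"
        with open(sidecar, "w") as fh:
            json.dump(spec_sidecar, fh, indent=1)


def load_stack(path, default_voxel_nm: tuple[float, float, float] = DEFAULT_VOXEL_NM) -> VoxelStack:
    """Read a multi-page TIFF into a :class:`VoxelStack`.

    Voxel sizes come from the JSON image description written by
    :func:`save_stack`; if absent, *default_voxel_nm* is used and a
    warning is logged.
    """
    try:
        with tifffile.TiffFile(str(path)) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description if tf.pages else ""
    except Exception as exc:  # noqa: BLE001 - normalise reader errors
        raise StackFormatError(f"cannot read TIFF {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise StackFormatError(f"expected a 3D stack in {path}, got shape {data.shape}")
    voxel = None
    if desc:
        try:
            meta = json.loads(desc)
            voxel = tuple(float(v) for v in meta["voxel_size_xyz_nm"])
        except (ValueError, KeyError, TypeError):
            voxel = None
    if voxel is None:
        log.warning("no voxel-size metadata in %s; using defaults %s nm", path, default_voxel_nm)
        warnings.warn(f"no voxel-size metadata in {path}; using defaults", stacklevel=2)
        voxel = tuple(default_voxel_nm)
    return VoxelStack(np.asarray(data, dtype=np.float64), voxel)
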