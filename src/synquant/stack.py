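"""Multi-channel z-stack container and TIFF/OME-TIFF I/O.

The in-memory unit of analysis is an :class:`ImageStack`: a ``(channel, z,
y, x)`` array of non-negative fluorescence intensities together with the
physical voxel geometry and a mapping from biological channel roles (LAMP,
LC3, GEFH1, OVA, ACTIN, BRIGHTFIELD) to channel indices.  All downstream
metrics work in physical micrometres derived from this metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

#: Channel roles understood by the pipeline.
VALID_ROLES = frozenset(
    {"OVA", "LAMP", "LC3", "GEFH1", "ACTIN", "BRIGHTFIELD"}
)


class StackError(ValueError):
    """Raised for malformed stacks, role maps or missing metadata."""


@dataclass
class ImageStack:
    """A multi-channel fluorescence z-stack with physical metadata.

    Parameters
    ----------
    voxels
        Intensities, shape ``(n_channels, n_z, n_y, n_x)``, finite and >= 0.
    pixel_size_um
        Lateral size of one pixel in micrometres.
    slice_step_um
        Axial distance between consecutive z-slices in micrometres.
    channel_roles
        Mapping from role name (see :data:`VALID_ROLES`) to channel index.
    """

    voxels: np.ndarray
    pixel_size_um: float
    slice_step_um: float
    channel_roles: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise StackError(
                f"voxels must be (channel, z, y, x); got ndim={self.voxels.ndim}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise StackError("voxel intensities must be finite")
        if np.any(self.voxels < 0):
            raise StackError("voxel intensities must be non-negative")
        if not (self.pixel_size_um > 0 and self.slice_step_um > 0):
            raise StackError("physical voxel sizes must be positive")
        n_chan = self.voxels.shape[0]
        for role, idx in self.channel_roles.items():
            if role not in VALID_ROLES:
                raise StackError(f"unknown channel role {role!r}")
            if not (0 <= idx < n_chan):
                raise StackError(
                    f"role {role!r} maps to channel {idx}, but the stack has "
                    f"only {n_chan} channels"
                )

    # -- convenience accessors -------------------------------------------

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[1]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    def channel(self, role: str) -> np.ndarray:
        """Return the ``(z, y, x)`` volume for a channel role."""
        if role not in self.channel_roles:
            raise StackError(f"channel role {role!r} not present in stack")
        return self.voxels[self.channel_roles[role]]

    def projection(self, role: str) -> np.ndarray:
        """Sum-of-slices (z-sum) projection of one channel, shape (y, x).

        Accumulated in float64 so downstream ratio metrics are exact
        regardless of the storage dtype.
        """
        return self.channel(role).sum(axis=0, dtype=np.float64)


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as OME-TIFF with physical sizes and a role sidecar.

    A JSON sidecar ``<path>.roles.json`` records the role map so that
    :func:`read_stack` can round-trip a stack without arguments.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        stack.voxels.astype(np.float32, copy=False),
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": stack.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.slice_step_um,
            "PhysicalSizeZUnit": "µm",
        },
    )
    sidecar = path.with_suffix(path.suffix + ".roles.json")
    sidecar.write_text(json.dumps(stack.channel_roles, indent=2))
    return path


def _ome_physical_sizes(tif: tifffile.TiffFile) -> tuple[float | None, float | None]:
    """Extract (lateral, axial) pixel sizes in µm from OME metadata, if any."""
    if not tif.ome_metadata:
        return None, None
    try:
        meta = tifffile.xml2dict(tif.ome_metadata)
        pixels = meta["OME"]["Image"]
        if isinstance(pixels, list):
            pixels = pixels[0]
        pixels = pixels["Pixels"]
        px = pixels.get("PhysicalSizeX")
        pz = pixels.get("PhysicalSizeZ")
        return (float(px) if px else None, float(pz) if pz else None)
    except (KeyError, TypeError, ValueError):
        return None, None


def read_stack(
    path: str | Path,
    channel_roles: Mapping[str, int] | None = None,
    pixel_size_um: float | None = None,
    slice_step_um: float | None = None,
) -> ImageStack:
    """Load a TIFF/OME-TIFF z-stack voxel-faithfully.

    Physical sizes are taken from OME metadata when present, else from the
    arguments; if neither supplies a value an error names the missing field.
    ``channel_roles`` falls back to the JSON sidecar written by
    :func:`write_stack`.
    """
    path = Path(path)
    if not path.exists():
        raise StackError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta_px, meta_pz = _ome_physical_sizes(tif)
    if data.ndim == 3:  # single channel
        data = data[np.newaxis]
    if data.ndim != 4:
        raise StackError(f"expected a (C, Z, Y, X) stack in {path}, got {data.shape}")

    px = pixel_size_um if pixel_size_um is not None else meta_px
    pz = slice_step_um if slice_step_um is not None else meta_pz
    if px is None:
        raise StackError(
            f"{path}: pixel_size_um missing from file metadata and no override given"
        )
    if pz is None:
        raise StackError(
            f"{path}: slice_step_um missing from file metadata and no override given"
        )

    roles: dict[str, int]
    if channel_roles is not None:
        roles = dict(channel_roles)
    else:
        sidecar = path.with_suffix(path.suffix + ".roles.json")
        roles = json.loads(sidecar.read_text()) if sidecar.exists() else {}

    return ImageStack(
        voxels=np.asarray(data, dtype=np.float32),
        pixel_size_um=float(px),
        slice_step_um=float(pz),
        channel_roles=roles,
    )
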