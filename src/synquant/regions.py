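"""Cell, bead and derived regions of interest.

The metrics operate on three regions extracted from (or provided with)
each stack: the cell footprint, a synapse disk concentric with the bead,
and a central ellipse holding one third of the footprint area.  Regions
are 2-D lateral masks applied per z-slice, matching an analysis based on
z-sum projections; all geometry is reported in physical micrometres with
voxel-center, 0-indexed coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .stack import ImageStack


class RegionError(ValueError):
    """Raised when a region cannot be constructed (blank channel, no bead...)."""


@dataclass
class RegionSet:
    """All regions needed by the per-cell metrics.

    ``provenance`` records, per region, whether it was detected from the
    image or provided by the user; ``synapse_clipped`` flags a synapse
    disk cut by the image border.
    """

    cell_mask: np.ndarray  # (y, x) bool footprint
    bead_center_um: tuple[float, float] | None = None
    bead_radius_um: float | None = None
    synapse_mask: np.ndarray | None = None
    central_mask: np.ndarray | None = None
    synapse_pad_um: float | None = None
    synapse_clipped: bool = False
    provenance: dict[str, Literal["detected", "provided"]] = field(
        default_factory=dict
    )


def cell_centroid_um(cell_mask: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Geometric (unweighted) centroid of the binary footprint, in µm."""
    if not cell_mask.any():
        raise RegionError("empty cell mask")
    ys, xs = np.nonzero(cell_mask)
    return np.array([ys.mean(), xs.mean()]) * pixel_size_um


def segment_cell(stack: ImageStack, role: str = "ACTIN") -> np.ndarray:
    """Detect the cell footprint from the cytoskeleton (phalloidin) channel.

    The z-sum projection is Otsu-thresholded; the largest connected
    component is kept and its holes filled.  This is an automated stand-in
    for a manually drawn cell border.
    """
    proj = stack.projection(role)
    if proj.max() <= proj.min():
        raise RegionError(f"channel {role!r} is blank; cannot segment the cell")
    thr = threshold_otsu(proj)
    fg = proj > thr
    if not fg.any():
        raise RegionError("no foreground component above threshold")
    labels = label(fg)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return ndimage.binary_fill_holes(labels == largest)


def detect_bead(
    stack: ImageStack,
    expected_diameter_um: float = 3.0,
    cell_mask: np.ndarray | None = None,
) -> tuple[tuple[float, float], float]:
    """Locate the antigen-coated bead; returns (center µm (y, x), radius µm).

    The OVA (or brightfield) projection is thresholded and hole-filled;
    candidate components must have an equivalent diameter within ±30 % of
    the expected bead size.  With several candidates the one nearest the
    cell footprint centroid is chosen; an exact tie is an error listing
    the candidates.
    """
    role = "OVA" if "OVA" in stack.channel_roles else "BRIGHTFIELD"
    if role not in stack.channel_roles:
        raise RegionError("bead detection needs an OVA or BRIGHTFIELD channel")
    proj = stack.projection(role)
    if proj.max() <= proj.min():
        raise RegionError("bead channel is blank")
    fg = ndimage.binary_fill_holes(proj > threshold_otsu(proj))
    px = stack.pixel_size_um
    candidates = []
    for region in regionprops(label(fg)):
        diam = region.equivalent_diameter_area * px
        if abs(diam - expected_diameter_um) <= 0.3 * expected_diameter_um:
            candidates.append((np.array(region.centroid) * px, diam / 2))
    if not candidates:
        raise RegionError(
            f"no circular object within ±30% of {expected_diameter_um} µm found"
        )
    if len(candidates) == 1:
        center, radius = candidates[0]
        return (float(center[0]), float(center[1])), float(radius)
    if cell_mask is None:
        raise RegionError(
            f"{len(candidates)} bead candidates but no cell mask to disambiguate"
        )
    ref = cell_centroid_um(cell_mask, px)
    dists = np.array([np.linalg.norm(c - ref) for c, _ in candidates])
    order = np.argsort(dists)
    if np.isclose(dists[order[0]], dists[order[1]]):
        listing = ", ".join(f"({c[0]:.2f}, {c[1]:.2f})" for c, _ in candidates)
        raise RegionError(f"bead candidates tie at equal distance: {listing}")
    center, radius = candidates[order[0]]
    return (float(center[0]), float(center[1])), float(radius)


def synapse_disk(
    stack: ImageStack,
    bead_center_um: tuple[float, float],
    bead_radius_um: float,
    pad_um: float | None = None,
) -> tuple[np.ndarray, bool]:
    """Concentric disk around the bead, applied per z-slice.

    The default pad equals the bead radius, giving a disk whose diameter
    is twice the bead diameter (a 3 µm radius around a 3 µm bead).
    Returns the 2-D mask and a flag set when the disk is clipped by the
    image border.
    """
    if pad_um is None:
        pad_um = bead_radius_um
    r = bead_radius_um + pad_um
    px = stack.pixel_size_um
    ny, nx = stack.shape_zyx[1:]
    y = np.arange(ny) * px
    x = np.arange(nx) * px
    mask = (y[:, None] - bead_center_um[0]) ** 2 + (
        x[None, :] - bead_center_um[1]
    ) ** 2 <= r**2
    clipped = (
        bead_center_um[0] - r < -px / 2
        or bead_center_um[1] - r < -px / 2
        or bead_center_um[0] + r > (ny - 0.5) * px
        or bead_center_um[1] + r > (nx - 0.5) * px
    )
    return mask, bool(clipped)


def central_ellipse(cell_mask: np.ndarray) -> np.ndarray:
    """Concentric ellipse covering one third of the footprint area.

    The ellipse shares the footprint's centroid, orientation and axis
    ratio (from the second central moments of the binary mask) and is
    scaled so its area equals one third of the footprint's.  For a
    circular footprint this is the concentric disk of radius r/sqrt(3).
    """
    n_px = int(cell_mask.sum())
    if n_px < 10:
        raise RegionError(f"degenerate cell mask ({n_px} px)")
    ys, xs = np.nonzero(cell_mask)
    cy, cx = ys.mean(), xs.mean()
    dy, dx = ys - cy, xs - cx
    cov = np.array(
        [[np.mean(dy * dy), np.mean(dy * dx)], [np.mean(dy * dx), np.mean(dx * dx)]]
    )
    evals, evecs = np.linalg.eigh(cov)  # ascending; columns are (y, x) axes
    evals = np.clip(evals, 1e-12, None)
    # axis ratio from moment eigenvalues; absolute scale set by target area
    ratio = np.sqrt(evals[1] / evals[0])  # major / minor
    target = n_px / 3.0
    b = np.sqrt(target / (np.pi * ratio))  # minor semi-axis, px
    a = b * ratio
    ny, nx = cell_mask.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    rel = np.stack([yy - cy, xx - cx], axis=-1)
    u = rel @ evecs[:, 1]  # along major axis
    v = rel @ evecs[:, 0]  # along minor axis
    ellipse = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return ellipse & cell_mask


def build_regions(
    stack: ImageStack,
    cell_mask: np.ndarray | None = None,
    bead: tuple[tuple[float, float], float] | None = None,
    expected_bead_diameter_um: float = 3.0,
    pad_um: float | None = None,
    with_bead: bool = True,
) -> RegionSet:
    """Assemble a full :class:`RegionSet`, detecting whatever is not provided.

    User-provided masks always override detection.
    """
    provenance: dict[str, str] = {}
    if cell_mask is None:
        cell_mask = segment_cell(stack)
        provenance["cell"] = "detected"
    else:
        cell_mask = np.asarray(cell_mask, dtype=bool)
        provenance["cell"] = "provided"

    bead_center = bead_radius = None
    syn_mask = None
    clipped = False
    if with_bead:
        if bead is None:
            bead_center, bead_radius = detect_bead(
                stack, expected_bead_diameter_um, cell_mask
            )
            provenance["bead"] = "detected"
        else:
            bead_center, bead_radius = bead
            provenance["bead"] = "provided"
        syn_mask, clipped = synapse_disk(stack, bead_center, bead_radius, pad_um)

    central = central_ellipse(cell_mask)
    return RegionSet(
        cell_mask=cell_mask,
        bead_center_um=bead_center,
        bead_radius_um=bead_radius,
        synapse_mask=syn_mask,
        central_mask=central,
        synapse_pad_um=pad_um if pad_um is not None else bead_radius,
        synapse_clipped=clipped,
        provenance=provenance,  # type: ignore[arg-type]
    )
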