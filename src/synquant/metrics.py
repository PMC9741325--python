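"""Per-cell immune-synapse metrics.

Implements the quantities read off bead-conjugate and spreading stacks:

* ``antigen_remaining`` — bead-associated OVA on the z-sum projection
  relative to a time-0 reference, and the percent extracted.
* ``recruitment_fraction`` — fraction of a channel's fluorescence inside
  the synapse disk.
* ``bead_fold_change`` — synapse-disk signal normalized by the time-0
  population mean (used for GEF-H1).
* ``polarity_index`` — projection of the channel center of mass (CL,
  measured from the cell center CC) onto the cell-center-to-bead axis
  (CB), divided by |CB|; 1 = fully polarized toward the bead, -1 =
  anti-polarized, 0 = unpolarized.
* ``central_enrichment`` — density in the central one-third-area ellipse
  over density in the whole footprint, minus 1, on the synaptic plane.
* ``z_profile`` / ``bottom_top_ratio`` — per-slice mean fluorescence in
  the cell from the synapse plane upward, and the summed bottom-half /
  top-half ratio (middle slice of an odd stack split equally).
* ``manders_overlap`` — Manders M1: fraction of channel-A intensity on
  pixels where channel B exceeds its threshold.

Center-of-mass quantities are computed on z-sum projections (2-D); only
the z-profile is intrinsically 3-D.  All ratio metrics are exactly
invariant to rescaling a channel by a positive constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dataclass_fields
from typing import NamedTuple

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .regions import RegionSet, cell_centroid_um
from .stack import ImageStack


class MetricError(ValueError):
    """Raised when a metric's preconditions are not met."""


# ---------------------------------------------------------------------------
# antigen extraction


class ExtractionResult(NamedTuple):
    fraction_remaining: float
    percent_extracted: float
    qc: tuple[str, ...]


def bead_total_intensity(
    stack: ImageStack,
    bead_mask: np.ndarray,
    channel_role: str = "OVA",
    background_subtract: bool = True,
) -> float:
    """Total channel intensity in the bead region on the z-sum projection.

    The local background (median projected intensity outside the region)
    is subtracted per pixel, as an absolute intensity readout is otherwise
    inflated by the camera noise floor.  On a noise-free image the
    correction is zero.
    """
    if not bead_mask.any():
        raise MetricError("empty bead region")
    proj = stack.projection(channel_role)
    total = float(proj[bead_mask].sum())
    if background_subtract and (~bead_mask).any():
        total -= float(np.median(proj[~bead_mask])) * int(bead_mask.sum())
    return max(total, 0.0)


def antigen_remaining(
    stack: ImageStack,
    bead_mask: np.ndarray,
    t0_reference: float,
    background_subtract: bool = True,
) -> ExtractionResult:
    """Bead OVA relative to the time-0 population reference.

    The bead signal is the background-corrected total OVA intensity inside
    ``bead_mask`` on the sum-of-slices projection (see
    :func:`bead_total_intensity`; the reference must be measured the same
    way).  ``percent_extracted = 100 * (1 - fraction)`` clipped to
    [0, 100]; a bead brighter than the reference yields 0 % with a
    ``negative_extraction`` QC flag.
    """
    if t0_reference <= 0:
        raise MetricError("t0 reference must be positive")
    total = bead_total_intensity(stack, bead_mask, "OVA", background_subtract)
    fraction = total / t0_reference
    qc: tuple[str, ...] = ()
    if fraction > 1:
        qc = ("negative_extraction",)
    percent = float(np.clip(100.0 * (1.0 - fraction), 0.0, 100.0))
    return ExtractionResult(fraction, percent, qc)


# ---------------------------------------------------------------------------
# recruitment


def recruitment_fraction(
    stack: ImageStack,
    channel_role: str,
    synapse_mask: np.ndarray,
    cell_mask: np.ndarray,
) -> float:
    """Fraction of a channel's fluorescence inside the synapse disk.

    Denominator is the union of the cell footprint and the disk (the disk
    extends over the bead, outside the footprint).  Uniform intensity
    gives exactly the area ratio.
    """
    if not synapse_mask.any():
        raise MetricError("empty synapse region")
    proj = stack.projection(channel_role)
    denom_mask = cell_mask | synapse_mask
    denom = float(proj[denom_mask].sum())
    if denom <= 0:
        raise MetricError("cell has no fluorescence in this channel")
    return float(proj[synapse_mask].sum() / denom)


def bead_fold_change(
    stack: ImageStack,
    channel_role: str,
    bead_mask: np.ndarray,
    t0_population_mean: float,
) -> float:
    """Signal at the bead area divided by the time-0 population mean."""
    if t0_population_mean <= 0:
        raise MetricError("t0 population mean must be positive")
    if not bead_mask.any():
        raise MetricError("empty bead region")
    return float(stack.projection(channel_role)[bead_mask].sum() / t0_population_mean)


# ---------------------------------------------------------------------------
# polarity


@dataclass(frozen=True)
class PolarityGeometry:
    """Geometry of the polarity computation (all vectors in µm, (y, x))."""

    cc_um: tuple[float, float]
    bead_center_um: tuple[float, float]
    cb_um: tuple[float, float]
    cb_norm_um: float
    cl_um: tuple[float, float]
    projection_um: float
    index: float


def _intensity_com_um(
    proj: np.ndarray, mask: np.ndarray | None, pixel_size_um: float
) -> np.ndarray:
    vals = proj if mask is None else np.where(mask, proj, 0.0)
    total = vals.sum()
    if total <= 0:
        raise MetricError("zero channel intensity in the measurement region")
    ny, nx = proj.shape
    cy = (vals.sum(axis=1) @ np.arange(ny)) / total
    cx = (vals.sum(axis=0) @ np.arange(nx)) / total
    return np.array([cy, cx]) * pixel_size_um


def polarity_index(
    stack: ImageStack,
    channel_role: str,
    cell_mask: np.ndarray | None,
    bead_center_um: tuple[float, float],
    cell_center_um: tuple[float, float] | None = None,
) -> PolarityGeometry:
    """Polarity index of a channel along the cell-to-bead axis.

    CL is the intensity-weighted center of mass of the channel's z-sum
    projection within the cell mask (whole image if no mask); CC is the
    geometric centroid of the binary mask (or an explicit center); CB is
    the vector CC->bead.  The index is |CL| cos(theta) / |CB|, i.e. the
    scalar projection of CL onto CB over |CB|, in [-1, 1] whenever
    |CL| <= |CB|.
    """
    px = stack.pixel_size_um
    if cell_center_um is not None:
        cc = np.asarray(cell_center_um, dtype=float)
    elif cell_mask is not None:
        cc = cell_centroid_um(cell_mask, px)
    else:
        raise MetricError("need a cell mask or an explicit cell center")
    bead = np.asarray(bead_center_um, dtype=float)
    cb = bead - cc
    cb_norm = float(np.linalg.norm(cb))
    if cb_norm == 0:
        raise MetricError("bead center coincides with cell center; CB undefined")
    cl = _intensity_com_um(stack.projection(channel_role), cell_mask, px) - cc
    projection = float(np.dot(cl, cb) / cb_norm)
    return PolarityGeometry(
        cc_um=tuple(cc),
        bead_center_um=tuple(bead),
        cb_um=tuple(cb),
        cb_norm_um=cb_norm,
        cl_um=tuple(cl),
        projection_um=projection,
        index=projection / cb_norm,
    )


# ---------------------------------------------------------------------------
# spreading-plane metrics


def central_enrichment(
    stack: ImageStack,
    channel_role: str,
    cell_mask: np.ndarray,
    central_mask: np.ndarray,
    slice_index: int = 0,
) -> float:
    """Density in the central ellipse over whole-footprint density, minus 1.

    Computed on the synaptic-plane slice (default slice 0).  0 means the
    channel is uniformly spread; 2 means all signal sits inside the
    one-third-area central ellipse; -1 means the center is empty.
    """
    a_central = int(central_mask.sum())
    a_total = int(cell_mask.sum())
    if a_central == 0:
        raise MetricError("empty central region")
    if a_total == 0:
        raise MetricError("empty cell mask")
    plane = stack.channel(channel_role)[slice_index]
    f_total = float(plane[cell_mask].sum(dtype=np.float64))
    if f_total <= 0:
        raise MetricError("zero channel intensity in the footprint")
    f_central = float(plane[central_mask].sum(dtype=np.float64))
    return (f_central / a_central) / (f_total / a_total) - 1.0


@dataclass(frozen=True)
class ZProfile:
    """Per-slice mean fluorescence intensity within the cell mask."""

    slice_index: np.ndarray
    z_um: np.ndarray
    mfi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"slice_index": self.slice_index, "z_um": self.z_um, "mfi": self.mfi}
        )


def z_profile(
    stack: ImageStack, channel_role: str, cell_mask: np.ndarray
) -> ZProfile:
    """MFI of a channel within the cell at each z-slice, synapse plane first."""
    if stack.n_slices < 2:
        raise MetricError("z-profile needs at least 2 slices")
    if not cell_mask.any():
        raise MetricError("empty cell mask")
    vol = stack.channel(channel_role)
    mfi = np.array([float(sl[cell_mask].mean(dtype=np.float64)) for sl in vol])
    idx = np.arange(stack.n_slices)
    return ZProfile(slice_index=idx, z_um=idx * stack.slice_step_um, mfi=mfi)


class BottomTopResult(NamedTuple):
    ratio: float
    qc: tuple[str, ...]


def bottom_top_ratio(profile: ZProfile) -> BottomTopResult:
    """Summed MFI of the synapse-proximal half over the distal half.

    The middle slice of an odd stack contributes half of its MFI to each
    side.  A zero upper half yields a +inf sentinel with a QC flag.
    """
    mfi = np.asarray(profile.mfi, dtype=float)
    if len(mfi) < 2:
        raise MetricError("profile must cover at least 2 slices")
    if not mfi.any():
        raise MetricError("all-zero profile")
    half, odd = divmod(len(mfi), 2)
    middle = mfi[half] / 2 if odd else 0.0
    bottom = mfi[:half].sum() + middle
    top = mfi[half + odd :].sum() + middle
    if top == 0:
        return BottomTopResult(math.inf, ("zero_upper_half",))
    return BottomTopResult(float(bottom / top), ())


# ---------------------------------------------------------------------------
# colocalization


def _channel_threshold(
    values: np.ndarray, method: str | float, mask: np.ndarray | None
) -> float:
    """Per-channel threshold after median background subtraction."""
    if isinstance(method, (int, float)) and not isinstance(method, bool):
        return float(method)
    region = values if mask is None else values[mask]
    if method == "zero":
        return 0.0
    if method == "otsu":
        background = float(np.median(region))
        shifted = region - background
        if shifted.max() <= 0:
            raise MetricError("channel has no signal above background")
        return background + float(threshold_otsu(shifted))
    raise MetricError(f"unknown threshold method {method!r}")


def manders_overlap(
    stack: ImageStack,
    role_a: str = "LAMP",
    role_b: str = "LC3",
    cell_mask: np.ndarray | None = None,
    threshold_method: str | float = "otsu",
) -> float:
    """Manders M1: fraction of channel-A intensity where B is above threshold.

    Computed on z-sum projections within the cell mask.  The default
    threshold is per-channel Otsu after median background subtraction;
    ``"zero"`` counts any positive B pixel, and a float is used verbatim.
    """
    proj_a = stack.projection(role_a)
    proj_b = stack.projection(role_b)
    mask = np.ones_like(proj_a, dtype=bool) if cell_mask is None else cell_mask
    total_a = float(proj_a[mask].sum())
    if total_a <= 0:
        raise MetricError("zero intensity in channel A")
    thr_b = _channel_threshold(proj_b, threshold_method, mask)
    overlap = mask & (proj_b > thr_b)
    return float(proj_a[overlap].sum() / total_a)


# ---------------------------------------------------------------------------
# composition


@dataclass
class References:
    """Population normalizers measured on the time-0 condition."""

    t0_bead_ova: float | None = None
    t0_gef_bead: float | None = None


@dataclass
class CellRecord:
    """All per-cell metrics for one cell/bead conjugate.

    A metric whose preconditions fail is NaN with an accompanying QC flag
    rather than aborting the whole cell.
    """

    cell_id: str
    condition: str = ""
    timepoint_min: float = 0.0
    percent_antigen_extracted: float = math.nan
    fraction_antigen_remaining: float = math.nan
    recruitment_fraction: float = math.nan
    bead_fold_change: float = math.nan
    polarity_index: float = math.nan
    central_enrichment: float = math.nan
    bottom_top_ratio: float = math.nan
    manders_m1: float = math.nan
    qc_flags: str = ""

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}


def quantify_cell(
    stack: ImageStack,
    regions: RegionSet,
    references: References | None = None,
    cell_id: str = "cell",
    condition: str = "",
    timepoint_min: float = 0.0,
    threshold_method: str | float = "otsu",
) -> CellRecord:
    """Compute every applicable metric for one cell; failures become NaN+flag."""
    references = references or References()
    rec = CellRecord(
        cell_id=cell_id, condition=condition, timepoint_min=timepoint_min
    )
    flags: list[str] = []
    if regions.synapse_clipped:
        flags.append("synapse_clipped")

    def attempt(name: str, fn):
        try:
            return fn()
        except (MetricError, KeyError, ValueError) as exc:
            flags.append(f"{name}:{type(exc).__name__}")
            return math.nan

    has_bead = regions.bead_center_um is not None

    if has_bead and references.t0_bead_ova:
        def _extract():
            res = antigen_remaining(
                stack, regions.synapse_mask, references.t0_bead_ova
            )
            flags.extend(res.qc)
            rec.fraction_antigen_remaining = res.fraction_remaining
            return res.percent_extracted

        rec.percent_antigen_extracted = attempt("antigen_extraction", _extract)

    if has_bead:
        rec.recruitment_fraction = attempt(
            "recruitment",
            lambda: recruitment_fraction(
                stack, "LAMP", regions.synapse_mask, regions.cell_mask
            ),
        )
        rec.polarity_index = attempt(
            "polarity",
            lambda: polarity_index(
                stack, "LAMP", regions.cell_mask, regions.bead_center_um
            ).index,
        )
        if references.t0_gef_bead:
            rec.bead_fold_change = attempt(
                "gef_fold_change",
                lambda: bead_fold_change(
                    stack, "GEFH1", regions.synapse_mask, references.t0_gef_bead
                ),
            )

    if regions.central_mask is not None:
        rec.central_enrichment = attempt(
            "central_enrichment",
            lambda: central_enrichment(
                stack, "LAMP", regions.cell_mask, regions.central_mask
            ),
        )

    def _btr():
        res = bottom_top_ratio(z_profile(stack, "LAMP", regions.cell_mask))
        flags.extend(res.qc)
        return res.ratio

    rec.bottom_top_ratio = attempt("bottom_top", _btr)
    rec.manders_m1 = attempt(
        "manders",
        lambda: manders_overlap(
            stack, "LAMP", "LC3", regions.cell_mask, threshold_method
        ),
    )
    rec.qc_flags = ";".join(flags)
    return rec


def records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    """Stack CellRecords into the per-cell results table."""
    return pd.DataFrame([r.to_dict() for r in records])
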