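"""Synthetic microscopy scenes with analytic ground truth.

Forward model for the two imaging assays the pipeline quantifies:

* **Bead conjugates** — a B cell (disk footprint spanning the stack) in
  contact with a 3 µm antigen-coated latex bead.  The bead carries an
  "OVA" signal rendered as a thin spherical shell whose amplitude scales
  with the fraction of antigen retained; lysosomes (LAMP) and
  autophagosomes (LC3) are isotropic Gaussian puncta whose angular
  placement around the cell center follows a von Mises law aimed at the
  bead (``polarization_kappa = 0`` recovers the uniform distribution);
  GEF-H1 has a diffuse cytoplasmic pool plus a synaptic pool at the
  bead-contact site; F-actin fills the cell.

* **Coverslip spreading** — an elliptical cell footprint with the synapse
  at slice 0.  Lysosome/LC3 puncta are placed laterally at random and
  share a deterministic exponential axial envelope
  ``exp(-axial_bias * z / height)``, so ``axial_bias = 0`` gives an exactly
  uniform axial distribution and any positive value a monotone decay.

Rendering is separable per punctum (1-D Gaussian factors over a cropped
window), and the recorded ground truth uses the same 1-D sums, so the
center of mass of the noiseless render matches the recorded value to
machine precision, including border-truncation effects.  Noise is Poisson
shot noise on the scaled intensity followed by additive Gaussian read
noise; optional Gaussian blur is applied before noise.  Identical config
and seed produce a bit-identical scene.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.ndimage import gaussian_filter

from .densitometry import DensitometryTable
from .stack import ImageStack, write_stack

#: Fixed channel layout of generated scenes.
CHANNEL_ROLES: dict[str, int] = {
    "OVA": 0,
    "LAMP": 1,
    "LC3": 2,
    "GEFH1": 3,
    "ACTIN": 4,
}


class SceneConfigError(ValueError):
    """Raised when a scene configuration is geometrically impossible."""


class SceneConfig(BaseModel):
    """Parameters of the synthetic forward model.

    All sizes are physical (micrometres); ``image_shape`` is ``(z, y, x)``
    voxel counts.  ``bead_offset_um`` is the lateral position of the bead
    center relative to the cell center, in ``(y, x)`` order; the default
    places the bead tangent to the cell edge along +x.
    """

    model_config = ConfigDict(frozen=True)

    image_shape: tuple[int, int, int] = (12, 168, 168)
    pixel_size_um: float = Field(0.1, gt=0)
    slice_step_um: float = Field(0.2, gt=0)
    cell_radius_um: float = Field(5.0, gt=0)
    bead_diameter_um: float = Field(3.0, gt=0)
    bead_offset_um: tuple[float, float] = (0.0, 5.0)
    n_lysosome_puncta: int = Field(200, ge=1)
    punctum_sigma_um: float = Field(0.15, gt=0)
    polarization_kappa: float = Field(0.0, ge=0)
    axial_bias: float = Field(0.0, ge=0)
    lc3_overlap_fraction: float = Field(0.0, ge=0, le=1)
    ova_retained_fraction: float = Field(1.0, ge=0, le=1)
    noise: tuple[float, float] = (50.0, 0.02)  # (poisson_scale, gaussian_sd)
    blur_sigma_um: float = Field(0.1, ge=0)
    seed: int = 0
    #: Optional explicit lateral LAMP punctum positions relative to the cell
    #: center (µm, (y, x) order); overrides random placement when given.
    lamp_positions_um: Optional[tuple[tuple[float, float], ...]] = None

    @model_validator(mode="after")
    def _check_geometry(self) -> "SceneConfig":
        if any(n < 2 for n in self.image_shape):
            raise ValueError("image_shape must be at least 2 voxels per axis")
        if self.noise[0] < 0 or self.noise[1] < 0:
            raise ValueError("noise parameters must be >= 0")
        ny, nx = self.image_shape[1], self.image_shape[2]
        half_y = ny * self.pixel_size_um / 2
        half_x = nx * self.pixel_size_um / 2
        if self.cell_radius_um >= min(half_y, half_x):
            raise ValueError("image too small to contain the cell footprint")
        return self

    def validate_bead(self) -> None:
        """Reject configs whose bead does not fit in the lateral field."""
        ny, nx = self.image_shape[1], self.image_shape[2]
        half = np.array([ny, nx]) * self.pixel_size_um / 2
        center = np.abs(np.asarray(self.bead_offset_um))
        r = self.bead_diameter_um / 2
        if np.any(center + r >= half):
            raise SceneConfigError(
                f"bead at offset {self.bead_offset_um} µm (radius {r} µm) "
                "falls outside the image"
            )


class GroundTruth(BaseModel):
    """True values a scene's metrics should recover.

    Lateral coordinates are in micrometres, ``(y, x)`` order, relative to
    the voxel grid origin (center of voxel ``(0, 0)``).
    """

    model_config = ConfigDict(frozen=True)

    config: SceneConfig
    scene_kind: str  # "bead" | "spreading"
    true_cell_center: tuple[float, float]
    true_bead_center: Optional[tuple[float, float]] = None
    true_com_offset: tuple[float, float]
    true_polarity_index: Optional[float] = None
    true_ova_retained_fraction: Optional[float] = None
    true_lc3_overlap_fraction: float = 0.0
    true_bottom_top_ratio: Optional[float] = None
    true_central_enrichment: Optional[float] = None
    footprint_semi_axes_um: tuple[float, float] = (0.0, 0.0)
    lamp_puncta_um: tuple[tuple[float, float], ...] = ()
    lc3_puncta_um: tuple[tuple[float, float], ...] = ()


# ---------------------------------------------------------------------------
# separable punctum rendering


def _axis_gaussian(n: int, center: float, sigma: float, radius: int):
    """1-D Gaussian sampled at voxel centers over a cropped window."""
    lo = max(0, int(np.floor(center - radius)))
    hi = min(n, int(np.ceil(center + radius)) + 1)
    xs = np.arange(lo, hi, dtype=float)
    g = np.exp(-0.5 * ((xs - center) / sigma) ** 2)
    return lo, hi, xs, g


def _render_puncta(
    shape_zyx: tuple[int, int, int],
    centers_px: np.ndarray,
    sigma_xy_px: float,
    sigma_z_px: float | None,
    z_envelope: np.ndarray | None,
    amplitude: float = 1.0,
):
    """Accumulate isotropic Gaussian puncta; return the volume and the exact
    per-punctum rendered mass and lateral center of mass (in pixels).

    Each punctum is separable: 1-D Gaussians along y/x and, along z, either
    a Gaussian at the punctum's z position or a shared envelope vector.
    """
    nz, ny, nx = shape_zyx
    vol = np.zeros(shape_zyx, dtype=float)
    r_lat = int(np.ceil(8 * sigma_xy_px)) + 1
    masses = np.empty(len(centers_px))
    coms = np.empty((len(centers_px), 2))
    for i, (cz, cy, cx) in enumerate(centers_px):
        if z_envelope is not None:
            gz = z_envelope
            z_lo, z_hi = 0, nz
        else:
            r_z = int(np.ceil(8 * sigma_z_px)) + 1
            z_lo, z_hi, _, gz = _axis_gaussian(nz, cz, sigma_z_px, r_z)
        y_lo, y_hi, ys, gy = _axis_gaussian(ny, cy, sigma_xy_px, r_lat)
        x_lo, x_hi, xs, gx = _axis_gaussian(nx, cx, sigma_xy_px, r_lat)
        vol[z_lo:z_hi, y_lo:y_hi, x_lo:x_hi] += amplitude * (
            gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        )
        sz, sy, sx = gz.sum(), gy.sum(), gx.sum()
        masses[i] = amplitude * sz * sy * sx
        coms[i] = ((ys * gy).sum() / sy, (xs * gx).sum() / sx)
    return vol, masses, coms


def _weighted_com_um(masses, coms_px, pixel_size_um) -> np.ndarray:
    w = masses / masses.sum()
    return (w[:, None] * coms_px).sum(axis=0) * pixel_size_um


# ---------------------------------------------------------------------------
# channel builders


def _grid_um(config: SceneConfig):
    nz, ny, nx = config.image_shape
    z = np.arange(nz) * config.slice_step_um
    y = np.arange(ny) * config.pixel_size_um
    x = np.arange(nx) * config.pixel_size_um
    return z, y, x


def _bead_shell(config: SceneConfig, bead_center_um: np.ndarray) -> np.ndarray:
    """Spherical shell ~2 lateral voxels thick; amplitude 1 before scaling."""
    z, y, x = _grid_um(config)
    cz = (config.image_shape[0] - 1) * config.slice_step_um / 2
    d = np.sqrt(
        (z[:, None, None] - cz) ** 2
        + (y[None, :, None] - bead_center_um[0]) ** 2
        + (x[None, None, :] - bead_center_um[1]) ** 2
    )
    r = config.bead_diameter_um / 2
    return (np.abs(d - r) <= config.pixel_size_um).astype(float)


def _apply_blur_and_noise(
    voxels: np.ndarray, config: SceneConfig, rng: np.random.Generator
) -> np.ndarray:
    if config.blur_sigma_um > 0:
        sig = (
            0.0,  # never mix channels
            config.blur_sigma_um / config.slice_step_um,
            config.blur_sigma_um / config.pixel_size_um,
            config.blur_sigma_um / config.pixel_size_um,
        )
        voxels = gaussian_filter(voxels, sigma=sig)
    poisson_scale, gaussian_sd = config.noise
    if poisson_scale > 0:
        voxels = rng.poisson(voxels * poisson_scale).astype(float) / poisson_scale
    if gaussian_sd > 0:
        voxels = voxels + rng.normal(0.0, gaussian_sd, size=voxels.shape)
    return np.clip(voxels, 0.0, None)


def _sample_lamp_lc3(
    config: SceneConfig,
    rng: np.random.Generator,
    cell_center_um: np.ndarray,
    lateral_sampler,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Draw LAMP positions and LC3 positions with the configured overlap.

    ``lateral_sampler(n)`` returns (n, 2) lateral offsets (µm) from the cell
    center.  Returns absolute (y, x) µm positions and the realized overlap
    fraction (the rounded co-placed count over the LC3 count).
    """
    n = config.n_lysosome_puncta
    if config.lamp_positions_um is not None:
        lamp = cell_center_um + np.asarray(config.lamp_positions_um, dtype=float)
    else:
        lamp = cell_center_um + lateral_sampler(n)
    n_lc3 = len(lamp)
    k = int(round(config.lc3_overlap_fraction * n_lc3))
    lc3_own = cell_center_um + lateral_sampler(n_lc3 - k)
    order = rng.permutation(n_lc3)  # avoid structural bias in which are shared
    lc3 = np.concatenate([lamp[order[:k]], lc3_own]) if k else lc3_own
    return lamp, lc3, (k / n_lc3 if n_lc3 else 0.0)


def _lateral_to_centers_px(
    lateral_um: np.ndarray, z_um: np.ndarray, config: SceneConfig
) -> np.ndarray:
    """(y,x) µm + per-punctum z µm -> (z, y, x) pixel coordinates."""
    out = np.empty((len(lateral_um), 3))
    out[:, 0] = z_um / config.slice_step_um
    out[:, 1] = lateral_um[:, 0] / config.pixel_size_um
    out[:, 2] = lateral_um[:, 1] / config.pixel_size_um
    return out


def _brute_bottom_top(volume: np.ndarray, footprint: np.ndarray) -> float:
    """Bottom/top ratio of per-slice means within a footprint mask; the
    middle slice of an odd stack contributes half to each side."""
    mfi = np.array([sl[footprint].mean() for sl in volume])
    n = len(mfi)
    half, odd = divmod(n, 2)
    bottom = mfi[:half].sum() + (mfi[half] / 2 if odd else 0.0)
    top = mfi[half + odd :].sum() + (mfi[half] / 2 if odd else 0.0)
    if top == 0:
        return float("inf")
    return float(bottom / top)


# ---------------------------------------------------------------------------
# public scene builders


def make_bead_scene(config: SceneConfig) -> tuple[ImageStack, GroundTruth]:
    """Render a B-cell/bead conjugate and its ground truth.

    The cell is a disk footprint of ``cell_radius_um`` spanning the stack;
    the bead center sits at ``bead_offset_um`` from the cell center.  LAMP
    puncta are drawn at angles ~ von Mises(direction-to-bead,
    ``polarization_kappa``) and area-uniform radii within 85 % of the cell
    radius; LC3 co-places a ``lc3_overlap_fraction`` subset with LAMP.
    """
    config.validate_bead()
    ss = np.random.SeedSequence(config.seed)
    rng_place, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]

    nz, ny, nx = config.image_shape
    cell_center = np.array(
        [(ny - 1) / 2 * config.pixel_size_um, (nx - 1) / 2 * config.pixel_size_um]
    )
    bead_center = cell_center + np.asarray(config.bead_offset_um, dtype=float)
    cb = bead_center - cell_center
    cb_norm = float(np.linalg.norm(cb))
    height_um = (nz - 1) * config.slice_step_um

    phi0 = np.arctan2(cb[0], cb[1]) if cb_norm > 0 else 0.0

    def lateral_sampler(n: int) -> np.ndarray:
        if n == 0:
            return np.zeros((0, 2))
        if config.polarization_kappa == 0:
            phi = rng_place.uniform(-np.pi, np.pi, size=n)
        else:
            phi = rng_place.vonmises(phi0, config.polarization_kappa, size=n)
        r = 0.85 * config.cell_radius_um * np.sqrt(rng_place.uniform(size=n))
        return np.stack([r * np.sin(phi), r * np.cos(phi)], axis=1)

    lamp_um, lc3_um, realized_overlap = _sample_lamp_lc3(
        config, rng_place, cell_center, lateral_sampler
    )
    lamp_z = rng_place.uniform(0, height_um, size=len(lamp_um))
    lc3_z = rng_place.uniform(0, height_um, size=len(lc3_um))

    sigma_xy = config.punctum_sigma_um / config.pixel_size_um
    sigma_z = config.punctum_sigma_um / config.slice_step_um
    lamp_vol, lamp_m, lamp_com = _render_puncta(
        config.image_shape,
        _lateral_to_centers_px(lamp_um, lamp_z, config),
        sigma_xy,
        sigma_z,
        None,
    )
    lc3_vol, _, _ = _render_puncta(
        config.image_shape,
        _lateral_to_centers_px(lc3_um, lc3_z, config),
        sigma_xy,
        sigma_z,
        None,
    )

    # cell body / actin
    z_grid, y_grid, x_grid = _grid_um(config)
    rr = np.sqrt(
        (y_grid[:, None] - cell_center[0]) ** 2
        + (x_grid[None, :] - cell_center[1]) ** 2
    )
    footprint = rr <= config.cell_radius_um
    actin_vol = np.broadcast_to(footprint, config.image_shape).astype(float).copy()

    ova_vol = config.ova_retained_fraction * _bead_shell(config, bead_center)

    # GEF-H1: diffuse cytoplasmic pool + synaptic pool at the contact site
    gef_vol = 0.05 * actin_vol
    if cb_norm > 0:
        contact = cell_center + cb / cb_norm * config.cell_radius_um
        contact_px = np.array(
            [
                (nz - 1) / 2,
                contact[0] / config.pixel_size_um,
                contact[1] / config.pixel_size_um,
            ]
        )
        blob, _, _ = _render_puncta(
            config.image_shape,
            contact_px[None, :],
            0.5 / config.pixel_size_um,
            0.5 / config.slice_step_um,
            None,
            amplitude=2.0,
        )
        gef_vol = gef_vol + blob

    voxels = np.zeros((5, nz, ny, nx), dtype=float)
    voxels[CHANNEL_ROLES["OVA"]] = ova_vol
    voxels[CHANNEL_ROLES["LAMP"]] = lamp_vol
    voxels[CHANNEL_ROLES["LC3"]] = lc3_vol
    voxels[CHANNEL_ROLES["GEFH1"]] = gef_vol
    voxels[CHANNEL_ROLES["ACTIN"]] = actin_vol
    voxels = _apply_blur_and_noise(voxels, config, rng_noise)

    com_um = _weighted_com_um(lamp_m, lamp_com, config.pixel_size_um)
    offset = com_um - cell_center
    polarity = float(np.dot(offset, cb) / cb_norm**2) if cb_norm > 0 else None

    truth = GroundTruth(
        config=config,
        scene_kind="bead",
        true_cell_center=tuple(cell_center),
        true_bead_center=tuple(bead_center),
        true_com_offset=tuple(offset),
        true_polarity_index=polarity,
        true_ova_retained_fraction=config.ova_retained_fraction,
        true_lc3_overlap_fraction=realized_overlap,
        footprint_semi_axes_um=(config.cell_radius_um, config.cell_radius_um),
        lamp_puncta_um=tuple(map(tuple, lamp_um)),
        lc3_puncta_um=tuple(map(tuple, lc3_um)),
    )
    stack = ImageStack(
        voxels=voxels.astype(np.float32),
        pixel_size_um=config.pixel_size_um,
        slice_step_um=config.slice_step_um,
        channel_roles=dict(CHANNEL_ROLES),
    )
    return stack, truth


def make_spreading_scene(config: SceneConfig) -> tuple[ImageStack, GroundTruth]:
    """Render a cell spreading on an antigen-coated coverslip.

    The synapse plane is slice 0.  The footprint is an ellipse with
    semi-axes ``(cell_radius_um, 0.75 * cell_radius_um)``; lysosome/LC3
    puncta are lateral Gaussians sharing the axial envelope
    ``exp(-axial_bias * z / height)``, so the recorded bottom/top ratio is
    exact and ``axial_bias = 0`` yields exactly 1.  Lateral placement is
    uniform in the footprint, so the expected central-ellipse enrichment
    is 0.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_place, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]

    nz, ny, nx = config.image_shape
    cell_center = np.array(
        [(ny - 1) / 2 * config.pixel_size_um, (nx - 1) / 2 * config.pixel_size_um]
    )
    semi_a, semi_b = config.cell_radius_um, 0.75 * config.cell_radius_um
    height_um = (nz - 1) * config.slice_step_um

    def lateral_sampler(n: int) -> np.ndarray:
        if n == 0:
            return np.zeros((0, 2))
        phi = rng_place.uniform(-np.pi, np.pi, size=n)
        r = np.sqrt(rng_place.uniform(size=n))
        return 0.85 * np.stack(
            [semi_b * r * np.sin(phi), semi_a * r * np.cos(phi)], axis=1
        )

    lamp_um, lc3_um, realized_overlap = _sample_lamp_lc3(
        config, rng_place, cell_center, lateral_sampler
    )

    z_idx = np.arange(nz, dtype=float)
    envelope = (
        np.exp(-config.axial_bias * z_idx * config.slice_step_um / height_um)
        if config.axial_bias > 0
        else np.ones(nz)
    )

    sigma_xy = config.punctum_sigma_um / config.pixel_size_um

    def render_lat(pts_um: np.ndarray):
        centers = np.zeros((len(pts_um), 3))
        centers[:, 1] = pts_um[:, 0] / config.pixel_size_um
        centers[:, 2] = pts_um[:, 1] / config.pixel_size_um
        return _render_puncta(
            config.image_shape, centers, sigma_xy, None, z_envelope=envelope
        )

    lamp_vol, lamp_m, lamp_com = render_lat(lamp_um)
    lc3_vol, _, _ = render_lat(lc3_um)

    _, y_grid, x_grid = _grid_um(config)
    footprint = (
        ((y_grid[:, None] - cell_center[0]) / semi_b) ** 2
        + ((x_grid[None, :] - cell_center[1]) / semi_a) ** 2
    ) <= 1.0
    actin_vol = np.broadcast_to(footprint, config.image_shape).astype(float).copy()
    gef_vol = 0.05 * actin_vol

    voxels = np.zeros((5, nz, ny, nx), dtype=float)
    voxels[CHANNEL_ROLES["LAMP"]] = lamp_vol
    voxels[CHANNEL_ROLES["LC3"]] = lc3_vol
    voxels[CHANNEL_ROLES["GEFH1"]] = gef_vol
    voxels[CHANNEL_ROLES["ACTIN"]] = actin_vol

    # record the axial truth from the noiseless (blurred) render
    noiseless_cfg = config.model_copy(update={"noise": (0.0, 0.0)})
    noiseless = _apply_blur_and_noise(
        voxels.copy(), noiseless_cfg, np.random.default_rng(0)
    )
    btr = _brute_bottom_top(noiseless[CHANNEL_ROLES["LAMP"]], footprint)

    voxels = _apply_blur_and_noise(voxels, config, rng_noise)

    com_um = _weighted_com_um(lamp_m, lamp_com, config.pixel_size_um)

    truth = GroundTruth(
        config=config,
        scene_kind="spreading",
        true_cell_center=tuple(cell_center),
        true_com_offset=tuple(com_um - cell_center),
        true_lc3_overlap_fraction=realized_overlap,
        true_bottom_top_ratio=btr,
        true_central_enrichment=0.0,
        footprint_semi_axes_um=(semi_a, semi_b),
        lamp_puncta_um=tuple(map(tuple, lamp_um)),
        lc3_puncta_um=tuple(map(tuple, lc3_um)),
    )
    stack = ImageStack(
        voxels=voxels.astype(np.float32),
        pixel_size_um=config.pixel_size_um,
        slice_step_um=config.slice_step_um,
        channel_roles=dict(CHANNEL_ROLES),
    )
    return stack, truth


def make_blot_table(
    n_lanes: int,
    effects: Sequence[float],
    seed: int = 0,
    loadings: Sequence[float] | None = None,
    noise_cv: float = 0.0,
) -> DensitometryTable:
    """Simulate a western-blot lane table with known fold changes.

    ``effects`` are true expression levels per lane (lane 0 is the
    control); ``loadings`` are per-lane loading multipliers (default 1).
    Densities are ``expression x loading x lognormal noise`` with
    coefficient of variation ``noise_cv``.  The true fold changes
    (``effects / effects[0]``) are recorded on the returned table.
    """
    if n_lanes < 2:
        raise ValueError("need at least 2 lanes")
    if len(effects) != n_lanes:
        raise ValueError("effects must have one entry per lane")
    loadings = np.ones(n_lanes) if loadings is None else np.asarray(loadings, float)
    if len(loadings) != n_lanes:
        raise ValueError("loadings must have one entry per lane")
    rng = np.random.default_rng(seed)
    effects = np.asarray(effects, dtype=float)

    def noisy(base: np.ndarray) -> np.ndarray:
        if noise_cv <= 0:
            return base
        sigma = np.sqrt(np.log1p(noise_cv**2))
        return base * rng.lognormal(-sigma**2 / 2, sigma, size=len(base))

    base_target, base_loading = 1000.0, 500.0
    lanes = pd.DataFrame(
        {
            "lane_id": [f"lane{i}" for i in range(n_lanes)],
            "condition": ["control"] + [f"cond{i}" for i in range(1, n_lanes)],
            "timepoint_min": 0,
            "target_density": noisy(base_target * effects * loadings),
            "loading_density": noisy(base_loading * loadings),
            "is_control": [i == 0 for i in range(n_lanes)],
        }
    )
    return DensitometryTable(
        lanes=lanes,
        true_fold_change=pd.Series(effects / effects[0], name="true_fold_change"),
    )


def write_scene(
    stack: ImageStack,
    truth: GroundTruth,
    directory: str | Path,
    overwrite: bool = False,
) -> dict[str, Path]:
    """Write a scene as OME-TIFF + ground-truth JSON + config YAML.

    The directory is created if missing; existing scene files are only
    replaced when ``overwrite`` is set.  Voxels round-trip bit-exactly
    through :func:`synquant.stack.read_stack`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "stack": directory / "scene.ome.tif",
        "ground_truth": directory / "ground_truth.json",
        "config": directory / "config.yaml",
    }
    clashes = [p for p in paths.values() if p.exists()]
    if clashes and not overwrite:
        raise FileExistsError(
            f"refusing to overwrite {clashes[0]} (pass overwrite=True)"
        )
    write_stack(stack, paths["stack"])
    paths["ground_truth"].write_text(truth.model_dump_json(indent=2))
    paths["config"].write_text(yaml.safe_dump(truth.config.model_dump()))
    return paths


def read_ground_truth(path: str | Path) -> GroundTruth:
    """Load a ground-truth JSON written by :func:`write_scene`."""
    return GroundTruth.model_validate(json.loads(Path(path).read_text()))
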