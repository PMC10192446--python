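"""Synthetic cell-seeded scaffolds and their fluorescence z-stacks.

This module generates ground-truth nucleus point patterns inside a virtual
collagen scaffold and renders sampled columns as calibrated z-stacks, emulating
DAPI-stained nuclei imaged with a low-NA widefield objective.  It provides the
ground truth against which the counting pipeline and the whole-scaffold
estimator are validated.

Geometry is in mm; image calibration (pixel size, PSF sigmas) in um.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidSpecError, OutOfBoundsError
from .sampling import ColumnSpec
from .segmentation import ImageStack, LabeledMask, relabel_consecutive
from skimage import measure

#: Seeding densities used throughout validation: cells per 500-ul scaffold.
SEEDING_DENSITIES = (10_000, 125_000, 250_000, 375_000)

DEFAULT_SCAFFOLD_VOLUME_UL = 500.0
#: Footprint of a 24-well plate well (15.6 mm diameter disc) approximated as
#: its bounding box; columns never approach the rim, so the corner volume
#: surplus only rescales the depth.
DEFAULT_XY_EXTENT_MM = (15.6, 15.6)


@dataclass(frozen=True)
class ScaffoldSpec:
    """The physical scaffold: volume, footprint and the seeded cell number."""

    volume_ul: float = DEFAULT_SCAFFOLD_VOLUME_UL
    xy_extent: tuple[float, float] = DEFAULT_XY_EXTENT_MM
    n_cells: int = 0
    pattern: str = "uniform"  # "uniform" | "clustered"
    cluster_mean_offspring: float = 5.0
    cluster_sd_mm: float = 0.05

    def __post_init__(self) -> None:
        if self.volume_ul <= 0:
            raise InvalidSpecError("scaffold volume must be positive")
        if self.xy_extent[0] <= 0 or self.xy_extent[1] <= 0:
            raise InvalidSpecError("xy extent must be positive")
        if self.n_cells < 0:
            raise InvalidSpecError("n_cells must be >= 0")
        if self.pattern not in ("uniform", "clustered"):
            raise InvalidSpecError("pattern must be 'uniform' or 'clustered'")

    @property
    def depth(self) -> float:
        """Scaffold depth in mm: volume / footprint area (1 ul = 1 mm^3)."""
        return self.volume_ul / (self.xy_extent[0] * self.xy_extent[1])

    @property
    def extent(self) -> tuple[float, float, float]:
        return (self.xy_extent[0], self.xy_extent[1], self.depth)


@dataclass(frozen=True)
class PointPattern:
    """Ground-truth nucleus centres, (n, 3) array of (x, y, z) in mm."""

    coordinates: np.ndarray
    extent: tuple[float, float, float]
    nucleus_radius_um: float = 5.0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "coordinates", coords)
        if coords.size:
            lo = coords.min(axis=0)
            hi = coords.max(axis=0)
            if (lo < -1e-12).any() or (hi > np.asarray(self.extent) + 1e-12).any():
                raise InvalidSpecError("coordinates must lie inside the extent")

    def __len__(self) -> int:
        return self.coordinates.shape[0]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.coordinates, columns=["x_mm", "y_mm", "z_mm"]).to_csv(
            path, index=False
        )

    @staticmethod
    def from_csv(path, extent, nucleus_radius_um: float = 5.0) -> "PointPattern":
        df = pd.read_csv(path)
        return PointPattern(
            df[["x_mm", "y_mm", "z_mm"]].to_numpy(), tuple(extent), nucleus_radius_um
        )


@dataclass(frozen=True)
class RenderConfig:
    """How nuclei are turned into pixels.

    Each nucleus contributes an anisotropic Gaussian blob: lateral sigma
    ``psf_sigma_xy`` (nucleus size convolved with the lateral PSF) and axial
    sigma ``psf_sigma_z`` (nucleus size plus widefield defocus -- a 10x/0.30
    objective barely sections optically, so nuclei stay visible one section
    away).  Background and per-voxel noise are added, then values are clipped
    to the bit depth.
    """

    pixel_size: float = 1.3  # um
    z_spacing: float | None = None  # um; None -> taken from the column geometry
    background_level: float = 100.0
    blob_amplitude: float = 1200.0
    psf_sigma_xy: float = 3.0  # um
    psf_sigma_z: float = 12.0  # um
    noise_model: str = "gaussian"  # "gaussian" | "poisson"
    noise_sd: float = 80.0  # gaussian model only
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.psf_sigma_xy <= 0 or self.psf_sigma_z <= 0:
            raise InvalidSpecError("pixel size and PSF sigmas must be positive")
        if self.z_spacing is not None and self.z_spacing <= 0:
            raise InvalidSpecError("z_spacing must be positive")
        if self.blob_amplitude <= 0:
            raise InvalidSpecError("blob_amplitude must be positive")
        if self.noise_model not in ("gaussian", "poisson"):
            raise InvalidSpecError("noise_model must be 'gaussian' or 'poisson'")
        if self.bit_depth not in (8, 16):
            raise InvalidSpecError("bit_depth must be 8 or 16")


def generate_points(spec: ScaffoldSpec, seed: int) -> PointPattern:
    """Draw exactly ``spec.n_cells`` nucleus centres inside the scaffold.

    "uniform": i.i.d. uniform over the scaffold box, emulating a homogeneously
    mixed cell suspension.  "clustered": a Thomas process (uniform parents,
    isotropic Gaussian offspring) conditioned on the total count -- offspring
    are assigned to parents multinomially, so the requested total is exact and
    no rejection loop over whole patterns is needed.
    """
    rng = np.random.default_rng(seed)
    ext = np.asarray(spec.extent)
    n = spec.n_cells
    if n == 0:
        return PointPattern(np.empty((0, 3)), spec.extent)
    if spec.pattern == "uniform":
        coords = rng.uniform(0.0, ext, size=(n, 3))
    else:
        n_parents = max(1, int(round(n / spec.cluster_mean_offspring)))
        parents = rng.uniform(0.0, ext, size=(n_parents, 3))
        assignment = rng.integers(0, n_parents, size=n)
        centres = parents[assignment]
        coords = centres + rng.normal(0.0, spec.cluster_sd_mm, size=(n, 3))
        # re-draw offspring that fell outside the scaffold from their parent
        for _ in range(1000):
            outside = ((coords < 0) | (coords > ext)).any(axis=1)
            if not outside.any():
                break
            k = int(outside.sum())
            coords[outside] = centres[outside] + rng.normal(
                0.0, spec.cluster_sd_mm, size=(k, 3)
            )
        else:  # pragma: no cover - sd << extent makes this unreachable
            coords = np.clip(coords, 0.0, ext)
    return PointPattern(coords, spec.extent)


def _pixel_grid(column: ColumnSpec, pixel_size_um: float) -> tuple[int, int]:
    nx = max(1, int(round(column.field_width * 1000.0 / pixel_size_um)))
    ny = max(1, int(round(column.field_height * 1000.0 / pixel_size_um)))
    return ny, nx


def _check_column_inside(points: PointPattern, column: ColumnSpec) -> None:
    ex, ey, ez = points.extent
    x0, y0 = column.origin
    if x0 < -1e-9 or y0 < -1e-9 or x0 + column.field_width > ex + 1e-9 or (
        y0 + column.field_height > ey + 1e-9
    ):
        raise OutOfBoundsError("column XY field lies outside the scaffold extent")


def render_stack(
    points: PointPattern,
    column: ColumnSpec,
    cfg: RenderConfig = RenderConfig(),
    seed: int = 0,
) -> ImageStack:
    """Render one column of ``column.n_sections`` optical sections.

    Section *i* is focused at the centre of its slab,
    ``z_start + (i + 1/2) * z_spacing``, so the stack's planes tile the column
    depth.  Every nucleus within 3 sigma of the column contributes a blob;
    noise is added per the config and values are clipped to the bit depth.
    """
    _check_column_inside(points, column)
    rng = np.random.default_rng(seed)
    ny, nx = _pixel_grid(column, cfg.pixel_size)
    nz = column.n_sections
    signal = np.zeros((nz, ny, nx), dtype=np.float32)

    sxy_mm = cfg.psf_sigma_xy / 1000.0
    sz_mm = cfg.psf_sigma_z / 1000.0
    x0, y0 = column.origin
    plane_z = column.z_start + (np.arange(nz) + 0.5) * column.z_spacing

    coords = points.coordinates
    if coords.size:
        near = (
            (coords[:, 0] >= x0 - 3 * sxy_mm)
            & (coords[:, 0] < x0 + column.field_width + 3 * sxy_mm)
            & (coords[:, 1] >= y0 - 3 * sxy_mm)
            & (coords[:, 1] < y0 + column.field_height + 3 * sxy_mm)
            & (coords[:, 2] >= column.z_start - 3 * sz_mm)
            & (coords[:, 2] < column.z_start + column.depth + 3 * sz_mm)
        )
        px_mm = cfg.pixel_size / 1000.0
        s_px = cfg.psf_sigma_xy / cfg.pixel_size
        half = int(np.ceil(4 * s_px))
        offsets = np.arange(-half, half + 1)
        for cx, cy, cz in coords[near]:
            # pixel-centre coordinates of the nucleus within the field
            jc = (cx - x0) / px_mm - 0.5
            ic = (cy - y0) / px_mm - 0.5
            j0, i0 = int(round(jc)), int(round(ic))
            jj = j0 + offsets
            ii = i0 + offsets
            jsel = (jj >= 0) & (jj < nx)
            isel = (ii >= 0) & (ii < ny)
            if not jsel.any() or not isel.any():
                continue
            gx = np.exp(-((jj[jsel] - jc) ** 2) / (2 * s_px**2))
            gy = np.exp(-((ii[isel] - ic) ** 2) / (2 * s_px**2))
            blob = cfg.blob_amplitude * np.outer(gy, gx)
            zf = np.exp(-((plane_z - cz) ** 2) / (2 * sz_mm**2))
            for k in np.flatnonzero(zf > 1e-4):
                signal[np.ix_([k], ii[isel], jj[jsel])] += zf[k] * blob[None]

    if cfg.noise_model == "gaussian":
        img = signal
        img += np.float32(cfg.background_level)
        if cfg.noise_sd > 0:
            noise = rng.standard_normal(img.shape, dtype=np.float32)
            noise *= np.float32(cfg.noise_sd)
            img += noise
    else:
        img = rng.poisson(signal + cfg.background_level).astype(np.float32)

    vmax = 2**cfg.bit_depth - 1
    np.rint(img, out=img)
    np.clip(img, 0, vmax, out=img)
    dtype = np.uint8 if cfg.bit_depth == 8 else np.uint16
    return ImageStack(
        voxels=img.astype(dtype),
        pixel_size=cfg.pixel_size,
        z_spacing=cfg.z_spacing
        if cfg.z_spacing is not None
        else column.z_spacing * 1000.0,
        bit_depth=cfg.bit_depth,
    )


def ground_truth_projection_mask(
    points: PointPattern,
    column: ColumnSpec,
    cfg: RenderConfig = RenderConfig(),
) -> np.ndarray:
    """Reference foreground mask for a rendered column's projection.

    Defined as the half-maximum level set of the *noiseless* rendered
    projection (pixels whose signal reaches at least half the nominal blob
    amplitude).  Used to derive training scribbles and to score segmentation
    quality against a rendering.
    """
    from dataclasses import replace

    noiseless = replace(
        cfg, background_level=0.0, noise_model="gaussian", noise_sd=0.0
    )
    stack = render_stack(points, column, noiseless, seed=0)
    proj = stack.voxels.max(axis=0).astype(np.float64)
    return proj >= cfg.blob_amplitude / 2.0


def _draw_discs(
    shape: tuple[int, int],
    centres_px: np.ndarray,
    radius_px: float,
) -> np.ndarray:
    """Boolean union of discs; centres may lie outside the grid (clipped)."""
    mask = np.zeros(shape, dtype=bool)
    r = int(np.ceil(radius_px))
    for ic, jc in centres_px:
        i0, i1 = int(np.floor(ic - r)), int(np.ceil(ic + r)) + 1
        j0, j1 = int(np.floor(jc - r)), int(np.ceil(jc + r)) + 1
        i0c, j0c = max(i0, 0), max(j0, 0)
        i1c, j1c = min(i1, shape[0]), min(j1, shape[1])
        if i0c >= i1c or j0c >= j1c:
            continue
        ii = np.arange(i0c, i1c)[:, None]
        jj = np.arange(j0c, j1c)[None, :]
        mask[i0c:i1c, j0c:j1c] |= (ii - ic) ** 2 + (jj - jc) ** 2 <= radius_px**2
    return mask


def _centres_px(
    coords: np.ndarray, column: ColumnSpec, pixel_size_um: float
) -> np.ndarray:
    px_mm = pixel_size_um / 1000.0
    x0, y0 = column.origin
    ic = (coords[:, 1] - y0) / px_mm - 0.5
    jc = (coords[:, 0] - x0) / px_mm - 0.5
    return np.column_stack([ic, jc])


def rasterize_sections(
    points: PointPattern,
    column: ColumnSpec,
    pixel_size_um: float = 1.3,
) -> list[LabeledMask]:
    """Idealized noise-free per-section masks for a column.

    Each nucleus is drawn as a disc of its nominal radius in the single
    section whose z-slab contains its centre; touching discs merge into one
    labelled object, exactly as a perfect segmenter would see them.  Pass
    ``column.with_lookup_section()`` to include the disector's lookup plane.
    """
    _check_column_inside(points, column)
    ny, nx = _pixel_grid(column, pixel_size_um)
    r_px = points.nucleus_radius_um / pixel_size_um
    r_mm = points.nucleus_radius_um / 1000.0
    coords = points.coordinates
    x0, y0 = column.origin
    masks: list[LabeledMask] = []
    if coords.size:
        near_xy = (
            (coords[:, 0] >= x0 - r_mm)
            & (coords[:, 0] < x0 + column.field_width + r_mm)
            & (coords[:, 1] >= y0 - r_mm)
            & (coords[:, 1] < y0 + column.field_height + r_mm)
        )
    else:
        near_xy = np.zeros(0, dtype=bool)
    for k in range(column.n_sections):
        z_lo = column.z_start + k * column.z_spacing
        z_hi = z_lo + column.z_spacing
        if coords.size:
            sel = near_xy & (coords[:, 2] >= z_lo) & (coords[:, 2] < z_hi)
            centres = _centres_px(coords[sel], column, pixel_size_um)
        else:
            centres = np.empty((0, 2))
        mask = _draw_discs((ny, nx), centres, r_px)
        labels = measure.label(mask, connectivity=2)
        labels, n = relabel_consecutive(labels)
        masks.append(LabeledMask(labels=labels, n_objects=n, provenance="section"))
    return masks


def rasterize_projection(
    points: PointPattern,
    column: ColumnSpec,
    pixel_size_um: float = 1.3,
) -> LabeledMask:
    """Idealized projection mask: discs of every nucleus in the column slab."""
    _check_column_inside(points, column)
    ny, nx = _pixel_grid(column, pixel_size_um)
    r_px = points.nucleus_radius_um / pixel_size_um
    r_mm = points.nucleus_radius_um / 1000.0
    coords = points.coordinates
    x0, y0 = column.origin
    if coords.size:
        sel = (
            (coords[:, 0] >= x0 - r_mm)
            & (coords[:, 0] < x0 + column.field_width + r_mm)
            & (coords[:, 1] >= y0 - r_mm)
            & (coords[:, 1] < y0 + column.field_height + r_mm)
            & (coords[:, 2] >= column.z_start)
            & (coords[:, 2] < column.z_start + column.depth)
        )
        centres = _centres_px(coords[sel], column, pixel_size_um)
    else:
        centres = np.empty((0, 2))
    mask = _draw_discs((ny, nx), centres, r_px)
    labels = measure.label(mask, connectivity=2)
    labels, n = relabel_consecutive(labels)
    return LabeledMask(labels=labels, n_objects=n, provenance="projection")
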