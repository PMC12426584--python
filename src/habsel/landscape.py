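"""Synthetic landscape covariates for habitat-selection analysis.

A landscape is a stack of co-registered 30-m rasters: vegetation masks
(forest, shrub), human land-use masks (development, agriculture, forestry
activity), linear features (riparian network, major roads), a smooth
elevation field, and every layer derived from them — focal percent cover
at multiple window radii, forest edge density, Euclidean distance
transforms, and terrain metrics (slope, ruggedness, topographic position
index).  All geometry is planar metres with the origin at the lower-left
corner; cell centres sit at ``(x0 + (j + 0.5) * res, y0 + (i + 0.5) * res)``
with row ``i`` increasing northward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "RasterGrid",
    "CovariateStack",
    "LandscapeConfig",
    "generate_landscape",
    "edge_density",
    "focal_percent_cover",
    "distance_to",
    "terrain_metrics",
]


@dataclass(frozen=True)
class RasterGrid:
    """A single-band planar raster.

    Parameters
    ----------
    values
        2-D float array, row 0 = southernmost row.
    resolution
        Cell size in metres (square cells).
    origin
        ``(x0, y0)`` of the lower-left cell *corner* in metres.
    name
        Covariate label.
    """

    values: np.ndarray
    resolution: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    name: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"raster {self.name!r} contains non-finite values")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster in metres."""
        ny, nx = self.values.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + nx * self.resolution, y0 + ny * self.resolution)

    def cell_at(self, x: float, y: float) -> tuple[int, int]:
        """Row/col indices of the cell containing planar point (x, y)."""
        x0, y0 = self.origin
        j = int(np.floor((x - x0) / self.resolution))
        i = int(np.floor((y - y0) / self.resolution))
        ny, nx = self.values.shape
        if not (0 <= i < ny and 0 <= j < nx):
            raise ValueError(f"point ({x}, {y}) outside raster extent")
        return i, j

    def value_at(self, x, y):
        """Vectorised cell-value lookup at planar coordinates."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        j = np.floor((x - x0) / self.resolution).astype(int)
        i = np.floor((y - y0) / self.resolution).astype(int)
        ny, nx = self.values.shape
        if np.any((i < 0) | (i >= ny) | (j < 0) | (j >= nx)):
            raise ValueError("point(s) outside raster extent")
        return self.values[i, j]

    def like(self, values: np.ndarray, name: str) -> "RasterGrid":
        return replace(self, values=np.asarray(values, dtype=float), name=name)


@dataclass
class CovariateStack:
    """Named, co-registered covariate rasters plus multi-scale variants."""

    layers: dict[str, RasterGrid] = field(default_factory=dict)
    scale_variants: dict[tuple[str, int], RasterGrid] = field(default_factory=dict)
    binary_masks: dict[str, RasterGrid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._check_aligned()

    def _check_aligned(self) -> None:
        grids = [*self.layers.values(), *self.scale_variants.values(),
                 *self.binary_masks.values()]
        if not grids:
            return
        ref = grids[0]
        for g in grids[1:]:
            if g.shape != ref.shape or g.resolution != ref.resolution \
                    or g.origin != ref.origin:
                raise ValueError(f"layer {g.name!r} not aligned with stack")

    @property
    def reference(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return self.reference.extent

    def layer(self, name: str, scale: int | None = None) -> RasterGrid:
        """Fetch a layer, optionally a percent-cover variant at `scale` m."""
        if scale is not None:
            key = (name, int(scale))
            if key not in self.scale_variants:
                raise KeyError(f"no scale variant {name!r} @ {scale} m")
            return self.scale_variants[key]
        if name not in self.layers:
            raise KeyError(f"no layer named {name!r}")
        return self.layers[name]

    def add(self, grid: RasterGrid, scale: int | None = None) -> None:
        if scale is None:
            self.layers[grid.name] = grid
        else:
            self.scale_variants[(grid.name, int(scale))] = grid
        self._check_aligned()


# ---------------------------------------------------------------------------
# focal / window helpers
# ---------------------------------------------------------------------------

def _circular_footprint(radius_m: float, resolution: float) -> np.ndarray:
    """Boolean window: cell centres within `radius_m` of the centre cell.

    Ties at exactly the radius are included.
    """
    r_cells = int(np.floor(radius_m / resolution + 1e-9))
    ii, jj = np.mgrid[-r_cells:r_cells + 1, -r_cells:r_cells + 1]
    dist = np.hypot(ii, jj) * resolution
    return dist <= radius_m + 1e-9


def _require_binary(mask: RasterGrid) -> np.ndarray:
    v = mask.values
    if not np.all((v == 0) | (v == 1)):
        raise ValueError(f"mask {mask.name!r} is not binary")
    return v


def focal_percent_cover(mask: RasterGrid, radius: float) -> RasterGrid:
    """Percent of positive cells within a circular window of each cell.

    Windows are clipped at the grid boundary (the denominator counts only
    in-grid cells), so values stay in [0, 100] everywhere.
    """
    v = _require_binary(mask)
    if radius < mask.resolution:
        raise ValueError("window radius must be at least one cell")
    foot = _circular_footprint(radius, mask.resolution).astype(float)
    hits = ndimage.convolve(v, foot, mode="constant", cval=0.0)
    denom = ndimage.convolve(np.ones_like(v), foot, mode="constant", cval=0.0)
    pct = 100.0 * hits / denom
    return mask.like(np.clip(pct, 0.0, 100.0), f"{mask.name}_cover")


def edge_density(forest_mask: RasterGrid, radius: float) -> RasterGrid:
    """Forest/non-forest boundary length per unit window area (m / m²).

    Each 4-neighbour adjacency between a forest and a non-forest cell
    contributes one cell width (e.g. 30 m) of boundary; that length is split
    half-and-half between the two adjacent cells, and per-cell totals are
    summed over the circular window, then divided by the (clipped) window
    area.
    """
    v = _require_binary(forest_mask)
    if radius < forest_mask.resolution:
        raise ValueError("window radius must be at least one cell")
    res = forest_mask.resolution
    diff_v = np.abs(np.diff(v, axis=0))   # vertical neighbours
    diff_h = np.abs(np.diff(v, axis=1))   # horizontal neighbours
    half = 0.5 * res
    per_cell = np.zeros_like(v)
    per_cell[:-1, :] += diff_v * half
    per_cell[1:, :] += diff_v * half
    per_cell[:, :-1] += diff_h * half
    per_cell[:, 1:] += diff_h * half
    foot = _circular_footprint(radius, res).astype(float)
    length = ndimage.convolve(per_cell, foot, mode="constant", cval=0.0)
    ncells = ndimage.convolve(np.ones_like(v), foot, mode="constant", cval=0.0)
    area = ncells * res * res
    return forest_mask.like(length / area, f"{forest_mask.name}_edge_density")


def distance_to(mask: RasterGrid) -> RasterGrid:
    """Euclidean distance (m) from every cell centre to the nearest positive
    cell centre; zero on positive cells.

    An empty mask yields the grid-diagonal sentinel everywhere (with a
    warning) so that downstream designs remain well defined when a synthetic
    configuration omits a land-use class entirely.
    """
    v = _require_binary(mask)
    name = f"dist_{mask.name}"
    if not v.any():
        ny, nx = v.shape
        diag = float(np.hypot(ny, nx) * mask.resolution)
        warnings.warn(
            f"mask {mask.name!r} is empty; distance set to grid diagonal "
            f"({diag:.0f} m)", stacklevel=2)
        return mask.like(np.full_like(v, diag), name)
    d = ndimage.distance_transform_edt(v == 0, sampling=mask.resolution)
    return mask.like(d, name)


def terrain_metrics(elevation: RasterGrid) -> tuple[RasterGrid, RasterGrid, RasterGrid]:
    """Slope (degrees), ruggedness (3×3 SD), and TPI from an elevation raster.

    Slope uses central finite differences on a reflect-padded grid;
    ruggedness is the standard deviation of the 3×3 neighbourhood; TPI is
    the cell elevation minus the mean of its 8 neighbours.
    """
    z = elevation.values
    res = elevation.resolution
    zp = np.pad(z, 1, mode="reflect")
    dz_dx = (zp[1:-1, 2:] - zp[1:-1, :-2]) / (2.0 * res)
    dz_dy = (zp[2:, 1:-1] - zp[:-2, 1:-1]) / (2.0 * res)
    slope = np.degrees(np.arctan(np.hypot(dz_dx, dz_dy)))

    kernel = np.ones((3, 3))
    s1 = ndimage.convolve(z, kernel, mode="reflect")
    s2 = ndimage.convolve(z * z, kernel, mode="reflect")
    var = np.maximum(s2 / 9.0 - (s1 / 9.0) ** 2, 0.0)
    rugged = np.sqrt(var)

    neigh_mean = (s1 - z) / 8.0
    tpi = z - neigh_mean

    return (elevation.like(slope, "slope"),
            elevation.like(rugged, "ruggedness"),
            elevation.like(tpi, "tpi"))


# ---------------------------------------------------------------------------
# synthetic landscape generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LandscapeConfig:
    """Configuration for the synthetic covariate generator.

    ``smoothness`` is the Gaussian correlation length in cells of the random
    fields used for land-cover masks; cover fractions are target mask
    occupancies in (0, 1) (0 disables the class).
    """

    shape: tuple[int, int] = (128, 128)
    resolution: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    smoothness: float = 5.0
    forest_fraction: float = 0.5
    shrub_fraction: float = 0.15
    development_fraction: float = 0.05
    agriculture_fraction: float = 0.08
    forestry_fraction: float = 0.05
    riparian_fraction: float = 0.04
    n_roads: int = 2
    elevation_relief: float = 600.0
    cover_radii: tuple[int, ...] = (100, 150, 500, 1000)

    def validate(self) -> None:
        ny, nx = self.shape
        if ny < 32 or nx < 32:
            raise ValueError("grid must be at least 32×32")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        for nm in ("forest_fraction", "shrub_fraction", "development_fraction",
                   "agriculture_fraction", "forestry_fraction",
                   "riparian_fraction"):
            f = getattr(self, nm)
            if not (0 <= f < 1):
                raise ValueError(f"{nm} must lie in [0, 1)")


def _smooth_field(rng: np.random.Generator, shape, smoothness: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma=smoothness, mode="reflect")
    return (f - f.mean()) / (f.std() + 1e-12)


def _threshold_to_fraction(fld: np.ndarray, fraction: float) -> np.ndarray:
    """Binary mask whose occupancy matches `fraction` of the cells."""
    if fraction <= 0:
        return np.zeros_like(fld)
    thr = np.quantile(fld, 1.0 - fraction)
    return (fld > thr).astype(float)


def _road_mask(rng: np.random.Generator, shape, n_roads: int) -> np.ndarray:
    """Rasterised sinusoidal polylines crossing the full grid."""
    ny, nx = shape
    mask = np.zeros(shape)
    for _ in range(n_roads):
        horizontal = rng.random() < 0.5
        n = nx if horizontal else ny
        base = rng.uniform(0.2, 0.8) * (ny if horizontal else nx)
        amp = rng.uniform(0.02, 0.12) * (ny if horizontal else nx)
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(n)
        cross = base + amp * np.sin(2 * np.pi * t / n * rng.integers(1, 4) + phase)
        cross = np.clip(np.round(cross).astype(int), 0, (ny if horizontal else nx) - 1)
        if horizontal:
            mask[cross, t] = 1.0
        else:
            mask[t, cross] = 1.0
    return mask


def generate_landscape(config: LandscapeConfig, seed: int) -> CovariateStack:
    """Generate a self-consistent synthetic covariate stack.

    Land-cover masks are thresholded smooth Gaussian random fields
    (threshold set at the empirical quantile matching the requested cover
    fraction), elevation is an independent smooth field scaled to the
    requested relief, roads are rasterised polylines, and the riparian
    network follows the low-elevation band of a smoothed field.  All derived
    layers (distances, focal covers, edge density, terrain metrics) are
    computed and attached.  Identical seed and config give identical stacks.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    shape = config.shape
    mk = lambda v, name: RasterGrid(v, config.resolution, config.origin, name)

    elev_f = _smooth_field(rng, shape, config.smoothness * 2.0)
    elevation = mk(elev_f * config.elevation_relief / 4.0
                   + config.elevation_relief / 2.0, "elevation")

    masks: dict[str, np.ndarray] = {}
    for name, frac in [("forest", config.forest_fraction),
                       ("shrub", config.shrub_fraction),
                       ("development", config.development_fraction),
                       ("agriculture", config.agriculture_fraction),
                       ("forestry", config.forestry_fraction)]:
        masks[name] = _threshold_to_fraction(
            _smooth_field(rng, shape, config.smoothness), frac)
    # riparian: low-elevation band of its own smooth field → branching network
    rip_field = _smooth_field(rng, shape, config.smoothness) + 0.5 * elev_f
    masks["riparian"] = _threshold_to_fraction(-np.abs(rip_field),
                                               config.riparian_fraction)
    masks["road"] = _road_mask(rng, shape, config.n_roads)

    stack = CovariateStack(layers={"elevation": elevation})
    for name, v in masks.items():
        stack.add(mk(v, name))
        stack.binary_masks[name] = stack.layers[name]

    slope, rugged, tpi = terrain_metrics(elevation)
    for g in (slope, rugged, tpi):
        stack.add(g)

    for name in ("development", "agriculture", "riparian", "road"):
        stack.add(distance_to(stack.layers[name]))

    for name in ("forest", "shrub", "development", "agriculture"):
        for radius in config.cover_radii:
            if radius >= config.resolution:
                stack.add(focal_percent_cover(stack.layers[name], radius),
                          scale=radius)

    stack.add(edge_density(stack.layers["forest"], 150.0))
    return stack


def standardize_stack(stack: CovariateStack,
                      skip: tuple[str, ...] = ()) -> CovariateStack:
    """Z-score every continuous layer and scale variant over study pixels.

    Binary masks are left untouched (they remain available through
    ``binary_masks``); layers listed in ``skip`` and constant layers are
    passed through unchanged.  Selection coefficients on a standardized
    stack are per-SD effect sizes, which makes generative truth values and
    fitted estimates directly comparable across covariates.
    """
    mask_names = set(stack.binary_masks)

    def z(grid: RasterGrid) -> RasterGrid:
        if grid.name in skip or grid.name in mask_names:
            return grid
        sd = grid.values.std()
        if sd == 0:
            return grid
        return grid.like((grid.values - grid.values.mean()) / sd, grid.name)

    out = CovariateStack(
        layers={k: z(g) for k, g in stack.layers.items()},
        scale_variants={k: z(g) for k, g in stack.scale_variants.items()},
        binary_masks=dict(stack.binary_masks))
    return out
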