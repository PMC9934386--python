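"""Seasonal kernel utilization distributions on the projected plane.

The utilization distribution (UD) is an isotropic Gaussian kernel density
over daily positions projected with the equal-area LAEA projection, so
that plane densities are directly interpretable as per-km^2 intensities.
The smoothing factor (default 100 km) is the kernel standard deviation, the
usual home-range convention for continental-scale seabird kernels.  Birds
should be restricted to their first year of data upstream so each
individual carries the same weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class UDGrid:
    """Regular density grid in the LAEA plane.

    ``density`` integrates to 1 over the grid (sum * cell area); ``x`` and
    ``y`` are cell-centre coordinates in km.
    """

    x: np.ndarray            # (nx,) cell-centre x in km
    y: np.ndarray            # (ny,) cell-centre y in km
    density: np.ndarray      # (ny, nx), >= 0
    cell_km: float
    smoothing_km: float

    @property
    def cell_area_km2(self) -> float:
        return self.cell_km**2

    def total_mass(self) -> float:
        return float(self.density.sum() * self.cell_area_km2)


def utilization_distribution(
    xy_km: np.ndarray,
    smoothing_km: float = 100.0,
    cell_km: float = 25.0,
    pad_bandwidths: float = 3.5,
) -> UDGrid:
    """Gaussian kernel UD of points in the projected plane.

    The evaluation grid pads the data extent by ``pad_bandwidths`` kernel
    standard deviations (>= 3 keeps >99.7% of each kernel's mass on-grid)
    and the density is renormalized to integrate to exactly 1.
    """
    if smoothing_km <= 0 or cell_km <= 0:
        raise ValueError("bandwidth and cell size must be positive")
    pts = np.atleast_2d(np.asarray(xy_km, float))
    if pts.size == 0:
        raise ValueError("utilization_distribution of no points")
    pad = pad_bandwidths * smoothing_km
    x = np.arange(pts[:, 0].min() - pad, pts[:, 0].max() + pad + cell_km, cell_km)
    y = np.arange(pts[:, 1].min() - pad, pts[:, 1].max() + pad + cell_km, cell_km)
    density = np.zeros((len(y), len(x)))
    inv2s2 = 1.0 / (2.0 * smoothing_km**2)
    # accumulate kernels in chunks of points to bound memory
    for i in range(0, len(pts), 256):
        chunk = pts[i : i + 256]
        dx2 = (x[None, :] - chunk[:, 0, None]) ** 2          # (k, nx)
        dy2 = (y[None, :] - chunk[:, 1, None]) ** 2          # (k, ny)
        density += np.einsum("ky,kx->yx", np.exp(-dy2 * inv2s2), np.exp(-dx2 * inv2s2))
    density /= density.sum() * cell_km**2
    return UDGrid(x=x, y=y, density=density, cell_km=cell_km, smoothing_km=smoothing_km)


def isopleth(grid: UDGrid, level: float) -> np.ndarray:
    """Smallest-area cell mask holding at least ``level`` probability mass.

    Cells are ranked by density; the mask is the shortest prefix of that
    ranking whose cumulative mass reaches the level.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    flat = grid.density.ravel()
    order = np.argsort(flat)[::-1]
    mass = np.cumsum(flat[order]) * grid.cell_area_km2
    k = int(np.searchsorted(mass, level)) + 1
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(grid.density.shape)


def isopleth_area_km2(grid: UDGrid, level: float) -> float:
    """Area of the ``level`` isopleth in km^2."""
    return float(isopleth(grid, level).sum()) * grid.cell_area_km2


def write_ascii_grid(grid: UDGrid, path) -> None:
    """Export the density surface as an ESRI ASCII grid (plane km units)."""
    half = grid.cell_km / 2.0
    header = (
        f"ncols {len(grid.x)}\n"
        f"nrows {len(grid.y)}\n"
        f"xllcorner {grid.x[0] - half:.3f}\n"
        f"yllcorner {grid.y[0] - half:.3f}\n"
        f"cellsize {grid.cell_km:.3f}\n"
        f"NODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ASCII grids run north to south
        np.savetxt(fh, grid.density[::-1], fmt="%.6e")


def isopleth_to_geojson(grid: UDGrid, level: float, path, projection=None) -> None:
    """Export an isopleth mask as a GeoJSON MultiPolygon of grid cells.

    With a projection the cell corners are inverse-projected to lon/lat;
    otherwise coordinates stay in plane km.
    """
    import json

    mask = isopleth(grid, level)
    half = grid.cell_km / 2.0
    polys = []
    ys, xs = np.nonzero(mask)
    for iy, ix in zip(ys, xs):
        cx, cy = grid.x[ix], grid.y[iy]
        ring = [(cx - half, cy - half), (cx + half, cy - half),
                (cx + half, cy + half), (cx - half, cy + half),
                (cx - half, cy - half)]
        if projection is not None:
            ring = [tuple(map(float, projection.inverse(x, y)[::-1])) for x, y in ring]
        polys.append([[list(map(lambda v: round(float(v), 6), pt)) for pt in ring]])
    feature = {
        "type": "FeatureCollection",
        "features": [{
            "type": "Feature",
            "properties": {"level": level, "smoothing_km": grid.smoothing_km},
            "geometry": {"type": "MultiPolygon", "coordinates": polys},
        }],
    }
    with open(path, "w") as fh:
        json.dump(feature, fh)
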