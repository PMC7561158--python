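"""Kernel-density heat maps of expected unintended events.

The search radius follows the mean-area-per-event rule: with a study region
of A square miles and E expected events per year, the radius is
sqrt(2 * A / E) miles.  The density surface uses the quartic (biweight)
kernel truncated at that radius,

    K(d) = 3 / (pi r^2) * (1 - (d/r)^2)^2   for d < r,  else 0,

which integrates to one, so the surface integrates to the total event
weight; dividing by the span of the birth window puts it in expected
events per square mile per year.  Events are weighted by their expected
probability (y_hat for births, u_hat for pregnancies) rather than
thresholded, which preserves totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError


def search_radius(total_area: float, annual_events: float) -> float:
    """Kernel search radius in miles from the mean area per annual event."""
    if total_area <= 0 or annual_events <= 0:
        raise InvalidArgumentError("total_area and annual_events must be > 0")
    return math.sqrt(2.0 * total_area / annual_events)


@dataclass
class GridSpec:
    """Geometry of a density grid: lower-left origin, cell size, shape."""

    origin_x: float
    origin_y: float
    cell_size: float
    ncols: int
    nrows: int

    @classmethod
    def for_bounds(cls, bounds, cell_size: float) -> "GridSpec":
        minx, miny, maxx, maxy = bounds
        return cls(
            origin_x=float(minx),
            origin_y=float(miny),
            cell_size=float(cell_size),
            ncols=int(math.ceil((maxx - minx) / cell_size)),
            nrows=int(math.ceil((maxy - miny) / cell_size)),
        )

    def cell_centers(self):
        xs = self.origin_x + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = self.origin_y + (np.arange(self.nrows) + 0.5) * self.cell_size
        return xs, ys


@dataclass
class DensityGrid:
    """Density surface in expected events per square mile per year.

    ``values[iy, ix]`` is the density at the cell center with
    x = origin_x + (ix + 0.5) cell, y = origin_y + (iy + 0.5) cell
    (row 0 is the southern edge).
    """

    origin: tuple
    cell_size: float
    values: np.ndarray
    radius_used: float

    def integral(self) -> float:
        """Total event weight per year represented by the surface."""
        return float(self.values.sum() * self.cell_size**2)


def kernel_density(points, radius: float, grid: GridSpec, years_span: float = 1.0) -> DensityGrid:
    """Quartic-kernel density surface of weighted events.

    ``points`` is an (n, 3) array-like of (x, y, weight) in miles; weights
    must be nonnegative.  The kernel is truncated at ``radius``: cells
    farther than the radius from every point are exactly zero.  An empty
    point list yields an all-zero grid.
    """
    if radius <= 0:
        raise InvalidArgumentError("radius must be > 0")
    if years_span <= 0:
        raise InvalidArgumentError("years_span must be > 0")
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) and pts[:, 2].min() < 0:
        raise InvalidArgumentError("event weights must be >= 0")

    values = np.zeros((grid.nrows, grid.ncols))
    xs, ys = grid.cell_centers()
    norm = 3.0 / (math.pi * radius**2)
    inv_r2 = 1.0 / radius**2
    cs = grid.cell_size

    for x, y, w in pts:
        if w == 0.0:
            continue
        ix0 = max(0, int(math.floor((x - radius - grid.origin_x) / cs)))
        ix1 = min(grid.ncols, int(math.ceil((x + radius - grid.origin_x) / cs)) + 1)
        iy0 = max(0, int(math.floor((y - radius - grid.origin_y) / cs)))
        iy1 = min(grid.nrows, int(math.ceil((y + radius - grid.origin_y) / cs)) + 1)
        if ix0 >= ix1 or iy0 >= iy1:
            continue
        dx2 = (xs[ix0:ix1] - x) ** 2
        dy2 = (ys[iy0:iy1] - y) ** 2
        d2 = dy2[:, None] + dx2[None, :]
        inside = d2 < radius**2
        patch = np.zeros_like(d2)
        patch[inside] = w * norm * (1.0 - d2[inside] * inv_r2) ** 2
        values[iy0:iy1, ix0:ix1] += patch

    return DensityGrid(origin=(grid.origin_x, grid.origin_y), cell_size=grid.cell_size,
                       values=values / years_span, radius_used=radius)


# ---------------------------------------------------------------------------
# output formats


def write_ascii_grid(grid: DensityGrid, path, nodata: float = -9999.0) -> None:
    """Write the surface as an ESRI ASCII raster (rows north to south)."""
    nrows, ncols = grid.values.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {grid.origin[0]:.6f}\n"
        f"yllcorner {grid.origin[1]:.6f}\n"
        f"cellsize {grid.cell_size:.6f}\n"
        f"NODATA_value {nodata:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid.values[::-1], fmt="%.6g")


def read_ascii_grid(path) -> DensityGrid:
    with open(path) as fh:
        meta = {}
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)[::-1]
    return DensityGrid(
        origin=(meta["xllcorner"], meta["yllcorner"]),
        cell_size=meta["cellsize"],
        values=values,
        radius_used=float("nan"),
    )


def write_png(grid: DensityGrid, path, title: str = "") -> None:
    """Quick-look rendering of the surface (not a cartographic product)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    nrows, ncols = grid.values.shape
    extent = (
        grid.origin[0],
        grid.origin[0] + ncols * grid.cell_size,
        grid.origin[1],
        grid.origin[1] + nrows * grid.cell_size,
    )
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(grid.values, origin="lower", extent=extent, cmap="magma")
    fig.colorbar(im, ax=ax, label="events / sq mile / year")
    ax.set_xlabel("x (miles)")
    ax.set_ylabel("y (miles)")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)
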