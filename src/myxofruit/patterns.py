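"""Spore point-pattern statistics shared by simulation output and comparison.

A square analysis window containing a disc is divided into an ``n x n`` grid
(default 100 x 100, mirroring the 400x400-pixel window of the reference
analysis).  Spore counts per grid cell form the concentration field; a
normalized Gaussian convolution yields the local density field, emulating
the finite footprint of the scanning beam.  Radial averages of the field and
3-degree angular sector counts summarize the pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SporePattern",
    "DensityField",
    "concentration_grid",
    "local_density_field",
    "radial_density_of_field",
    "angular_spore_counts",
    "nearest_neighbor_distances",
]


@dataclass(frozen=True)
class SporePattern:
    """2D spore positions (µm) with their analysis disc."""

    points: np.ndarray = field(repr=False)  # (n, 2)
    disc_center: tuple[float, float] = (0.0, 0.0)
    disc_radius: float = 50.0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if not np.isfinite(pts).all():
            raise ValueError("spore coordinates must be finite")
        object.__setattr__(self, "points", pts)

    def in_disc(self) -> np.ndarray:
        d = self.points - np.asarray(self.disc_center)
        return (d**2).sum(axis=1) <= self.disc_radius**2


@dataclass(frozen=True)
class GridGeometry:
    """Square analysis window split into n x n cells."""

    origin: tuple[float, float]  # lower corner (x, y), µm
    extent: float  # window side length, µm
    n: int

    @property
    def cell_um(self) -> float:
        return self.extent / self.n

    def node_centers(self) -> tuple[np.ndarray, np.ndarray]:
        c = (np.arange(self.n) + 0.5) * self.cell_um
        return self.origin[0] + c, self.origin[1] + c


@dataclass(frozen=True)
class DensityField:
    """Gaussian-smoothed spore density on the analysis grid.

    ``values[iy, ix]`` holds the density at grid node (ix, iy); the total
    over nodes equals the in-window spore count up to edge truncation.
    """

    values: np.ndarray = field(repr=False)
    geometry: GridGeometry = GridGeometry((0.0, 0.0), 1.0, 1)
    sigma_cells: float = 0.0


def default_window(pattern: SporePattern, pad: float = 1.2) -> GridGeometry:
    """Square window centered on the disc, slightly larger than the disc."""
    cx, cy = pattern.disc_center
    half = pattern.disc_radius * pad
    return GridGeometry(origin=(cx - half, cy - half), extent=2 * half, n=100)


def concentration_grid(
    pattern: SporePattern, window: GridGeometry | None = None, n: int = 100
) -> tuple[np.ndarray, GridGeometry]:
    """Count spores per grid cell; points outside the window are ignored."""
    if window is None:
        window = default_window(pattern)
    if window.n != n:
        window = GridGeometry(window.origin, window.extent, n)
    ox, oy = window.origin
    edges = np.linspace(0.0, window.extent, n + 1)
    counts, _, _ = np.histogram2d(
        pattern.points[:, 1] - oy, pattern.points[:, 0] - ox, bins=(edges, edges)
    )
    return counts, window


def local_density_field(
    grid: np.ndarray,
    sigma: float = 2.0,
    geometry: GridGeometry | None = None,
) -> DensityField:
    """Convolve the concentration grid with a unit-mass Gaussian kernel.

    ``sigma`` is in grid cells.  Edge handling renormalizes the truncated
    kernel (division by the smoothed indicator of the window), so interior
    mass is conserved exactly and edge nodes are unbiased averages.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    grid = np.asarray(grid, dtype=float)
    smoothed = ndimage.gaussian_filter(grid, sigma=sigma, mode="constant", cval=0.0)
    norm = ndimage.gaussian_filter(np.ones_like(grid), sigma=sigma, mode="constant", cval=0.0)
    values = smoothed / norm
    if geometry is None:
        geometry = GridGeometry((0.0, 0.0), float(grid.shape[0]), grid.shape[0])
    return DensityField(values=values, geometry=geometry, sigma_cells=float(sigma))


def radial_density_of_field(
    field: DensityField,
    center: tuple[float, float],
    max_radius: float | None = None,
) -> pd.DataFrame:
    """Mean field value per radial bin (bin width = one grid cell) about center.

    ``center`` is in µm (window coordinates); the curve extends to
    ``max_radius`` (default: the largest radius fully inside the window),
    giving ``floor(max_radius / cell)`` bins.
    """
    geo = field.geometry
    xs, ys = geo.node_centers()
    xx, yy = np.meshgrid(xs, ys)
    cx, cy = center
    if not (xs[0] <= cx <= xs[-1] and ys[0] <= cy <= ys[-1]):
        raise ValueError("center must lie inside the grid")
    r = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    cell = geo.cell_um
    if max_radius is None:
        max_radius = min(
            cx - geo.origin[0], geo.origin[0] + geo.extent - cx,
            cy - geo.origin[1], geo.origin[1] + geo.extent - cy,
        )
    n_bins = int(np.floor(max_radius / cell))
    idx = (r.ravel() / cell).astype(int)
    sel = idx < n_bins
    s = np.bincount(idx[sel], weights=field.values.ravel()[sel], minlength=n_bins)
    c = np.bincount(idx[sel], minlength=n_bins)
    mean = np.where(c > 0, s / np.maximum(c, 1), np.nan)
    return pd.DataFrame(
        {
            "radius_um": (np.arange(n_bins) + 0.5) * cell,
            "mean_density": mean,
            "n_nodes": c,
        }
    )


def angular_spore_counts(
    pattern: SporePattern,
    sector_deg: float = 3.0,
    grid: np.ndarray | None = None,
    geometry: GridGeometry | None = None,
) -> pd.DataFrame:
    """Spore counts per angular sector of the disc (default 3°, 120 sectors).

    By default counts are taken from the raw in-disc points (exact); passing
    a concentration ``grid`` with its ``geometry`` instead sums grid-cell
    counts by the sector of each cell center, matching the grid-based
    variant of the measurement.  Sectors run counter-clockwise from +x.
    """
    n_sectors = 360.0 / sector_deg
    if abs(n_sectors - round(n_sectors)) > 1e-9:
        raise ValueError(f"sector width {sector_deg} does not divide 360")
    n_sectors = int(round(n_sectors))
    cx, cy = pattern.disc_center
    if grid is not None:
        if geometry is None:
            raise ValueError("grid mode requires the grid geometry")
        xs, ys = geometry.node_centers()
        xx, yy = np.meshgrid(xs, ys)
        r = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
        ang = np.degrees(np.arctan2(yy - cy, xx - cx)) % 360.0
        sel = (r <= pattern.disc_radius).ravel()
        weights = np.asarray(grid, dtype=float).ravel()[sel]
        sec = np.minimum((ang.ravel()[sel] / sector_deg).astype(int), n_sectors - 1)
        counts = np.bincount(sec, weights=weights, minlength=n_sectors)
    else:
        pts = pattern.points[pattern.in_disc()]
        ang = np.degrees(np.arctan2(pts[:, 1] - cy, pts[:, 0] - cx)) % 360.0
        sec = np.minimum((ang / sector_deg).astype(int), n_sectors - 1)
        counts = np.bincount(sec, minlength=n_sectors).astype(float)
    centers = (np.arange(n_sectors) + 0.5) * sector_deg
    return pd.DataFrame({"sector_center_deg": centers, "count": counts})


def nearest_neighbor_distances(points: np.ndarray) -> np.ndarray:
    """Distance from each point to its nearest other point."""
    from scipy.spatial import cKDTree

    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        return np.full(len(pts), np.nan)
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return d[:, 1]
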