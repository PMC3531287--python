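"""Volumetric intensity statistics for fruiting-body scans.

Works on 3D grayscale intensity volumes (8-bit, z index 0 at the mound base)
in which backscatter intensity is taken as proportional to local spore
density.  Each in-plane cross-section is summarized by an intensity-weighted
equivalent ellipse obtained from the image moments; radial profiles average
intensity over elliptical annuli of that fit, angular profiles over pie-slice
sectors, and high-density pockets are extracted as connected components of an
isovalue threshold in 3D.

Conventions: ``x`` is the column index and ``y`` the row index of an image
``I[y, x]``; orientation angles are measured counter-clockwise from the +x
axis (in the x/y index frame) and reported in degrees on (-90, 90].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "IntensityVolume",
    "EllipseFit",
    "RadialProfile",
    "AngularProfile",
    "PlaneHistogram",
    "DegenerateImageError",
    "to_grayscale",
    "extract_plane",
    "image_moments",
    "ellipse_fit",
    "elliptical_radius",
    "radial_profile",
    "angular_profile",
    "plane_intensity_distributions",
    "axes_vs_height",
    "isovolume_pockets",
]

#: Isovalue of the mound's outer shell; also the default mask threshold for
#: per-plane statistics.
SURFACE_ISOVALUE = 10

#: Default in-plane pixel spacing, µm per pixel.
DEFAULT_PIXEL_UM = 3.3


class DegenerateImageError(ValueError):
    """Raised when an image carries no intensity mass (undefined centroid)."""


@dataclass
class IntensityVolume:
    """3D grayscale grid with physical spacing.

    ``data`` has shape (nz, ny, nx) with z index 0 at the mound base;
    values live in [0, 255].
    """

    data: np.ndarray
    pixel_um: float = DEFAULT_PIXEL_UM
    slice_um: float = DEFAULT_PIXEL_UM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if self.pixel_um <= 0 or self.slice_um <= 0:
            raise ValueError("spacings must be positive")
        if self.data.min() < 0 or self.data.max() > 255:
            raise ValueError("intensity values must lie in [0, 255]")

    @property
    def n_planes(self) -> int:
        return self.data.shape[0]

    def heights_um(self) -> np.ndarray:
        """Physical height of each plane above the base."""
        return np.arange(self.n_planes) * self.slice_um


@dataclass(frozen=True)
class EllipseFit:
    """Equivalent ellipse of an intensity-weighted cross-section."""

    centroid: tuple[float, float]  # (x, y), pixels
    orientation_deg: float  # (-90, 90], CCW from +x
    eccentricity: float
    semi_major: float  # pixels
    semi_minor: float  # pixels
    m00: float
    degenerate: bool = False  # near-isotropic or collinear mass


@dataclass(frozen=True)
class RadialProfile:
    """Per-annulus statistics in normalized elliptical radius."""

    bin_edges: np.ndarray  # normalized radius, length n_rings + 1
    mean: np.ndarray
    sd: np.ndarray
    count: np.ndarray


@dataclass(frozen=True)
class AngularProfile:
    """Per-sector mean intensity, sectors CCW from +x."""

    sector_edges_deg: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    count: np.ndarray


@dataclass(frozen=True)
class PlaneHistogram:
    z: int
    counts: np.ndarray  # 256 bins
    normalized: np.ndarray
    smoothed: np.ndarray
    n_pixels: int


# ITU-R 601 luminance weights
_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """Convert an RGB image to 8-bit grayscale (ITU-R 601 luminance)."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected an (ny, nx, 3) RGB image, got shape {rgb.shape}")
    gray = rgb.astype(float) @ _LUMA
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def extract_plane(volume: IntensityVolume, z: int) -> np.ndarray:
    """Return the xy-slice at height index ``z`` (no resampling)."""
    if not 0 <= z < volume.n_planes:
        raise IndexError(f"plane index {z} out of range [0, {volume.n_planes})")
    return volume.data[z]


def image_moments(I: np.ndarray) -> dict[str, float]:
    """Raw and second central intensity-weighted image moments.

    ``m_pq = sum_x sum_y x**p * y**q * I(x, y)``; central moments are taken
    about the intensity centroid.  The image is used as-is (not binarized).
    """
    I = np.asarray(I, dtype=float)
    m00 = I.sum()
    if m00 <= 0:
        raise DegenerateImageError("image has no intensity mass; centroid undefined")
    ny, nx = I.shape
    x = np.arange(nx, dtype=float)
    y = np.arange(ny, dtype=float)
    col = I.sum(axis=0)  # mass per x
    row = I.sum(axis=1)  # mass per y
    m10 = float(col @ x)
    m01 = float(row @ y)
    xbar, ybar = m10 / m00, m01 / m00
    dx, dy = x - xbar, y - ybar
    mu20 = float(col @ dx**2)
    mu02 = float(row @ dy**2)
    mu11 = float(dx @ (I.T @ dy))
    return {
        "m00": float(m00),
        "m10": m10,
        "m01": m01,
        "xbar": xbar,
        "ybar": ybar,
        "mu20": mu20,
        "mu11": mu11,
        "mu02": mu02,
    }


def ellipse_fit(I: np.ndarray, eccentricity_floor: float = 0.05) -> EllipseFit:
    """Equivalent ellipse from the covariance of the intensity distribution.

    The covariance matrix is built from normalized central moments; its
    eigen-decomposition gives the axes.  Semi-axes are scaled as
    ``2 * sqrt(eigenvalue)``, which is exact for a uniformly filled ellipse
    (a uniform ellipse with semi-axis ``a`` has variance ``a**2 / 4`` along
    that axis).  Near-isotropic fits (eccentricity below
    ``eccentricity_floor``) are flagged: their orientation is unconstrained.
    """
    mom = image_moments(I)
    m00 = mom["m00"]
    cov = np.array(
        [[mom["mu20"], mom["mu11"]], [mom["mu11"], mom["mu02"]]]
    ) / m00
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam2, lam1 = float(evals[0]), float(evals[1])
    if lam1 <= 0:
        raise DegenerateImageError("degenerate (collinear) intensity mass")
    semi_major = 2.0 * np.sqrt(lam1)
    semi_minor = 2.0 * np.sqrt(max(lam2, 0.0))
    vx, vy = evecs[:, 1]  # principal eigenvector
    angle = np.degrees(np.arctan2(vy, vx))
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    ecc = float(np.sqrt(max(0.0, 1.0 - (semi_minor / semi_major) ** 2)))
    return EllipseFit(
        centroid=(mom["xbar"], mom["ybar"]),
        orientation_deg=float(angle),
        eccentricity=ecc,
        semi_major=float(semi_major),
        semi_minor=float(max(semi_minor, 1e-9)),
        m00=m00,
        degenerate=bool(ecc < eccentricity_floor or lam2 <= 0),
    )


def elliptical_radius(shape: tuple[int, int], fit: EllipseFit) -> np.ndarray:
    """Normalized elliptical radius of every pixel (1.0 on the fitted ellipse)."""
    ny, nx = shape
    xbar, ybar = fit.centroid
    yy, xx = np.mgrid[0:ny, 0:nx]
    dx, dy = xx - xbar, yy - ybar
    th = np.radians(fit.orientation_deg)
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)
    return np.sqrt((u / fit.semi_major) ** 2 + (v / fit.semi_minor) ** 2)


def radial_profile(
    I: np.ndarray,
    fit: EllipseFit,
    n_rings: int = 20,
    max_radius: float = 1.5,
) -> RadialProfile:
    """Mean/sd intensity in elliptical annuli of equal normalized width.

    Pixels are binned by the affine-invariant elliptical radius of ``fit``;
    ``n_rings`` annuli cover normalized radius [0, max_radius].  The annuli
    partition the pixels inside the outermost ellipse.
    """
    if n_rings < 1:
        raise ValueError("n_rings must be >= 1")
    I = np.asarray(I, dtype=float)
    rho = elliptical_radius(I.shape, fit)
    edges = np.linspace(0.0, max_radius, n_rings + 1)
    idx = np.digitize(rho.ravel(), edges) - 1  # ring index; outside -> n_rings
    inside = (idx >= 0) & (idx < n_rings)
    vals = I.ravel()[inside]
    ring = idx[inside]
    count = np.bincount(ring, minlength=n_rings)
    s1 = np.bincount(ring, weights=vals, minlength=n_rings)
    s2 = np.bincount(ring, weights=vals**2, minlength=n_rings)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, s1 / np.maximum(count, 1), np.nan)
        var = np.where(count > 0, s2 / np.maximum(count, 1) - mean**2, np.nan)
    sd = np.sqrt(np.clip(var, 0.0, None))
    return RadialProfile(bin_edges=edges, mean=mean, sd=sd, count=count)


def angular_profile(
    I: np.ndarray,
    center: tuple[float, float],
    sector_width_deg: float = 10.0,
    mask: np.ndarray | None = None,
) -> AngularProfile:
    """Mean intensity per pie-slice sector about ``center``.

    ``sector_width_deg`` must divide 360.  Sectors are indexed
    counter-clockwise from the +x axis.  ``mask`` selects the analyzed domain
    (default: pixels at or above the outer-shell isovalue).
    """
    n_sectors = 360.0 / sector_width_deg
    if abs(n_sectors - round(n_sectors)) > 1e-9:
        raise ValueError(f"sector width {sector_width_deg} does not divide 360")
    n_sectors = int(round(n_sectors))
    I = np.asarray(I, dtype=float)
    if mask is None:
        mask = I >= SURFACE_ISOVALUE
    cx, cy = center
    ny, nx = I.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    ang = np.degrees(np.arctan2(yy - cy, xx - cx)) % 360.0
    sector = np.minimum((ang / sector_width_deg).astype(int), n_sectors - 1)
    sel = mask.ravel()
    sec = sector.ravel()[sel]
    vals = I.ravel()[sel]
    count = np.bincount(sec, minlength=n_sectors)
    s1 = np.bincount(sec, weights=vals, minlength=n_sectors)
    s2 = np.bincount(sec, weights=vals**2, minlength=n_sectors)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, s1 / np.maximum(count, 1), np.nan)
        var = np.where(count > 0, s2 / np.maximum(count, 1) - mean**2, np.nan)
    edges = np.arange(n_sectors + 1) * sector_width_deg
    return AngularProfile(
        sector_edges_deg=edges,
        mean=mean,
        sd=np.sqrt(np.clip(var, 0.0, None)),
        count=count,
    )


def _fold_smooth(counts: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average that conserves total mass exactly.

    The full convolution with a normalized boxcar conserves mass; the
    overhanging tails are folded back onto the edge bins.
    """
    kernel = np.full(window, 1.0 / window)
    full = np.convolve(counts.astype(float), kernel, mode="full")
    half = (window - 1) // 2
    out = full[half : half + counts.size].copy()
    # fold leading/trailing overhang back into the ends
    for i in range(half):
        out[0] += full[i]
    for i in range(full.size - (window - 1 - half), full.size):
        out[-1] += full[i]
    return out


def plane_intensity_distributions(
    volume: IntensityVolume,
    z_range: tuple[int, int] | None = None,
    mask_isovalue: float = SURFACE_ISOVALUE,
    smooth_window: int = 5,
) -> list[PlaneHistogram]:
    """Raw, area-normalized and smoothed intensity histograms per plane.

    Histograms are computed over the pixels at or above ``mask_isovalue``
    (the analyzed "disc" of each plane); the normalized histogram divides by
    that pixel count, and the smoothed histogram applies a centered
    mass-conserving moving average of ``smooth_window`` intensity bins.
    """
    if z_range is None:
        z_range = (0, volume.n_planes)
    z0, z1 = z_range
    if not (0 <= z0 < z1 <= volume.n_planes):
        raise ValueError(f"invalid z_range {z_range}")
    out = []
    for z in range(z0, z1):
        plane = volume.data[z]
        vals = plane[plane >= mask_isovalue].astype(int)
        counts = np.bincount(vals.ravel(), minlength=256)[:256].astype(float)
        n = int(vals.size)
        normalized = counts / n if n else counts
        smoothed = _fold_smooth(counts, smooth_window)
        out.append(
            PlaneHistogram(z=z, counts=counts, normalized=normalized, smoothed=smoothed, n_pixels=n)
        )
    return out


@dataclass(frozen=True)
class AxesTrend:
    """Per-plane ellipse fits plus linear semi-axis trends vs height."""

    table: pd.DataFrame = field(repr=False)
    slope_major_um_per_um: float = 0.0
    slope_minor_um_per_um: float = 0.0
    r2_major: float = 0.0
    r2_minor: float = 0.0


def _linfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), r2


def axes_vs_height(
    volume: IntensityVolume, surface_isovalue: float = SURFACE_ISOVALUE
) -> AxesTrend:
    """Ellipse fit per plane (pixels >= isovalue) and axis-vs-height trends.

    A linearly tapering (cone-like) mound shows negative slopes with high R².
    Axes and heights are reported in µm.
    """
    rows = []
    for z in range(volume.n_planes):
        plane = volume.data[z].astype(float)
        masked = np.where(plane >= surface_isovalue, plane, 0.0)
        if masked.sum() <= 0:
            continue
        try:
            fit = ellipse_fit(masked)
        except DegenerateImageError:
            continue
        rows.append(
            {
                "z": z,
                "height_um": z * volume.slice_um,
                "centroid_x_px": fit.centroid[0],
                "centroid_y_px": fit.centroid[1],
                "orientation_deg": fit.orientation_deg,
                "eccentricity": fit.eccentricity,
                "semi_major_um": fit.semi_major * volume.pixel_um,
                "semi_minor_um": fit.semi_minor * volume.pixel_um,
                "m00": fit.m00,
            }
        )
    if len(rows) < 3:
        raise ValueError("need at least 3 planes with mass above the isovalue")
    table = pd.DataFrame(rows)
    h = table["height_um"].to_numpy()
    slope_a, r2_a = _linfit(h, table["semi_major_um"].to_numpy())
    slope_b, r2_b = _linfit(h, table["semi_minor_um"].to_numpy())
    return AxesTrend(
        table=table,
        slope_major_um_per_um=slope_a,
        slope_minor_um_per_um=slope_b,
        r2_major=r2_a,
        r2_minor=r2_b,
    )


def isovolume_pockets(
    volume: IntensityVolume, isovalue: float, min_voxels: int = 1
) -> pd.DataFrame:
    """High-density pockets: 26-connected components of ``data >= isovalue``.

    Returns one row per component with voxel count, physical volume,
    equivalent spherical diameter (µm) and centroid (µm, x/y/z).  Components
    smaller than ``min_voxels`` are dropped (single-voxel noise hits).
    """
    if not 0 < isovalue < 255:
        raise ValueError("isovalue must lie in (0, 255)")
    mask = volume.data >= isovalue
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labels, n = ndimage.label(mask, structure=structure)
    cols = ["label", "voxels", "volume_um3", "equiv_diameter_um", "x_um", "y_um", "z_um"]
    if n == 0:
        return pd.DataFrame(columns=cols)
    counts = np.bincount(labels.ravel())[1:]
    centroids = ndimage.center_of_mass(mask, labels, index=np.arange(1, n + 1))
    voxel_um3 = volume.pixel_um**2 * volume.slice_um
    rows = []
    for lab, cnt, (cz, cy, cx) in zip(range(1, n + 1), counts, centroids):
        if cnt < min_voxels:
            continue
        vol = cnt * voxel_um3
        rows.append(
            {
                "label": lab,
                "voxels": int(cnt),
                "volume_um3": vol,
                "equiv_diameter_um": (6.0 * vol / np.pi) ** (1.0 / 3.0),
                "x_um": cx * volume.pixel_um,
                "y_um": cy * volume.pixel_um,
                "z_um": cz * volume.slice_um,
            }
        )
    return pd.DataFrame(rows, columns=cols)
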