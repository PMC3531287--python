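"""Synthetic-data generators with machine-readable ground truth.

Three generators emulate the statistical structure the analyses assume:

- uniform-intensity ellipse phantoms (moment/ellipse-fit oracles);
- cone-like mound volumes — linearly shrinking elliptical cross-sections
  around an interior base intensity of ~130 with additive Gaussian noise and
  planted spherical high-density pockets of 12-25 µm diameter;
- clustered 2D spore point patterns inside an analysis disc.

Every generator is deterministic under its seed and returns the ground truth
alongside the data, so recovery tests can compare measured statistics against
the construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging import DEFAULT_PIXEL_UM, IntensityVolume

__all__ = [
    "EllipseTruth",
    "MoundTruth",
    "SporeTruth",
    "synth_ellipse_image",
    "synth_mound_volume",
    "synth_clustered_spores",
    "uniform_disc_points",
]


@dataclass(frozen=True)
class EllipseTruth:
    a: float  # semi-major, pixels
    b: float  # semi-minor, pixels
    angle_deg: float
    center: tuple[float, float]  # (x, y) pixels
    intensity: float
    eccentricity: float


@dataclass(frozen=True)
class MoundTruth:
    """Construction parameters of a synthetic cone-like mound.

    The mound interior (a linearly tapering elliptical cone) carries
    ``base_intensity`` plus Gaussian noise; each pocket is a sphere adding
    ``pocket_boost``.  ``background`` stays below the outer-shell isovalue.
    """

    base_semi_axes_um: tuple[float, float] = (60.0, 40.0)
    apex_height_um: float = 90.0
    base_intensity: float = 130.0  # middle of the observed 120-140 band
    noise_sd: float = 8.0
    background: float = 2.0
    pocket_boost: float = 40.0
    pockets: tuple[tuple[tuple[float, float, float], float], ...] = ()
    # each pocket: ((x_um, y_um, z_um), diameter_um)

    def __post_init__(self) -> None:
        a, b = self.base_semi_axes_um
        if a <= 0 or b <= 0 or self.apex_height_um <= 0:
            raise ValueError("mound geometry must be positive")
        if not 0 < self.base_intensity < 255:
            raise ValueError("base_intensity must lie in (0, 255)")
        for center, diam in self.pockets:
            if diam <= 0:
                raise ValueError("pocket diameters must be positive")
            if not self._inside_cone(center):
                raise ValueError(f"pocket at {center} lies outside the cone")

    def _inside_cone(self, center: tuple[float, float, float]) -> bool:
        x, y, z = center
        if not 0 <= z < self.apex_height_um:
            return False
        s = 1.0 - z / self.apex_height_um
        a, b = self.base_semi_axes_um
        return (x / (a * s)) ** 2 + (y / (b * s)) ** 2 <= 1.0


@dataclass(frozen=True)
class SporeTruth:
    centers: np.ndarray = field(repr=False)  # (k, 2) cluster centers, µm
    membership: np.ndarray = field(repr=False)  # cluster index per point
    cluster_sd_um: float = 0.0


def synth_ellipse_image(
    a: float,
    b: float,
    angle_deg: float = 0.0,
    intensity: float = 200.0,
    size: tuple[int, int] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, EllipseTruth]:
    """Uniform-intensity filled ellipse centered in the frame.

    ``a >= b > 0`` are the semi-axes in pixels; ``angle_deg`` rotates the
    major axis CCW from +x.  Raises if the rotated ellipse does not fit.
    """
    if not a >= b > 0:
        raise ValueError("require a >= b > 0")
    if size is None:
        margin = int(np.ceil(a)) + 4
        size = (2 * margin + 1, 2 * margin + 1)
    ny, nx = size
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    # rotated-ellipse bounding half-widths
    th = np.radians(angle_deg)
    half_x = np.sqrt((a * np.cos(th)) ** 2 + (b * np.sin(th)) ** 2)
    half_y = np.sqrt((a * np.sin(th)) ** 2 + (b * np.cos(th)) ** 2)
    if half_x > cx or half_y > cy:
        raise ValueError("ellipse exceeds the image frame")
    # 4x4 subpixel coverage sampling: boundary pixels carry fractional
    # intensity, so image moments match the continuous uniform ellipse
    ss = 4
    off = (np.arange(ss) + 0.5) / ss - 0.5
    cover = np.zeros((ny, nx))
    yy, xx = np.mgrid[0:ny, 0:nx]
    for oy in off:
        for ox in off:
            dx, dy = xx + ox - cx, yy + oy - cy
            u = dx * np.cos(th) + dy * np.sin(th)
            v = -dx * np.sin(th) + dy * np.cos(th)
            cover += (u / a) ** 2 + (v / b) ** 2 <= 1.0
    cover /= ss * ss
    img = cover * float(intensity)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape) * (cover > 0)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    ecc = float(np.sqrt(1.0 - (b / a) ** 2))
    return img, EllipseTruth(a, b, angle_deg, (cx, cy), intensity, ecc)


def _default_pockets(
    truth: MoundTruth, k: int, rng: np.random.Generator,
    diameter_range: tuple[float, float] = (12.0, 25.0),
) -> tuple[tuple[tuple[float, float, float], float], ...]:
    """Rejection-sample pocket centers inside the cone.

    Centers are kept at least one pocket diameter apart so planted pockets
    do not merge unintentionally; pockets stay clear of the cone surface.
    """
    a0, b0 = truth.base_semi_axes_um
    h = truth.apex_height_um
    placed: list[tuple[tuple[float, float, float], float]] = []
    attempts = 0
    while len(placed) < k:
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError("could not place pockets with required separation")
        d = float(rng.uniform(*diameter_range))
        z = float(rng.uniform(0.05 * h, 0.45 * h))
        s = 1.0 - z / h
        # margin keeps the whole sphere inside the tapered section
        ax, bx = a0 * s - d / 2 - 1, b0 * s - d / 2 - 1
        if ax <= 0 or bx <= 0:
            continue
        x = float(rng.uniform(-ax, ax))
        y = float(rng.uniform(-bx, bx))
        if (x / ax) ** 2 + (y / bx) ** 2 > 1.0:
            continue
        ok = True
        for (px, py, pz), pd in placed:
            sep = np.sqrt((x - px) ** 2 + (y - py) ** 2 + (z - pz) ** 2)
            # keep surfaces ~2 voxels apart so discretization/noise cannot
            # bridge neighboring pockets into one component
            if sep < (d + pd) / 2 + 7.0:
                ok = False
                break
        if ok:
            placed.append(((x, y, z), d))
    return tuple(placed)


def synth_mound_volume(
    truth: MoundTruth | None = None,
    pixel_um: float = DEFAULT_PIXEL_UM,
    slice_um: float = DEFAULT_PIXEL_UM,
    n_pockets: int | None = None,
    seed: int = 0,
) -> tuple[IntensityVolume, MoundTruth]:
    """Voxelize a cone-like mound with planted high-density pockets.

    Interior voxels get ``base_intensity`` + Gaussian noise; pocket spheres
    add ``pocket_boost``; everything outside the cone is ``background``
    (below the outer-shell isovalue).  If ``n_pockets`` is given and the
    truth lists none, pockets are sampled inside the cone with minimum
    separation.  Values are clipped to the 8-bit range.
    """
    rng = np.random.default_rng(seed)
    if truth is None:
        truth = MoundTruth()
    if n_pockets and not truth.pockets:
        from dataclasses import replace

        truth = replace(truth, pockets=_default_pockets(truth, n_pockets, rng))
    a0, b0 = truth.base_semi_axes_um
    h = truth.apex_height_um
    nx = int(np.ceil(2 * a0 / pixel_um)) + 7
    ny = int(np.ceil(2 * b0 / pixel_um)) + 7
    nz = int(np.ceil(h / slice_um)) + 2
    x = (np.arange(nx) - (nx - 1) / 2.0) * pixel_um
    y = (np.arange(ny) - (ny - 1) / 2.0) * pixel_um
    z = np.arange(nz) * slice_um
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    s = np.clip(1.0 - zz / h, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(
            s > 0,
            (xx / np.maximum(a0 * s, 1e-12)) ** 2 + (yy / np.maximum(b0 * s, 1e-12)) ** 2,
            np.inf,
        )
    inside = r2 <= 1.0
    vol = np.full((nz, ny, nx), float(truth.background))
    vol[inside] = truth.base_intensity
    if truth.noise_sd > 0:
        vol[inside] += rng.normal(0.0, truth.noise_sd, int(inside.sum()))
    for (px, py, pz), diam in truth.pockets:
        d2 = (xx - px) ** 2 + (yy - py) ** 2 + (zz - pz) ** 2
        vol[d2 <= (diam / 2.0) ** 2] += truth.pocket_boost
    data = np.clip(np.rint(vol), 0, 255).astype(np.uint8)
    return IntensityVolume(data, pixel_um=pixel_um, slice_um=slice_um), truth


def uniform_disc_points(
    n: int, center: tuple[float, float], radius: float, rng: np.random.Generator
) -> np.ndarray:
    """n i.i.d. uniform points in a disc (area-uniform radius sampling)."""
    r = radius * np.sqrt(rng.random(n))
    th = rng.uniform(0.0, 2 * np.pi, n)
    return np.column_stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)])


def synth_clustered_spores(
    n_clusters: int,
    spores_per_cluster_mean: float,
    cluster_sd_um: float,
    disc_center: tuple[float, float] = (0.0, 0.0),
    disc_radius_um: float = 50.0,
    seed: int = 0,
) -> tuple[np.ndarray, SporeTruth]:
    """Poisson-sized Gaussian clusters around uniform centers in a disc.

    Cluster centers are uniform in the disc (kept one sd clear of the rim);
    offspring are isotropic Gaussians about their center.  Returns the point
    array (k, 2) in µm plus the truth (centers and memberships).
    """
    if disc_radius_um <= cluster_sd_um:
        raise ValueError("disc radius must exceed the cluster sd")
    rng = np.random.default_rng(seed)
    inner = max(disc_radius_um - cluster_sd_um, 1e-9)
    centers = uniform_disc_points(n_clusters, disc_center, inner, rng)
    pts = []
    member = []
    for k in range(n_clusters):
        n_k = max(1, int(rng.poisson(spores_per_cluster_mean)))
        offs = rng.normal(0.0, cluster_sd_um, size=(n_k, 2))
        pts.append(centers[k] + offs)
        member.extend([k] * n_k)
    points = np.vstack(pts)
    return points, SporeTruth(
        centers=centers, membership=np.asarray(member), cluster_sd_um=cluster_sd_um
    )
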