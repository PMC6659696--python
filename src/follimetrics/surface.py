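"""Surface detection, parameterization, and pullback projection.

The organ (a near-spheroidal monolayer epithelium) is represented as a
surface of revolution plus low-order azimuthal harmonics.  Coordinates are
``(s, phi)`` where ``s`` is meridional arc length in μm measured from the
anterior pole and ``phi`` in ``[0, 2π)`` is azimuth about the A–P axis.
All length/area measurements go through the induced metric tensor of the
embedding, so chart distortion never enters a measurement.

Conventions
-----------
* Volumes are indexed ``(z, y, x)`` with the A–P axis along axis 0 (the
  slowest-varying axis); the anterior pole sits at the minimal axis
  coordinate.
* Charts: ``cylinder`` covers ``s`` away from the poles (default cap angle
  25°); ``polar_anterior`` / ``polar_posterior`` are azimuthal-equidistant
  charts covering the caps with overlap.
* Pixel-level metrics are expressed in pixel units (μm² per pixel²), so a
  cell area is simply the sum of ``sqrt(det g)`` over its pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import PchipInterpolator
from scipy.signal import savgol_filter

__all__ = [
    "PointCloud",
    "SurfaceParam",
    "MetricField",
    "Pullback",
    "spheroid_param",
    "extract_pointcloud",
    "fit_surface",
    "surface_area",
    "enclosed_volume",
    "make_pullback",
]

DEFAULT_CAP_ANGLE_DEG = 25.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PointCloud:
    """3D surface point cloud in μm."""

    points: np.ndarray  # (N, 3) in (z, y, x) physical coordinates

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (N, 3)")
        if len(self.points) < 100:
            raise ValueError(
                f"point cloud too sparse ({len(self.points)} points; need >= 100)"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point cloud contains non-finite coordinates")


@dataclass
class SurfaceParam:
    """Smooth embedding of a genus-0 surface over ``(s, phi)``.

    ``embedding[i, j]`` is the 3D position (μm) of the point at arc position
    ``s_grid[i]`` and azimuth ``phi_grid[j]``.  ``rho`` is the distance from
    the A–P axis and ``z_of_s`` the axial coordinate (from the organ center)
    of each meridian node.
    """

    axis: np.ndarray            # unit vector, anterior -> posterior
    center: np.ndarray          # organ center, μm
    anterior_pole: np.ndarray   # 3D position of s = 0
    posterior_pole: np.ndarray  # 3D position of s = L
    s_grid: np.ndarray          # (n_s,), 0 .. L
    phi_grid: np.ndarray        # (n_phi,), [0, 2π)
    embedding: np.ndarray       # (n_s, n_phi, 3)
    rho: np.ndarray             # (n_s, n_phi) distance from axis
    z_of_s: np.ndarray          # (n_s,) axial coordinate relative to center
    L: float                    # meridian length, μm

    @property
    def n_s(self) -> int:
        return len(self.s_grid)

    @property
    def n_phi(self) -> int:
        return len(self.phi_grid)

    def frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Right-handed orthonormal frame (axis, e1, e2)."""
        a = self.axis
        probe = np.array([1.0, 0.0, 0.0])
        if abs(a @ probe) > 0.9:
            probe = np.array([0.0, 1.0, 0.0])
        e1 = probe - (probe @ a) * a
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(a, e1)
        return a, e1, e2

    def point(self, s, phi) -> np.ndarray:
        """Embed arbitrary ``(s, phi)`` (arrays ok) by interpolation."""
        s = np.asarray(s, dtype=float)
        phi = np.mod(np.asarray(phi, dtype=float), 2 * np.pi)
        rho = self._interp_rho(s, phi)
        z = np.interp(s, self.s_grid, self.z_of_s)
        a, e1, e2 = self.frame()
        return (
            self.center
            + z[..., None] * a
            + rho[..., None] * (np.cos(phi)[..., None] * e1 + np.sin(phi)[..., None] * e2)
        )

    def _interp_rho(self, s, phi) -> np.ndarray:
        si = np.clip(np.interp(s, self.s_grid, np.arange(self.n_s)), 0, self.n_s - 1)
        pj = phi / (2 * np.pi) * self.n_phi  # periodic index
        i0 = np.floor(si).astype(int)
        i1 = np.minimum(i0 + 1, self.n_s - 1)
        fi = si - i0
        j0 = np.floor(pj).astype(int) % self.n_phi
        j1 = (j0 + 1) % self.n_phi
        fj = pj - np.floor(pj)
        r = (
            self.rho[i0, j0] * (1 - fi) * (1 - fj)
            + self.rho[i1, j0] * fi * (1 - fj)
            + self.rho[i0, j1] * (1 - fi) * fj
            + self.rho[i1, j1] * fi * fj
        )
        return r

    def rho_profile(self, s) -> np.ndarray:
        """Azimuthally averaged radius at arc position(s) ``s``."""
        return np.interp(s, self.s_grid, self.rho.mean(axis=1))


@dataclass
class MetricField:
    """Induced metric components on the ``(s, phi)`` grid of a SurfaceParam.

    Units: g_ss is dimensionless (μm²/μm²), g_sphi μm²/(μm·rad),
    g_phiphi μm²/rad².
    """

    g_ss: np.ndarray
    g_sphi: np.ndarray
    g_phiphi: np.ndarray

    def det(self) -> np.ndarray:
        return self.g_ss * self.g_phiphi - self.g_sphi**2

    def check_positive_definite(self, interior_margin: int = 1) -> bool:
        """Positive definiteness at interior nodes (poles excluded)."""
        sl = slice(interior_margin, -interior_margin or None)
        return bool(
            np.all(self.g_ss[sl] > 0) and np.all(self.det()[sl] > 0)
        )


@dataclass
class Pullback:
    """2D chart image with per-pixel surface coordinates and pixel metric.

    ``g11, g12, g22`` are the induced metric in *pixel* coordinates
    (axis 0 = image rows, axis 1 = image columns), so the true area of one
    pixel is ``sqrt(g11 g22 - g12²)`` μm².
    """

    image: np.ndarray         # (H, W) float
    s_map: np.ndarray         # (H, W) arc position μm (NaN outside chart)
    phi_map: np.ndarray       # (H, W) azimuth rad
    g11: np.ndarray
    g12: np.ndarray
    g22: np.ndarray
    chart: str                # cylinder | polar_anterior | polar_posterior
    pixel_size: float         # nominal chart pixel pitch, μm
    valid: np.ndarray         # (H, W) bool; False where sampling failed
    wraps_phi: bool = False   # column axis is periodic in phi
    offsets: tuple = ()
    slab: float = 0.0

    @property
    def pixel_area(self) -> np.ndarray:
        d = self.g11 * self.g22 - self.g12**2
        return np.sqrt(np.clip(d, 0, None))


# ---------------------------------------------------------------------------
# analytic spheroid parameterization (shared with the synthetic generator)
# ---------------------------------------------------------------------------

def spheroid_param(
    a: float,
    b: float,
    center=(0.0, 0.0, 0.0),
    n_s: int | None = None,
    n_phi: int | None = None,
    grid_step: float = 0.2,
) -> SurfaceParam:
    """Exact parameterization of the spheroid z²/a² + (y²+x²)/b² = 1.

    ``a`` is the semi-axis along A–P (volume axis 0), ``b`` equatorial.
    The meridian is sampled uniformly in arc length.
    """
    if a <= 0 or b <= 0:
        raise ValueError("semi-axes must be positive")
    center = np.asarray(center, dtype=float)
    # dense polar-angle sampling; chord-sum arc length handles the pole
    # sqrt-singularity of rho(z)
    theta = np.linspace(0.0, np.pi, 8192)
    z = -a * np.cos(theta)          # anterior at z = -a
    r = b * np.sin(theta)
    seg = np.hypot(np.diff(z), np.diff(r))
    s_cum = np.concatenate([[0.0], np.cumsum(seg)])
    L = float(s_cum[-1])
    if n_s is None:
        n_s = max(64, int(round(L / grid_step)) + 1)
    if n_phi is None:
        n_phi = max(64, int(round(2 * np.pi * b / grid_step)))
    s_grid = np.linspace(0.0, L, n_s)
    z_of_s = np.interp(s_grid, s_cum, z)
    rho_1d = np.interp(s_grid, s_cum, r)
    phi_grid = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)
    rho = np.repeat(rho_1d[:, None], n_phi, axis=1)
    axis = np.array([1.0, 0.0, 0.0])  # (z, y, x) order: axis 0
    e1 = np.array([0.0, 1.0, 0.0])
    e2 = np.array([0.0, 0.0, 1.0])
    emb = (
        center
        + z_of_s[:, None, None] * axis
        + rho[:, :, None] * (np.cos(phi_grid)[None, :, None] * e1
                             + np.sin(phi_grid)[None, :, None] * e2)
    )
    return SurfaceParam(
        axis=axis,
        center=center,
        anterior_pole=center - a * axis,
        posterior_pole=center + a * axis,
        s_grid=s_grid,
        phi_grid=phi_grid,
        embedding=emb,
        rho=rho,
        z_of_s=z_of_s,
        L=L,
    )


def metric_field(param: SurfaceParam) -> MetricField:
    """Induced metric by centered finite differences of the embedding."""
    emb = param.embedding
    ds = param.s_grid[1] - param.s_grid[0]
    dphi = param.phi_grid[1] - param.phi_grid[0]
    d_s = np.gradient(emb, ds, axis=0)
    # periodic centered difference in phi
    d_p = (np.roll(emb, -1, axis=1) - np.roll(emb, 1, axis=1)) / (2 * dphi)
    g_ss = np.einsum("ijk,ijk->ij", d_s, d_s)
    g_sp = np.einsum("ijk,ijk->ij", d_s, d_p)
    g_pp = np.einsum("ijk,ijk->ij", d_p, d_p)
    return MetricField(g_ss=g_ss, g_sphi=g_sp, g_phiphi=g_pp)


# ---------------------------------------------------------------------------
# surface detection
# ---------------------------------------------------------------------------

def extract_pointcloud(volume: np.ndarray, voxel_size, threshold: float) -> PointCloud:
    """Outer-shell voxel centers of the thresholded object, in μm.

    A voxel belongs to the shell if it is above threshold and 6-adjacent to
    a below-threshold voxel (or the volume border).
    """
    volume = np.asarray(volume)
    voxel_size = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    if np.any(voxel_size <= 0):
        raise ValueError("voxel sizes must be positive")
    mask = volume > threshold
    if not mask.any():
        raise ValueError("no surface detected: threshold excludes all voxels")
    eroded = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(3, 1))
    shell = mask & ~eroded
    idx = np.argwhere(shell)
    pts = idx * voxel_size
    return PointCloud(points=pts)


# ---------------------------------------------------------------------------
# surface fitting
# ---------------------------------------------------------------------------

def fit_surface(
    cloud: PointCloud,
    smoothing: float = 1.0,
    n_profile_bins: int = 96,
    n_phi_bins: int = 96,
    n_harmonics: int = 4,
    n_s: int = 400,
    n_phi: int = 256,
    anterior_at_min: bool = True,
    axis_hint=None,
    star_tolerance: float = 0.35,
) -> tuple[SurfaceParam, MetricField]:
    """Fit an axisymmetric-plus-harmonics surface to a point cloud.

    The A–P axis is the principal axis of the cloud (or ``axis_hint``, the
    manual override for e.g. oblate organs).  The spherical profile
    R(t, φ) about the centroid — polar angle t from the anterior pole —
    comes from binned means, smoothed with a truncated Fourier series in φ
    (``n_harmonics`` ≤ 4) and local quadratic (Savitzky–Golay) smoothing
    along t; pole radii come from even-symmetry regression on the raw cap
    points.  The meridian is re-sampled uniformly in arc length and the
    metric obtained by centered finite differences of the embedding.

    Raises ``ValueError`` when the cloud is not star-shaped about its
    centroid (radius spread within a (t, φ) bin beyond ``star_tolerance``
    of the local radius).
    """
    pts = cloud.points
    center = pts.mean(axis=0)
    d = pts - center
    if axis_hint is not None:
        # manual A–P override (e.g. oblate organs where the principal axis
        # of the cloud is equatorial)
        axis = np.asarray(axis_hint, dtype=float)
        axis = axis / np.linalg.norm(axis)
    else:
        cov = d.T @ d / len(d)
        evals, evecs = np.linalg.eigh(cov)
        axis = evecs[:, np.argmax(evals)]
    # deterministic sign, then anterior convention
    k = np.argmax(np.abs(axis))
    if axis[k] < 0:
        axis = -axis
    z = d @ axis
    if anterior_at_min:
        pass  # s measured from the min-z end
    else:
        axis = -axis
        z = -z
    probe = np.array([1.0, 0.0, 0.0])
    if abs(axis @ probe) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    e1 = probe - (probe @ axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    u = d @ e1
    v = d @ e2
    r = np.hypot(u, v)
    phi = np.mod(np.arctan2(v, u), 2 * np.pi)

    # spherical profile R(t, phi) about the centroid, with polar angle t
    # measured from the anterior direction: smooth everywhere, including
    # flat (oblate) caps where a z-binned radial profile degenerates
    R = np.hypot(r, z)
    t = np.arctan2(r, -z)  # 0 = anterior pole, pi = posterior pole
    n_t_bins = n_profile_bins
    tb = np.clip((t / np.pi * n_t_bins).astype(int), 0, n_t_bins - 1)
    pb = (phi / (2 * np.pi) * n_phi_bins).astype(int) % n_phi_bins
    flat = tb * n_phi_bins + pb
    n_bins = n_t_bins * n_phi_bins
    counts = np.bincount(flat, minlength=n_bins)
    sums = np.bincount(flat, weights=R, minlength=n_bins)
    sq = np.bincount(flat, weights=R * R, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_R = sums / counts
        var_R = sq / counts - mean_R**2
    mean_R = mean_R.reshape(n_t_bins, n_phi_bins)
    sd_R = np.sqrt(np.clip(var_R, 0, None)).reshape(n_t_bins, n_phi_bins)
    occupied = counts.reshape(n_t_bins, n_phi_bins) > 0
    # star-shapedness: radius spread inside an angular bin stays small
    good = occupied & (mean_R > 1e-9)
    bad = good & (sd_R > star_tolerance * np.maximum(mean_R, 1.0))
    if np.count_nonzero(bad) > 0.05 * np.count_nonzero(good):
        raise ValueError(
            "surface is not star-shaped about its centroid: "
            f"{np.count_nonzero(bad)} (t, phi) bins have multi-valued radii"
        )

    # fill unoccupied bins along phi (periodic interpolation)
    prof = np.where(occupied, mean_R, np.nan)
    for i in range(n_t_bins):
        row = prof[i]
        if np.isnan(row).all():
            prof[i] = np.nanmean(prof) if np.isfinite(prof).any() else 0.0
            continue
        if np.isnan(row).any():
            jj = np.arange(n_phi_bins)
            ok = ~np.isnan(row)
            prof[i] = np.interp(jj, jj[ok], row[ok], period=n_phi_bins)

    # azimuthal smoothing: truncated Fourier series (<= n_harmonics)
    Fc = np.fft.rfft(prof, axis=1)
    Fc[:, n_harmonics + 1:] = 0.0
    prof_s = np.fft.irfft(Fc, n=n_phi_bins, axis=1)
    mean_prof = prof_s.mean(axis=1)
    resid = prof_s - mean_prof[:, None]

    # local quadratic smoothing of the axisymmetric profile (scale-free)
    t_centers = (np.arange(n_t_bins) + 0.5) * np.pi / n_t_bins
    win = max(5, 2 * int(round(4.5 * max(smoothing, 0.1))) + 1)
    win = min(win, n_t_bins - (1 - n_t_bins % 2))
    R_s = savgol_filter(mean_prof, win, polyorder=2, mode="interp")

    # pole radii from even-symmetry quadratic regression on the raw cap
    # points (dR/dt = 0 at both poles for a smooth closed surface)
    def _pole_radius(t_local, fallback):
        m = t_local < t_centers[6]
        if np.count_nonzero(m) < 30:
            return fallback
        design = np.stack([np.ones(m.sum()), t_local[m] ** 2], axis=1)
        coef, *_ = np.linalg.lstsq(design, R[m], rcond=None)
        out = float(coef[0])
        return out if 0 < out < 2 * fallback else fallback

    R_ant = _pole_radius(t, R_s[0])
    R_post = _pole_radius(np.pi - t, R_s[-1])
    interp_R = PchipInterpolator(
        np.concatenate([[0.0], t_centers, [np.pi]]),
        np.concatenate([[R_ant], R_s, [R_post]]),
    )

    t_fine = np.linspace(0.0, np.pi, 8192)
    R_fine = np.clip(interp_R(t_fine), 0.0, None)
    z_fine = -R_fine * np.cos(t_fine)
    rho_fine = R_fine * np.sin(t_fine)
    seg = np.hypot(np.diff(z_fine), np.diff(rho_fine))
    s_cum = np.concatenate([[0.0], np.cumsum(seg)])
    L = float(s_cum[-1])

    s_grid = np.linspace(0.0, L, n_s)
    z_of_s = np.interp(s_grid, s_cum, z_fine)
    rho_axi = np.interp(s_grid, s_cum, rho_fine)
    t_of_s = np.interp(s_grid, s_cum, t_fine)
    phi_grid = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)
    # azimuthal-harmonic residual applied radially: delta_rho = delta_R sin t
    res_on_s = np.empty((n_s, n_phi))
    for j, pphi in enumerate(phi_grid):
        col = np.interp(pphi,
                        np.linspace(0, 2 * np.pi, n_phi_bins, endpoint=False),
                        np.arange(n_phi_bins), period=2 * np.pi)
        j0 = int(np.floor(col)) % n_phi_bins
        j1 = (j0 + 1) % n_phi_bins
        fj = col - np.floor(col)
        col_r = resid[:, j0] * (1 - fj) + resid[:, j1] * fj
        res_on_s[:, j] = np.interp(t_of_s, t_centers, col_r, left=0.0, right=0.0)
    rho = np.clip(rho_axi[:, None] + res_on_s * np.sin(t_of_s)[:, None], 0.0, None)
    rho[0] = rho[-1] = 0.0

    emb = (
        center
        + z_of_s[:, None, None] * axis
        + rho[:, :, None] * (np.cos(phi_grid)[None, :, None] * e1
                             + np.sin(phi_grid)[None, :, None] * e2)
    )
    param = SurfaceParam(
        axis=axis,
        center=center,
        anterior_pole=center + z_of_s[0] * axis,
        posterior_pole=center + z_of_s[-1] * axis,
        s_grid=s_grid,
        phi_grid=phi_grid,
        embedding=emb,
        rho=rho,
        z_of_s=z_of_s,
        L=L,
    )
    return param, metric_field(param)


# ---------------------------------------------------------------------------
# integral measurements
# ---------------------------------------------------------------------------

def surface_area(param: SurfaceParam, metric: MetricField | None = None) -> float:
    """Total area ∬ sqrt(det g) ds dφ over the full surface, μm²."""
    if metric is None:
        metric = metric_field(param)
    integrand = np.sqrt(np.clip(metric.det(), 0, None))
    ds = param.s_grid[1] - param.s_grid[0]
    dphi = param.phi_grid[1] - param.phi_grid[0]
    # phi is periodic: plain sum; s: trapezoid
    per_s = integrand.sum(axis=1) * dphi
    return float(np.trapezoid(per_s, dx=ds))


def enclosed_volume(
    mask: np.ndarray | None = None,
    voxel_size=None,
    param: SurfaceParam | None = None,
) -> float:
    """Enclosed volume in μm³.

    Mask path: voxel count × voxel volume.  Param path: solid-of-revolution
    quadrature ∫ (1/2)∮ ρ² dφ dz along the axis.  Exactly one input route
    must be given.
    """
    if (mask is None) == (param is None):
        raise ValueError("provide either a mask (with voxel_size) or a SurfaceParam")
    if mask is not None:
        if voxel_size is None:
            raise ValueError("voxel_size required with mask")
        voxel_size = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
        return float(np.count_nonzero(mask) * np.prod(voxel_size))
    if param.rho[0].max() > 1e-6 * param.L or param.rho[-1].max() > 1e-6 * param.L:
        raise ValueError("open surface: radial profile does not close at the poles")
    dphi = param.phi_grid[1] - param.phi_grid[0]
    cross = 0.5 * (param.rho**2).sum(axis=1) * dphi  # cross-section area per s node
    return float(np.trapezoid(cross, param.z_of_s))


# ---------------------------------------------------------------------------
# pullback projection
# ---------------------------------------------------------------------------

def _sample_volume(volume, voxel_size, points, fill=np.nan):
    coords = (points / voxel_size).T  # (3, N) fractional voxel indices
    return ndimage.map_coordinates(
        volume.astype(float), coords, order=1, mode="constant", cval=fill
    )


def _pixel_metric_from_positions(P: np.ndarray, wraps_phi: bool):
    """Metric in pixel units from the (H, W, 3) position map."""
    d0 = np.gradient(P, axis=0)
    if wraps_phi:
        d1 = (np.roll(P, -1, axis=1) - np.roll(P, 1, axis=1)) / 2.0
    else:
        d1 = np.gradient(P, axis=1)
    g11 = np.einsum("ijk,ijk->ij", d0, d0)
    g12 = np.einsum("ijk,ijk->ij", d0, d1)
    g22 = np.einsum("ijk,ijk->ij", d1, d1)
    return g11, g12, g22


def chart_grid(
    param: SurfaceParam,
    chart: str = "cylinder",
    pixel_size: float = 0.2,
    cap_angle_deg: float = DEFAULT_CAP_ANGLE_DEG,
    cap_overlap_deg: float = 10.0,
):
    """Per-pixel (s, phi) maps and pixel metric for a chart.

    Returns ``(s_map, phi_map, g11, g12, g22, valid, wraps_phi)``.  The cap
    angle is expressed as a fraction of the meridian (exact polar angle on a
    sphere).  ``chart='sphere'`` is the full closed chart (caps included),
    used by the synthetic generator and whole-organ integrals.
    """
    L = param.L
    if chart in ("cylinder", "sphere"):
        if chart == "cylinder":
            s_lo = L * cap_angle_deg / 180.0
            s_hi = L * (1 - cap_angle_deg / 180.0)
        else:
            s_lo, s_hi = 0.0, L
        n_rows = max(8, int(round((s_hi - s_lo) / pixel_size)) + 1)
        rho_eq = float(param.rho_profile(L / 2))
        n_cols = max(16, int(round(2 * np.pi * rho_eq / pixel_size)))
        s_map = np.repeat(np.linspace(s_lo, s_hi, n_rows)[:, None], n_cols, axis=1)
        phi_map = np.repeat(
            np.linspace(0, 2 * np.pi, n_cols, endpoint=False)[None, :], n_rows, axis=0
        )
        valid = np.ones_like(s_map, bool)
        P = param.point(s_map, phi_map)
        g11, g12, g22 = _pixel_metric_from_positions(P, wraps_phi=True)
        return s_map, phi_map, g11, g12, g22, valid, True
    if chart in ("polar_anterior", "polar_posterior"):
        s_max = L * (cap_angle_deg + cap_overlap_deg) / 180.0
        n = 2 * int(np.ceil(s_max / pixel_size)) + 1
        u = (np.arange(n) - n // 2) * pixel_size
        U, V = np.meshgrid(u, u, indexing="ij")
        s_loc = np.hypot(U, V)
        phi_map = np.mod(np.arctan2(V, U), 2 * np.pi)
        valid = s_loc <= s_max
        s_map = s_loc if chart == "polar_anterior" else L - s_loc
        s_map = np.clip(s_map, 0.0, L)
        P = param.point(s_map, phi_map)
        g11, g12, g22 = _pixel_metric_from_positions(P, wraps_phi=False)
        s_map = np.where(valid, s_map, np.nan)
        return s_map, phi_map, g11, g12, g22, valid, False
    raise ValueError(f"unknown chart {chart!r}")


def make_pullback(
    volume: np.ndarray,
    voxel_size,
    param: SurfaceParam,
    offsets=(3.0, 3.5, 4.0),
    slab: float = 0.5,
    chart: str = "cylinder",
    pixel_size: float = 0.2,
    cap_angle_deg: float = DEFAULT_CAP_ANGLE_DEG,
    fill_value: float = np.nan,
) -> Pullback:
    """Maximum-intensity projection of offset surfaces onto a chart.

    For each ``offset`` (μm, inward along the radial direction — the normal
    approximation for near-spheroids) the volume is sampled on the offset
    surface, with ``slab``-thick sub-sampling, and the projection is the
    pixel-wise maximum across offsets.  Pixels whose offset exceeds the
    local radius are filled with ``fill_value`` and marked invalid.
    """
    if slab <= 0:
        raise ValueError("slab must be > 0")
    offsets = tuple(float(o) for o in offsets)
    if any(o < 0 for o in offsets):
        raise ValueError("offsets must be inward (non-negative)")
    voxel_size = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    s_map, phi_map, g11, g12, g22, valid, wraps = chart_grid(
        param, chart=chart, pixel_size=pixel_size, cap_angle_deg=cap_angle_deg
    )
    P = param.point(np.nan_to_num(s_map), phi_map)
    # inward radial direction: toward the local axis point
    a, _, _ = param.frame()
    z_loc = np.einsum("ijk,k->ij", P - param.center, a)
    axis_pt = param.center + z_loc[..., None] * a
    radial = P - axis_pt
    r_len = np.linalg.norm(radial, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        inward = -radial / r_len[..., None]
    inward = np.nan_to_num(inward)

    best = np.full(s_map.shape, -np.inf)
    reachable = np.zeros(s_map.shape, bool)
    sub = np.linspace(-slab / 2, slab / 2, 3)
    for off in offsets:
        for d in sub:
            depth = off + d
            ok = r_len > depth
            pts = P + depth * inward
            vals = _sample_volume(volume, voxel_size, pts.reshape(-1, 3)).reshape(s_map.shape)
            vals = np.where(ok, vals, -np.inf)
            best = np.maximum(best, vals)
            reachable |= ok
    out_valid = valid & reachable & np.isfinite(best)
    img = np.where(out_valid, best, fill_value)
    if np.count_nonzero(~out_valid & valid):
        warnings.warn(
            f"{np.count_nonzero(~out_valid & valid)} pullback pixels exceed the "
            "local radius; filled with sentinel",
            stacklevel=2,
        )
    return Pullback(
        image=img,
        s_map=s_map,
        phi_map=phi_map,
        g11=g11,
        g12=g12,
        g22=g22,
        chart=chart,
        pixel_size=pixel_size,
        valid=out_valid,
        wraps_phi=wraps,
        offsets=offsets,
        slab=slab,
    )


def pullback_from_labels(
    param: SurfaceParam,
    image: np.ndarray,
    chart: str = "sphere",
    pixel_size: float = 0.2,
    cap_angle_deg: float = DEFAULT_CAP_ANGLE_DEG,
) -> Pullback:
    """Wrap a pre-made chart image (e.g. synthetic) with coordinate/metric maps.

    The image must have been rasterized on the grid produced by
    :func:`chart_grid` with identical arguments.
    """
    s_map, phi_map, g11, g12, g22, valid, wraps = chart_grid(
        param, chart=chart, pixel_size=pixel_size, cap_angle_deg=cap_angle_deg
    )
    if image.shape != s_map.shape:
        raise ValueError(f"image shape {image.shape} != chart shape {s_map.shape}")
    return Pullback(
        image=np.asarray(image),
        s_map=s_map,
        phi_map=phi_map,
        g11=g11,
        g12=g12,
        g22=g22,
        chart=chart,
        pixel_size=pixel_size,
        valid=valid,
        wraps_phi=wraps,
    )
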