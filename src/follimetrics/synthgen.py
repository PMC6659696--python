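"""Synthetic spheroidal epithelia, division events, and FRAP traces.

Everything downstream (surface fitting, segmentation, lattice topology,
per-cell shape, FRAP fitting) is validated against ground truth produced
here.  The generator is an artifact convention, not a biological model: it
emulates a monolayer epithelium wrapping a spheroid (100–900 cells, stages
where the organ is a near-surface-of-revolution), division midbody segments
with a stated angular distribution, and FRAP channel tables whose double
normalization yields a one-phase association recovery.

Cells are produced by an anisotropic centroidal-Voronoi tessellation on the
spheroid: seeds are relaxed by Lloyd iterations under a distance locally
stretched by ``k = 1/sqrt(1 - e²)`` along each cell's elongation axis, which
imposes the target eccentricity ``e`` and orientation bias.  Ground-truth
per-cell shape is measured on the resulting label field with the exact
surface metric, before rasterization noise enters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, ndimage

from .division import DivisionEvent
from .frap import FrapTrace
from .surface import (
    Pullback,
    SurfaceParam,
    chart_grid,
    pullback_from_labels,
    spheroid_param,
)

__all__ = [
    "SynthParams",
    "GroundTruth",
    "SyntheticEpithelium",
    "spheroid_truth",
    "make_spheroid",
    "make_epithelium",
    "make_division_events",
    "make_frap_trace",
]

# sub-seed tags so one global seed drives independent streams per operation
_SEED_SPHEROID = 11
_SEED_EPITHELIUM = 23
_SEED_DIVISION = 37
_SEED_FRAP = 53

DEFAULT_MEMBRANE = 1.0
DEFAULT_INTERIOR = 0.1


@dataclass
class SynthParams:
    """Stated world of one synthetic follicle.

    semi_axis_ap (a) runs along the A–P axis (volume axis 0); semi_axis_eq
    (b) is equatorial.  ``target_eccentricity`` is the per-cell eccentricity
    the relaxation imposes; ``orientation_bias`` orients cell long axes
    (latitudinal = 0°, meridional = 90°, or uniform) with von Mises
    concentration ``concentration``.
    """

    semi_axis_ap: float = 12.0
    semi_axis_eq: float = 10.0
    n_cells: int = 200
    target_eccentricity: float = 0.0
    orientation_bias: str = "uniform"   # latitudinal | meridional | uniform
    concentration: float = 0.0
    voxel_size: tuple = (0.2, 0.2, 0.2)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.semi_axis_ap <= 0 or self.semi_axis_eq <= 0:
            raise ValueError("semi-axes must be positive")
        if self.n_cells < 12:
            raise ValueError("n_cells must be >= 12")
        if not 0 <= self.target_eccentricity < 1:
            raise ValueError("target_eccentricity must be in [0, 1)")
        if self.orientation_bias not in ("latitudinal", "meridional", "uniform"):
            raise ValueError(f"unknown orientation_bias {self.orientation_bias!r}")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        vs = np.broadcast_to(np.asarray(self.voxel_size, dtype=float), (3,))
        if np.any(vs <= 0):
            raise ValueError("voxel sizes must be positive")
        self.voxel_size = tuple(vs)


@dataclass
class GroundTruth:
    """True per-cell and organ-level quantities of a synthetic epithelium.

    ``cells`` columns: cell, s, phi, cz/cy/cx, eccentricity and
    orientation_deg (metric-exact moments of the realized tessellation on a
    2× supersampled pre-noise assignment — these carry the intrinsic packing
    disorder of a Voronoi tessellation, see docs), eccentricity_target and
    axis_angle_deg (the imposed generating anisotropy), n_neighbors.
    """

    cells: pd.DataFrame
    neighbors: set               # frozenset pairs of 1-based cell labels
    organ: dict                  # surface_area, volume, meridian_length, circumference, aspect_ratio

    def __post_init__(self) -> None:
        for pair in self.neighbors:
            if len(pair) != 2:
                raise ValueError("neighbor pairs must link two distinct cells")


@dataclass
class SyntheticEpithelium:
    """Pullback membrane image plus full ground truth and the generating surface."""

    params: SynthParams
    param: SurfaceParam          # exact spheroid parameterization
    pullback: Pullback           # membrane image on the closed ('sphere') chart
    labels: np.ndarray           # ground-truth label field on the same chart, 1-based
    truth: GroundTruth
    seeds_xyz: np.ndarray        # (n_cells, 3) relaxed seed positions
    seed_axes_deg: np.ndarray    # (n_cells,) imposed elongation axis angles
    pixel_size: float

    @property
    def image(self) -> np.ndarray:
        return self.pullback.image

    def labels_on(self, pullback: Pullback) -> np.ndarray:
        """Rasterize the ground-truth tessellation onto another chart."""
        pts = self.param.point(
            np.nan_to_num(pullback.s_map), np.nan_to_num(pullback.phi_map)
        ).reshape(-1, 3)
        k = 1.0 / np.sqrt(1.0 - self.params.target_eccentricity**2)
        assign = _assign_anisotropic(
            pts.astype(np.float32),
            self.seeds_xyz.astype(np.float32),
            _seed_axes_3d(
                self.seeds_xyz,
                np.deg2rad(self.seed_axes_deg),
                self.params.semi_axis_ap,
                self.params.semi_axis_eq,
                self.param.center,
            ).astype(np.float32),
            k,
        )
        lab = (assign + 1).reshape(pullback.s_map.shape)
        return np.where(pullback.valid, lab, 0)


# ---------------------------------------------------------------------------
# organ-level truth
# ---------------------------------------------------------------------------

def spheroid_truth(a: float, b: float) -> dict:
    """Closed-form / quadrature organ quantities of the spheroid.

    Volume is analytic; surface area and meridian length come from
    high-resolution quadrature of the generating-ellipse integrals.
    """
    def ds_dtheta(theta):
        return np.sqrt(a**2 * np.sin(theta) ** 2 + b**2 * np.cos(theta) ** 2)

    L, _ = integrate.quad(ds_dtheta, 0.0, np.pi, limit=200)
    area, _ = integrate.quad(lambda t: 2 * np.pi * b * np.sin(t) * ds_dtheta(t),
                             0.0, np.pi, limit=200)
    return {
        "volume": 4.0 / 3.0 * np.pi * a * b**2,
        "surface_area": float(area),
        "meridian_length": float(L),
        "circumference": 2 * np.pi * b,
        "aspect_ratio": a / b,
    }


# ---------------------------------------------------------------------------
# voxel volumes
# ---------------------------------------------------------------------------

def make_spheroid(
    params: SynthParams,
    margin_voxels: int = 4,
    shape: tuple | None = None,
):
    """Voxelize the spheroid as interior mask + membrane-like shell image.

    Returns ``(mask, membrane, organ_truth)``.  The shell is an anti-aliased
    Gaussian ridge (sd ≈ 1 voxel) on the surface, signal 1.0 on the
    membrane, 0.1 interior, plus Gaussian noise.
    """
    a, b = params.semi_axis_ap, params.semi_axis_eq
    vs = np.asarray(params.voxel_size, dtype=float)
    extent = np.array([a, b, b])
    need = np.ceil(2 * extent / vs).astype(int) + 2 * margin_voxels
    if shape is None:
        shape = tuple(need)
    else:
        shape = tuple(shape)
        if any(s < n - 2 * margin_voxels + 4 for s, n in zip(shape, need)):
            raise ValueError(
                f"grid {shape} cannot contain the spheroid with a 2-voxel margin"
            )
    center = (np.asarray(shape) - 1) / 2.0 * vs
    zz = np.arange(shape[0]) * vs[0] - center[0]
    yy = np.arange(shape[1]) * vs[1] - center[1]
    xx = np.arange(shape[2]) * vs[2] - center[2]
    F = (
        (zz[:, None, None] / a) ** 2
        + (yy[None, :, None] / b) ** 2
        + (xx[None, None, :] / b) ** 2
    ).astype(np.float32)
    mask = F <= 1.0
    # approximate signed distance to the surface along the radial ray
    R = np.sqrt(
        zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
    ).astype(np.float32)
    sqF = np.sqrt(F, dtype=np.float32)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = R * np.abs(1.0 - 1.0 / sqF)
    dist = np.nan_to_num(dist, nan=np.inf)
    sigma = float(vs.mean())
    membrane = DEFAULT_INTERIOR * mask + (DEFAULT_MEMBRANE - DEFAULT_INTERIOR) * np.exp(
        -0.5 * (dist / sigma) ** 2
    )
    rng = np.random.default_rng([params.seed, _SEED_SPHEROID])
    if params.noise_sd > 0:
        membrane = membrane + rng.normal(0.0, params.noise_sd, membrane.shape)
    return mask.astype(np.uint8), membrane.astype(np.float32), spheroid_truth(a, b)


# ---------------------------------------------------------------------------
# anisotropic CVT epithelium
# ---------------------------------------------------------------------------

def _seed_axes_3d(seeds_xyz, theta_rad, a, b, center):
    """Unit 3D elongation axes from per-seed tangent frames and axis angles.

    ``theta`` is measured from the latitudinal direction (0°) toward the
    meridional direction (90°).
    """
    p = seeds_xyz - center
    z = p[:, 0]
    rho = np.hypot(p[:, 1], p[:, 2])
    phi = np.arctan2(p[:, 2], p[:, 1])
    # generating-ellipse angle: z = -a cos(t), rho = b sin(t)
    t = np.arctan2(np.clip(rho / b, 0, None), np.clip(-z / a, -1.5, 1.5))
    dz = a * np.sin(t)
    dr = b * np.cos(t)
    nrm = np.hypot(dz, dr)
    e_s = np.stack([dz / nrm, (dr / nrm) * np.cos(phi), (dr / nrm) * np.sin(phi)], axis=1)
    e_lat = np.stack([np.zeros_like(phi), -np.sin(phi), np.cos(phi)], axis=1)
    return (
        np.cos(theta_rad)[:, None] * e_lat + np.sin(theta_rad)[:, None] * e_s
    )


def _assign_anisotropic(X, seeds, axes, k, chunk=64):
    """Nearest-seed assignment under per-seed stretched chord distance.

    d² = |Δ|² − (1 − 1/k²)(Δ·u)² with u the seed's elongation axis; k ≥ 1.
    """
    c = 1.0 - 1.0 / (k * k)
    n_pix = X.shape[0]
    best = np.full(n_pix, np.inf, dtype=np.float32)
    assign = np.zeros(n_pix, dtype=np.int32)
    for lo in range(0, len(seeds), chunk):
        S = seeds[lo:lo + chunk]
        U = axes[lo:lo + chunk]
        diff = X[None, :, :] - S[:, None, :]
        d2 = np.einsum("spk,spk->sp", diff, diff)
        if c > 0:
            du = np.einsum("spk,sk->sp", diff, U)
            d2 -= c * du * du
        local_best = d2.argmin(axis=0)
        local_val = d2[local_best, np.arange(n_pix)]
        better = local_val < best
        best[better] = local_val[better]
        assign[better] = local_best[better].astype(np.int32) + lo
    return assign


def _project_to_spheroid(pts, a, b, center):
    p = pts - center
    F = (p[:, 0] / a) ** 2 + (p[:, 1] / b) ** 2 + (p[:, 2] / b) ** 2
    t = 1.0 / np.sqrt(np.maximum(F, 1e-12))
    return center + p * t[:, None]


def _draw_axis_angles(rng, n, bias, kappa):
    """Per-cell elongation axis angles in degrees from latitudinal, [0, 180)."""
    if bias == "uniform" or kappa == 0:
        return rng.uniform(0.0, 180.0, n)
    mu = 0.0 if bias == "latitudinal" else 90.0
    if np.isinf(kappa):
        return np.full(n, mu)
    # axes are pi-periodic: sample the doubled angle on the circle
    two_theta = rng.vonmises(2 * np.deg2rad(mu), kappa, n)
    return np.rad2deg(np.mod(two_theta / 2.0, np.pi))


def fold_angle(theta_deg):
    """Fold an axis angle into [0°, 90°] (0 = latitudinal, 90 = meridional)."""
    t = np.mod(np.asarray(theta_deg, dtype=float), 180.0)
    return np.where(t > 90.0, 180.0 - t, t)


def make_epithelium(
    params: SynthParams,
    pixel_size: float = 0.2,
    n_iter: int = 80,
    tol: float = 2e-3,
) -> SyntheticEpithelium:
    """Generate a membrane pullback image with full ground truth.

    Seeds are placed area-uniformly on the spheroid and relaxed by Lloyd
    iterations of an anisotropic Voronoi tessellation (3D chord distance
    stretched along each cell's elongation axis).  Cell boundaries are then
    rasterized into the closed cylinder-chart pullback as a ~2-pixel
    anti-aliased membrane (1.0 on membrane, 0.1 interior) plus Gaussian
    noise.  Non-convergence after ``n_iter`` iterations raises a warning
    carrying the residual.
    """
    a, b = params.semi_axis_ap, params.semi_axis_eq
    rng = np.random.default_rng([params.seed, _SEED_EPITHELIUM])
    param = spheroid_param(a, b, grid_step=pixel_size)
    s_map, phi_map, g11, g12, g22, valid, _ = chart_grid(
        param, chart="sphere", pixel_size=pixel_size
    )
    H, W = s_map.shape
    X = param.point(s_map, phi_map).reshape(-1, 3).astype(np.float32)
    w = np.sqrt(np.clip(g11 * g22 - g12**2, 0, None)).ravel().astype(np.float32)

    n = params.n_cells
    probs = (w / w.sum()).astype(np.float64)
    probs /= probs.sum()
    # Fibonacci-lattice initialization: near-uniform packing from the start,
    # randomized by a global azimuth rotation and a small jitter
    i = np.arange(n)
    zs = (1.0 - 2.0 * (i + 0.5) / n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phis = np.mod(i * golden + rng.uniform(0, 2 * np.pi), 2 * np.pi)
    rs = np.sqrt(np.clip(1.0 - zs**2, 0, None))
    seeds = param.center + np.stack(
        [a * zs, b * rs * np.cos(phis), b * rs * np.sin(phis)], axis=1
    )
    spacing = np.sqrt(spheroid_truth(a, b)["surface_area"] / n)
    seeds = seeds + rng.normal(0.0, 0.1 * spacing, seeds.shape)
    seeds = _project_to_spheroid(seeds, a, b, param.center)
    theta_deg = _draw_axis_angles(rng, n, params.orientation_bias, params.concentration)
    k = 1.0 / np.sqrt(1.0 - params.target_eccentricity**2)

    residual = np.inf
    assign = None
    for _ in range(n_iter):
        axes = _seed_axes_3d(seeds, np.deg2rad(theta_deg), a, b, param.center)
        assign = _assign_anisotropic(
            X, seeds.astype(np.float32), axes.astype(np.float32), k
        )
        wsum = np.bincount(assign, weights=w, minlength=n)
        new = np.empty_like(seeds)
        for m in range(3):
            new[:, m] = np.bincount(assign, weights=w * X[:, m], minlength=n)
        empty = wsum <= 0
        if empty.any():
            refill = rng.choice(len(X), size=int(empty.sum()), p=probs)
            new[empty] = X[refill]
            wsum[empty] = 1.0
        new /= np.maximum(wsum, 1e-12)[:, None]
        # over-relaxed Lloyd step for faster convergence
        new = seeds + 1.7 * (new - seeds)
        new = _project_to_spheroid(new, a, b, param.center)
        residual = float(np.linalg.norm(new - seeds, axis=1).max()) / 1.7
        seeds = new
        if residual < tol:
            break
    if residual >= tol * 10:
        warnings.warn(
            f"centroidal-Voronoi relaxation did not converge after {n_iter} "
            f"iterations (residual {residual:.4f} μm)",
            stacklevel=2,
        )
    axes = _seed_axes_3d(seeds, np.deg2rad(theta_deg), a, b, param.center)
    assign = _assign_anisotropic(X, seeds.astype(np.float32), axes.astype(np.float32), k)
    labels = (assign + 1).reshape(H, W).astype(np.int32)

    # ---- ground truth on a 2x supersampled pre-noise assignment ----
    fs_map, fphi_map, fg11, fg12, fg22, _, _ = chart_grid(
        param, chart="sphere", pixel_size=pixel_size / 2
    )
    fH, fW = fs_map.shape
    Xf = param.point(fs_map, fphi_map).reshape(-1, 3).astype(np.float32)
    wf = np.sqrt(np.clip(fg11 * fg22 - fg12**2, 0, None)).ravel().astype(np.float32)
    assign_f = _assign_anisotropic(
        Xf, seeds.astype(np.float32), axes.astype(np.float32), k
    )
    labels_f = (assign_f + 1).reshape(fH, fW)
    neighbors = _label_adjacency(labels_f, wrap_phi=True)
    cells = _true_cell_table(
        labels_f, Xf.reshape(fH, fW, 3), wf.reshape(fH, fW), fs_map, fphi_map,
        a, b, param.center, neighbors,
    )
    cells["eccentricity_target"] = params.target_eccentricity
    cells["axis_angle_deg"] = fold_angle(theta_deg)
    organ = spheroid_truth(a, b)

    # ---- membrane raster ----
    boundary = np.zeros((H, W), bool)
    boundary |= labels != np.roll(labels, 1, axis=1)
    vert = labels != np.roll(labels, 1, axis=0)
    vert[0] = False
    boundary |= vert
    boundary = ndimage.binary_dilation(boundary, iterations=1)
    ridge = ndimage.gaussian_filter(boundary.astype(np.float32), 0.5)
    ridge /= max(ridge.max(), 1e-9)
    img = DEFAULT_INTERIOR + (DEFAULT_MEMBRANE - DEFAULT_INTERIOR) * ridge
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, img.shape)
    pullback = pullback_from_labels(param, img.astype(np.float32), chart="sphere",
                                    pixel_size=pixel_size)
    truth = GroundTruth(cells=cells, neighbors=neighbors, organ=organ)
    return SyntheticEpithelium(
        params=params,
        param=param,
        pullback=pullback,
        labels=labels,
        truth=truth,
        seeds_xyz=seeds,
        seed_axes_deg=theta_deg,
        pixel_size=pixel_size,
    )


def _label_adjacency(labels: np.ndarray, wrap_phi: bool) -> set:
    """Symmetric 4-adjacency pairs of a label field (φ-periodic columns)."""
    pairs = set()

    def collect(A, B):
        diff = A != B
        a, bb = A[diff].ravel(), B[diff].ravel()
        for x, y in zip(a.tolist(), bb.tolist()):
            if x > 0 and y > 0:
                pairs.add(frozenset((x, y)))

    collect(labels[:, 1:], labels[:, :-1])
    collect(labels[1:, :], labels[:-1, :])
    if wrap_phi:
        collect(labels[:, :1], labels[:, -1:])
    return pairs


def _true_cell_table(labels, X3, w, s_map, phi_map, a, b, center, neighbors):
    n = labels.max()
    flat = labels.ravel() - 1
    wf = w.ravel()
    Xf = X3.reshape(-1, 3)
    wsum = np.bincount(flat, weights=wf, minlength=n)
    c3 = np.stack(
        [np.bincount(flat, weights=wf * Xf[:, m], minlength=n) for m in range(3)],
        axis=1,
    ) / np.maximum(wsum, 1e-12)[:, None]
    c3 = _project_to_spheroid(c3, a, b, center)
    s_mean = np.bincount(flat, weights=wf * s_map.ravel(), minlength=n) / np.maximum(wsum, 1e-12)
    cphi = np.arctan2(
        np.bincount(flat, weights=wf * np.sin(phi_map.ravel()), minlength=n),
        np.bincount(flat, weights=wf * np.cos(phi_map.ravel()), minlength=n),
    ) % (2 * np.pi)
    deg = np.zeros(n, dtype=int)
    for pair in neighbors:
        for lab in pair:
            deg[lab - 1] += 1

    ecc = np.full(n, np.nan)
    ori = np.full(n, np.nan)
    frames = _tangent_frames(c3, a, b, center)
    order = np.argsort(flat, kind="stable")
    sorted_lab = flat[order]
    starts = np.searchsorted(sorted_lab, np.arange(n))
    ends = np.searchsorted(sorted_lab, np.arange(n) + 1)
    for i in range(n):
        idx = order[starts[i]:ends[i]]
        if len(idx) < 10:
            continue
        d = Xf[idx] - c3[i]
        u = d @ frames[0][i]  # latitudinal component
        v = d @ frames[1][i]  # meridional component
        ww = wf[idx]
        cov = np.array([
            [np.average(u * u, weights=ww), np.average(u * v, weights=ww)],
            [np.average(u * v, weights=ww), np.average(v * v, weights=ww)],
        ])
        evals, evecs = np.linalg.eigh(cov)
        lam2, lam1 = evals  # ascending
        if lam1 <= 0:
            continue
        e = float(np.sqrt(max(0.0, 1.0 - lam2 / lam1)))
        ecc[i] = e
        if e > 0.05:
            vec = evecs[:, 1]
            ori[i] = fold_angle(np.rad2deg(np.arctan2(vec[1], vec[0])))
    df = pd.DataFrame({
        "cell": np.arange(1, n + 1),
        "s": s_mean,
        "phi": cphi,
        "cz": c3[:, 0],
        "cy": c3[:, 1],
        "cx": c3[:, 2],
        "eccentricity": ecc,
        "orientation_deg": ori,
        "n_neighbors": deg,
    })
    return df


def _tangent_frames(points, a, b, center):
    """(e_lat, e_s) unit tangent vectors at 3D points on the spheroid."""
    p = points - center
    z = p[:, 0]
    rho = np.hypot(p[:, 1], p[:, 2])
    phi = np.arctan2(p[:, 2], p[:, 1])
    t = np.arctan2(np.clip(rho / b, 0, None), np.clip(-z / a, -1.5, 1.5))
    dz = a * np.sin(t)
    dr = b * np.cos(t)
    nrm = np.maximum(np.hypot(dz, dr), 1e-12)
    e_s = np.stack([dz / nrm, (dr / nrm) * np.cos(phi), (dr / nrm) * np.sin(phi)], axis=1)
    e_lat = np.stack([np.zeros_like(phi), -np.sin(phi), np.cos(phi)], axis=1)
    return e_lat, e_s


# ---------------------------------------------------------------------------
# division events
# ---------------------------------------------------------------------------

def make_division_events(
    n: int,
    distribution: str = "uniform",
    mu_deg: float = 90.0,
    kappa: float | None = None,
    seed: int = 0,
    param: SurfaceParam | None = None,
    separation: float = 2.0,
    stage_group: str | None = None,
) -> list[DivisionEvent]:
    """Surface segments a fixed geodesic distance apart with stated axis angles.

    ``distribution`` is ``uniform`` (axis angle uniform on [0°, 180°)) or
    ``vonmises`` with mean ``mu_deg`` and concentration ``kappa`` (sampled on
    the doubled-angle circle since axes are π-periodic).  Midpoints are
    placed area-uniformly away from the poles of ``param`` (default: sphere
    of radius 20 μm).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if distribution not in ("uniform", "vonmises"):
        raise ValueError(f"unknown distribution {distribution!r}")
    if distribution == "vonmises":
        if kappa is None:
            raise ValueError("vonmises distribution requires kappa")
        if kappa < 0:
            raise ValueError("kappa must be >= 0")
    rng = np.random.default_rng([seed, _SEED_DIVISION])
    if param is None:
        param = spheroid_param(20.0, 20.0)
    if distribution == "uniform":
        theta = rng.uniform(0.0, 180.0, n)
    elif np.isinf(kappa):
        theta = np.full(n, mu_deg)
    elif kappa == 0:
        theta = rng.uniform(0.0, 180.0, n)
    else:
        theta = np.rad2deg(
            np.mod(rng.vonmises(2 * np.deg2rad(mu_deg), kappa, n) / 2.0, np.pi)
        )
    # area-uniform arc positions away from the poles
    rho_bar = param.rho.mean(axis=1)
    lo, hi = 0.12 * param.L, 0.88 * param.L
    band = (param.s_grid >= lo) & (param.s_grid <= hi)
    cdf = np.cumsum(rho_bar * band)
    cdf /= cdf[-1]
    s_mid = np.interp(rng.uniform(0, 1, n), cdf, param.s_grid)
    phi_mid = rng.uniform(0.0, 2 * np.pi, n)
    rho_mid = np.interp(s_mid, param.s_grid, rho_bar)
    h = separation / 2.0
    th = np.deg2rad(theta)
    ds = h * np.sin(th)
    dphi = h * np.cos(th) / np.maximum(rho_mid, 1e-9)
    events = []
    for i in range(n):
        events.append(DivisionEvent(
            s1=float(s_mid[i] - ds[i]),
            phi1=float(np.mod(phi_mid[i] - dphi[i], 2 * np.pi)),
            s2=float(s_mid[i] + ds[i]),
            phi2=float(np.mod(phi_mid[i] + dphi[i], 2 * np.pi)),
            stage_group=stage_group,
        ))
    return events


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------

def make_frap_trace(
    Y0: float,
    P: float,
    K: float,
    duration: float = 300.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    ref_bleach_rate: float = 0.0,
    n_prebleach: int = 5,
) -> FrapTrace:
    """Raw FRAP channels whose double normalization recovers the stated curve.

    The recovery is ``f(t) = Y0 + (P − Y0)(1 − exp(−K t))`` with Gaussian
    noise of sd ``noise_sd`` added on the normalized scale; the reference
    channel decays exponentially at ``ref_bleach_rate`` (s⁻¹) to emulate
    acquisition photobleaching, which the normalization cancels exactly.
    """
    if not (0 <= Y0 <= P <= 1.5):
        raise ValueError("require 0 <= Y0 <= P <= 1.5")
    if K <= 0:
        raise ValueError("K must be > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rng = np.random.default_rng([seed, _SEED_FRAP])
    t = np.arange(0.0, duration + 0.5 * dt, dt)
    f = Y0 + (P - Y0) * (1.0 - np.exp(-K * t))
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, f.shape)
    bg = 10.0
    c_ref = 80.0
    c_pre = 100.0
    decay = np.exp(-ref_bleach_rate * t)
    y_ref = bg + c_ref * decay
    y_bl = bg + c_pre * decay * f
    y_bg = np.full_like(t, bg)
    return FrapTrace(
        t=t,
        y_bl=y_bl,
        y_ref=y_ref,
        y_bg=y_bg,
        y_pre=bg + c_pre,
        y_ref0=bg + c_ref,
        y_bg0=bg,
    )
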