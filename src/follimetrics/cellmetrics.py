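"""Metric-corrected per-cell area, eccentricity, orientation, and regions.

Cell area is the integral of sqrt(det g) over the cell's pixels — the true
surface area regardless of chart distortion.  Shape comes from the second
moments of the cell's pixels expressed in locally orthonormalized
coordinates (chart axes rescaled by the matrix square root of the metric at
the centroid; valid while cells are small against the curvature radius).
Eccentricity is e = sqrt(1 − λ₂/λ₁) of the moment eigenvalues — equal to
sqrt(1 − (minor/major)²) of the best-fit ellipse, matching a 0–0.83 display
scale that an aspect ratio (≥ 1) could not.  Orientation is the angle of
the λ₁ eigenvector to the latitudinal direction folded into [0°, 90°]
(90° = meridional/A–P), defined only when e > 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lattice import LabelImage
from .surface import Pullback, SurfaceParam

__all__ = [
    "ECC_ORIENTATION_FLOOR",
    "cell_area",
    "cell_shape",
    "assign_region",
    "orientation_distribution",
    "measure_cells",
]

ECC_ORIENTATION_FLOOR = 0.05  # below this the long axis is noise
REGIONS = ("A-1/3", "M-1/3", "P-1/3")


def _local_sqrt_metric(g11, g12, g22):
    """Symmetric square root of the 2×2 metric [[g11, g12], [g12, g22]]."""
    g = np.array([[g11, g12], [g12, g22]], dtype=float)
    evals, evecs = np.linalg.eigh(g)
    evals = np.clip(evals, 0, None)
    return evecs @ np.diag(np.sqrt(evals)) @ evecs.T


def cell_area(mask: np.ndarray, pullback: Pullback) -> float:
    """Area of one cell (boolean pixel mask) in μm²: Σ sqrt(det g) per pixel."""
    if not mask.any():
        raise ValueError("zero-pixel face")
    return float(pullback.pixel_area[mask].sum())


def cell_areas(label_image: LabelImage, pullback: Pullback) -> pd.DataFrame:
    """Vectorized per-cell areas for a whole label field."""
    labels = label_image.labels
    pa = pullback.pixel_area
    flat = labels.ravel()
    areas = np.bincount(flat, weights=pa.ravel())
    uniq = np.unique(flat[flat > 0])
    return pd.DataFrame({"cell": uniq, "area": areas[uniq]})


def cell_shape(mask: np.ndarray, pullback: Pullback) -> tuple[float, float]:
    """(eccentricity, orientation°) of one cell from metric-corrected moments.

    Returns orientation NaN (sentinel) for near-circular cells
    (e ≤ 0.05) and raises on degenerate (< 10 pixel or collinear) faces.
    """
    ii, jj = np.nonzero(mask)
    if len(ii) < 10:
        raise ValueError(f"face has {len(ii)} pixels; need >= 10")
    W = mask.shape[1]
    ci = ii.mean()
    # centroid column with seam wrap
    if pullback.wraps_phi:
        ang = jj * (2 * np.pi / W)
        cj_ang = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
        dj = (jj - cj_ang / (2 * np.pi / W) + W / 2) % W - W / 2
        cj = (cj_ang / (2 * np.pi / W)) % W
    else:
        cj = jj.mean()
        dj = jj - cj
    di = ii - ci
    i0 = int(round(np.clip(ci, 0, mask.shape[0] - 1)))
    j0 = int(round(cj)) % W
    A = _local_sqrt_metric(
        pullback.g11[i0, j0], pullback.g12[i0, j0], pullback.g22[i0, j0]
    )
    xy = A @ np.stack([di, dj])
    cov = xy @ xy.T / len(ii)
    evals, evecs = np.linalg.eigh(cov)
    lam2, lam1 = np.clip(evals, 0, None)
    if lam1 <= 0:
        raise ValueError("degenerate face: zero principal moment")
    e = float(np.sqrt(1.0 - lam2 / lam1))
    if e <= ECC_ORIENTATION_FLOOR:
        return e, float("nan")
    v = evecs[:, 1]                      # principal axis in orthonormal coords
    lat = A @ np.array([0.0, 1.0])       # image of the latitudinal chart axis
    lat /= np.linalg.norm(lat)
    mer = A @ np.array([1.0, 0.0])
    mer /= np.linalg.norm(mer)
    ang = np.degrees(np.arctan2(v @ mer, v @ lat)) % 180.0
    if ang > 90.0:
        ang = 180.0 - ang
    return e, float(ang)


def assign_region(s: float, L: float, tol: float = 1e-9) -> str:
    """Anterior / middle / posterior third along the meridian.

    A if s < L/3, M if L/3 ≤ s < 2L/3, else P; the posterior boundary s = L
    is inclusive.
    """
    if s < -tol or s > L + tol:
        raise ValueError(f"arc position s={s} outside [0, L={L}]")
    s = min(max(s, 0.0), L)
    if s < L / 3:
        return "A-1/3"
    if s < 2 * L / 3:
        return "M-1/3"
    return "P-1/3"


def orientation_distribution(
    orientations_deg,
    bandwidth: float | None = None,
    grid: np.ndarray | None = None,
) -> dict:
    """Reflected-boundary kernel density of cell orientations on [0°, 90°].

    Orientations are folded axis angles, so the density is reflected at both
    0 and 90 to remove boundary bias; it integrates to 1 over [0, 90].
    Returns the evaluation grid, density, and the per-sample mean.
    """
    ang = np.asarray(orientations_deg, dtype=float)
    ang = ang[np.isfinite(ang)]
    if len(ang) < 20:
        raise ValueError(f"need >= 20 cells with defined orientation (got {len(ang)})")
    if grid is None:
        grid = np.linspace(0.0, 90.0, 361)
    augmented = np.concatenate([ang, -ang, 180.0 - ang])
    if bandwidth is None:
        kde = stats.gaussian_kde(augmented, bw_method=len(ang) ** (-1.0 / 5.0))
    else:
        kde = stats.gaussian_kde(augmented, bw_method=bandwidth / augmented.std(ddof=1))
    dens = kde(grid) * 3.0
    dens /= np.trapezoid(dens, grid)
    return {
        "grid": grid,
        "density": dens,
        "mean": float(ang.mean()),
        "n": int(len(ang)),
    }


def measure_cells(
    label_image: LabelImage,
    pullback: Pullback,
    param: SurfaceParam,
    lattice=None,
    fill: bool = True,
) -> pd.DataFrame:
    """Full per-cell record table for a segmented pullback.

    Columns: cell, s, phi, cz, cy, cx, area, eccentricity, orientation_deg,
    n_neighbors (if a lattice is given), region, boundary.  With ``fill``
    (default) membrane/skeleton pixels are apportioned to the nearest cell
    so that cell areas partition the chart (Σ areas = total surface area on
    closed charts).
    """
    from .lattice import _fill_labels

    labels = label_image.labels
    if fill:
        labels = _fill_labels(labels, label_image.wraps_phi)
    uniq = np.unique(labels[labels > 0])
    pa = pullback.pixel_area
    s_map = pullback.s_map
    phi_map = pullback.phi_map
    records = []
    nbr = {}
    if lattice is not None:
        nbr = {lab: f["n_neighbors"] for lab, f in lattice.faces.items()}
    for lab in uniq:
        mask = labels == lab
        w = pa[mask]
        wsum = w.sum()
        s_c = float((s_map[mask] * w).sum() / wsum)
        ph = phi_map[mask]
        phi_c = float(np.arctan2((np.sin(ph) * w).sum(), (np.cos(ph) * w).sum()) % (2 * np.pi))
        xyz = param.point(s_c, phi_c)
        try:
            e, ori = cell_shape(mask, pullback)
        except ValueError:
            e, ori = np.nan, np.nan
        records.append({
            "cell": int(lab),
            "s": s_c,
            "phi": phi_c,
            "cz": float(xyz[0]), "cy": float(xyz[1]), "cx": float(xyz[2]),
            "area": float(wsum),
            "eccentricity": e,
            "orientation_deg": ori,
            "n_neighbors": nbr.get(int(lab), np.nan),
            "region": assign_region(s_c, param.L),
            "boundary": int(lab) in label_image.boundary_labels,
        })
    return pd.DataFrame(records)
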