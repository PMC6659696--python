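"""Cell segmentation and the vertex/bond/face lookup table.

Membrane-bright pullback images are thresholded, the membrane skeletonized,
and the complementary regions labelled as cells (labels unified across the
azimuthal seam).  From a label field the lattice lookup table is built:
junction points where ≥3 cells meet become vertices, shared boundary
segments become bonds, and cells are faces whose neighbor number is their
bond count.  Charts whose column axis is periodic in φ are handled
throughout; on closed (whole-surface) charts the lattice satisfies the
Euler relation V − E + F = 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import skeletonize
from skimage.segmentation import expand_labels

from .surface import Pullback

__all__ = ["LabelImage", "CellLattice", "segment_cells", "build_lattice", "neighbor_stats"]

_PAD = 16  # column padding used to make skeletonization seam-aware


@dataclass
class LabelImage:
    """2D integer cell label field; 0 = membrane/background."""

    labels: np.ndarray
    wraps_phi: bool = True
    closed: bool = False            # True when the chart covers the whole surface
    pixel_area: np.ndarray | None = None  # μm² per pixel, same shape
    boundary_labels: set = field(default_factory=set)

    @property
    def n_cells(self) -> int:
        return len(np.unique(self.labels[self.labels > 0]))


class _UnionFind:
    def __init__(self, n):
        self.p = list(range(n))

    def find(self, x):
        while self.p[x] != x:
            self.p[x] = self.p[self.p[x]]
            x = self.p[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.p[rb] = ra


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_cells(
    pullback,
    threshold: float | None = None,
    min_cell_area: float = 3.0,
    expected_cells: int | None = None,
    wraps_phi: bool | None = None,
    closed: bool | None = None,
    pixel_area=None,
) -> LabelImage:
    """Threshold membrane signal, skeletonize, and label cell interiors.

    ``pullback`` may be a :class:`~follimetrics.surface.Pullback` (pixel
    areas taken from its metric) or a plain 2D array (optionally with a
    scalar or per-pixel ``pixel_area`` in μm²).  The default threshold is
    Otsu's on the valid pixels.  Regions smaller than ``min_cell_area`` μm²
    are discarded; labels are unified across the φ seam.
    """
    if isinstance(pullback, Pullback):
        img = np.asarray(pullback.image, dtype=float)
        valid = pullback.valid
        if wraps_phi is None:
            wraps_phi = pullback.wraps_phi
        if closed is None:
            closed = pullback.chart == "sphere"
        pa = pullback.pixel_area
    else:
        img = np.asarray(pullback, dtype=float)
        valid = np.isfinite(img)
        if wraps_phi is None:
            wraps_phi = True
        if closed is None:
            closed = False
        if pixel_area is None:
            pa = np.ones_like(img)
        else:
            pa = np.broadcast_to(np.asarray(pixel_area, dtype=float), img.shape)
    if threshold is None:
        threshold = float(threshold_otsu(img[valid]))
    membrane = (img >= threshold) & valid

    if wraps_phi:
        tiled = np.concatenate([membrane[:, -_PAD:], membrane, membrane[:, :_PAD]], axis=1)
        skel = skeletonize(tiled)[:, _PAD:-_PAD]
    else:
        skel = skeletonize(membrane)
    interior = valid & ~skel
    labels = sk_label(interior, connectivity=1)

    if wraps_phi:
        uf = _UnionFind(labels.max() + 1)
        left, right = labels[:, 0], labels[:, -1]
        for a, b in zip(left.tolist(), right.tolist()):
            if a > 0 and b > 0:
                uf.union(a, b)
        roots = np.array([uf.find(i) for i in range(labels.max() + 1)])
        labels = roots[labels]

    # area filter in μm²
    areas = np.bincount(labels.ravel(), weights=pa.ravel())
    small = np.flatnonzero(areas < min_cell_area)
    if small.size:
        kill = np.isin(labels, small[small > 0])
        labels = np.where(kill, 0, labels)
    # compact, deterministic relabelling
    uniq = np.unique(labels[labels > 0])
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[uniq] = np.arange(1, len(uniq) + 1)
    labels = remap[labels]

    boundary_labels = set()
    if not closed:
        boundary_labels |= set(np.unique(labels[0])) | set(np.unique(labels[-1]))
        if not wraps_phi:
            boundary_labels |= set(np.unique(labels[:, 0])) | set(np.unique(labels[:, -1]))
        boundary_labels.discard(0)

    n = len(uniq)
    if n <= 1 and expected_cells is not None and expected_cells > 1:
        raise ValueError("segmentation produced a single region (blank image?)")
    if expected_cells is not None and n > 2 * expected_cells:
        warnings.warn(
            f"over-fragmentation: {n} labels vs {expected_cells} expected cells",
            stacklevel=2,
        )
    return LabelImage(
        labels=labels.astype(np.int32),
        wraps_phi=wraps_phi,
        closed=closed,
        pixel_area=np.asarray(pa, dtype=float),
        boundary_labels=boundary_labels,
    )


# ---------------------------------------------------------------------------
# lattice construction
# ---------------------------------------------------------------------------

@dataclass
class CellLattice:
    """Lookup table of vertices, bonds, and faces.

    vertices: list of ``{"pos": (row, col), "labels": set}``.
    bonds: list of ``{"labels": frozenset, "pixels": (m, 2) array,
    "vertices": [vertex ids]}``.
    faces: dict label -> ``{"bonds": [bond ids], "n_neighbors": int,
    "boundary": bool}``.
    """

    vertices: list
    bonds: list
    faces: dict
    closed: bool

    @property
    def V(self) -> int:
        return len(self.vertices)

    @property
    def E(self) -> int:
        return len(self.bonds)

    @property
    def F(self) -> int:
        return len(self.faces)

    def euler_characteristic(self) -> int:
        return self.V - self.E + self.F

    def neighbor_pairs(self) -> set:
        return {b["labels"] for b in self.bonds}

    def vertex_degrees(self) -> np.ndarray:
        """Bond-incidence degree of each vertex."""
        deg = np.zeros(self.V, dtype=int)
        for b in self.bonds:
            for vid in b["vertices"]:
                deg[vid] += 1
        return deg

    def is_three_regular(self) -> bool:
        return bool(np.all(self.vertex_degrees() == 3))

    def validate(self) -> list:
        """Report faces whose boundary fails to close (odd vertex use)."""
        bad = []
        for lab, f in self.faces.items():
            if f["boundary"]:
                continue
            use = {}
            for bid in f["bonds"]:
                for vid in self.bonds[bid]["vertices"]:
                    use[vid] = use.get(vid, 0) + 1
            odd = [v for v, c in use.items() if c % 2]
            if odd:
                bad.append((lab, [tuple(self.vertices[v]["pos"]) for v in odd]))
        return bad


def _fill_labels(labels: np.ndarray, wraps_phi: bool) -> np.ndarray:
    """Expand labels to cover membrane/skeleton pixels (0s)."""
    if not (labels == 0).any():
        return labels
    if wraps_phi:
        tiled = np.concatenate([labels[:, -_PAD:], labels, labels[:, :_PAD]], axis=1)
        out = expand_labels(tiled, distance=6)[:, _PAD:-_PAD]
    else:
        out = expand_labels(labels, distance=6)
    if (out == 0).any():
        out = expand_labels(out, distance=max(out.shape))
    return out


def build_lattice(label_image: LabelImage) -> CellLattice:
    """Vertices, bonds, and faces from a label field.

    Junction corners (2×2 pixel blocks with ≥3 distinct labels) are
    clustered into vertices; the shared boundary between each adjacent label
    pair is split into connected components, each a bond.  On closed charts
    the polar image rows are treated as single points, so bond runs meeting
    at a pole are merged and a pole junction of ≥3 cells becomes a vertex.
    Vertices where only two faces meet (degree 2) never arise because bonds
    are maximal boundary components.
    """
    labels = _fill_labels(np.asarray(label_image.labels), label_image.wraps_phi)
    H, W = labels.shape
    wrap = label_image.wraps_phi

    # ---- junction corners ----
    A = labels[:-1, :]
    C = labels[1:, :]
    if wrap:
        B = np.roll(labels, -1, axis=1)[:-1, :]
        D = np.roll(labels, -1, axis=1)[1:, :]
        block = np.stack([A, B, C, D])
    else:
        A, B = labels[:-1, :-1], labels[:-1, 1:]
        C, D = labels[1:, :-1], labels[1:, 1:]
        block = np.stack([A, B, C, D])
    srt = np.sort(block, axis=0)
    distinct = 1 + (np.diff(srt, axis=0) > 0).sum(axis=0)
    corner = distinct >= 3

    # cluster corner pixels into junction vertices, but only across pixels
    # that describe the SAME junction (one label set contains the other);
    # two distinct 3-way vertices joined by a short bond stay separate
    corner_idx = {}
    corner_sets = []
    for i, j in zip(*np.nonzero(corner)):
        corner_idx[(i, j)] = len(corner_sets)
        corner_sets.append(frozenset(int(v) for v in block[:, i, j]))
    uf = _UnionFind(len(corner_sets))
    for (i, j), a in corner_idx.items():
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                jj = (j + dj) % W if wrap else j + dj
                bkey = (i + di, jj)
                b = corner_idx.get(bkey)
                if b is None or b <= a:
                    continue
                sa, sb = corner_sets[a], corner_sets[b]
                if sa <= sb or sb <= sa:
                    uf.union(a, b)
    clusters = {}
    for (i, j), a in corner_idx.items():
        clusters.setdefault(uf.find(a), []).append((i, j))
    vertices = []
    for root in sorted(clusters):
        pix = clusters[root]
        labs = set()
        for p in pix:
            labs |= corner_sets[corner_idx[p]]
        ii = np.array([p[0] for p in pix], float)
        jj = np.array([p[1] for p in pix], float)
        vertices.append({"pos": (float(ii.mean()) + 0.5, float(jj.mean()) + 0.5),
                         "labels": labs})

    # pole vertices on closed charts: >= 3 labels meeting in a polar row
    pole_vertex = {}
    if label_image.closed:
        for row, name in ((0, "anterior"), (H - 1, "posterior")):
            labs = set(int(v) for v in np.unique(labels[row]))
            if len(labs) >= 3:
                pole_vertex[name] = len(vertices)
                vertices.append({"pos": (float(row), np.nan), "labels": labs})

    # ---- boundary edge elements per adjacent pair ----
    elements = {}  # frozenset pair -> list of (2i, 2j) doubled-grid coords

    def add_elements(mask, coords_fn, lab_a, lab_b):
        ii, jj = np.nonzero(mask)
        for i, j in zip(ii, jj):
            pa, pb = int(lab_a[i, j]), int(lab_b[i, j])
            if pa != pb:
                elements.setdefault(frozenset((pa, pb)), []).append(coords_fn(i, j))

    if wrap:
        la, lb = labels, np.roll(labels, -1, axis=1)
        add_elements(la != lb, lambda i, j: (2 * i, 2 * j + 1), la, lb)
    else:
        la, lb = labels[:, :-1], labels[:, 1:]
        add_elements(la != lb, lambda i, j: (2 * i, 2 * j + 1), la, lb)
    la, lb = labels[:-1, :], labels[1:, :]
    add_elements(la != lb, lambda i, j: (2 * i + 1, 2 * j), la, lb)

    pole_two = {}
    if label_image.closed:
        for row, key in ((0, "top"), (H - 1, "bottom")):
            labs = frozenset(int(v) for v in np.unique(labels[row]))
            if len(labs) == 2:
                pole_two[key] = labs
    bonds = []
    for pair, elems in sorted(elements.items(), key=lambda kv: sorted(kv[0])):
        comps = _cluster_elements(elems, 2 * W if wrap else None)
        if label_image.closed:
            comps = _merge_pole_components(comps, H, pair, pole_two)
        for comp in comps:
            arr = np.array(comp, dtype=float) / 2.0
            endpoints = _bond_vertices(pair, arr, vertices, pole_vertex, H, W, wrap)
            bonds.append({"labels": pair, "pixels": arr, "vertices": endpoints})

    faces = {}
    all_labels = [int(v) for v in np.unique(labels[labels > 0])]
    for lab in all_labels:
        faces[lab] = {"bonds": [], "n_neighbors": 0,
                      "boundary": lab in label_image.boundary_labels}
    for bid, b in enumerate(bonds):
        for lab in b["labels"]:
            if lab in faces:
                faces[lab]["bonds"].append(bid)
    for lab in faces:
        faces[lab]["n_neighbors"] = len(faces[lab]["bonds"])
    return CellLattice(vertices=vertices, bonds=bonds, faces=faces,
                       closed=label_image.closed)


def _cluster_elements(elems, wrap_width):
    """Group boundary edge elements into connected components."""
    m = len(elems)
    if m == 1:
        return [elems]
    pts = np.array(elems, dtype=float)
    uf = _UnionFind(m)
    di = np.abs(pts[:, None, 0] - pts[None, :, 0])
    dj = np.abs(pts[:, None, 1] - pts[None, :, 1])
    if wrap_width is not None:
        dj = np.minimum(dj, wrap_width - dj)
    close = np.maximum(di, dj) <= 2
    ii, jj = np.nonzero(close)
    for a, b in zip(ii.tolist(), jj.tolist()):
        if a < b:
            uf.union(a, b)
    groups = {}
    for idx in range(m):
        groups.setdefault(uf.find(idx), []).append(elems[idx])
    return list(groups.values())


def _merge_pole_components(comps, H, pair, pole_two):
    """Merge a pair's bond runs that pass through a pole (closed charts).

    Only applies when exactly two labels reach the polar image row — then
    the pole point lies on their shared boundary and the runs on either
    side are one bond.  With ≥3 labels at a pole the pole is a vertex and
    the runs are distinct bonds ending there.
    """
    checks = []
    if pole_two.get("top") == pair:
        checks.append(lambda c: any(p[0] <= 1 for p in c))
    if pole_two.get("bottom") == pair:
        checks.append(lambda c: any(p[0] >= 2 * H - 3 for p in c))
    for test in checks:
        touching = [c for c in comps if test(c)]
        if len(touching) > 1:
            merged = [p for c in touching for p in c]
            comps = [c for c in comps if not test(c)] + [merged]
    return comps


def _bond_vertices(pair, arr, vertices, pole_vertex, H, W, wrap):
    """Vertex ids incident to a bond: vertices containing both its labels
    and lying near the bond's pixel set."""
    ids = []
    for vid, v in enumerate(vertices):
        if not pair <= v["labels"]:
            continue
        pos = v["pos"]
        if np.isnan(pos[1]):  # pole vertex
            near = np.any(np.abs(arr[:, 0] - pos[0]) <= 1.5)
        else:
            di = np.abs(arr[:, 0] - pos[0])
            dj = np.abs(arr[:, 1] - pos[1])
            if wrap:
                dj = np.minimum(dj, W - dj)
            near = np.any(np.maximum(di, dj) <= 1.5)
        if near:
            ids.append(vid)
    return ids


# ---------------------------------------------------------------------------
# topology statistics
# ---------------------------------------------------------------------------

def neighbor_stats(lattice: CellLattice, exclude_boundary: bool = True):
    """Per-cell neighbor counts and polygon-class summary.

    Returns ``(per_cell DataFrame, summary dict)`` where the summary holds
    the hexagon fraction (topological order), the full polygon histogram,
    and the mean neighbor number.  Cells flagged ``boundary`` are excluded
    from the summary when ``exclude_boundary``.
    """
    rows = [
        {"cell": lab, "n_neighbors": f["n_neighbors"], "boundary": f["boundary"]}
        for lab, f in sorted(lattice.faces.items())
    ]
    df = pd.DataFrame(rows)
    use = df[~df["boundary"]] if exclude_boundary else df
    counts = use["n_neighbors"].to_numpy()
    hist = {int(k): int(v) for k, v in zip(*np.unique(counts, return_counts=True))}
    summary = {
        "n_cells": int(len(use)),
        "mean_neighbors": float(counts.mean()) if len(use) else np.nan,
        "hexagon_fraction": float(np.mean(counts == 6)) if len(use) else np.nan,
        "histogram": hist,
    }
    return df, summary
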