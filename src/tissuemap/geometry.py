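"""Tissue surfaces, distances, and random-point controls.

A :class:`Surface` wraps the alpha shape of a point set — a generalization
of the convex hull controlled by a scale parameter ``alpha`` (µm) that can
represent concavities and holes.  The construction keeps every Delaunay
simplex whose circumradius is at most ``alpha`` and takes the union (2D) or
the once-used boundary faces (3D); as ``alpha → ∞`` the result is the
convex hull.  Surfaces support containment gating and signed distances to
their border (negative inside, positive outside, 0 on the boundary).

Distance analyses against discrete landmark objects (e.g. blood-vessel
centroids) use exact nearest-neighbor Euclidean distances, with a
"proximal fraction" summary (fraction of cells within a cutoff, 20 µm by
default).  Randomly distributed points (RDPs) uniform over the plotted
bounding box provide the null reference for these distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Delaunay, QhullError, cKDTree
from shapely.geometry import Polygon

from .io_tables import CellTable

__all__ = [
    "Surface",
    "make_surface",
    "signed_distance",
    "nearest_object_distance",
    "proximal_fraction",
    "generate_random_points",
    "gate_points",
]

PROXIMAL_CUTOFF_UM = 20.0

# fixed ray direction for 3D parity tests; irrational-ish components make
# hitting a mesh edge exactly a measure-zero event
_RAY = np.array([0.5773502691896258, 0.2672612419124244, 0.7745966692414834])
_RAY /= np.linalg.norm(_RAY)


@dataclass
class Surface:
    """Alpha-shape boundary of a point cloud.

    2D surfaces store a shapely (Multi)Polygon; 3D surfaces store a
    triangle mesh (``vertices`` (V,3) and ``faces`` (F,3)).  ``contains``
    counts boundary points as inside.
    """

    is_2d: bool
    alpha: float
    source_point_count: int
    polygon: shapely.Geometry | None = None
    vertices: np.ndarray | None = None
    faces: np.ndarray | None = None

    # -- queries -----------------------------------------------------------

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership per point; the boundary counts as inside."""
        pts = _as_points(points, self.is_2d)
        if self.is_2d:
            return shapely.covers(self.polygon, shapely.points(pts[:, :2]))
        inside = _ray_parity(pts, self.vertices, self.faces)
        on_boundary = self.boundary_distance(pts) == 0.0
        return inside | on_boundary

    def boundary_distance(self, points: np.ndarray) -> np.ndarray:
        """Unsigned Euclidean distance to the nearest boundary point."""
        pts = _as_points(points, self.is_2d)
        if self.is_2d:
            boundary = self.polygon.boundary
            return shapely.distance(shapely.points(pts[:, :2]), boundary)
        return _mesh_distance(pts, self.vertices, self.faces)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance to the border: negative inside, positive outside, 0 on it."""
        pts = _as_points(points, self.is_2d)
        d = self.boundary_distance(pts)
        sign = np.where(self.contains(pts), -1.0, 1.0)
        return np.where(d == 0.0, 0.0, sign * d)


def _as_points(points, is_2d: bool) -> np.ndarray:
    if isinstance(points, CellTable):
        points = points.positions
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] == 2:
        pts = np.column_stack([pts, np.zeros(len(pts))])
    return pts


# -- alpha-shape construction ---------------------------------------------


def _circumradius_2d(tri: np.ndarray) -> np.ndarray:
    """Circumradius of each triangle (n,3,2); degenerate -> inf."""
    a = np.linalg.norm(tri[:, 1] - tri[:, 2], axis=1)
    b = np.linalg.norm(tri[:, 0] - tri[:, 2], axis=1)
    c = np.linalg.norm(tri[:, 0] - tri[:, 1], axis=1)
    u = tri[:, 1] - tri[:, 0]
    v = tri[:, 2] - tri[:, 0]
    area = 0.5 * np.abs(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        r = a * b * c / (4.0 * area)
    return np.where(area > 0, r, np.inf)


def _circumradius_3d(tet: np.ndarray) -> np.ndarray:
    """Circumradius of each tetrahedron (n,4,3); degenerate -> inf."""
    a = tet[:, 0]
    rhs_pts = tet[:, 1:]
    A = 2.0 * (rhs_pts - a[:, None, :])
    b = (rhs_pts**2).sum(axis=2) - (a**2).sum(axis=1)[:, None]
    det = np.linalg.det(A)
    scale = np.abs(A).max(axis=(1, 2)) ** 3 + 1e-300
    ok = np.abs(det) > 1e-12 * scale
    r = np.full(len(tet), np.inf)
    if ok.any():
        centers = np.linalg.solve(A[ok], b[ok][..., None])[..., 0]
        r[ok] = np.linalg.norm(centers - a[ok], axis=1)
    return r


def make_surface(points, alpha: float | None = None) -> Surface:
    """Alpha shape of a point cloud (2D polygon set or 3D triangle mesh).

    ``alpha`` is in µm; ``None`` (or ``inf``) keeps all simplices and yields
    the convex hull.  Points with zero z extent are treated as 2D.  Raises
    on degenerate input (collinear in 2D, coplanar in 3D).
    """
    pts = _as_points(points, is_2d=False)
    is_2d = np.ptp(pts[:, 2]) == 0.0
    alpha_val = np.inf if alpha is None else float(alpha)
    if alpha_val <= 0:
        raise ValueError("alpha must be > 0")

    if is_2d:
        xy = pts[:, :2]
        if len(xy) < 3:
            raise ValueError("need >= 3 points for a 2D surface")
        try:
            tri = Delaunay(xy)
        except QhullError as err:
            raise ValueError("degenerate 2D geometry (points are collinear)") from err
        simplices = xy[tri.simplices]
        keep = _circumradius_2d(simplices) <= alpha_val
        if not keep.any():
            raise ValueError("alpha too small: no simplex survives")
        polys = [Polygon(s) for s in simplices[keep]]
        geom = shapely.union_all(polys)
        geom = shapely.make_valid(geom)
        return Surface(is_2d=True, alpha=alpha_val, source_point_count=len(xy), polygon=geom)

    if len(pts) < 4:
        raise ValueError("need >= 4 points for a 3D surface")
    try:
        tri = Delaunay(pts)
    except QhullError as err:
        raise ValueError("degenerate 3D geometry (points are coplanar)") from err
    keep = _circumradius_3d(pts[tri.simplices]) <= alpha_val
    if not keep.any():
        raise ValueError("alpha too small: no simplex survives")
    tets = tri.simplices[keep]
    # boundary = triangular faces used by exactly one kept tetrahedron
    faces = np.vstack(
        [tets[:, [0, 1, 2]], tets[:, [0, 1, 3]], tets[:, [0, 2, 3]], tets[:, [1, 2, 3]]]
    )
    key = np.sort(faces, axis=1)
    _, inverse, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary = faces[counts[inverse] == 1]
    return Surface(
        is_2d=False,
        alpha=alpha_val,
        source_point_count=len(pts),
        vertices=pts,
        faces=boundary,
    )


# -- 3D mesh queries -------------------------------------------------------


def _ray_parity(points: np.ndarray, vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Odd crossing parity of a fixed ray from each point (Moller-Trumbore)."""
    v0 = vertices[faces[:, 0]]
    e1 = vertices[faces[:, 1]] - v0
    e2 = vertices[faces[:, 2]] - v0
    h = np.cross(_RAY, e2)  # (F,3)
    det = (e1 * h).sum(axis=1)  # (F,)
    parallel = np.abs(det) < 1e-12
    inside = np.zeros(len(points), dtype=bool)
    for start in range(0, len(points), 512):
        P = points[start : start + 512]
        s = P[:, None, :] - v0[None, :, :]  # (p,F,3)
        with np.errstate(divide="ignore", invalid="ignore"):
            u = (s * h[None, :, :]).sum(axis=2) / det[None, :]
            q = np.cross(s, e1[None, :, :])
            v = (q * _RAY).sum(axis=2) / det[None, :]
            t = (q * e2[None, :, :]).sum(axis=2) / det[None, :]
        hit = (
            ~parallel[None, :]
            & (u >= 0.0)
            & (v >= 0.0)
            & (u + v <= 1.0)
            & (t > 0.0)
        )
        inside[start : start + 512] = hit.sum(axis=1) % 2 == 1
    return inside


def _segment_distance(P: np.ndarray, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Distance from points (p,1,3)-broadcastable to segments A->B (F,3)."""
    d = B - A  # (F,3)
    len2 = (d * d).sum(axis=1)  # (F,)
    ap = P - A[None, :, :]  # (p,F,3)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ap * d[None, :, :]).sum(axis=2) / len2[None, :]
    t = np.clip(np.nan_to_num(t), 0.0, 1.0)  # zero-length segments -> endpoint
    closest = A[None, :, :] + t[..., None] * d[None, :, :]
    return np.linalg.norm(P - closest, axis=2)


def _mesh_distance(points: np.ndarray, vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Min distance from each point to any triangle of the mesh.

    Per triangle: the orthogonal distance to the plane when the projection
    falls inside the triangle (barycentric test), else the minimum of the
    three edge-segment distances.
    """
    A = vertices[faces[:, 0]]
    B = vertices[faces[:, 1]]
    C = vertices[faces[:, 2]]
    ab = B - A
    ac = C - A
    n = np.cross(ab, ac)  # (F,3)
    nn = (n * n).sum(axis=1)  # (F,)
    # Gram-matrix terms for barycentric coordinates of the projection
    d00 = (ab * ab).sum(axis=1)
    d01 = (ab * ac).sum(axis=1)
    d11 = (ac * ac).sum(axis=1)
    denom = d00 * d11 - d01 * d01  # (F,)
    degenerate = denom <= 0

    out = np.empty(len(points))
    for start in range(0, len(points), 256):
        P = points[start : start + 256][:, None, :]  # (p,1,3)
        ap = P - A[None, :, :]  # (p,F,3)
        d20 = (ap * ab[None, :, :]).sum(axis=2)
        d21 = (ap * ac[None, :, :]).sum(axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            v = (d11[None, :] * d20 - d01[None, :] * d21) / denom[None, :]
            w = (d00[None, :] * d21 - d01[None, :] * d20) / denom[None, :]
            plane = np.abs((ap * n[None, :, :]).sum(axis=2)) / np.sqrt(nn)[None, :]
        interior = (
            ~degenerate[None, :] & (v >= 0.0) & (w >= 0.0) & (v + w <= 1.0)
        )
        edge = np.minimum(
            _segment_distance(P, A, B),
            np.minimum(_segment_distance(P, B, C), _segment_distance(P, C, A)),
        )
        d = np.where(interior, plane, edge)
        out[start : start + 256] = d.min(axis=1)
    return out


# -- distance tables -------------------------------------------------------


def signed_distance(cells, surface: Surface) -> pd.DataFrame:
    """Per-cell signed distance (µm) to a surface border; negative = inside."""
    pts = _as_points(cells, surface.is_2d)
    return pd.DataFrame({"signed_distance_um": surface.signed_distance(pts)})


def nearest_object_distance(cells, targets) -> pd.DataFrame:
    """Per-cell unsigned distance (µm) to the nearest target object."""
    pts = _as_points(cells, is_2d=False)
    tgt = _as_points(targets, is_2d=False)
    if len(tgt) == 0:
        raise ValueError("target set is empty")
    tree = cKDTree(tgt)
    d, _ = tree.query(pts)
    return pd.DataFrame({"distance_um": d})


def proximal_fraction(distances, cutoff_um: float = PROXIMAL_CUTOFF_UM) -> float:
    """Fraction of cells with nearest-object distance <= cutoff (20 µm default)."""
    d = np.asarray(distances["distance_um"] if isinstance(distances, pd.DataFrame) else distances)
    if len(d) == 0:
        raise ValueError("empty distance table")
    return float(np.mean(d <= cutoff_um))


# -- randomly distributed points ------------------------------------------


def generate_random_points(reference: CellTable, n: int, seed: int) -> CellTable:
    """Uniform control points ("RDP") on the reference bounding box.

    Only the plotted axes are randomized: x and y always, z only if the
    reference has nonzero z extent (otherwise the constant z is copied).
    All channel values are 0.  Deterministic per seed.
    """
    if reference.n == 0:
        raise ValueError("reference table is empty")
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = np.random.default_rng(seed)
    pos = reference.positions
    lo, hi = pos.min(axis=0), pos.max(axis=0)
    xyz = np.empty((n, 3))
    for axis in range(2):
        xyz[:, axis] = rng.uniform(lo[axis], hi[axis], size=n)
    if hi[2] > lo[2]:
        xyz[:, 2] = rng.uniform(lo[2], hi[2], size=n)
    else:
        xyz[:, 2] = lo[2]
    samples = reference.samples
    df = pd.DataFrame(
        {
            "sample_id": samples[0] if len(samples) == 1 else "RDP",
            "phenotype": "RDP",
            "x_um": xyz[:, 0],
            "y_um": xyz[:, 1],
            "z_um": xyz[:, 2],
        }
    )
    for c in reference.channel_names:
        df[c] = 0.0
    vocab = tuple(sorted(set(reference.vocabulary) | {"RDP"}))
    return CellTable(df, vocabulary=vocab)


def gate_points(points: CellTable, surface: Surface) -> CellTable:
    """Retain the points inside the surface (boundary counts as inside)."""
    inside = surface.contains(points.positions)
    return points.subset(np.asarray(inside))
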