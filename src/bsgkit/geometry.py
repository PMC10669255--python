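"""Implicit-solid geometry kernel.

All guide solids are represented as signed-distance-like scalar fields
(negative inside the solid) sampled on a regular axis-aligned grid in the
patient frame (mm).  Constructive solid geometry is performed by pointwise
``min`` (union) / ``max`` (intersection / subtraction with a negated field),
and the final surface is extracted once with marching cubes.  Because the
zero level set of a continuous field bounded away from the grid boundary is
closed, every meshed solid is watertight and self-intersection free by
construction — the robustness contract that a boundary-representation
boolean engine has to fight for.

The kernel also provides the mesh-side primitives the QC code needs and
that are not available in the installed trimesh build: nearest-surface
signed distance (KD-tree + vertex-normal projection), first-hit ray casting
(Möller–Trumbore with a KD-tree candidate prefilter), plan-view triangle
rasterisation, and circle / cylinder fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from skimage import measure as _sk_measure

BIG = 1.0e6


@dataclass(frozen=True)
class Grid:
    """Regular sampling grid: point ``(i,j,k)`` sits at ``origin + (i,j,k)*pitch``."""

    origin: np.ndarray
    pitch: float
    shape: tuple[int, int, int]

    # fixed sub-cell offset keeps axis-aligned feature planes (chest plane,
    # arm walls) off the node lattice, where marching cubes would otherwise
    # emit degenerate, non-manifold vertices
    _DITHER = np.array([0.1371, 0.2713, 0.3137])

    @classmethod
    def from_bounds(cls, lo, hi, pitch: float, pad: int = 2) -> "Grid":
        lo = np.asarray(lo, dtype=float) - (pad + cls._DITHER) * pitch
        hi = np.asarray(hi, dtype=float) + pad * pitch
        shape = tuple(int(np.ceil((hi[i] - lo[i]) / pitch)) + 1 for i in range(3))
        return cls(origin=lo, pitch=float(pitch), shape=shape)

    def axes(self):
        return tuple(
            self.origin[i] + self.pitch * np.arange(self.shape[i]) for i in range(3)
        )

    def evaluate(self, func, chunk: int = 8) -> np.ndarray:
        """Evaluate ``func(points (N,3)) -> (N,)`` over the grid, in z-slabs."""
        xs, ys, zs = self.axes()
        out = np.empty(self.shape, dtype=np.float32)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        for k0 in range(0, self.shape[2], chunk):
            k1 = min(k0 + chunk, self.shape[2])
            Z = zs[k0:k1]
            pts = np.stack(
                [
                    np.broadcast_to(X[:, :, None], (*X.shape, k1 - k0)),
                    np.broadcast_to(Y[:, :, None], (*X.shape, k1 - k0)),
                    np.broadcast_to(Z[None, None, :], (*X.shape, k1 - k0)),
                ],
                axis=-1,
            ).reshape(-1, 3)
            out[:, :, k0:k1] = func(pts).reshape(X.shape[0], X.shape[1], k1 - k0)
        return out


def mesh_field(grid: Grid, field: np.ndarray, level: float = 0.0) -> trimesh.Trimesh:
    """Marching-cubes the level set ``field == level`` into a watertight mesh.

    The field is clamped to a few pitches around the level first: cells with
    larger magnitude are more than a cell away from the surface, so clamping
    cannot move the level set, but it stops near-degenerate triangles where
    a sentinel value (``BIG``) sits next to a near-zero cell.
    """
    if field.min() >= level:
        raise ValueError("field has no interior at the requested level")
    clip = 2.0 * grid.pitch
    f = np.clip(field, level - clip, level + clip)
    # flat solid faces (e.g. the chest-plane underside at z=0) can put the
    # level exactly on grid nodes; nudge those nodes inside so the extracted
    # surface stays manifold
    f[f == level] = level - 1e-4 * grid.pitch
    f[0, :, :] = f[-1, :, :] = level + clip
    f[:, 0, :] = f[:, -1, :] = level + clip
    f[:, :, 0] = f[:, :, -1] = level + clip
    verts, faces, _, _ = _sk_measure.marching_cubes(
        f, level=level, spacing=(grid.pitch,) * 3
    )
    verts = verts + grid.origin
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if not mesh.is_watertight:
        # crossings within float noise of a grid node can emit twin vertices
        # a few 1e-6 apart that exact deduplication misses; snap and rebuild
        snapped = np.round(mesh.vertices / (1e-4 * grid.pitch)) * (1e-4 * grid.pitch)
        mesh = trimesh.Trimesh(vertices=snapped, faces=mesh.faces, process=True)
        mesh.update_faces(mesh.nondegenerate_faces())
        mesh.process()
    if mesh.volume < 0:
        mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# field primitives (all take (N,3) points, return (N,) signed values, <0 inside)

def sdf_cylinder(points, axis_point, axis_dir, radius):
    """Infinite cylinder around the line through ``axis_point`` along ``axis_dir``."""
    a = np.asarray(axis_dir, dtype=float)
    a = a / np.linalg.norm(a)
    d = points - np.asarray(axis_point, dtype=float)
    t = d @ a
    radial = d - t[:, None] * a
    return np.linalg.norm(radial, axis=1) - radius


def sdf_box(points, lo, hi):
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    c = (lo + hi) / 2.0
    h = (hi - lo) / 2.0
    q = np.abs(points - c) - h
    outside = np.linalg.norm(np.maximum(q, 0.0), axis=1)
    inside = np.minimum(q.max(axis=1), 0.0)
    return outside + inside


class MeshSDF:
    """Signed distance to a closed triangle mesh, via nearest-vertex normal projection.

    For a densely and smoothly sampled surface (marching-cubes output after
    Taubin smoothing) the projection of ``p - v`` onto the vertex normal of
    the nearest vertices is accurate to well under the vertex spacing, and is
    smooth — which a binary-voxel distance transform is not.
    """

    def __init__(self, mesh: trimesh.Trimesh, k: int = 6):
        self.vertices = np.asarray(mesh.vertices, dtype=float)
        self.normals = np.asarray(mesh.vertex_normals, dtype=float)
        self.tree = cKDTree(self.vertices)
        self.k = min(k, len(self.vertices))

    def __call__(self, points: np.ndarray) -> np.ndarray:
        d, idx = self.tree.query(points, k=self.k)
        if self.k == 1:
            d = d[:, None]
            idx = idx[:, None]
        diff = points[:, None, :] - self.vertices[idx]
        proj = np.einsum("nkd,nkd->nk", diff, self.normals[idx])
        w = 1.0 / (d + 1e-9)
        return np.einsum("nk,nk->n", w, proj) / w.sum(axis=1)


# ---------------------------------------------------------------------------
# 2-D region fields (shapely polygons extruded along z)

class Polygon2DSDF:
    """Signed plan-view distance to a shapely polygon (negative inside)."""

    def __init__(self, polygon):
        import shapely

        self.polygon = polygon
        self._boundary = polygon.boundary
        self._shapely = shapely

    def __call__(self, xy: np.ndarray) -> np.ndarray:
        sh = self._shapely
        pts = sh.points(np.asarray(xy, dtype=float))
        dist = sh.distance(self._boundary, pts)
        inside = sh.contains(self.polygon, pts)
        return np.where(inside, -dist, dist)

    def prism(self, points3d: np.ndarray) -> np.ndarray:
        return self(points3d[:, :2])


# ---------------------------------------------------------------------------
# mesh-side measurement primitives

def _triangle_data(mesh: trimesh.Trimesh):
    tri = mesh.triangles
    centroids = tri.mean(axis=1)
    radii = np.linalg.norm(tri - centroids[:, None, :], axis=2).max(axis=1)
    return tri, centroids, radii


def ray_first_hit(mesh, origins, directions, max_dist=50.0, offset=1e-4):
    """First intersection of each ray with the mesh.

    Returns (distances, triangle indices); ``np.inf`` / ``-1`` where no hit
    within ``max_dist``.  Candidate triangles are prefiltered with a KD-tree
    on triangle centroids, then tested with Möller–Trumbore.
    """
    tri, centroids, radii = _triangle_data(mesh)
    tree = cKDTree(centroids)
    rmax = float(radii.max())
    origins = np.asarray(origins, dtype=float)
    directions = np.asarray(directions, dtype=float)
    directions = directions / np.linalg.norm(directions, axis=1, keepdims=True)
    n = len(origins)
    hit_t = np.full(n, np.inf)
    hit_tri = np.full(n, -1, dtype=int)
    # sample candidate triangles near points along each ray
    n_samp = max(2, int(np.ceil(max_dist / max(rmax, 1e-6))) + 1)
    ts = np.linspace(0.0, max_dist, n_samp)
    for i in range(n):
        o, d = origins[i], directions[i]
        samples = o[None, :] + ts[:, None] * d[None, :]
        cand = tree.query_ball_point(samples, r=rmax * 1.5 + max_dist / (n_samp - 1))
        cand = np.unique(np.concatenate([np.asarray(c, dtype=int) for c in cand]))
        if len(cand) == 0:
            continue
        t = _moller_trumbore(o, d, tri[cand])
        valid = (t > offset) & (t <= max_dist)
        if valid.any():
            j = np.argmin(np.where(valid, t, np.inf))
            hit_t[i] = t[j]
            hit_tri[i] = cand[j]
    return hit_t, hit_tri


def _moller_trumbore(origin, direction, triangles, eps=1e-9):
    v0 = triangles[:, 0]
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0
    h = np.cross(direction[None, :], e2)
    a = np.einsum("nd,nd->n", e1, h)
    parallel = np.abs(a) < eps
    f = np.where(parallel, np.nan, 1.0 / np.where(parallel, 1.0, a))
    s = origin[None, :] - v0
    u = f * np.einsum("nd,nd->n", s, h)
    q = np.cross(s, e1)
    v = f * (q @ direction)
    t = f * np.einsum("nd,nd->n", e2, q)
    ok = (~parallel) & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps)
    return np.where(ok, t, np.inf)


def plan_raster(mesh, xs, ys):
    """Rasterise plan-view (z-projection) occupancy and top height of a mesh.

    Returns (occupancy bool (nx,ny), top_z float (nx,ny) with -inf where empty).
    A cell is occupied if any triangle's plan projection covers its centre.
    """
    from skimage.draw import polygon as _draw_polygon

    xs = np.asarray(xs)
    ys = np.asarray(ys)
    dx = xs[1] - xs[0]
    dy = ys[1] - ys[0]
    occ = np.zeros((len(xs), len(ys)), dtype=bool)
    top = np.full((len(xs), len(ys)), -np.inf)
    tri = np.asarray(mesh.triangles)
    # cull triangles outside the raster window
    tmin = tri[:, :, :2].min(axis=1)
    tmax = tri[:, :, :2].max(axis=1)
    keep = (
        (tmax[:, 0] >= xs[0]) & (tmin[:, 0] <= xs[-1])
        & (tmax[:, 1] >= ys[0]) & (tmin[:, 1] <= ys[-1])
    )
    for t in tri[keep]:
        ri = (t[:, 0] - xs[0]) / dx
        ci = (t[:, 1] - ys[0]) / dy
        rr, cc = _draw_polygon(ri, ci, shape=occ.shape)
        if len(rr) == 0:
            continue
        occ[rr, cc] = True
        # plane height at the covered cells (barycentric on the plan projection)
        px = xs[rr]
        py = ys[cc]
        z = _plane_z(t, px, py)
        np.maximum.at(top, (rr, cc), z)
    return occ, top


def _plane_z(tri, px, py):
    (x0, y0, z0), (x1, y1, z1), (x2, y2, z2) = tri
    det = (y1 - y2) * (x0 - x2) + (x2 - x1) * (y0 - y2)
    if abs(det) < 1e-12:
        return np.full_like(px, tri[:, 2].max())
    l0 = ((y1 - y2) * (px - x2) + (x2 - x1) * (py - y2)) / det
    l1 = ((y2 - y0) * (px - x2) + (x0 - x2) * (py - y2)) / det
    l2 = 1.0 - l0 - l1
    return l0 * z0 + l1 * z1 + l2 * z2


def nearest_surface_distance(mesh, points, search_radius=4.0):
    """Exact distance from each point to the mesh surface (point-triangle).

    Candidate triangles come from a KD-tree on centroids; the closest point
    on a triangle is either the in-plane projection (when its barycentric
    coordinates are all non-negative) or the closest point on an edge.
    """
    tri, centroids, radii = _triangle_data(mesh)
    tree = cKDTree(centroids)
    rmax = float(radii.max())
    points = np.asarray(points, dtype=float)
    out = np.empty(len(points))
    for i, p in enumerate(points):
        r = search_radius + rmax
        cand = tree.query_ball_point(p, r=r)
        while not cand:
            r *= 2.0
            cand = tree.query_ball_point(p, r=r)
        out[i] = _point_triangles_distance(p, tri[cand]).min()
    return out


def _point_triangles_distance(p, triangles):
    a, b, c = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    n = np.cross(b - a, c - a)
    nn = np.linalg.norm(n, axis=1)
    ok = nn > 1e-12
    n[ok] /= nn[ok, None]
    dist_plane = np.abs(np.einsum("nd,nd->n", p[None, :] - a, n))
    proj = p[None, :] - np.einsum("nd,nd->n", p[None, :] - a, n)[:, None] * n
    # barycentric of the projection
    v0, v1, v2 = b - a, c - a, proj - a
    d00 = np.einsum("nd,nd->n", v0, v0)
    d01 = np.einsum("nd,nd->n", v0, v1)
    d11 = np.einsum("nd,nd->n", v1, v1)
    d20 = np.einsum("nd,nd->n", v2, v0)
    d21 = np.einsum("nd,nd->n", v2, v1)
    den = d00 * d11 - d01 * d01
    den = np.where(np.abs(den) < 1e-18, 1e-18, den)
    v = (d11 * d20 - d01 * d21) / den
    w = (d00 * d21 - d01 * d20) / den
    inside = (v >= 0) & (w >= 0) & (v + w <= 1) & ok
    d_edges = np.min(
        [
            _point_segments_distance(p, a, b),
            _point_segments_distance(p, b, c),
            _point_segments_distance(p, c, a),
        ],
        axis=0,
    )
    return np.where(inside, dist_plane, d_edges)


def _point_segments_distance(p, a, b):
    ab = b - a
    t = np.einsum("nd,nd->n", p[None, :] - a, ab) / np.maximum(
        np.einsum("nd,nd->n", ab, ab), 1e-18
    )
    t = np.clip(t, 0.0, 1.0)
    closest = a + t[:, None] * ab
    return np.linalg.norm(p[None, :] - closest, axis=1)


def fit_circle_2d(points_xy):
    """Kåsa algebraic circle fit. Returns (centre (2,), radius)."""
    pts = np.asarray(points_xy, dtype=float)
    A = np.column_stack([2 * pts[:, 0], 2 * pts[:, 1], np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    centre = sol[:2]
    radius = np.sqrt(sol[2] + centre @ centre)
    return centre, radius


def fit_cylinder_axis(points, axis_init=(0.0, 0.0, 1.0), centre_init=None):
    """Least-squares cylinder fit: minimise the variance of radial distances.

    Returns (centre (3,), unit axis (3,), radius).  The axis is parameterised
    by two tilt angles about the initial direction, so the fit is stable for
    near-vertical channels.
    """
    from scipy.optimize import least_squares

    pts = np.asarray(points, dtype=float)
    if centre_init is None:
        centre_init = pts.mean(axis=0)
    a0 = np.asarray(axis_init, float)
    a0 = a0 / np.linalg.norm(a0)
    # local frame around a0
    tmp = np.array([1.0, 0.0, 0.0]) if abs(a0[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(a0, tmp)
    u /= np.linalg.norm(u)
    v = np.cross(a0, u)

    def radial(params):
        ta, tb, cx, cy = params
        axis = a0 + ta * u + tb * v
        axis = axis / np.linalg.norm(axis)
        centre = centre_init + cx * u + cy * v
        d = pts - centre
        rad = np.linalg.norm(d - (d @ axis)[:, None] * axis, axis=1)
        return rad - rad.mean()

    res = least_squares(radial, x0=[0.0, 0.0, 0.0, 0.0], method="lm")
    ta, tb, cx, cy = res.x
    axis = a0 + ta * u + tb * v
    axis = axis / np.linalg.norm(axis)
    centre = centre_init + cx * u + cy * v
    d = pts - centre
    radius = float(np.linalg.norm(d - (d @ axis)[:, None] * axis, axis=1).mean())
    return centre, axis, radius
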