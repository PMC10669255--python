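"""Voronoi lightweighting of the guide shell.

Seed points are sampled uniformly (triangle-area weighted) over the shell's
outer surface; the surface Voronoi diagram of the seeds partitions the shell
into cells, and each cell's interior is carved out as a through-thickness
void, leaving solid ribs along the cell boundaries.  The rib-width guarantee
is built into the carving rule: a point belongs to a void only when its
distance to the second-nearest seed exceeds the distance to the nearest by
at least the rib width ``w``, which keeps every void boundary at least
``w/2`` away from the bisector between the two seeds — so two voids in
adjacent cells are separated by a solid rib of at least ``w`` (straight-line,
hence also geodesic).  ``w = min_rib + rib_allowance`` so the as-built rib
stays above the design bound after meshing and rasterisation.

Functional regions are protected by exclusion zones (coverage rim, nipple
hole collar, manubrium notch collar, injection-channel annulus), each padded
by ``min_rib``; any cell whose void would touch a zone is dropped entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .geometry import BIG
from .guide import DesignParams, GuideDesign


@dataclass
class VoidSpec:
    """One lightweighting void: its Voronoi seed and boundary polygon.

    ``boundary`` is the closed polyline (K,3) where the carving criterion
    crosses its threshold on the outer surface — the as-designed void edge.
    ``normal`` is the outer-surface normal at the seed (the through-cut
    direction).
    """

    seed_point: np.ndarray
    normal: np.ndarray
    boundary: np.ndarray
    boundary_normals: np.ndarray
    retained: bool


class LightweightWarning(UserWarning):
    pass


def _outer_submesh(design: GuideDesign) -> trimesh.Trimesh:
    """Faces of the current shell lying on the outer offset surface."""
    mesh = design.shell.mesh
    t = design.params.shell_thickness
    centroids = mesh.triangles.mean(axis=1)
    d = design.body_sdf(centroids)
    keep = d > t - 0.6
    return mesh.submesh([np.nonzero(keep)[0]], append=True)


def _exclusion_mask(design: GuideDesign, pts: np.ndarray, pad: float) -> np.ndarray:
    """True where a point falls inside any functional exclusion zone."""
    params = design.params
    xy = pts[:, :2]
    om = design.omega_sdf()
    excl = om(xy) >= -pad  # rim band of the coverage region
    if design.nipple_hole is not None:
        c = design.nipple_hole["centre"][:2]
        r = design.nipple_hole["diameter"] / 2.0
        excl |= np.hypot(*(xy - c).T) <= r + pad
    if design.notch is not None:
        v = design.notch["vertex"][:2]
        excl |= np.hypot(*(xy - v).T) <= params.notch_depth + pad
    circ = design.resection_circle
    rad = np.hypot(*(xy - circ.centre[:2]).T)
    half = params.channel_diameter / 2.0 + pad
    excl |= np.abs(rad - circ.radius) <= half  # channel annulus collar
    return excl


def voronoi_lightweight(
    design: GuideDesign, params: DesignParams | None = None
) -> tuple[GuideDesign, list[VoidSpec]]:
    """Carve the Voronoi void pattern into the shell. Returns (shell', voids)."""
    params = params or design.params
    rng = np.random.default_rng(params.seed)
    outer = _outer_submesh(design)
    seeds, seed_faces = trimesh.sample.sample_surface(
        outer, params.n_voronoi, seed=int(rng.integers(0, 2**31 - 1))
    )
    seeds = np.asarray(seeds)
    seed_normals = np.asarray(outer.face_normals[seed_faces])
    w = params.min_rib + params.rib_allowance

    # dense surface samples: void membership + exclusion decisions
    n_dense = max(150_000, params.n_voronoi * 3000)
    dense, dense_faces = trimesh.sample.sample_surface(
        outer, n_dense, seed=int(rng.integers(0, 2**31 - 1))
    )
    dense = np.asarray(dense)
    dense_normals = np.asarray(outer.face_normals[dense_faces])
    tree = cKDTree(seeds)
    dd, ii = tree.query(dense, k=2)
    margin = dd[:, 1] - dd[:, 0]
    is_void = margin >= w
    excluded = _exclusion_mask(design, dense, pad=params.min_rib + 0.2)

    # suppress voids too small to print or weigh anything (area from the
    # dense-sample density on the outer surface)
    density = n_dense / float(outer.area)
    min_count = max(10, int(round(params.min_void_area * density)))
    retained = np.zeros(len(seeds), dtype=bool)
    for s in range(len(seeds)):
        sel = is_void & (ii[:, 0] == s)
        if sel.sum() < min_count:
            continue
        retained[s] = not (sel & excluded).any()

    voids = []
    for s in range(len(seeds)):
        boundary, bnormals = _void_boundary(
            design, seeds, s, dense, dense_normals, margin, ii[:, 0], w
        )
        voids.append(
            VoidSpec(
                seed_point=seeds[s],
                normal=seed_normals[s],
                boundary=boundary,
                boundary_normals=bnormals,
                retained=bool(retained[s]),
            )
        )
    n_ret = int(retained.sum())
    if n_ret < 3:
        warnings.warn(
            f"only {n_ret} voids retained: lightweighting is degenerate",
            LightweightWarning,
        )
    if n_ret == 0:
        return design._evolve(design.field.copy(), voids=voids), voids

    # carve: subtract the region {second-nearest - nearest >= w} of retained cells
    grid = design.grid

    def void_sdf(pts):
        d, idx = tree.query(pts, k=2)
        m = d[:, 1] - d[:, 0]
        val = w - m  # negative inside a void
        val[~retained[idx[:, 0]]] = BIG
        return val

    cut = grid.evaluate(void_sdf)
    # belt and braces: never carve inside an exclusion zone
    xs, ys, _ = grid.axes()
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    plan_pts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
    excl_plan = _exclusion_mask(design, plan_pts, pad=params.min_rib).reshape(X.shape)
    cut[excl_plan, :] = BIG
    new_field = np.maximum(design.field, -cut)
    return design._evolve(new_field, voids=voids), voids


def _void_boundary(design, seeds, s, dense, dense_normals, margin, owner, w,
                   band=1.2):
    """Polyline where the carving criterion crosses ``w`` in cell ``s``.

    Band samples near the level are Newton-projected onto the exact level set
    (along the surface tangent), then ordered by angle about the seed normal.
    """
    sel = (owner == s) & (margin >= w - band / 2) & (margin <= w + band)
    pts = dense[sel]
    if len(pts) < 6:
        return np.zeros((0, 3)), np.zeros((0, 3))
    nrm = dense_normals[sel]
    t = design.params.shell_thickness
    others = np.delete(np.arange(len(seeds)), s)
    other_tree = cKDTree(seeds[others])
    for _ in range(6):
        d1 = np.linalg.norm(pts - seeds[s], axis=1)
        d2, j = other_tree.query(pts)
        m = d2 - d1
        g = (pts - seeds[others][j]) / d2[:, None] - (pts - seeds[s]) / d1[:, None]
        g_t = g - np.einsum("nd,nd->n", g, nrm)[:, None] * nrm  # surface tangent
        norm2 = np.einsum("nd,nd->n", g_t, g_t)
        step = np.clip((m - w) / np.maximum(norm2, 1e-6), -1.0, 1.0)
        pts = pts - step[:, None] * g_t
        # reproject to the outer offset surface
        f = design.body_sdf(pts) - t
        pts = pts - f[:, None] * nrm
    # drop non-converged points (cell corners, samples that left the cell)
    d1 = np.linalg.norm(pts - seeds[s], axis=1)
    d2, _ = other_tree.query(pts)
    ok = np.abs((d2 - d1) - w) < 0.05
    pts = pts[ok]
    nrm = nrm[ok]
    if len(pts) < 6:
        return np.zeros((0, 3)), np.zeros((0, 3))
    centre = pts.mean(axis=0)
    d = pts - centre
    _, _, vt = np.linalg.svd(d - d.mean(axis=0), full_matrices=False)
    u, v = vt[0], vt[1]
    ang = np.arctan2(d @ v, d @ u)
    order = np.argsort(ang)
    return pts[order], nrm[order]


# ---------------------------------------------------------------------------
# measurement


def _wall_vertices(mesh_vertices, vtree, void, thickness, horiz_tol=0.3):
    """As-built wall vertices of one void, found near its designed boundary.

    Candidates are mesh vertices within ``thickness + 1`` mm of the void's
    boundary polyline; a candidate counts as wall if it sits at mid-wall
    depth below the outer surface (0.15-0.85 of the shell thickness along
    the local normal) and within ``horiz_tol`` of the boundary in the
    tangent plane.  Measuring at mid-depth avoids the chamfer that surface
    extraction leaves at the void lip.  Returns an (N,3) array or None.
    """
    if void.boundary is None or len(void.boundary) == 0:
        return None
    if getattr(void, "boundary_normals", None) is not None and len(
        void.boundary_normals
    ) == len(void.boundary):
        bn = np.asarray(void.boundary_normals, dtype=float)
    else:
        bn = np.tile(np.asarray(void.normal, dtype=float), (len(void.boundary), 1))
    bn = bn / np.linalg.norm(bn, axis=1, keepdims=True)
    btree = cKDTree(void.boundary)
    cand = vtree.query_ball_point(void.boundary, r=thickness + 1.0)
    cand = np.unique(np.concatenate([np.asarray(c, dtype=int) for c in cand]))
    if len(cand) == 0:
        return None
    pts = mesh_vertices[cand]
    _, j = btree.query(pts)
    rel = pts - void.boundary[j]
    nj = bn[j]
    depth = np.einsum("nd,nd->n", rel, nj)
    horiz = np.linalg.norm(rel - depth[:, None] * nj, axis=1)
    wall = (
        (depth <= -0.3 * thickness)
        & (depth >= -0.8 * thickness)
        & (horiz <= horiz_tol)
    )
    if not wall.any():
        return None
    return pts[wall]


def measure_min_rib(
    mesh,
    voids: list[VoidSpec],
    max_search: float = 12.0,
    shell_thickness: float = 3.0,
) -> float:
    """Minimum solid rib between lightweighting voids, measured from the mesh.

    For every retained void the as-built wall is located on the mesh (the
    vertices at mid-wall depth along the void\'s own surface normal, so ribs
    on steep dome flanks are not foreshortened by any projection), and the
    rib is the minimum 3-D distance between wall vertices belonging to
    different voids.  Returns ``inf`` with fewer than two retained voids.
    """
    retained = [v for v in voids if v.retained]
    if len(retained) < 2:
        return float("inf")
    if hasattr(mesh, "mesh"):
        mesh = mesh.mesh
    verts = np.asarray(mesh.vertices)
    vtree = cKDTree(verts)
    pts3d = []
    comp_of = []
    for k, void in enumerate(retained):
        w = _wall_vertices(verts, vtree, void, shell_thickness)
        if w is None:
            continue
        pts3d.append(w)
        comp_of.append(np.full(len(w), k))
    if len(pts3d) < 2:
        return float("inf")
    pts3d = np.vstack(pts3d)
    comp_of = np.concatenate(comp_of)
    tree = cKDTree(pts3d)
    pairs = tree.query_pairs(r=max_search, output_type="ndarray")
    if len(pairs) == 0:
        return float("inf")
    diff = comp_of[pairs[:, 0]] != comp_of[pairs[:, 1]]
    if not diff.any():
        return float("inf")
    d = np.linalg.norm(pts3d[pairs[diff, 0]] - pts3d[pairs[diff, 1]], axis=1)
    return float(d.min())


def count_detected_voids(mesh, voids: list[VoidSpec],
                         shell_thickness: float = 3.0,
                         min_wall_vertices: int = 5) -> int:
    """Number of retained voids whose carved wall is actually on the mesh."""
    if hasattr(mesh, "mesh"):
        mesh = mesh.mesh
    verts = np.asarray(mesh.vertices)
    vtree = cKDTree(verts)
    n = 0
    for void in voids:
        if not void.retained:
            continue
        w = _wall_vertices(verts, vtree, void, shell_thickness)
        if w is not None and len(w) >= min_wall_vertices:
            n += 1
    return n


def min_rib_bruteforce(voids: list[VoidSpec]) -> float:
    """Oracle: exhaustive pairwise distances between retained void boundaries."""
    polys = [v.boundary for v in voids if v.retained and len(v.boundary) >= 3]
    if len(polys) < 2:
        return float("inf")
    best = float("inf")
    for a in range(len(polys)):
        for b in range(a + 1, len(polys)):
            d = np.linalg.norm(
                polys[a][:, None, :] - polys[b][None, :, :], axis=-1
            ).min()
            best = min(best, float(d))
    return best
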