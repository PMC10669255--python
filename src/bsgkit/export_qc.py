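"""STL export, slicing preview, embossed ID tab, and geometric QC.

Everything in the QC report is measured from the output mesh itself (for the
acceptance path: from the exported STL re-read from disk), never echoed from
the design parameters — the report is the independent check that the printed
constants actually made it into the geometry.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import trimesh
from scipy import ndimage

from .geometry import (
    BIG,
    fit_circle_2d,
    fit_cylinder_axis,
    plan_raster,
    ray_first_hit,
)
from .guide import GuideDesign
from .lightweight import count_detected_voids, measure_min_rib
from .segrecon import SurfaceMesh, TumourModel


class ExportError(ValueError):
    pass


def _as_trimesh(mesh) -> trimesh.Trimesh:
    return mesh.mesh if isinstance(mesh, SurfaceMesh) else mesh


# ---------------------------------------------------------------------------
# STL


def write_stl(mesh, path, mode: str = "binary", force: bool = False) -> Path:
    """Write the mesh to STL at 1:1 scale (coordinates already in mm).

    Refuses non-watertight meshes unless ``force`` — a guide with open edges
    is not printable and its volume is undefined.
    """
    m = _as_trimesh(mesh)
    if not m.is_watertight and not force:
        raise ExportError("mesh is not watertight; pass force=True to export anyway")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if mode == "binary":
        data = m.export(file_type="stl")
        path.write_bytes(data)
    elif mode == "ascii":
        path.write_text(m.export(file_type="stl_ascii"))
    else:
        raise ExportError(f"unknown STL mode {mode!r}")
    return path


def read_stl(path) -> trimesh.Trimesh:
    m = trimesh.load(str(path), file_type="stl")
    return m


# ---------------------------------------------------------------------------
# slicing preview


def slice_preview(mesh, layer_thickness: float):
    """Planar contours at the print layer heights.

    Planes sit at ``z_min + (k + 0.5) * layer`` for ``k = 0 .. ceil(h/layer)-1``;
    every returned contour is a closed (first point == last point) polyline
    in the slicing plane.
    """
    if layer_thickness <= 0:
        raise ExportError("layer thickness must be positive")
    m = _as_trimesh(mesh)
    zmin, zmax = m.bounds[0][2], m.bounds[1][2]
    n = int(np.ceil((zmax - zmin) / layer_thickness))
    heights = zmin + (np.arange(n) + 0.5) * layer_thickness
    sections = m.section_multiplane(
        plane_origin=[0, 0, zmin], plane_normal=[0, 0, 1], heights=heights - zmin
    )
    return _collect_contours(heights, sections)


def _collect_contours(heights, sections):
    out = []
    for z, sec in zip(heights, sections):
        contours = []
        if sec is not None:
            for loop in sec.discrete:
                loop = np.asarray(loop)
                if len(loop) < 3:
                    continue
                if not np.allclose(loop[0], loop[-1]):
                    loop = np.vstack([loop, loop[0]])
                contours.append(loop)
        out.append((float(z), contours))
    return out


def contour_area(contours) -> float:
    """Even-odd total area of one plane's closed contours (holes subtract)."""
    from shapely.geometry import Polygon as _P

    polys = [_P(c) for c in contours if len(c) >= 4]
    area = 0.0
    for i, p in enumerate(polys):
        depth = sum(1 for j, q in enumerate(polys) if j != i and q.contains(p))
        area += p.area if depth % 2 == 0 else -p.area
    return area


# ---------------------------------------------------------------------------
# wall thickness


def measure_shell_thickness(mesh, n_samples: int = 2000, seed: int = 0,
                            max_valid: float = 10.0):
    """Wall thickness by inward ray casting from sampled surface points.

    Returns dict with median/p5/p95 over valid hits; samples whose inward ray
    exits through a hole, a void wall, or the rim (no hit, or an implausibly
    long first hit) are excluded by the hit-validity test.
    """
    m = _as_trimesh(mesh)
    if len(m.faces) < 4:
        raise ExportError("degenerate mesh")
    pts, fidx = trimesh.sample.sample_surface(m, n_samples, seed=seed)
    normals = m.face_normals[fidx]
    t, tri = ray_first_hit(m, pts, -normals, max_dist=max_valid)
    valid = np.isfinite(t) & (t > 0.05)
    if valid.sum() < 10:
        raise ExportError("too few valid thickness samples")
    tv = t[valid]
    return {
        "median": float(np.median(tv)),
        "p5": float(np.percentile(tv, 5)),
        "p95": float(np.percentile(tv, 95)),
        "n_valid": int(valid.sum()),
    }


# ---------------------------------------------------------------------------
# channel detection


def detect_channels(mesh, design: GuideDesign, raster_pitch: float = 0.1):
    """Find the injection channels on the mesh by through-hole cylinder fitting.

    Candidate through-holes are plan-raster components inside the resection
    annulus; a hole counts as a channel iff a cylinder fit to its wall has a
    radius within 25% of the design bore radius and an axis within 5 degrees
    of the pectoralis normal.  Returns a list of dicts (centre, axis, radius,
    angle) for accepted channels.
    """
    m = _as_trimesh(mesh)
    circ = design.resection_circle
    r_ch = design.params.channel_diameter / 2.0
    pad = 3.0 * r_ch + 2.0
    lo = circ.centre[:2] - circ.radius - pad
    hi = circ.centre[:2] + circ.radius + pad
    xs = np.arange(lo[0], hi[0], raster_pitch)
    ys = np.arange(lo[1], hi[1], raster_pitch)
    occ, top = plan_raster(m, xs, ys)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    rad = np.hypot(X - circ.centre[0], Y - circ.centre[1])
    annulus = np.abs(rad - circ.radius) <= 3.0 * r_ch
    holes = (~occ) & annulus
    labels, n = ndimage.label(holes)
    found = []
    normal = design.pect_normal / np.linalg.norm(design.pect_normal)
    verts = np.asarray(m.vertices)
    for lab in range(1, n + 1):
        comp = labels == lab
        area = comp.sum() * raster_pitch**2
        r_area = np.sqrt(area / np.pi)
        if not (0.5 * r_ch <= r_area <= 2.0 * r_ch):
            continue
        cx = X[comp].mean()
        cy = Y[comp].mean()
        # wall points: mesh vertices close to the hole axis over its depth
        plan_d = np.hypot(verts[:, 0] - cx, verts[:, 1] - cy)
        wall = (plan_d >= 0.6 * r_ch) & (plan_d <= 1.35 * r_ch)
        if wall.sum() < 12:
            continue
        centre, axis, radius = fit_cylinder_axis(
            verts[wall], axis_init=normal, centre_init=np.array([cx, cy, verts[wall][:, 2].mean()])
        )
        if axis @ normal < 0:
            axis = -axis
        dev = np.degrees(np.arccos(np.clip(axis @ normal, -1, 1)))
        if abs(radius - r_ch) / r_ch > 0.25 or dev > 5.0:
            continue
        found.append(
            {
                "centre": np.array([cx, cy]),
                "axis": axis,
                "radius": float(radius),
                "perp_dev_deg": float(dev),
            }
        )
    return found


# ---------------------------------------------------------------------------
# QC report


@dataclass
class QCReport:
    watertight: bool
    n_channels_detected: int
    channel_angular_gaps: list
    channel_perpendicularity_max_dev: float
    measured_margin: float
    shell_thickness_median: float
    shell_thickness_p5: float
    shell_thickness_p95: float
    min_rib_measured: float
    n_voids_retained: int
    slice_plane_spacing: float
    enclosed_volume: float

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2, default=float)
        if path is not None:
            Path(path).write_text(s)
        return s


def verify_design(mesh, design: GuideDesign, tumour: TumourModel) -> QCReport:
    """Measure every QC quantity from the mesh geometry alone."""
    m = _as_trimesh(mesh)
    channels = detect_channels(m, design)
    # angular positions around the fitted channel circle
    gaps: list = []
    measured_margin = float("nan")
    max_dev = float("nan")
    if len(channels) >= 3:
        centres = np.array([c["centre"] for c in channels])
        fit_centre, fit_radius = fit_circle_2d(centres)
        ang = np.degrees(
            np.arctan2(centres[:, 1] - fit_centre[1], centres[:, 0] - fit_centre[0])
        )
        ang = np.sort(ang % 360.0)
        gaps = list(np.diff(np.append(ang, ang[0] + 360.0)))
        measured_margin = float(fit_radius - tumour.projected_max_radius)
        max_dev = float(max(c["perp_dev_deg"] for c in channels))

    thickness = measure_shell_thickness(m)
    retained = [v for v in design.voids if v.retained]
    t_shell = design.params.shell_thickness
    min_rib = (
        measure_min_rib(m, design.voids, shell_thickness=t_shell)
        if len(retained) >= 2
        else float("inf")
    )
    n_voids = (
        count_detected_voids(m, design.voids, shell_thickness=t_shell)
        if retained
        else 0
    )

    # slice spacing measured from an actual slicing run over a 2 mm window
    zmin = m.bounds[0][2]
    layers = slice_preview_window(m, design.params.layer_thickness, zmin, zmin + 2.0)
    zs = np.array([z for z, _ in layers])
    spacing = float(np.diff(zs).mean()) if len(zs) > 1 else float("nan")

    return QCReport(
        watertight=bool(m.is_watertight),
        n_channels_detected=len(channels),
        channel_angular_gaps=[float(g) for g in gaps],
        channel_perpendicularity_max_dev=max_dev,
        measured_margin=measured_margin,
        shell_thickness_median=thickness["median"],
        shell_thickness_p5=thickness["p5"],
        shell_thickness_p95=thickness["p95"],
        min_rib_measured=float(min_rib),
        n_voids_retained=n_voids,
        slice_plane_spacing=spacing,
        enclosed_volume=float(m.volume),
    )


def slice_preview_window(mesh, layer_thickness, z0, z1):
    """Slice preview restricted to a z-window (same plane lattice as full run)."""
    m = _as_trimesh(mesh)
    zmin = m.bounds[0][2]
    if layer_thickness <= 0:
        raise ExportError("layer thickness must be positive")
    k0 = max(0, int(np.ceil((z0 - zmin) / layer_thickness - 0.5)))
    k1 = int(np.floor((z1 - zmin) / layer_thickness - 0.5))
    heights = zmin + (np.arange(k0, k1 + 1) + 0.5) * layer_thickness
    sections = m.section_multiplane(
        plane_origin=[0, 0, zmin], plane_normal=[0, 0, 1], heights=heights - zmin
    )
    return _collect_contours(heights, sections)


# ---------------------------------------------------------------------------
# embossed ID tab


def emboss_id_tag(design: GuideDesign, id_string: str,
                  sidecar_path=None) -> GuideDesign:
    """Attach a flat ID tab at a chest-plane rim point of the coverage region.

    The tab carries a grid of embossed pits encoding a 32-bit hash of the ID;
    the full metadata goes to a JSON sidecar (a printable barcode is outside
    the design pipeline's scope).  An empty ID leaves the guide unchanged.
    """
    if id_string == "":
        return design
    if len(id_string) > 32 or not id_string.isalnum():
        raise ExportError("ID must be alphanumeric and at most 32 characters")
    params = design.params
    t = params.shell_thickness
    # rim point on the chest plane (so the tab is flat and printable)
    boundary = np.asarray(design.omega.exterior.coords)
    breast_r = float(np.hypot(*design.breast.vertices[:, :2].T).max())
    on_plane = np.hypot(boundary[:, 0], boundary[:, 1]) > breast_r + 3.0
    if not on_plane.any():
        raise ExportError("no chest-plane rim available for the ID tab")
    cand = boundary[on_plane]
    anchor = cand[np.argmin(cand[:, 1])]  # most inferior flat rim point
    centroid = np.array(design.omega.centroid.coords[0])
    out_dir = anchor - centroid
    out_dir /= np.linalg.norm(out_dir)
    L, W = 24.0, 14.0  # tab size, mm
    centre = anchor + out_dir * (L / 2 - 3.0)  # overlap the rim by 3 mm
    u = out_dir
    v = np.array([-u[1], u[0]])

    digest = hashlib.sha256(id_string.encode()).hexdigest()[:8]
    bits = np.array([int(b) for b in bin(int(digest, 16))[2:].zfill(32)])

    grid = design.grid

    def tab_sdf(pts):
        local = pts[:, :2] - centre
        a = local @ u
        b = local @ v
        q = np.stack([np.abs(a) - L / 2, np.abs(b) - W / 2,
                      np.abs(pts[:, 2] - t / 2) - t / 2], axis=1)
        outside = np.linalg.norm(np.maximum(q, 0.0), axis=1)
        inside = np.minimum(q.max(axis=1), 0.0)
        return outside + inside

    field = np.minimum(design.field, grid.evaluate(tab_sdf).astype(np.float32))

    # pits: 8x4 grid of 1.4 mm squares, 0.8 mm deep, where the bit is set
    pit = 1.4
    step_a = L / 9.0
    step_b = W / 5.0
    pits = []
    for n, bit in enumerate(bits):
        if not bit:
            continue
        r, c = divmod(n, 8)
        a = -L / 2 + (c + 1) * step_a
        b = -W / 2 + (r + 1) * step_b
        pits.append((a, b))
    if pits:
        def pits_sdf(pts):
            local = pts[:, :2] - centre
            a = local @ u
            b = local @ v
            best = np.full(len(pts), BIG)
            for pa, pb in pits:
                q = np.stack(
                    [np.abs(a - pa) - pit / 2, np.abs(b - pb) - pit / 2,
                     np.abs(pts[:, 2] - t) - 0.8], axis=1)
                outside = np.linalg.norm(np.maximum(q, 0.0), axis=1)
                inside = np.minimum(q.max(axis=1), 0.0)
                best = np.minimum(best, outside + inside)
            return best

        field = np.maximum(field, -grid.evaluate(pits_sdf).astype(np.float32))

    new = design._evolve(field, id_tag=id_string)
    if sidecar_path is not None:
        Path(sidecar_path).write_text(
            json.dumps({"id": id_string, "hash": digest, "tab_centre":
                        [float(c) for c in centre], "tab_size_mm": [L, W]}, indent=2)
        )
    return new
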