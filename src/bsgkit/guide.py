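"""Guide geometry construction.

The guide is a conformal shell offset from the breast skin by the design
thickness, trimmed to a coverage region (resection circle + margin, the
nipple, and a midline arm reaching the manubrium), with four functional
features cut into it:

* a circular nipple hole — the primary registration landmark,
* a V-notch at the end of the midline arm whose vertex seats on the
  manubrium — the secondary registration landmark (dual positioning removes
  the rotational ambiguity of nipple-only placement),
* a resection circle at the tumour's projected maximal radius plus the safe
  margin, and
* evenly spaced dye-injection channels on that circle, drilled along the
  pectoralis normal so the dye is deposited perpendicular to the chest wall.

All solids live in the implicit kernel (`bsgkit.geometry`); every operation
updates the scalar field and the final mesh is extracted once, so the result
is watertight after any number of subtractions.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dc_field

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon

from .geometry import BIG, Grid, MeshSDF, Polygon2DSDF, mesh_field, sdf_cylinder
from .segrecon import SurfaceMesh, TumourModel


class DesignError(ValueError):
    pass


class BodySDF:
    """Signed distance to the skin body: breast mesh union the chest half-space."""

    def __init__(self, mesh_sdf: MeshSDF):
        self.mesh_sdf = mesh_sdf

    def __call__(self, pts):
        return np.minimum(self.mesh_sdf(pts), pts[:, 2])


@dataclass(frozen=True)
class DesignParams:
    """Every design constant, with the defaults the guide is specified at.

    margin              safe resection margin added around the projected
                        tumour boundary (5 mm = 0.5 cm per side by default;
                        ``margin_mode='diameter'`` instead spreads the 5 mm
                        over the full diameter, i.e. 2.5 mm per side)
    n_channels          dye-injection channels evenly spread on the circle
    shell_thickness     conformal shell wall thickness, mm
    channel_diameter    injection channel bore, mm (fits an injection needle)
    nipple_hole_diameter  primary positioning hole, mm
    n_voronoi           Voronoi cells seeded for lightweighting
    min_rib             minimum solid rib between adjacent voids, mm
    rib_allowance       extra rib width carved beyond min_rib to absorb
                        discretisation, mm
    layer_thickness     slicing layer height for print preview, mm
    channel_start_angle first channel's angular position, degrees CCW from
                        the direction toward the manubrium
    coverage_margin     how far the shell extends beyond the resection
                        circle, mm
    nipple_pad          solid coverage kept around the nipple hole, mm
    arm_width           width of the midline arm to the manubrium, mm
    notch_depth         depth of the manubrium V-notch, mm
    notch_half_angle    half-opening of the V-notch, degrees
    mesh_pitch          implicit-grid sampling pitch, mm
    seed                RNG seed for the lightweighting pattern
    """

    margin: float = 5.0
    margin_mode: str = "radial"  # or "diameter"
    n_channels: int = 8
    shell_thickness: float = 3.0
    channel_diameter: float = 2.0
    nipple_hole_diameter: float = 25.0
    n_voronoi: int = 80
    min_rib: float = 3.0
    rib_allowance: float = 0.35
    min_void_area: float = 8.0  # mm^2; smaller cells are kept solid
    layer_thickness: float = 0.1
    channel_start_angle: float = 0.0
    coverage_margin: float = 20.0
    nipple_pad: float = 10.0
    arm_width: float = 18.0
    notch_depth: float = 6.0
    notch_half_angle: float = 30.0
    mesh_pitch: float = 0.5
    seed: int = 42

    MIN_PRINTABLE_RIB = 1.0

    def validate(self) -> None:
        lengths = dict(
            margin=self.margin,
            shell_thickness=self.shell_thickness,
            channel_diameter=self.channel_diameter,
            nipple_hole_diameter=self.nipple_hole_diameter,
            min_rib=self.min_rib,
            layer_thickness=self.layer_thickness,
            coverage_margin=self.coverage_margin,
            arm_width=self.arm_width,
            mesh_pitch=self.mesh_pitch,
        )
        for name, v in lengths.items():
            if v <= 0:
                raise DesignError(f"{name} must be > 0, got {v}")
        if self.n_channels < 3:
            raise DesignError("need at least 3 injection channels")
        if self.min_rib < self.MIN_PRINTABLE_RIB:
            raise DesignError(
                f"min_rib {self.min_rib} mm is below the printability bound "
                f"({self.MIN_PRINTABLE_RIB} mm)"
            )
        if self.margin_mode not in ("radial", "diameter"):
            raise DesignError("margin_mode must be 'radial' or 'diameter'")

    @property
    def margin_per_side(self) -> float:
        return self.margin if self.margin_mode == "radial" else self.margin / 2.0


@dataclass(frozen=True)
class ResectionCircle:
    """The resection boundary circle in the chest-wall-parallel plane."""

    centre: np.ndarray  # 3-vector, on the chest-wall plane
    radius: float
    normal: np.ndarray

    def point_at(self, angle_deg: float, reference_dir: np.ndarray) -> np.ndarray:
        """Point on the circle at ``angle_deg`` CCW from ``reference_dir`` (plan)."""
        ref = np.asarray(reference_dir, dtype=float)[:2]
        ref = ref / np.linalg.norm(ref)
        a = np.deg2rad(angle_deg)
        d = np.array(
            [
                ref[0] * np.cos(a) - ref[1] * np.sin(a),
                ref[0] * np.sin(a) + ref[1] * np.cos(a),
            ]
        )
        return self.centre + self.radius * np.array([d[0], d[1], 0.0])


@dataclass(frozen=True)
class ChannelSpec:
    entry_point: np.ndarray
    axis: np.ndarray
    diameter: float
    angle_deg: float


@dataclass
class GuideDesign:
    """The guide under construction: implicit field plus structured feature specs."""

    grid: Grid
    field: np.ndarray
    body_sdf: object  # callable (N,3)->(N,): signed distance to the skin body
    omega: Polygon  # plan-view coverage region
    params: DesignParams
    landmarks: object
    pect_normal: np.ndarray
    breast: SurfaceMesh
    resection_circle: ResectionCircle
    nipple_hole: dict | None = None
    notch: dict | None = None
    channels: list = dc_field(default_factory=list)
    voids: list = dc_field(default_factory=list)
    id_tag: str = ""
    _mesh_cache: object = None

    def _evolve(self, new_field: np.ndarray, **changes) -> "GuideDesign":
        new = copy.copy(self)
        new.field = new_field
        new._mesh_cache = None
        for k, v in changes.items():
            setattr(new, k, v)
        return new

    @property
    def shell(self) -> SurfaceMesh:
        if self._mesh_cache is None:
            self._mesh_cache = SurfaceMesh(
                mesh=mesh_field(self.grid, self.field), role="guide"
            )
        return self._mesh_cache

    @property
    def n_registration_features(self) -> int:
        return int(self.nipple_hole is not None) + int(self.notch is not None)

    def omega_sdf(self) -> Polygon2DSDF:
        return Polygon2DSDF(self.omega)


# ---------------------------------------------------------------------------


def compute_resection_circle(
    tumour: TumourModel,
    params: DesignParams,
    pect_normal=(0.0, 0.0, 1.0),
) -> ResectionCircle:
    """Project the tumour centre to the chest-wall plane and add the margin.

    A zero margin is the degenerate identity (circle at the projected tumour
    boundary); a negative margin is rejected.
    """
    if params.margin < 0:
        raise DesignError(f"resection margin must be >= 0, got {params.margin}")
    centre = np.array([tumour.centre[0], tumour.centre[1], 0.0])
    radius = tumour.projected_max_radius + params.margin_per_side
    n = np.asarray(pect_normal, dtype=float)
    return ResectionCircle(centre=centre, radius=radius, normal=n / np.linalg.norm(n))


def _coverage_polygon(circle, landmarks, params) -> Polygon:
    nip = np.asarray(landmarks.nipple[:2], dtype=float)
    man = np.asarray(landmarks.manubrium[:2], dtype=float)
    discs = [
        Point(circle.centre[:2]).buffer(circle.radius + params.coverage_margin, 64),
        Point(nip).buffer(params.nipple_hole_diameter / 2 + params.nipple_pad, 64),
    ]
    u = man - nip
    dist = np.linalg.norm(u)
    if dist < 1e-9:
        raise DesignError("nipple and manubrium coincide")
    u = u / dist
    overhang = params.notch_depth + 4.0
    arm = LineString([nip, man + u * overhang]).buffer(
        params.arm_width / 2, 16, cap_style="flat"
    )
    return shapely.unary_union(discs + [arm])


def fit_guide_shell(
    breast: SurfaceMesh,
    landmarks,
    circle: ResectionCircle,
    params: DesignParams,
    pect_normal=(0.0, 0.0, 1.0),
) -> GuideDesign:
    """Build the conformal shell: offset band of the skin, trimmed to coverage.

    The skin body is the union of the reconstructed breast and the chest
    half-space z <= 0; the shell is the band 0 <= d(skin) <= thickness,
    intersected with the prism over the plan-view coverage region.  An
    implicit offset cannot self-intersect, so no repair pass is needed.
    """
    params.validate()
    if not breast.is_watertight:
        raise DesignError("breast mesh must be watertight")
    t = params.shell_thickness
    omega = _coverage_polygon(circle, landmarks, params)
    mesh_sdf = MeshSDF(breast.mesh)
    body_sdf = BodySDF(mesh_sdf)

    pitch = params.mesh_pitch
    lo2, hi2 = np.array(omega.bounds[:2]), np.array(omega.bounds[2:])
    zhi = float(breast.vertices[:, 2].max()) + t + 2 * pitch
    grid = Grid.from_bounds(
        [lo2[0], lo2[1], -2 * pitch], [hi2[0], hi2[1], zhi], pitch, pad=3
    )

    field = _shell_band_field(grid, mesh_sdf, omega, t, pitch)

    design = GuideDesign(
        grid=grid,
        field=field,
        body_sdf=body_sdf,
        omega=omega,
        params=params,
        landmarks=landmarks,
        pect_normal=np.asarray(pect_normal, dtype=float),
        breast=breast,
        resection_circle=circle,
    )
    return design


def _shell_band_field(grid, mesh_sdf, omega, thickness, pitch):
    """Evaluate max(-d, d - t, omega) with a two-stage nearest-vertex scheme.

    A cheap k=1 distance bounds the body distance everywhere; the accurate
    k-NN normal projection is only run in the band near the skin where the
    level sets live.
    """
    xs, ys, zs = grid.axes()
    om = Polygon2DSDF(omega)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    sd2d = om(np.column_stack([X.ravel(), Y.ravel()])).reshape(X.shape)
    field = np.full(grid.shape, BIG, dtype=np.float32)
    cols = sd2d <= 2 * pitch  # columns that can contribute surface
    pts2 = np.column_stack([X[cols], Y[cols]])
    v = mesh_sdf.vertices
    n2 = len(pts2)
    chunk = 16
    for k0 in range(0, len(zs), chunk):
        zk = zs[k0 : k0 + chunk]
        pts = np.empty((n2 * len(zk), 3))
        pts[:, :2] = np.repeat(pts2, len(zk), axis=0)
        pts[:, 2] = np.tile(zk, n2)
        d1, idx = mesh_sdf.tree.query(pts, k=1)
        diff = pts - v[idx]
        f = np.einsum("nd,nd->n", diff, mesh_sdf.normals[idx])
        band = d1 <= thickness + 4 * pitch
        if band.any():
            f[band] = mesh_sdf(pts[band])
        f = np.minimum(f, pts[:, 2])  # union with the chest half-space
        vals = np.maximum(np.maximum(-f, f - thickness), np.repeat(sd2d[cols], len(zk)))
        block = np.full((X.shape[0], X.shape[1], len(zk)), BIG, dtype=np.float32)
        block[cols, :] = vals.reshape(n2, len(zk))
        field[:, :, k0 : k0 + len(zk)] = block
    return field


# ---------------------------------------------------------------------------


def _surface_normal_at(design: GuideDesign, point, radius=4.0) -> np.ndarray:
    """Mean breast vertex normal near a surface point (the local skin normal)."""
    sdf = MeshSDF(design.breast.mesh)
    idx = sdf.tree.query_ball_point(np.asarray(point, dtype=float), r=radius)
    if len(idx) == 0:
        _, i = sdf.tree.query(np.asarray(point, dtype=float))
        idx = [i]
    n = sdf.normals[idx].mean(axis=0)
    return n / np.linalg.norm(n)


def place_nipple_hole(
    design: GuideDesign, landmarks=None, params: DesignParams | None = None
) -> GuideDesign:
    """Drill the primary positioning hole through the shell at the nipple."""
    landmarks = landmarks or design.landmarks
    params = params or design.params
    nip = np.asarray(landmarks.nipple, dtype=float)
    r = params.nipple_hole_diameter / 2.0
    if not design.omega.contains(Point(nip[:2]).buffer(r, 16)):
        raise DesignError("nipple hole is not fully inside the shell coverage region")
    c = design.resection_circle
    clearance = (
        np.linalg.norm(nip[:2] - c.centre[:2])
        - r
        - c.radius
        - params.channel_diameter / 2.0
    )
    if clearance < params.min_rib:
        raise DesignError(
            "nipple hole would overlap the injection-channel annulus "
            f"(clearance {clearance:.1f} mm < min rib {params.min_rib} mm); "
            "use a smaller hole or a laterally farther tumour/breast"
        )
    axis = _surface_normal_at(design, nip)

    def cut(pts):
        return sdf_cylinder(pts, nip, axis, r)

    new_field = np.maximum(design.field, -design.grid.evaluate(cut))
    return design._evolve(
        new_field,
        nipple_hole={"centre": nip, "axis": axis, "diameter": params.nipple_hole_diameter},
    )


def place_manubrium_feature(design: GuideDesign, landmarks=None) -> GuideDesign:
    """Cut the V-notch whose vertex seats on the manubrium landmark."""
    landmarks = landmarks or design.landmarks
    params = design.params
    man = np.asarray(landmarks.manubrium, dtype=float)
    nip = np.asarray(landmarks.nipple, dtype=float)
    if not design.omega.buffer(1.0).contains(Point(man[:2])):
        raise DesignError(
            "midline arm does not reach the manubrium; increase arm length/volume bounds"
        )
    u = man[:2] - nip[:2]
    u = u / np.linalg.norm(u)
    depth = params.notch_depth + 8.0  # overshoot so the cut clears the arm end
    w = depth * np.tan(np.deg2rad(params.notch_half_angle))
    perp = np.array([-u[1], u[0]])
    tri = Polygon(
        [
            tuple(man[:2]),
            tuple(man[:2] + u * depth + perp * w),
            tuple(man[:2] + u * depth - perp * w),
        ]
    )
    tri_sdf = Polygon2DSDF(tri)
    new_field = np.maximum(
        design.field, -design.grid.evaluate(lambda p: tri_sdf(p[:, :2]))
    )
    vertex = np.array([man[0], man[1], 0.0])
    return design._evolve(
        new_field,
        omega=design.omega.difference(tri),
        notch={"vertex": vertex, "half_angle": params.notch_half_angle,
               "depth": params.notch_depth, "direction": u},
    )


def place_injection_channels(
    design: GuideDesign,
    circle: ResectionCircle | None = None,
    pect_normal=None,
    params: DesignParams | None = None,
) -> tuple[GuideDesign, list[ChannelSpec]]:
    """Drill the evenly spaced dye-injection channels along the pectoralis normal."""
    circle = circle or design.resection_circle
    params = params or design.params
    normal = np.asarray(
        pect_normal if pect_normal is not None else design.pect_normal, dtype=float
    )
    normal = normal / np.linalg.norm(normal)
    n = params.n_channels
    r_ch = params.channel_diameter / 2.0

    gap = 2.0 * circle.radius * np.sin(np.pi / n) - params.channel_diameter
    if gap < params.min_rib:
        raise DesignError(
            f"adjacent channels would be {gap:.1f} mm apart (< min rib "
            f"{params.min_rib} mm): the resection circle is too small for "
            f"{n} channels of {params.channel_diameter} mm"
        )
    ring = Point(circle.centre[:2]).buffer(circle.radius + r_ch, 64).difference(
        Point(circle.centre[:2]).buffer(max(circle.radius - r_ch, 0.0), 64)
    )
    if not design.omega.contains(ring):
        raise DesignError("resection circle is not fully inside the shell coverage")
    if design.nipple_hole is not None:
        hole_r = design.nipple_hole["diameter"] / 2.0
        d_nip = np.linalg.norm(
            design.nipple_hole["centre"][:2] - circle.centre[:2]
        )
        if d_nip - circle.radius - r_ch - hole_r < params.min_rib:
            raise DesignError("injection channels would intersect the nipple hole")

    ref_dir = design.landmarks.manubrium[:2] - circle.centre[:2]
    angles = params.channel_start_angle + 360.0 * np.arange(n) / n
    centres = [circle.point_at(a, ref_dir) for a in angles]

    field = design.field
    specs = []
    for a, c in zip(angles, centres):
        cut = design.grid.evaluate(lambda p: sdf_cylinder(p, c, normal, r_ch))
        field = np.maximum(field, -cut)
        entry = _cast_to_outer_surface(design, c, normal)
        specs.append(
            ChannelSpec(
                entry_point=entry,
                axis=normal.copy(),
                diameter=params.channel_diameter,
                angle_deg=float(a % 360.0),
            )
        )
    new = design._evolve(field, channels=specs)
    return new, specs


def _cast_to_outer_surface(design: GuideDesign, point, direction, max_dist=200.0):
    """March along ``direction`` from the chest plane to the outer shell surface
    (the level set body-distance == shell thickness)."""
    t = design.params.shell_thickness
    p0 = np.asarray(point, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)

    def g(s):
        return float(design.body_sdf((p0 + s * d)[None, :])[0]) - t

    lo, hi = 0.0, max_dist
    if g(lo) > 0:  # started outside the body: walk in until inside
        lo = -max_dist
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if g(mid) <= 0:
            lo = mid
        else:
            hi = mid
    return p0 + 0.5 * (lo + hi) * d
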