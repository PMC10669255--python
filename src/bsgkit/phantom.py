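"""Synthetic supine-breast phantom generation.

The phantom is a digital stand-in for a supine, contrast-enhanced breast MRI
acquisition: a superellipsoid breast dome resting on a flat chest-wall
(pectoralis) plane at z = 0, with a bright ellipsoidal tumour embedded in the
gland, additive Gaussian image noise, and the two registration landmarks the
guide design needs (nipple apex and manubrium).

Coordinate convention (used by every module): right-handed patient frame in
mm; +z anterior (out of the chest, chest-wall plane at z = 0), +x patient-left
lateral, +y superior.  Voxel index ``(i,j,k)`` maps to the voxel-centre
position ``origin + index * spacing``.

Labels: 0 = outside the body, 1 = breast gland, 2 = tumour, 3 = pectoralis
surface stratum (the one-voxel chest-wall layer surrounding the dome, from
which the injection normal field is derived).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.spatial.transform import Rotation

MAX_SLICE_SPACING = 3.0  # mm; acquisitions must be finer than this

LABEL_OUTSIDE = 0
LABEL_BREAST = 1
LABEL_TUMOUR = 2
LABEL_PECTORALIS = 3


class PhantomError(ValueError):
    """Invalid phantom parameterisation."""


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, intensity and noise parameters of the synthetic acquisition.

    Defaults describe the reference phantom used throughout: a hemispherical
    breast of radius 60 mm with a lateral 24x16x12 mm tumour at 20 mm depth
    above the chest wall, imaged at 1 mm isotropic voxels with a
    contrast-enhanced tumour twice as bright as the gland relative to noise.
    """

    breast_base_radius: float = 60.0
    breast_height: float = 60.0
    dome_exponent: float = 2.0
    tumour_centre: tuple = (38.0, 0.0, 20.0)
    tumour_semi_axes: tuple = (12.0, 8.0, 6.0)
    tumour_rotation: tuple = (0.0, 0.0, 0.0)  # Euler xyz, degrees
    voxel_spacing: tuple = (1.0, 1.0, 1.0)
    noise_sd: float = 15.0
    tumour_intensity: float = 300.0
    background_intensity: float = 100.0
    outside_intensity: float = 0.0
    manubrium_y: float = 120.0
    seed: int = 42

    def validate(self) -> None:
        a, b, c = self.tumour_semi_axes
        if not (a >= b >= c > 0):
            raise PhantomError(
                f"tumour semi-axes must satisfy a >= b >= c > 0, got {self.tumour_semi_axes}"
            )
        if any(s <= 0 for s in self.voxel_spacing):
            raise PhantomError("voxel spacing must be positive")
        if any(s >= MAX_SLICE_SPACING for s in self.voxel_spacing):
            raise PhantomError(
                f"voxel spacing {self.voxel_spacing} mm has a component >= "
                f"{MAX_SLICE_SPACING} mm; the pipeline requires finer slices"
            )
        if self.breast_base_radius <= 0 or self.breast_height <= 0:
            raise PhantomError("breast dimensions must be positive")
        self._check_tumour_inside()

    def _check_tumour_inside(self, n_dirs: int = 400) -> None:
        """Reject tumours whose surface leaves the breast dome."""
        rng = np.random.default_rng(0)
        dirs = rng.normal(size=(n_dirs, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        R = Rotation.from_euler("xyz", self.tumour_rotation, degrees=True).as_matrix()
        surf = np.asarray(self.tumour_centre) + (
            dirs * np.asarray(self.tumour_semi_axes)
        ) @ R.T
        inside = _inside_dome(
            surf, self.breast_base_radius, self.breast_height, self.dome_exponent
        )
        if not inside.all():
            worst = surf[~inside][0]
            raise PhantomError(
                "tumour is not fully inside the breast dome: surface point "
                f"{np.round(worst, 2)} mm lies outside the dome "
                f"(base radius {self.breast_base_radius} mm, height {self.breast_height} mm)"
            )


def _inside_dome(points, base_radius, height, exponent):
    """Superellipsoid dome test: (rho/R)^e + (z/H)^e <= 1 with z >= 0."""
    p = np.asarray(points, dtype=float)
    rho = np.hypot(p[..., 0], p[..., 1])
    z = p[..., 2]
    val = (rho / base_radius) ** exponent + (np.maximum(z, 0.0) / height) ** exponent
    return (z >= 0) & (val <= 1.0)


@dataclass
class LabelledVolume:
    """Intensity + label voxel grids with physical spacing/origin (mm)."""

    intensity: np.ndarray
    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int16)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.intensity.shape != self.labels.shape:
            raise PhantomError("intensity and label grids must share a shape")
        if (self.spacing <= 0).any():
            raise PhantomError("spacing must be positive")
        bad = set(np.unique(self.labels)) - {0, 1, 2, 3}
        if bad:
            raise PhantomError(f"unknown labels present: {sorted(bad)}")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centres(self, mask: np.ndarray) -> np.ndarray:
        idx = np.argwhere(mask)
        return self.origin + idx * self.spacing


@dataclass(frozen=True)
class LandmarkSet:
    """The two registration landmarks, in mm patient coordinates."""

    nipple: np.ndarray
    manubrium: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "nipple", np.asarray(self.nipple, dtype=float))
        object.__setattr__(self, "manubrium", np.asarray(self.manubrium, dtype=float))


def make_breast_phantom(params: PhantomParams) -> tuple[LabelledVolume, LandmarkSet]:
    """Generate the labelled volume and landmarks for one synthetic acquisition.

    Deterministic for a fixed ``params.seed``: the label field is purely
    analytic (a voxel is labelled iff its centre lies inside the shape) and
    the only randomness is the additive Gaussian intensity noise.
    """
    params.validate()
    sp = np.asarray(params.voxel_spacing, dtype=float)
    R = params.breast_base_radius
    H = params.breast_height
    pad = 3.0
    lo = np.array([-(R + pad), -(R + pad), -2.0 * sp[2] - 0.5])
    hi = np.array([R + pad, max(R + pad, params.manubrium_y + 6.0), H + pad])
    # snap the origin to the spacing lattice so that x=0, y=0, z=0 are voxel centres
    origin = np.floor(lo / sp) * sp
    shape = np.ceil((hi - origin) / sp).astype(int) + 1

    xs = origin[0] + sp[0] * np.arange(shape[0])
    ys = origin[1] + sp[1] * np.arange(shape[1])
    zs = origin[2] + sp[2] * np.arange(shape[2])
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)

    in_dome = _inside_dome(pts, R, H, params.dome_exponent)

    Rm = Rotation.from_euler("xyz", params.tumour_rotation, degrees=True).as_matrix()
    local = (pts - np.asarray(params.tumour_centre)) @ Rm
    in_tum = ((local / np.asarray(params.tumour_semi_axes)) ** 2).sum(axis=-1) <= 1.0

    pect = (Z >= 0.0) & (Z < sp[2]) & ~in_dome

    labels = np.zeros(tuple(shape), dtype=np.int16)
    labels[pect] = LABEL_PECTORALIS
    labels[in_dome] = LABEL_BREAST
    labels[in_tum] = LABEL_TUMOUR

    intensity = np.full(tuple(shape), params.outside_intensity, dtype=np.float32)
    intensity[labels == LABEL_BREAST] = params.background_intensity
    intensity[labels == LABEL_PECTORALIS] = params.background_intensity
    intensity[labels == LABEL_TUMOUR] = params.tumour_intensity
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        intensity = intensity + rng.normal(
            0.0, params.noise_sd, size=intensity.shape
        ).astype(np.float32)

    volume = LabelledVolume(intensity, labels, sp, origin)

    # nipple = apex: the breast voxel with the greatest anterior coordinate
    # (ties broken toward the midline axis)
    breast_idx = np.argwhere(labels == LABEL_BREAST)
    centres = origin + breast_idx * sp
    zmax = centres[:, 2].max()
    at_top = centres[np.abs(centres[:, 2] - zmax) < 1e-9]
    nipple = at_top[np.argmin(np.hypot(at_top[:, 0], at_top[:, 1]))]
    landmarks = LandmarkSet(
        nipple=nipple, manubrium=np.array([0.0, params.manubrium_y, 0.0])
    )
    return volume, landmarks


def pectoralis_normal(volume: LabelledVolume) -> np.ndarray:
    """Outward (anterior) unit normal of the chest-wall plane.

    Fitted from the label-3 stratum voxel centres; for the flat phantom this
    is +z exactly, but the fit keeps downstream code honest about where the
    injection direction comes from.
    """
    pts = volume.voxel_centres(volume.labels == LABEL_PECTORALIS)
    if len(pts) < 3:
        return np.array([0.0, 0.0, 1.0])
    centred = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    n = vt[2]
    return n if n[2] > 0 else -n


# ---------------------------------------------------------------------------
# on-disk format: NIfTI volumes + JSON landmarks


def write_phantom(volume: LabelledVolume, landmarks: LandmarkSet, path) -> dict:
    """Write ``intensity.nii.gz``, ``labels.nii.gz`` and ``landmarks.json``.

    The NIfTI affine is diagonal(spacing) with the origin in the translation
    column, so world coordinates round-trip exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*volume.spacing, 1.0])
    affine[:3, 3] = volume.origin
    files = {}
    for name, arr in [("intensity", volume.intensity), ("labels", volume.labels)]:
        img = nib.Nifti1Image(np.asarray(arr), affine)
        f = path / f"{name}.nii.gz"
        nib.save(img, f)
        files[name] = f
    lm = path / "landmarks.json"
    lm.write_text(
        json.dumps(
            {
                "nipple": [float(v) for v in landmarks.nipple],
                "manubrium": [float(v) for v in landmarks.manubrium],
            },
            indent=2,
        )
    )
    files["landmarks"] = lm
    return files


def read_phantom(path) -> tuple[LabelledVolume, LandmarkSet]:
    path = Path(path)
    inten = nib.load(path / "intensity.nii.gz")
    lab = nib.load(path / "labels.nii.gz")
    affine = inten.affine
    spacing = np.diag(affine)[:3].copy()
    origin = affine[:3, 3].copy()
    volume = LabelledVolume(
        np.asarray(inten.dataobj, dtype=np.float32),
        np.asarray(lab.dataobj, dtype=np.int16),
        spacing,
        origin,
    )
    d = json.loads((path / "landmarks.json").read_text())
    return volume, LandmarkSet(np.array(d["nipple"]), np.array(d["manubrium"]))
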