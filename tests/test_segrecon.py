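"""Segmentation + reconstruction: thresholding, meshing, tumour axes."""

from dataclasses import replace

import numpy as np
import pytest
import trimesh

from bsgkit import phantom as ph
from bsgkit import segrecon as sr

NOISELESS = ph.PhantomParams(noise_sd=0.0)
MID_THRESHOLD = 200.0  # midway between gland (100) and enhanced tumour (300)


@pytest.fixture(scope="module")
def noiseless_volume():
    return ph.make_breast_phantom(NOISELESS)[0]


@pytest.fixture(scope="module")
def noisy_volume():
    return ph.make_breast_phantom(ph.PhantomParams(seed=42))[0]


def test_noiseless_threshold_recovers_exact_tumour(noiseless_volume):
    mask = sr.threshold_segment(noiseless_volume, MID_THRESHOLD)
    np.testing.assert_array_equal(mask, noiseless_volume.labels == 2)


def test_threshold_above_everything_reports_no_lesion(noiseless_volume):
    with pytest.raises(sr.NoLesionFoundError):
        sr.threshold_segment(noiseless_volume, 1e6)


def test_noisy_segmentation_dice_at_least_095(noisy_volume):
    mask = sr.threshold_segment(noisy_volume, MID_THRESHOLD)
    truth = noisy_volume.labels == 2
    dice = 2.0 * (mask & truth).sum() / (mask.sum() + truth.sum())
    assert dice >= 0.95


def test_slicewise_mode_matches_global_threshold(noisy_volume):
    a = sr.threshold_segment(noisy_volume, MID_THRESHOLD, slicewise=False)
    b = sr.threshold_segment(noisy_volume, MID_THRESHOLD, slicewise=True)
    np.testing.assert_array_equal(a, b)


def test_raw_mask_is_monotone_in_threshold(noisy_volume):
    prev = None
    for t in (150.0, 200.0, 250.0):
        mask = sr.threshold_segment(noisy_volume, t, largest_component=False)
        if prev is not None:
            assert (mask <= prev).all()  # higher threshold is a subset
        prev = mask


def _sphere_mask(radius, spacing):
    n = int(np.ceil(radius / spacing)) + 3
    ax = spacing * np.arange(-n, n + 1)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    return (X**2 + Y**2 + Z**2 <= radius**2), ax[0]


def test_sphere_reconstruction_volume_and_watertightness():
    mask, o = _sphere_mask(10.0, 1.0)
    mesh = sr.reconstruct_surface(mask, (1, 1, 1), (o, o, o), smoothing_iters=0)
    analytic = 4.0 / 3.0 * np.pi * 1000.0
    assert mesh.is_watertight
    assert abs(mesh.volume - analytic) / analytic < 0.05


def test_smoothing_preserves_volume_within_2_percent():
    mask, o = _sphere_mask(10.0, 1.0)
    raw = sr.reconstruct_surface(mask, (1, 1, 1), (o, o, o), smoothing_iters=0)
    smooth = sr.reconstruct_surface(mask, (1, 1, 1), (o, o, o), smoothing_iters=10)
    assert abs(smooth.volume - raw.volume) / raw.volume < 0.02


def test_reconstruction_error_shrinks_with_spacing():
    analytic = 4.0 / 3.0 * np.pi * 1000.0
    errors = []
    for sp in (2.0, 1.0, 0.5):
        mask, o = _sphere_mask(10.0, sp)
        mesh = sr.reconstruct_surface(mask, (sp,) * 3, (o,) * 3, smoothing_iters=0)
        errors.append(abs(mesh.volume - analytic) / analytic)
    assert errors[0] > errors[1] > errors[2]


def test_boundary_touching_mask_is_rejected():
    mask = np.ones((4, 4, 4), dtype=bool)
    with pytest.raises(ValueError, match="pad"):
        sr.reconstruct_surface(mask, (1, 1, 1), (0, 0, 0))


# ---------------------------------------------------------------------------
# tumour axes


@pytest.fixture(scope="module")
def ellipsoid_model(noiseless_volume):
    mask = sr.threshold_segment(noiseless_volume, MID_THRESHOLD)
    mesh = sr.reconstruct_surface(
        mask, noiseless_volume.spacing, noiseless_volume.origin
    )
    return sr.tumour_axes(mesh)


def test_ellipsoid_longest_axis_and_centre(ellipsoid_model):
    voxdiag = np.sqrt(3.0)
    assert abs(ellipsoid_model.axis_length - 24.0) <= voxdiag
    np.testing.assert_allclose(
        ellipsoid_model.centre, [38.0, 0.0, 20.0], atol=0.87  # half voxel diagonal
    )
    np.testing.assert_allclose(
        ellipsoid_model.centre, (ellipsoid_model.axis_p + ellipsoid_model.axis_q) / 2
    )


def test_ellipsoid_projected_max_radius(ellipsoid_model):
    assert abs(ellipsoid_model.projected_max_radius - 12.0) <= np.sqrt(3.0)


def test_axis_length_invariant_under_rotation():
    rng = np.random.default_rng(0)
    lengths = []
    for _ in range(5):
        euler = rng.uniform(-90, 90, size=3)
        pp = replace(
            NOISELESS,
            tumour_centre=(0.0, 0.0, 30.0),
            tumour_rotation=tuple(euler),
        )
        vol, _ = ph.make_breast_phantom(pp)
        mask = sr.threshold_segment(vol, MID_THRESHOLD)
        mesh = sr.reconstruct_surface(mask, vol.spacing, vol.origin)
        lengths.append(sr.tumour_axes(mesh).axis_length)
    assert np.ptp(lengths) < 2.0 * np.sqrt(3.0)
    assert abs(np.mean(lengths) - 24.0) < np.sqrt(3.0)


@pytest.mark.parametrize("subdiv", [2, 3])  # 162 and 642 vertices
def test_hull_search_equals_bruteforce_on_small_meshes(subdiv):
    m = trimesh.creation.icosphere(subdiv)
    m.vertices *= np.array([12.0, 8.0, 6.0])
    surf = sr.SurfaceMesh(mesh=m, role="tumour")
    model = sr.tumour_axes(surf)
    i, j, length = sr.longest_axis_bruteforce(m.vertices)
    assert model.axis_length == pytest.approx(length, abs=1e-12)
    np.testing.assert_allclose(model.axis_p, m.vertices[i])
    np.testing.assert_allclose(model.axis_q, m.vertices[j])


def test_hull_search_equals_bruteforce_above_decimation_size():
    rng = np.random.default_rng(1)
    m = trimesh.creation.icosphere(4)  # 2562 vertices: the hull path engages
    m.vertices *= np.array([12.0, 8.0, 6.0])
    m.vertices += rng.normal(0, 0.01, m.vertices.shape)
    surf = sr.SurfaceMesh(mesh=m, role="tumour")
    model = sr.tumour_axes(surf)
    _, _, length = sr.longest_axis_bruteforce(m.vertices)
    assert model.axis_length == pytest.approx(length, abs=1e-12)


def test_pca_axis_option_matches_chord_for_a_clean_ellipsoid():
    m = trimesh.creation.icosphere(3)
    m.vertices *= np.array([12.0, 8.0, 6.0])
    surf = sr.SurfaceMesh(mesh=m, role="tumour")
    chord = sr.tumour_axes(surf, method="chord")
    pca = sr.tumour_axes(surf, method="pca")
    assert abs(chord.axis_length - pca.axis_length) < 0.5


def test_degenerate_mesh_is_rejected():
    m = trimesh.Trimesh(vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]], faces=[[0, 1, 2]])
    with pytest.raises(sr.DegenerateMeshError):
        sr.tumour_axes(sr.SurfaceMesh(mesh=m, role="tumour"))


# ---------------------------------------------------------------------------
# slice-spacing validation


@pytest.mark.parametrize(
    "spacing,ok",
    [((1.0, 1.0, 2.9), True), ((1.0, 1.0, 3.0), False), ((0.5, 0.5, 0.5), True)],
)
def test_slice_spacing_bound_is_strict(spacing, ok):
    vol = ph.LabelledVolume(
        intensity=np.zeros((3, 3, 3), dtype=np.float32),
        labels=np.zeros((3, 3, 3), dtype=np.int16),
        spacing=np.array(spacing),
        origin=np.zeros(3),
    )
    assert sr.validate_slice_spacing(vol).ok is ok
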