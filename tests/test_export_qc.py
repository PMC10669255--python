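"""STL export, slicing, thickness measurement, channel detection, ID tab."""

import json

import numpy as np
import pytest
import trimesh

from bsgkit import export_qc as eq
from bsgkit.geometry import Grid, mesh_field


def test_unit_cube_stl_round_trip(tmp_path):
    cube = trimesh.creation.box(extents=(1, 1, 1))
    path = eq.write_stl(cube, tmp_path / "cube.stl")
    assert path.stat().st_size == 84 + 50 * len(cube.faces)  # binary STL layout
    back = eq.read_stl(path)
    assert len(back.faces) == 12
    assert back.volume == pytest.approx(1.0, abs=1e-9)
    assert len(back.vertices) == len(cube.vertices)


def test_ascii_stl_mode(tmp_path):
    cube = trimesh.creation.box(extents=(2, 2, 2))
    path = eq.write_stl(cube, tmp_path / "cube.stl", mode="ascii")
    text = path.read_text()
    assert text.lstrip().startswith("solid")
    assert eq.read_stl(path).volume == pytest.approx(8.0, abs=1e-6)


def test_non_watertight_mesh_is_refused(tmp_path):
    cube = trimesh.creation.box(extents=(1, 1, 1))
    open_mesh = trimesh.Trimesh(
        vertices=cube.vertices, faces=cube.faces[:-1], process=False
    )
    assert not open_mesh.is_watertight
    with pytest.raises(eq.ExportError):
        eq.write_stl(open_mesh, tmp_path / "open.stl")
    eq.write_stl(open_mesh, tmp_path / "open.stl", force=True)  # explicit override


def test_slice_plane_count_and_closure():
    solid = trimesh.creation.box(extents=(10, 10, 3.0))
    layers = eq.slice_preview(solid, 0.1)
    assert len(layers) == 30
    zs = np.array([z for z, _ in layers])
    np.testing.assert_allclose(np.diff(zs), 0.1, atol=1e-9)
    for _, contours in layers:
        assert len(contours) >= 1
        for c in contours:
            np.testing.assert_allclose(c[0], c[-1])


def test_slice_areas_integrate_to_cylinder_volume():
    cyl = trimesh.creation.cylinder(radius=5.0, height=6.0, sections=256)
    layers = eq.slice_preview(cyl, 0.1)
    vol = sum(eq.contour_area(c) for _, c in layers) * 0.1
    assert vol == pytest.approx(np.pi * 25.0 * 6.0, rel=0.01)


def test_zero_layer_thickness_is_rejected():
    with pytest.raises(eq.ExportError):
        eq.slice_preview(trimesh.creation.box(), 0.0)


def test_thickness_of_a_flat_slab_is_exact():
    slab = trimesh.creation.box(extents=(40, 40, 3.0))
    stats = eq.measure_shell_thickness(slab, n_samples=1500, seed=0)
    assert stats["median"] == pytest.approx(3.0, abs=1e-6)
    assert stats["p95"] == pytest.approx(3.0, abs=1e-6)


def test_thickness_of_concentric_spherical_shell():
    grid = Grid.from_bounds([-64, -64, -64], [64, 64, 64], 0.8)

    def band(pts):
        r = np.linalg.norm(pts, axis=1)
        return np.maximum(60.0 - r, r - 63.0)

    shell = mesh_field(grid, grid.evaluate(band))
    assert shell.is_watertight
    stats = eq.measure_shell_thickness(shell, n_samples=1200, seed=0)
    assert stats["median"] == pytest.approx(3.0, abs=0.05)


def test_degenerate_mesh_thickness_is_rejected():
    tri = trimesh.Trimesh(vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]], faces=[[0, 1, 2]])
    with pytest.raises(eq.ExportError):
        eq.measure_shell_thickness(tri)


# ---------------------------------------------------------------------------
# channel detection and the full report


def test_channels_detected_from_geometry(small_run):
    found = eq.detect_channels(small_run.design.shell.mesh, small_run.design)
    assert len(found) == 8


def test_plugging_a_channel_reduces_the_detected_count(small_run):
    """Channel detection is genuine: fill one bore and one fewer is found."""
    from bsgkit.geometry import sdf_cylinder

    design = small_run.stage_channels
    before = small_run.stage_notch  # same shell, channels not yet drilled
    c = small_run.channels[0]
    axis_point = np.array([c.entry_point[0], c.entry_point[1], 0.0])
    plug = design.grid.evaluate(
        lambda p: sdf_cylinder(p, axis_point, c.axis, c.diameter / 2.0 + 0.3)
    )
    plugged_field = np.where(plug < 0, before.field, design.field)
    plugged = design._evolve(plugged_field)
    found = eq.detect_channels(plugged.shell.mesh, plugged)
    assert len(found) == 7


def test_qc_report_fields_are_measured(small_run, tmp_path):
    stl = tmp_path / "guide.stl"
    eq.write_stl(small_run.design.shell, stl)
    mesh = eq.read_stl(stl)
    qc = eq.verify_design(mesh, small_run.design, small_run.tumour)
    assert qc.watertight
    assert qc.n_channels_detected == 8
    np.testing.assert_allclose(qc.channel_angular_gaps, 45.0, atol=0.5)
    assert qc.channel_perpendicularity_max_dev < 5.0
    assert qc.measured_margin == pytest.approx(5.0, abs=1.0)
    assert qc.shell_thickness_median == pytest.approx(3.0, abs=0.15)
    assert qc.slice_plane_spacing == pytest.approx(0.1, abs=1e-9)
    assert qc.enclosed_volume == pytest.approx(mesh.volume)
    parsed = json.loads(qc.to_json())
    assert parsed["n_channels_detected"] == 8


# ---------------------------------------------------------------------------
# embossed ID tab


def test_id_tab_keeps_the_mesh_watertight(small_run, tmp_path):
    sidecar = tmp_path / "id.json"
    tagged = eq.emboss_id_tag(small_run.design, "PT001", sidecar_path=sidecar)
    assert tagged.shell.is_watertight
    assert tagged.id_tag == "PT001"
    meta = json.loads(sidecar.read_text())
    assert meta["id"] == "PT001"
    # the tab added material
    assert tagged.shell.volume > small_run.design.shell.volume


def test_empty_id_leaves_the_guide_unchanged(small_run):
    out = eq.emboss_id_tag(small_run.design, "")
    assert out is small_run.design


@pytest.mark.parametrize("bad", ["PT-001", "a" * 33, "id with spaces"])
def test_invalid_ids_are_rejected(small_run, bad):
    with pytest.raises(eq.ExportError):
        eq.emboss_id_tag(small_run.design, bad)
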