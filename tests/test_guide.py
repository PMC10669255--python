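"""Guide construction: resection circle, shell, positioning features, channels."""

from dataclasses import replace

import numpy as np
import pytest

from bsgkit import guide as g
from bsgkit import segrecon as sr
from bsgkit.export_qc import measure_shell_thickness
from bsgkit.geometry import nearest_surface_distance


def test_resection_circle_radius_is_projected_radius_plus_margin(small_run):
    tum = small_run.tumour
    circ = g.compute_resection_circle(tum, g.DesignParams(margin=5.0))
    assert circ.radius == pytest.approx(tum.projected_max_radius + 5.0, abs=1e-12)
    np.testing.assert_allclose(circ.centre[:2], tum.centre[:2])
    assert circ.centre[2] == 0.0


def test_resection_circle_margin_modes(small_run):
    tum = small_run.tumour
    radial = g.compute_resection_circle(tum, g.DesignParams(margin=5.0))
    diam = g.compute_resection_circle(
        tum, g.DesignParams(margin=5.0, margin_mode="diameter")
    )
    assert radial.radius - diam.radius == pytest.approx(2.5)
    zero = g.compute_resection_circle(tum, replace(g.DesignParams(), margin=0.0))
    assert zero.radius == pytest.approx(tum.projected_max_radius)


def test_negative_margin_is_rejected(small_run):
    with pytest.raises(g.DesignError):
        g.compute_resection_circle(small_run.tumour, replace(g.DesignParams(), margin=-1.0))


def test_design_params_invariants():
    with pytest.raises(g.DesignError):
        g.DesignParams(n_channels=2).validate()
    with pytest.raises(g.DesignError):
        g.DesignParams(min_rib=0.5).validate()
    with pytest.raises(g.DesignError):
        g.DesignParams(shell_thickness=-1.0).validate()


def test_shell_is_watertight_and_conformal(small_run):
    shell = small_run.stage_shell.shell
    assert shell.is_watertight
    # inner surface tracks the breast skin: skin samples inside the covered
    # region must lie on the guide's inner surface within 0.5 mm
    breast = small_run.breast
    om = small_run.stage_shell.omega_sdf()
    verts = breast.vertices
    inside = (om(verts[:, :2]) < -6.0) & (verts[:, 2] > 2.0)
    samples = verts[inside][:: max(1, inside.sum() // 400)]
    gaps = nearest_surface_distance(shell.mesh, samples)
    assert gaps.max() <= 0.5


def test_shell_thickness_matches_design(small_run):
    stats = measure_shell_thickness(small_run.stage_shell.shell, n_samples=1500, seed=0)
    assert stats["median"] == pytest.approx(3.0, abs=0.15)


def test_nipple_hole_topology_and_position(small_run):
    before = small_run.stage_shell.shell.mesh
    after = small_run.stage_hole.shell.mesh
    # one through-hole: Euler characteristic drops by 2 (genus +1)
    assert before.euler_number - after.euler_number == 2
    assert after.is_watertight
    hole = small_run.stage_hole.nipple_hole
    np.testing.assert_allclose(
        hole["centre"][:2], small_run.landmarks.nipple[:2], atol=0.1
    )


def test_nipple_hole_clearance_error(small_run):
    # a hole large enough to swallow the channel circle must be refused
    big = replace(small_run.design_params, nipple_hole_diameter=40.0, nipple_pad=2.0)
    shell = replace_params_shell(small_run, big)
    with pytest.raises(g.DesignError, match="annulus|coverage"):
        g.place_nipple_hole(shell, params=big)


def replace_params_shell(run, params):
    """Re-fit only the shell with modified params (cheap on the small grid)."""
    return g.fit_guide_shell(
        run.breast, run.landmarks, run.circle, params, pect_normal=[0, 0, 1]
    )


def test_manubrium_notch_seats_on_the_landmark(small_run):
    notch = small_run.stage_notch.notch
    np.testing.assert_allclose(
        notch["vertex"], np.append(small_run.landmarks.manubrium[:2], 0.0), atol=1e-12
    )
    d = nearest_surface_distance(
        small_run.stage_notch.shell.mesh, notch["vertex"][None, :]
    )
    assert d[0] <= 0.5
    assert small_run.stage_notch.shell.is_watertight


def test_dual_positioning_feature_count(small_run):
    assert small_run.stage_notch.n_registration_features == 2
    assert small_run.stage_hole.n_registration_features == 1  # before the notch
    assert small_run.stage_shell.n_registration_features == 0


def test_channels_are_evenly_spaced_and_perpendicular(small_run):
    chans = small_run.channels
    assert len(chans) == 8
    angles = np.sort([c.angle_deg for c in chans])
    gaps = np.diff(np.append(angles, angles[0] + 360.0))
    np.testing.assert_allclose(gaps, 45.0, atol=1e-6)
    for c in chans:
        dev = np.degrees(np.arccos(np.clip(c.axis @ np.array([0, 0, 1.0]), -1, 1)))
        assert dev < 1.0


def test_channel_entry_points_sit_on_the_resection_circle(small_run):
    circ = small_run.circle
    for c in small_run.channels:
        r = np.hypot(*(c.entry_point[:2] - circ.centre[:2]))
        assert abs(r - circ.radius) <= 0.5


def test_too_many_channels_for_the_circle_is_refused(small_run):
    crowded = replace(small_run.design_params, n_channels=24, channel_diameter=3.0)
    with pytest.raises(g.DesignError, match="too small"):
        g.place_injection_channels(small_run.stage_notch, params=crowded)


def test_channel_circle_must_fit_inside_coverage(small_run):
    big_margin = replace(small_run.design_params, margin=40.0)
    circle = g.compute_resection_circle(small_run.tumour, big_margin)
    with pytest.raises(g.DesignError, match="coverage"):
        g.place_injection_channels(
            small_run.stage_notch, circle=circle, params=big_margin
        )


def test_boolean_stages_all_watertight(small_run):
    for stage in (
        small_run.stage_shell,
        small_run.stage_hole,
        small_run.stage_notch,
        small_run.stage_channels,
        small_run.design,
    ):
        assert stage.shell.is_watertight


def test_absolute_dimensions_survive_phantom_scaling(small_run, small_run_scaled):
    """Scaling breast+tumour scales the coverage but not thickness or margin."""
    for run in (small_run, small_run_scaled):
        stats = measure_shell_thickness(run.design.shell, n_samples=1200, seed=1)
        assert stats["median"] == pytest.approx(3.0, abs=0.15)
        measured_margin = run.circle.radius - run.tumour.projected_max_radius
        assert measured_margin == pytest.approx(5.0, abs=1e-9)
    # the tumour-driven coverage grew with the phantom while the margin stayed put
    assert small_run_scaled.tumour.projected_max_radius == pytest.approx(
        1.25 * small_run.tumour.projected_max_radius, abs=np.sqrt(3.0)
    )
    assert small_run_scaled.design.omega.area > small_run.design.omega.area
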