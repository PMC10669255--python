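"""Shared fixtures: a small fast phantom chain and the full-size reference run.

The small run (30 mm hemisphere, coarse 0.8 mm design grid) exercises every
pipeline stage in a few tens of seconds and is shared by most unit tests.
The reference run is the full-size configuration (60 mm hemisphere,
24x16x12 mm tumour, 1 mm voxels, 0.5 mm design grid) exported to STL and
re-measured from disk; building it is expensive, so it is session scoped and
used by the end-to-end verification tests.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import replace
from types import SimpleNamespace

import numpy as np
import pytest

from bsgkit import export_qc as eq
from bsgkit import guide as g
from bsgkit import lightweight as lw
from bsgkit import phantom as ph
from bsgkit import segrecon as sr


SMALL_PHANTOM = ph.PhantomParams(
    breast_base_radius=30.0,
    breast_height=30.0,
    manubrium_y=70.0,
    tumour_centre=(21.0, 0.0, 9.0),
    tumour_semi_axes=(6.0, 4.0, 3.0),
    seed=42,
)

SMALL_DESIGN = g.DesignParams(
    nipple_hole_diameter=10.0,
    nipple_pad=6.0,
    coverage_margin=10.0,
    arm_width=14.0,
    mesh_pitch=0.8,
    n_voronoi=40,
    seed=42,
)


def build_chain(pp: ph.PhantomParams, dp: g.DesignParams,
                lightweighted: bool = True) -> SimpleNamespace:
    """Run the pipeline keeping every intermediate stage."""
    volume, landmarks = ph.make_breast_phantom(pp)
    thr = 0.5 * (pp.background_intensity + pp.tumour_intensity)
    mask = sr.threshold_segment(volume, thr)
    tumour_mesh = sr.reconstruct_surface(mask, volume.spacing, volume.origin)
    tumour = sr.tumour_axes(tumour_mesh)
    breast_mask = (volume.labels == 1) | (volume.labels == 2)
    breast = sr.reconstruct_surface(
        breast_mask, volume.spacing, volume.origin, role="breast"
    )
    normal = ph.pectoralis_normal(volume)
    circle = g.compute_resection_circle(tumour, dp, pect_normal=normal)
    shell = g.fit_guide_shell(breast, landmarks, circle, dp, pect_normal=normal)
    with_hole = g.place_nipple_hole(shell)
    with_notch = g.place_manubrium_feature(with_hole)
    with_channels, channels = g.place_injection_channels(with_notch)
    voids = []
    final = with_channels
    if lightweighted:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", lw.LightweightWarning)
            final, voids = lw.voronoi_lightweight(with_channels)
    return SimpleNamespace(
        phantom_params=pp,
        design_params=dp,
        volume=volume,
        landmarks=landmarks,
        lesion_mask=mask,
        tumour=tumour,
        breast=breast,
        circle=circle,
        stage_shell=shell,
        stage_hole=with_hole,
        stage_notch=with_notch,
        stage_channels=with_channels,
        channels=channels,
        design=final,
        voids=voids,
    )


@pytest.fixture(scope="session")
def small_run():
    return build_chain(SMALL_PHANTOM, SMALL_DESIGN)


@pytest.fixture(scope="session")
def small_run_scaled():
    """The small configuration scaled up 1.25x (breast and tumour together)."""
    pp = replace(
        SMALL_PHANTOM,
        breast_base_radius=37.5,
        breast_height=37.5,
        manubrium_y=80.0,
        tumour_centre=(26.25, 0.0, 11.25),
        tumour_semi_axes=(7.5, 5.0, 3.75),
    )
    return build_chain(pp, SMALL_DESIGN)


@pytest.fixture(scope="session")
def reference_run(tmp_path_factory):
    """Full-size run, exported to STL and QC'd from the file on disk."""
    t0 = time.time()
    chain = build_chain(ph.PhantomParams(), g.DesignParams())
    stl = tmp_path_factory.mktemp("guide") / "guide.stl"
    eq.write_stl(chain.design.shell, stl)
    mesh = eq.read_stl(stl)
    qc = eq.verify_design(mesh, chain.design, chain.tumour)
    chain.stl_path = stl
    chain.stl_mesh = mesh
    chain.qc = qc
    chain.wall_seconds = time.time() - t0
    return chain
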