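"""End-to-end convenience: phantom → segmentation → guide → QC."""

from __future__ import annotations

from dataclasses import dataclass

from . import export_qc, guide, lightweight, phantom, segrecon


@dataclass
class PipelineResult:
    volume: phantom.LabelledVolume
    landmarks: phantom.LandmarkSet
    tumour: segrecon.TumourModel
    breast: segrecon.SurfaceMesh
    design: guide.GuideDesign
    voids: list
    qc: export_qc.QCReport | None = None


def default_threshold(params: phantom.PhantomParams) -> float:
    return 0.5 * (params.background_intensity + params.tumour_intensity)


def run_pipeline(
    phantom_params: phantom.PhantomParams | None = None,
    design_params: guide.DesignParams | None = None,
    threshold: float | None = None,
    lightweighted: bool = True,
    id_tag: str = "",
    stl_path=None,
    qc: bool = False,
) -> PipelineResult:
    """Run the full design pipeline on a synthetic phantom.

    When ``stl_path`` is given the guide is exported there and, if ``qc``,
    the QC report is measured on the mesh re-read from disk (end to end).
    """
    pp = phantom_params or phantom.PhantomParams()
    volume, landmarks = phantom.make_breast_phantom(pp)
    thr = default_threshold(pp) if threshold is None else threshold
    return design_from_volume(
        volume, landmarks, design_params=design_params, threshold=thr,
        lightweighted=lightweighted, id_tag=id_tag, stl_path=stl_path, qc=qc,
    )


def design_from_volume(
    volume: phantom.LabelledVolume,
    landmarks: phantom.LandmarkSet,
    design_params: guide.DesignParams | None = None,
    threshold: float = 200.0,
    lightweighted: bool = True,
    id_tag: str = "",
    stl_path=None,
    qc: bool = False,
) -> PipelineResult:
    """Design a guide from an already-acquired labelled volume + landmarks."""
    dp = design_params or guide.DesignParams()
    thr = threshold

    tum_mask = segrecon.threshold_segment(volume, thr)
    tum_mesh = segrecon.reconstruct_surface(
        tum_mask, volume.spacing, volume.origin, smoothing_iters=10, role="tumour"
    )
    tumour = segrecon.tumour_axes(tum_mesh)

    breast_mask = (volume.labels == 1) | (volume.labels == 2)
    breast = segrecon.reconstruct_surface(
        breast_mask, volume.spacing, volume.origin, smoothing_iters=10, role="breast"
    )

    normal = phantom.pectoralis_normal(volume)
    circle = guide.compute_resection_circle(tumour, dp, pect_normal=normal)
    design = guide.fit_guide_shell(breast, landmarks, circle, dp, pect_normal=normal)
    design = guide.place_nipple_hole(design)
    design = guide.place_manubrium_feature(design)
    design, _ = guide.place_injection_channels(design)
    voids: list = []
    if lightweighted:
        design, voids = lightweight.voronoi_lightweight(design)
    if id_tag:
        design = export_qc.emboss_id_tag(design, id_tag)

    result = PipelineResult(
        volume=volume, landmarks=landmarks, tumour=tumour, breast=breast,
        design=design, voids=voids,
    )
    if stl_path is not None:
        export_qc.write_stl(design.shell, stl_path)
        if qc:
            mesh = export_qc.read_stl(stl_path)
            result.qc = export_qc.verify_design(mesh, design, tumour)
    elif qc:
        result.qc = export_qc.verify_design(design.shell, design, tumour)
    return result
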