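"""Shared synthetic-assay configurations used across the test modules.

Geometry note: per-cell measurement stays clean when the minimum centre
spacing is at least (nucleus radius + ROI dilation) plus the neighbour's
ring outer radius, so a cell's ROI can never swallow a neighbouring cell's
membrane ring.  Both configurations below respect that bound.
"""

from dataclasses import replace

from hciscreen import AnalysisConfig, PreprocessParams, SegParams, SimParams


def plate_field_params(**overrides) -> SimParams:
    """Small field (192 px, ~22 cells) used for whole-plate simulations."""
    base = dict(
        field_height_px=192,
        field_width_px=192,
        n_cells_mean=22,
        nucleus_radius_px=(5.0, 0.6),
        min_center_spacing_px=24.0,
        membrane_offset_px=2.0,
        ch2_ring_width_px=3.0,
        transfected_fraction=0.4,
        bound_fraction=0.0,
        ch1_signal=(3000.0, 400.0),
        ch2_ring_signal=(2500.0, 300.0),
        background_level=(400.0, 300.0),
        noise_sd=(60.0, 50.0),
    )
    base.update(overrides)
    return SimParams(**base)


def recovery_field_params(**overrides) -> SimParams:
    """Large field (640 px, ~200 cells) for ground-truth recovery checks."""
    base = dict(
        field_height_px=640,
        field_width_px=640,
        n_cells_mean=200,
        nucleus_radius_px=(6.0, 0.6),
        min_center_spacing_px=28.0,
        membrane_offset_px=2.0,
        ch2_ring_width_px=3.0,
        transfected_fraction=1.0,
        bound_fraction=0.4,
        ch1_signal=(3000.0, 400.0),
        ch2_ring_signal=(2500.0, 300.0),
        background_level=(400.0, 300.0),
        noise_sd=(60.0, 50.0),
    )
    base.update(overrides)
    return SimParams(**base)


def plate_analysis_config(**overrides) -> AnalysisConfig:
    cfg = AnalysisConfig(
        preprocess=PreprocessParams(kernel_px=32, smooth_sigma=5.0),
        segmentation=SegParams(
            smoothing_sigma=1.5, min_area_px=20, min_peak_distance_px=7
        ),
        dilation_px=8,
        fixed_threshold=400.0,
        response_limit=650.0,
    )
    return replace(cfg, **overrides)


def recovery_analysis_config(**overrides) -> AnalysisConfig:
    cfg = AnalysisConfig(
        preprocess=PreprocessParams(kernel_px=40, smooth_sigma=6.0),
        segmentation=SegParams(
            smoothing_sigma=1.5, min_area_px=20, min_peak_distance_px=10
        ),
        dilation_px=8,
        fixed_threshold=400.0,
        response_limit=650.0,
    )
    return replace(cfg, **overrides)
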