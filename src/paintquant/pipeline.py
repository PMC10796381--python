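"""End-to-end analysis pipelines wiring the stages together.

Stage order follows the acquisition-processing narrative: precision/width
filtering, redundant cross-correlation drift correction, structure
picking and picked-centroid drift refinement, then structure detection
(reference image + PAINT render), localization grouping and per-structure
quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import calibrate as cal
from . import drift as drift_mod
from . import occupancy as occ_mod
from . import roi as roi_mod
from .io import LocalizationTable, filter_localizations
from .occupancy import OccupancyConfig, OccupancyDistribution, SiteOccupancy
from .roi import OrigamiROI

__all__ = [
    "PipelineParams",
    "preprocess",
    "detect_rois",
    "median_precision_nm",
    "calibrate_reference",
    "calibrate_linearity",
    "run_calibration",
    "run_quantification",
]


@dataclass(frozen=True)
class PipelineParams:
    """All stage parameters with their documented defaults."""

    # filtering
    max_precision_px: float = 0.15
    max_sigma_px: float = 1.62
    # drift correction
    drift_correct: bool = True
    segment_frames: int = 200
    rcc_oversampling: int = 8
    rcc_blur_px: float | None = None
    pick_diameter_px: float = 1.5
    pick_std: float = 1.6
    n_seed_picks: int = 20
    # reference-channel detection
    cy5_block_px: int = 15
    cy5_offset: float = 0.15
    cy5_min_area_px: float = 2.0
    cy5_max_area_px: float = 200.0
    # PAINT-channel detection
    paint_oversampling: int = 1
    paint_count_threshold: int = 5
    paint_min_area_px: float = 4.0
    paint_max_area_px: float = 80.0
    overlap_factor: float = 0.9
    roi_radius_nm: float | None = None
    # calibration
    dbscan_eps_nm: float = 3.0
    dbscan_min_samples: int = 20
    refine_pair_distance: bool = True
    min_calibration_rois: int = 50
    # occupancy
    occupancy: OccupancyConfig = field(default_factory=OccupancyConfig)


def median_precision_nm(table: LocalizationTable) -> float:
    """Median reported per-axis precision, in nm (blur width for renders)."""
    if len(table) == 0:
        return table.pixel_size_nm * 0.05
    lp = np.median(np.concatenate([table.df["lpx"].to_numpy(),
                                   table.df["lpy"].to_numpy()]))
    return float(lp * table.pixel_size_nm)


def preprocess(table: LocalizationTable, params: PipelineParams = PipelineParams(),
               ) -> LocalizationTable:
    """Filter, then the two drift-correction rounds."""
    table = filter_localizations(table, params.max_precision_px,
                                 params.max_sigma_px)
    if not params.drift_correct or len(table) == 0:
        return table
    if table.n_frames >= 2 * params.segment_frames:
        table, _ = drift_mod.rcc_correct(
            table, params.segment_frames, params.rcc_oversampling,
            params.rcc_blur_px)
    seeds = drift_mod.auto_seed_picks(table, params.n_seed_picks,
                                      params.pick_diameter_px)
    if len(seeds) >= 2:
        picks = drift_mod.pick_similar(table, seeds, params.pick_diameter_px,
                                       params.pick_std)
        table, _ = drift_mod.undrift_picked(table, picks,
                                            params.segment_frames)
    return table


def detect_rois(table: LocalizationTable, cy5_image: np.ndarray,
                params: PipelineParams = PipelineParams()) -> list[OrigamiROI]:
    """Detect structures in both channels, merge, group localizations."""
    cy5 = roi_mod.detect_cy5_contours(
        cy5_image, table.pixel_size_nm, params.cy5_block_px, params.cy5_offset,
        params.cy5_min_area_px, params.cy5_max_area_px)
    paint = roi_mod.detect_paint_contours(
        table, params.paint_oversampling, params.paint_count_threshold,
        params.paint_min_area_px, params.paint_max_area_px)
    rois = roi_mod.merge_contours(cy5, paint, params.overlap_factor,
                                  params.roi_radius_nm)
    return roi_mod.assign_localizations(table, rois)


def calibrate_reference(table2x: LocalizationTable, cy5_image: np.ndarray,
                        params: PipelineParams = PipelineParams(),
                        preprocessed: bool = False,
                        ) -> cal.ReferenceCalibration:
    """Site-to-site reference distance from a two-site rod dataset."""
    if not preprocessed:
        table2x = preprocess(table2x, params)
    rois = detect_rois(table2x, cy5_image, params)
    xy = table2x.xy_nm()
    distances = []
    for roi in rois:
        if len(roi.members) < 2 * params.dbscan_min_samples:
            continue
        d = cal.cluster_pair_distance(
            xy[roi.members], params.dbscan_eps_nm, params.dbscan_min_samples,
            params.refine_pair_distance,
            sigma0_nm=median_precision_nm(table2x))
        if d is not None:
            distances.append(d)
    return cal.fit_reference_distance(distances, params.min_calibration_rois)


def calibrate_linearity(table4x: LocalizationTable, cy5_image: np.ndarray,
                        ref: cal.ReferenceCalibration,
                        params: PipelineParams = PipelineParams(),
                        preprocessed: bool = False) -> cal.LinearityCalibration:
    """Linearity-score cutoff from a four-site rod dataset.

    Only structures with exactly four detected positions contribute to the
    score distribution.
    """
    if not preprocessed:
        table4x = preprocess(table4x, params)
    rois = detect_rois(table4x, cy5_image, params)
    xy = table4x.xy_nm()
    blur = median_precision_nm(table4x)
    ocfg = params.occupancy
    scores = []
    for roi in rois:
        if len(roi.members) == 0:
            continue
        img = occ_mod.render_roi(xy[roi.members], roi.center_nm, roi.radius_nm,
                                 ocfg.sr_pixel_nm,
                                 ocfg.blur_nm if ocfg.blur_nm is not None else blur)
        pos = occ_mod.initial_positions(img, ref.ref_distance_nm,
                                        ocfg.threshold_rel, ocfg.min_sep_factor,
                                        ocfg.outlier_factor)
        if len(pos) == 4:
            scores.append(cal.linearity_score(pos))
    return cal.linearity_cutoff(scores, params.min_calibration_rois)


def run_calibration(table2x: LocalizationTable, cy5_2x: np.ndarray,
                    table4x: LocalizationTable, cy5_4x: np.ndarray,
                    params: PipelineParams = PipelineParams(),
                    ) -> tuple[cal.ReferenceCalibration, cal.LinearityCalibration]:
    ref = calibrate_reference(table2x, cy5_2x, params)
    lin = calibrate_linearity(table4x, cy5_4x, ref, params)
    return ref, lin


def run_quantification(table: LocalizationTable, cy5_image: np.ndarray,
                       designed_n: int, ref: cal.ReferenceCalibration,
                       lin: cal.LinearityCalibration,
                       params: PipelineParams = PipelineParams(),
                       preprocessed: bool = False,
                       ) -> tuple[list[SiteOccupancy], OccupancyDistribution,
                                  list[OrigamiROI]]:
    """Full counting pipeline for one dataset; returns per-structure
    results, the population distribution and the detected ROIs."""
    if not preprocessed:
        table = preprocess(table, params)
    rois = detect_rois(table, cy5_image, params)
    xy = table.xy_nm()
    blur = median_precision_nm(table)
    occs = [
        occ_mod.quantify_roi(roi, xy[roi.members], ref, lin, designed_n,
                             params.occupancy, blur)
        for roi in rois
    ]
    dist = occ_mod.aggregate(occs, designed_n) if occs else None
    return occs, dist, rois
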