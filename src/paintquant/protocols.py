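"""Standard simulation-and-analysis protocols at the study conditions.

Each protocol generates the stated synthetic dataset(s), runs the relevant
pipeline stages and returns the measured quantity.  They exist so that the
same conditions are exercised identically by the test suite, the
reproduction script and interactive use.

Conditions shared by all protocols: 87 nm camera pixels, 12000 frames,
two docking strands per protein, imager kinetics producing ~120
localizations per occupied site, rods at 0.9 structures/um^2.  The
distance-calibration protocol uses 5 nm localization precision; the
counting protocols use 2 nm ("high signal-to-noise": long acquisitions
with bright imagers), where all designed spacings are resolvable.
"""

from __future__ import annotations

import numpy as np

from .calibrate import LinearityCalibration, ReferenceCalibration
from .drift import auto_seed_picks, pick_similar, rcc_correct, undrift_picked
from .io import filter_localizations
from .occupancy import OccupancyConfig, OccupancyDistribution
from .pipeline import (PipelineParams, calibrate_linearity,
                       calibrate_reference, preprocess, run_quantification)
from .simulate import (AcquisitionConfig, KineticsConfig, NanorodDesign,
                       render_cy5, sample_field, simulate_drift,
                       simulate_localizations)

__all__ = [
    "reference_distance_protocol",
    "counting_calibrations",
    "modal_occupancy_protocol",
    "occupancy_distribution_protocol",
    "drift_recovery_protocol",
]

DENSITY_PER_UM2 = 0.9


def _dataset(design: NanorodDesign, acq: AcquisitionConfig,
             kin: KineticsConfig, labeling_p: float, seed: int,
             bend_sd: float = 0.0):
    gt = sample_field(design, acq, DENSITY_PER_UM2, labeling_p, bend_sd,
                      seed=seed)
    table = simulate_localizations(gt, acq, kin, None, seed=seed + 1)
    cy5 = render_cy5(gt, acq, seed=seed + 2)
    return gt, table, cy5


def reference_distance_protocol(spacing_nm: float, seed: int,
                                precision_nm: float = 5.0,
                                fov_px: int = 220,
                                ) -> tuple[ReferenceCalibration, int]:
    """Site-to-site distance calibration on >= 300 two-site rods.

    Simulates fully labeled two-site rods at the given spacing, runs
    filtering, structure detection and the per-structure cluster-pair
    distance measurement, and fits the distance distribution.  Returns the
    calibration and the number of simulated rods.
    """
    acq = AcquisitionConfig(fov_px=fov_px, n_frames=12000)
    kin = KineticsConfig(precision_nm=precision_nm)
    params = PipelineParams(drift_correct=False)
    gt, table, cy5 = _dataset(NanorodDesign(2, spacing_nm), acq, kin, 1.0,
                              seed=seed * 1000 + 11)
    table = preprocess(table, params)
    ref = calibrate_reference(table, cy5, params, preprocessed=True)
    return ref, gt.n_rods


def counting_calibrations(spacing_nm: float, seed: int,
                          precision_nm: float = 2.0, fov_px: int = 180,
                          ) -> tuple[ReferenceCalibration, LinearityCalibration,
                                     PipelineParams]:
    """Reference distance (two-site data) and linearity cutoff (four-site
    data) at counting conditions, plus the matching pipeline parameters."""
    acq = AcquisitionConfig(fov_px=fov_px, n_frames=12000)
    kin = KineticsConfig(precision_nm=precision_nm)
    sr = 2.0 if spacing_nm < 20.0 else 5.0
    params = PipelineParams(drift_correct=False,
                            occupancy=OccupancyConfig(sr_pixel_nm=sr))
    _, t2, c2 = _dataset(NanorodDesign(2, spacing_nm), acq, kin, 1.0,
                         seed=seed * 1000 + 100)
    t2 = preprocess(t2, params)
    ref = calibrate_reference(t2, c2, params, preprocessed=True)
    _, t4, c4 = _dataset(NanorodDesign(4, spacing_nm), acq, kin, 1.0,
                         seed=seed * 1000 + 200, bend_sd=0.1)
    t4 = preprocess(t4, params)
    lin = calibrate_linearity(t4, c4, ref, params, preprocessed=True)
    return ref, lin, params


def modal_occupancy_protocol(n_sites: int, spacing_nm: float, seed: int,
                             labeling_p: float = 0.9,
                             calibrations=None,
                             ) -> tuple[OccupancyDistribution, int]:
    """Counting pipeline on >= 200 rods of one design; returns the
    population distribution and the rod count."""
    acq = AcquisitionConfig(fov_px=180, n_frames=12000)
    kin = KineticsConfig(precision_nm=2.0)
    if calibrations is None:
        calibrations = counting_calibrations(spacing_nm, seed)
    ref, lin, params = calibrations
    gt, table, cy5 = _dataset(NanorodDesign(n_sites, spacing_nm), acq, kin,
                              labeling_p, seed=seed * 1000 + 300 + n_sites)
    table = preprocess(table, params)
    _, dist, _ = run_quantification(table, cy5, n_sites, ref, lin, params,
                                    preprocessed=True)
    return dist, gt.n_rods


def occupancy_distribution_protocol(seed: int, labeling_p: float = 0.8,
                                    ) -> OccupancyDistribution:
    """Four-site design at the given labeling probability, high SNR."""
    dist, _ = modal_occupancy_protocol(4, 28.0, seed, labeling_p)
    return dist


def drift_recovery_protocol(seed: int, step_sd_nm: float = 0.05,
                            ) -> tuple[float, float]:
    """Inject a random-walk drift, correct it, measure what remains.

    Returns (residual_rms_nm, injected_rms_nm): the RMS difference between
    the estimated (RCC + picked refinement) and the injected per-frame
    trajectory, and the RMS of the injected trajectory itself.
    """
    acq = AcquisitionConfig(fov_px=32, n_frames=12000)
    kin = KineticsConfig()
    gt = sample_field(NanorodDesign(4, 28.0), acq, 8.0, 1.0,
                      seed=seed * 1000 + 500)
    drift = simulate_drift(acq.n_frames, step_sd_nm, seed=seed * 1000 + 501)
    table = simulate_localizations(gt, acq, kin, drift,
                                   seed=seed * 1000 + 502)
    table = filter_localizations(table)
    table, est1 = rcc_correct(table)
    picks = pick_similar(table, auto_seed_picks(table))
    _, est2 = undrift_picked(table, picks)
    total = est1.displacement_nm + est2.displacement_nm
    residual = total - drift.displacement_nm
    residual_rms = float(np.sqrt(np.mean(np.sum(residual**2, axis=1))))
    return residual_rms, drift.rms_nm()
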