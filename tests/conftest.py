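"""Shared simulated datasets (session-scoped; everything is seeded)."""

from __future__ import annotations

import numpy as np
import pytest

from paintquant import (AcquisitionConfig, KineticsConfig, NanorodDesign,
                        render_cy5, sample_field, simulate_localizations)
from paintquant.pipeline import PipelineParams, preprocess


ACQ = AcquisitionConfig(fov_px=128, n_frames=12000)
KIN = KineticsConfig(precision_nm=5.0)
NO_DRIFT_PARAMS = PipelineParams(drift_correct=False)


def simulate_dataset(design: NanorodDesign, labeling_p: float, seed: int,
                     acq: AcquisitionConfig = ACQ,
                     kin: KineticsConfig = KIN,
                     density: float = 0.9, bend_sd: float = 0.0):
    """One seeded dataset: ground truth, localization table, Cy5 image."""
    gt = sample_field(design, acq, density, labeling_p, bend_sd, seed=seed)
    table = simulate_localizations(gt, acq, kin, None, seed=seed + 1)
    cy5 = render_cy5(gt, acq, seed=seed + 2)
    return gt, table, cy5


@pytest.fixture(scope="session")
def dataset_4x():
    """Four-site rods at 28 nm, 90% labeling — the main quantification case."""
    return simulate_dataset(NanorodDesign(4, 28.0), 0.9, seed=400)


@pytest.fixture(scope="session")
def dataset_2x():
    """Two-site rods at 28 nm, fully labeled — the distance-reference case."""
    return simulate_dataset(NanorodDesign(2, 28.0), 1.0, seed=200)


@pytest.fixture(scope="session")
def reference_calibration(dataset_2x):
    from paintquant.pipeline import calibrate_reference

    _, table, cy5 = dataset_2x
    table = preprocess(table, NO_DRIFT_PARAMS)
    return calibrate_reference(table, cy5, NO_DRIFT_PARAMS, preprocessed=True)


@pytest.fixture(scope="session")
def linearity_calibration(reference_calibration):
    from paintquant.pipeline import calibrate_linearity

    _, table, cy5 = simulate_dataset(NanorodDesign(4, 28.0), 1.0, seed=410,
                                     bend_sd=0.1)
    table = preprocess(table, NO_DRIFT_PARAMS)
    return calibrate_linearity(table, cy5, reference_calibration,
                               NO_DRIFT_PARAMS, preprocessed=True)
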