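"""Per-structure site counting and population aggregation tests."""

import numpy as np
import pytest

from paintquant import (AcquisitionConfig, KineticsConfig, NanorodDesign,
                        OccupancyConfig, aggregate, quantify_roi)
from paintquant.calibrate import LinearityCalibration, ReferenceCalibration
from paintquant.occupancy import (ACCEPTED, CY5_ONLY_ZERO, DISCARDED_EXCESS,
                                  DISCARDED_LINEARITY, SiteOccupancy,
                                  initial_positions, render_roi)
from paintquant.roi import OrigamiROI
from tests.conftest import NO_DRIFT_PARAMS, simulate_dataset


REF = ReferenceCalibration(28.0, 1.0, 100, np.full(100, 28.0))
LIN = LinearityCalibration(0.1, 100, np.full(100, 0.02))


def cluster_roi(site_offsets, occupied=None, n_per=120, sd=2.0, seed=0,
                center=(1000.0, 1000.0), radius=150.0):
    """Synthetic ROI: localization clouds at given site offsets (nm)."""
    rng = np.random.default_rng(seed)
    center = np.asarray(center, dtype=float)
    sites = center + np.asarray(site_offsets, dtype=float)
    occupied = [True] * len(sites) if occupied is None else occupied
    locs = [s + rng.normal(0, sd, (n_per, 2))
            for s, occ in zip(sites, occupied) if occ]
    locs = np.vstack(locs) if locs else np.empty((0, 2))
    roi = OrigamiROI(0, center, radius, "PAINT" if len(locs) else "CY5_ONLY",
                     np.arange(len(locs)))
    return roi, locs, sites


def line_offsets(n, spacing=28.0):
    return [(i * spacing - (n - 1) * spacing / 2.0, 0.0) for i in range(n)]


class TestRenderRoi:
    def test_single_localization_peaks_at_one(self):
        img = render_roi(np.array([[1000.0, 1000.0]]), np.array([1000.0, 1000.0]),
                         radius_nm=50.0, blur_nm=5.0)
        assert img.data.max() == pytest.approx(1.0)
        assert (img.data == 1.0).sum() == 1

    def test_two_equal_clusters_two_unit_maxima(self):
        rng = np.random.default_rng(1)
        a = rng.normal([980.0, 1000.0], 1.0, (400, 2))
        b = rng.normal([1020.0, 1000.0], 1.0, (400, 2))
        img = render_roi(np.vstack([a, b]), np.array([1000.0, 1000.0]),
                         radius_nm=60.0, blur_nm=3.0)
        pos = initial_positions(img, 28.0)
        assert len(pos) == 2
        vals = []
        for p in pos:
            col = int((p[0] - img.origin_nm[0]) / img.sr_pixel_nm)
            row = int((p[1] - img.origin_nm[1]) / img.sr_pixel_nm)
            vals.append(img.data[row, col])
        assert min(vals) > 0.7

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            render_roi(np.empty((0, 2)), np.zeros(2), 50.0)

    def test_peak_positions_near_true_sites(self):
        roi, locs, sites = cluster_roi(line_offsets(4), seed=2)
        img = render_roi(locs, roi.center_nm, roi.radius_nm, blur_nm=3.0)
        pos = initial_positions(img, 28.0)
        assert len(pos) == 4
        for s in sites:
            assert np.min(np.linalg.norm(pos - s, axis=1)) < 5.0


class TestInitialPositions:
    def test_single_cluster(self):
        roi, locs, _ = cluster_roi([(0.0, 0.0)], seed=3)
        img = render_roi(locs, roi.center_nm, roi.radius_nm, blur_nm=3.0)
        assert len(initial_positions(img, 28.0)) == 1

    def test_four_collinear_ordered_with_design_gaps(self):
        roi, locs, _ = cluster_roi(line_offsets(4), seed=4)
        img = render_roi(locs, roi.center_nm, roi.radius_nm, blur_nm=3.0)
        pos = initial_positions(img, 28.0)
        assert len(pos) == 4
        gaps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        assert np.all(np.abs(gaps - 28.0) < 5.0)
        # end-to-end ordering: x strictly monotone along the rod
        assert np.all(np.diff(pos[:, 0]) > 0) or np.all(np.diff(pos[:, 0]) < 0)

    def test_stray_maximum_removed_as_outlier(self):
        offsets = line_offsets(2) + [(5 * 28.0, 120.0)]
        roi, locs, _ = cluster_roi(offsets, seed=5, radius=250.0)
        img = render_roi(locs, roi.center_nm, roi.radius_nm, blur_nm=3.0)
        pos = initial_positions(img, 28.0)
        assert len(pos) == 2
        assert np.all(pos[:, 1] < 1050.0)


class TestQuantifyRoi:
    def test_fully_occupied_high_snr(self):
        roi, locs, _ = cluster_roi(line_offsets(4), seed=6)
        occ = quantify_roi(roi, locs, REF, LIN, 4)
        assert occ.status == ACCEPTED
        assert occ.occupancy == 4
        assert occ.pattern.all()

    def test_partial_pattern_positions(self):
        """A missing middle site leaves a gap in the ordered pattern."""
        roi, locs, _ = cluster_roi(line_offsets(4),
                                   occupied=[True, False, True, True], seed=7)
        occ = quantify_roi(roi, locs, REF, LIN, 4)
        assert occ.status == ACCEPTED
        assert occ.occupancy == 3
        assert sorted(occ.pattern.tolist()) == [False, True, True, True]
        assert not occ.pattern[1] or not occ.pattern[2]

    def test_excess_positions_discarded(self):
        roi, locs, _ = cluster_roi(line_offsets(5), seed=8, radius=200.0)
        occ = quantify_roi(roi, locs, REF, LIN, 4)
        assert occ.status == DISCARDED_EXCESS

    def test_bent_rod_discarded_by_linearity(self):
        bent = [(-42.0, 0.0), (-14.0, 0.0), (14.0, 20.0), (42.0, 48.0)]
        roi, locs, _ = cluster_roi(bent, seed=9)
        occ = quantify_roi(roi, locs, REF, LIN, 4)
        assert occ.status == DISCARDED_LINEARITY
        assert occ.linearity > LIN.cutoff

    def test_reference_only_structure_zero(self):
        roi, locs, _ = cluster_roi(line_offsets(4),
                                   occupied=[False] * 4, seed=10)
        occ = quantify_roi(roi, locs, REF, LIN, 4)
        assert occ.status == CY5_ONLY_ZERO
        assert occ.occupancy == 0
        assert not occ.pattern.any()

    def test_missing_calibration_rejected(self):
        roi, locs, _ = cluster_roi(line_offsets(4), seed=11)
        with pytest.raises(ValueError):
            quantify_roi(roi, locs, None, LIN, 4)

    def test_rescue_recovers_weak_site(self):
        """A sparsely sampled site below the primary threshold is still
        counted through the putative-region rescue scan."""
        rng = np.random.default_rng(12)
        center = np.array([1000.0, 1000.0])
        sites = center + np.asarray(line_offsets(4))
        locs = np.vstack(
            [s + rng.normal(0, 2.0, (120, 2)) for s in sites[:3]]
            + [sites[3] + rng.normal(0, 2.0, (18, 2))])
        roi = OrigamiROI(0, center, 150.0, "PAINT", np.arange(len(locs)))
        occ = quantify_roi(roi, locs, REF, LIN, 4)
        assert occ.status == ACCEPTED
        assert occ.occupancy == 4

    def test_occupancy_never_exceeds_designed(self):
        for n in (1, 2, 3, 4):
            for seed in range(3):
                roi, locs, _ = cluster_roi(line_offsets(n), seed=20 + seed)
                occ = quantify_roi(roi, locs, REF, LIN, n)
                if occ.status == ACCEPTED:
                    assert occ.occupancy <= n
                    assert occ.pattern.sum() == occ.occupancy


class TestAggregate:
    def make(self, occs, designed=4, status=ACCEPTED):
        return [SiteOccupancy(i, status, o, np.zeros(designed, bool),
                              np.empty((0, 2))) for i, o in enumerate(occs)]

    def test_simple_fractions(self):
        dist = aggregate(self.make([4, 4, 3]), 4)
        np.testing.assert_allclose(dist.fractions,
                                   [0, 0, 0, 1 / 3, 2 / 3])
        assert dist.mean_state == pytest.approx(11 / 3)

    def test_all_zero(self):
        dist = aggregate(self.make([0, 0, 0], status=CY5_ONLY_ZERO), 4)
        assert dist.fractions[0] == 1.0
        assert dist.mean_state == 0.0

    def test_discarded_excluded(self):
        occs = self.make([4, 4]) + self.make([9], status=DISCARDED_EXCESS)
        dist = aggregate(occs, 4)
        assert dist.n_used == 2
        assert dist.counts_by_status[DISCARDED_EXCESS] == 1

    def test_all_discarded_rejected(self):
        with pytest.raises(ValueError):
            aggregate(self.make([5], status=DISCARDED_EXCESS), 4)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(13)
        dist = aggregate(self.make(rng.integers(0, 5, 50)), 4)
        assert dist.fractions.sum() == pytest.approx(1.0, abs=1e-9)


class TestPipeline:
    def test_deterministic(self, dataset_4x, reference_calibration,
                           linearity_calibration):
        from paintquant.pipeline import run_quantification

        _, table, cy5 = dataset_4x
        results = []
        for _ in range(2):
            occs, dist, _ = run_quantification(
                table, cy5, 4, reference_calibration, linearity_calibration,
                NO_DRIFT_PARAMS)
            results.append((tuple(o.occupancy for o in occs),
                            tuple(o.status for o in occs),
                            tuple(dist.fractions)))
        assert results[0] == results[1]

    def test_mean_state_monotone_in_labeling(self, reference_calibration,
                                             linearity_calibration):
        """Mean functionalization state increases with labeling
        probability."""
        from paintquant.pipeline import run_quantification

        acq = AcquisitionConfig(fov_px=96, n_frames=12000)
        means = []
        for p in (0.3, 0.6, 0.9):
            _, table, cy5 = simulate_dataset(NanorodDesign(4, 28.0), p,
                                             seed=600, acq=acq)
            _, dist, _ = run_quantification(
                table, cy5, 4, reference_calibration, linearity_calibration,
                NO_DRIFT_PARAMS)
            means.append(dist.mean_state)
        assert means[0] < means[1] < means[2]
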