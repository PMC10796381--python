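"""Tests of the synthetic SMLM generator against independent oracles."""

import numpy as np
import pytest
from scipy.stats import binom, chisquare

from paintquant import (AcquisitionConfig, DriftTrajectory, KineticsConfig,
                        NanorodDesign, render_cy5, sample_field,
                        simulate_drift, simulate_localizations)


SMALL_ACQ = AcquisitionConfig(fov_px=32, n_frames=2000)


class TestParameterValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_sites": -1},
        {"n_sites": 2, "site_spacing_nm": 0.0},
        {"n_sites": 2, "docking_per_site": 0},
    ])
    def test_bad_design_rejected(self, kwargs):
        with pytest.raises(ValueError):
            NanorodDesign(**kwargs)

    def test_bad_field_parameters_rejected(self):
        design = NanorodDesign(2, 28.0)
        with pytest.raises(ValueError):
            sample_field(design, SMALL_ACQ, -1.0, 0.5)
        with pytest.raises(ValueError):
            sample_field(design, SMALL_ACQ, 1.0, 1.5)
        with pytest.raises(ValueError):
            AcquisitionConfig(fov_px=0)
        tiny = AcquisitionConfig(fov_px=1, n_frames=100)
        with pytest.raises(ValueError):
            sample_field(NanorodDesign(8, 28.0), tiny, 1.0, 0.5)


class TestFieldSampling:
    def test_full_and_zero_labeling(self):
        design = NanorodDesign(4, 28.0)
        gt1 = sample_field(design, SMALL_ACQ, 8.0, 1.0, seed=0)
        assert gt1.n_rods > 0
        assert all(rod.site_occupied.all() for rod in gt1.rods)
        gt0 = sample_field(design, SMALL_ACQ, 8.0, 0.0, seed=0)
        assert not any(rod.site_occupied.any() for rod in gt0.rods)

    def test_occupancy_matches_binomial_oracle(self):
        """Occupied fraction sits in the exact 99% binomial interval and the
        per-rod occupancy histogram passes a goodness-of-fit test."""
        design = NanorodDesign(4, 28.0)
        acq = AcquisitionConfig(fov_px=256, n_frames=100)
        gt = sample_field(design, acq, 8.0, 0.8, seed=7)
        occ = np.array([rod.site_occupied.sum() for rod in gt.rods])
        n_sites = 4 * gt.n_rods
        assert n_sites >= 10_000
        k = int(occ.sum())
        lo, hi = binom.ppf([0.005, 0.995], n_sites, 0.8)
        assert lo <= k <= hi
        observed = np.bincount(occ, minlength=5)
        expected = binom.pmf(np.arange(5), 4, 0.8) * gt.n_rods
        _, p = chisquare(observed, expected)
        assert p > 1e-3

    def test_rod_geometry(self):
        """Straight rods are exactly collinear with the designed spacing and
        lie fully inside the field of view."""
        design = NanorodDesign(4, 28.0)
        gt = sample_field(design, SMALL_ACQ, 8.0, 1.0, bend_sd_rad=0.0, seed=3)
        fov = SMALL_ACQ.fov_nm
        for rod in gt.rods:
            sites = rod.site_positions_nm
            gaps = np.linalg.norm(np.diff(sites, axis=0), axis=1)
            assert np.allclose(gaps, 28.0, atol=1e-9)
            chord = sites[-1] - sites[0]
            u = chord / np.linalg.norm(chord)
            perp = (sites - sites[0]) @ np.array([-u[1], u[0]])
            assert np.max(np.abs(perp)) < 1e-9
            assert sites.min() > 0 and sites.max() < fov

    def test_bent_rods_are_not_collinear(self):
        design = NanorodDesign(4, 28.0)
        gt = sample_field(design, SMALL_ACQ, 8.0, 1.0, bend_sd_rad=0.5, seed=3)
        worst = 0.0
        for rod in gt.rods:
            sites = rod.site_positions_nm
            chord = sites[-1] - sites[0]
            u = chord / np.linalg.norm(chord)
            perp = (sites - sites[0]) @ np.array([-u[1], u[0]])
            worst = max(worst, np.max(np.abs(perp)))
        assert worst > 1.0


class TestDrift:
    def test_zero_and_single_frame(self):
        assert np.all(simulate_drift(100, 0.0).displacement_nm == 0.0)
        single = simulate_drift(1, 0.5, seed=1)
        assert single.displacement_nm.shape == (1, 2)
        assert np.all(single.displacement_nm == 0.0)

    def test_step_sd_matches_sample_oracle(self):
        traj = simulate_drift(12000, 0.05, seed=5)
        steps = np.diff(traj.displacement_nm, axis=0)
        sd = steps.std(axis=0, ddof=1)
        # 99% chi-square band for a sample sd at n ~ 12000
        assert np.all(np.abs(sd - 0.05) < 0.05 * 3.0 / np.sqrt(2 * 11998))

    def test_anchored_at_zero(self):
        assert np.all(simulate_drift(50, 1.0, seed=2).displacement_nm[0] == 0)


class TestLocalizations:
    def test_empty_field_gives_empty_table(self):
        design = NanorodDesign(4, 28.0)
        gt = sample_field(design, SMALL_ACQ, 8.0, 0.0, seed=0)
        kin = KineticsConfig(false_loc_rate=0.0)
        table = simulate_localizations(gt, SMALL_ACQ, kin, None, seed=1)
        assert len(table) == 0

    def test_drift_length_mismatch_rejected(self):
        design = NanorodDesign(1, 28.0)
        gt = sample_field(design, SMALL_ACQ, 2.0, 1.0, seed=0)
        bad = DriftTrajectory.zero(SMALL_ACQ.n_frames - 1)
        with pytest.raises(ValueError):
            simulate_localizations(gt, SMALL_ACQ, KineticsConfig(), bad)

    def test_event_count_matches_renewal_oracle(self):
        """Bright-frame count of one site (two docking strands) over 12000
        frames falls in the 99% interval of an independent renewal-process
        simulation."""
        acq = AcquisitionConfig(fov_px=16, n_frames=12000)
        design = NanorodDesign(1, 28.0)
        kin = KineticsConfig(mean_dark_frames=199.0, mean_bright_frames=1.0,
                             false_loc_rate=0.0)

        # independent oracle: alternate geometric dark/bright runs per strand
        rng = np.random.default_rng(2024)
        reps = 100_000
        n_cycles = 150
        dark = rng.geometric(1 / 199.0, size=(reps, n_cycles))
        bright = rng.geometric(1.0, size=(reps, n_cycles))
        ends = np.cumsum(dark + bright, axis=1)
        counts = np.minimum(
            np.maximum(acq.n_frames - (ends - bright), 0), bright).sum(axis=1)
        pair_counts = counts[::2] + counts[1::2]   # two strands per site
        lo, hi = np.percentile(pair_counts, [0.5, 99.5])
        assert 90 < lo < 120 < hi < 160  # sanity: mean is 2*12000/200 = 120

        observed = []
        for seed in range(10):
            gt = sample_field(design, acq, 3.0, 1.0, seed=seed)
            if gt.n_rods == 0:
                continue
            table = simulate_localizations(gt, acq, kin, None, seed=seed + 50)
            per_rod = table.df.groupby("rod_id").size()
            observed.extend(per_rod.tolist())
        inside = np.mean([(lo <= c <= hi) for c in observed])
        assert inside >= 0.95

    def test_localization_noise_matches_precision(self):
        """With zero drift, localization scatter about the true site is the
        configured precision per axis."""
        acq = AcquisitionConfig(fov_px=16, n_frames=12000)
        design = NanorodDesign(1, 28.0)
        kin = KineticsConfig(precision_nm=5.0, false_loc_rate=0.0,
                             mean_dark_frames=20.0)
        gt = sample_field(design, acq, 3.0, 1.0, seed=9)
        table = simulate_localizations(gt, acq, kin, None, seed=10)
        site_by_rod = {r: rod.site_positions_nm[0]
                       for r, rod in enumerate(gt.rods)}
        xy = table.xy_nm()
        rod_ids = table.df["rod_id"].to_numpy()
        devs = np.concatenate([
            xy[rod_ids == r] - site for r, site in site_by_rod.items()
        ])
        assert len(devs) > 5000
        sd = devs.std(axis=0, ddof=1)
        assert np.all(np.abs(sd - 5.0) < 0.3)

    def test_count_scales_with_frames_and_docking(self):
        design1 = NanorodDesign(2, 28.0, docking_per_site=1)
        design2 = NanorodDesign(2, 28.0, docking_per_site=2)
        kin = KineticsConfig(false_loc_rate=0.0)
        acq_a = AcquisitionConfig(fov_px=32, n_frames=3000)
        acq_b = AcquisitionConfig(fov_px=32, n_frames=6000)
        gt = sample_field(design1, acq_a, 8.0, 1.0, seed=4)
        n_a = len(simulate_localizations(gt, acq_a, kin, None, seed=5))
        gt_b = sample_field(design1, acq_b, 8.0, 1.0, seed=4)
        n_b = len(simulate_localizations(gt_b, acq_b, kin, None, seed=5))
        assert abs(n_b / n_a - 2.0) < 0.15
        gt_d = sample_field(design2, acq_a, 8.0, 1.0, seed=4)
        n_d = len(simulate_localizations(gt_d, acq_a, kin, None, seed=5))
        assert abs(n_d / n_a - 2.0) < 0.15

    def test_injected_drift_visible_in_localizations(self):
        """Mean displacement of localizations from their true sites tracks
        the injected trajectory."""
        acq = AcquisitionConfig(fov_px=32, n_frames=4000)
        design = NanorodDesign(4, 28.0)
        kin = KineticsConfig(false_loc_rate=0.0, mean_dark_frames=20.0)
        drift = simulate_drift(acq.n_frames, 0.5, seed=11)
        gt = sample_field(design, acq, 8.0, 1.0, seed=12)
        table = simulate_localizations(gt, acq, kin, drift, seed=13)
        site_pos, rod_ids, site_ids = gt.occupied_sites()
        key = {(r, s): p for p, r, s in zip(site_pos, rod_ids, site_ids)}
        xy = table.xy_nm()
        frames = table.df["frame"].to_numpy()
        true_xy = np.array([key[(r, s)] for r, s in
                            zip(table.df["rod_id"], table.df["site_id"])])
        dev = xy - true_xy
        for f0 in (1000, 3000):
            sel = (frames >= f0) & (frames < f0 + 200)
            est = dev[sel].mean(axis=0)
            true = drift.displacement_nm[f0:f0 + 200].mean(axis=0)
            tol = 3 * 5.0 / np.sqrt(sel.sum())
            assert np.all(np.abs(est - true) < max(tol, 1.0))


class TestCy5Render:
    def test_empty_field_is_flat_background(self):
        design = NanorodDesign(4, 28.0)
        gt = sample_field(design, SMALL_ACQ, 8.0, 1.0, seed=1)
        gt.rods = []
        img = render_cy5(gt, SMALL_ACQ, background=100.0, noise_sd=0.0)
        assert np.allclose(img, 100.0)

    def test_single_rod_peak_near_midline(self):
        design = NanorodDesign(4, 28.0)
        gt = sample_field(design, SMALL_ACQ, 8.0, 1.0, seed=1)
        gt.rods = gt.rods[:1]
        img = render_cy5(gt, SMALL_ACQ, noise_sd=0.0)
        peak = np.unravel_index(np.argmax(img), img.shape)
        center_px = gt.rods[0].center_nm / SMALL_ACQ.pixel_size_nm - 0.5
        assert abs(peak[1] - center_px[0]) <= 1.0
        assert abs(peak[0] - center_px[1]) <= 1.0

    def test_intensity_linear_in_rod_count(self):
        """Integrated above-background signal superposes linearly."""
        design = NanorodDesign(4, 28.0)
        acq = AcquisitionConfig(fov_px=96, n_frames=100)
        gt = sample_field(design, acq, 2.0, 1.0, seed=21)
        assert gt.n_rods >= 40
        totals = []
        for n in (10, 20, 40):
            sub = sample_field(design, acq, 2.0, 1.0, seed=21)
            sub.rods = gt.rods[:n]
            img = render_cy5(sub, acq, background=100.0, noise_sd=0.0)
            totals.append((img - 100.0).sum())
        assert abs(totals[1] / totals[0] - 2.0) < 0.1
        assert abs(totals[2] / totals[0] - 4.0) < 0.2

    def test_nonnegative_with_noise(self):
        design = NanorodDesign(2, 28.0)
        gt = sample_field(design, SMALL_ACQ, 4.0, 1.0, seed=2)
        img = render_cy5(gt, SMALL_ACQ, background=5.0, noise_sd=20.0, seed=3)
        assert img.min() >= 0.0
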