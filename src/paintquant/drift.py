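"""Stage drift estimation and removal for localization data.

Two rounds, mirroring common super-resolution practice: first redundant
cross-correlation (RCC) over temporal segments of the movie, then a
refinement that tracks the centroids of individually picked structures
over time.  RCC partitions the frames into consecutive segments, renders
each segment as a super-resolved histogram image, measures every pairwise
segment-to-segment shift by cross-correlation, and solves the
overdetermined system for per-segment drift by least squares; per-frame
drift is linearly interpolated between segment midpoints and anchored so
frame 0 has zero displacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.registration import phase_cross_correlation

from .io import LocalizationTable
from .simulate import DriftTrajectory

__all__ = [
    "SuperResImage",
    "Pick",
    "render_image",
    "rcc_correct",
    "auto_seed_picks",
    "pick_similar",
    "undrift_picked",
]


@dataclass
class SuperResImage:
    """Oversampled 2-D localization histogram.

    ``data[i, j]`` counts localizations with y in oversampled row i and x
    in column j; camera pixel ``i`` spans ``[i, i + 1)``, so oversampled
    pixel ``j`` spans ``[j/os, (j+1)/os)`` in camera-pixel units.
    """

    data: np.ndarray
    oversampling: int

    def __post_init__(self) -> None:
        if self.oversampling < 1:
            raise ValueError("oversampling must be >= 1")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")


def render_image(table_or_xy, fov_px: int | None = None, oversampling: int = 1,
                 blur_sd_px: float = 0.0) -> SuperResImage:
    """Histogram localizations onto an oversampled grid.

    Accepts a :class:`LocalizationTable` or a raw (n, 2) array of x, y in
    camera pixels (then ``fov_px`` is required).  Before smoothing, the
    total mass equals the number of in-field localizations.
    """
    if isinstance(table_or_xy, LocalizationTable):
        xy = table_or_xy.xy_px()
        fov_px = table_or_xy.fov_px
    else:
        xy = np.asarray(table_or_xy, dtype=float).reshape(-1, 2)
        if fov_px is None:
            raise ValueError("fov_px required when passing raw coordinates")
    n_bins = fov_px * oversampling
    edges = np.arange(n_bins + 1) / oversampling
    if len(xy) == 0:
        data = np.zeros((n_bins, n_bins))
    else:
        data, _, _ = np.histogram2d(xy[:, 1], xy[:, 0], bins=[edges, edges])
    if blur_sd_px > 0:
        data = gaussian_filter(data, sigma=blur_sd_px * oversampling)
    return SuperResImage(data, oversampling)


def _segment_bounds(n_frames: int, segment_frames: int) -> list[tuple[int, int]]:
    n_seg = n_frames // segment_frames
    bounds = [(s * segment_frames, (s + 1) * segment_frames) for s in range(n_seg)]
    # fold the remainder into the last segment
    bounds[-1] = (bounds[-1][0], n_frames)
    return bounds


def _solve_redundant(n_seg: int, pairs: list[tuple[int, int]],
                     shifts: np.ndarray) -> np.ndarray:
    """Least-squares per-segment drift from pairwise shifts, seg 0 anchored."""
    a = np.zeros((len(pairs), n_seg - 1))
    for row, (i, j) in enumerate(pairs):
        if j > 0:
            a[row, j - 1] += 1.0
        if i > 0:
            a[row, i - 1] -= 1.0
    sol, *_ = np.linalg.lstsq(a, shifts, rcond=None)
    return np.vstack([np.zeros((1, 2)), sol])


def rcc_correct(table: LocalizationTable, segment_frames: int = 200,
                oversampling: int = 8, blur_sd_px: float | None = None,
                max_pair_shift_px: float = 3.0, upsample_factor: int = 20,
                ) -> tuple[LocalizationTable, DriftTrajectory]:
    """Redundant cross-correlation drift correction.

    Measures the relative shift of every pair of segment renderings
    (upsampled-DFT cross-correlation), discards pair shifts larger than
    ``max_pair_shift_px``, solves for per-segment drift by least squares
    and subtracts the per-frame linear interpolation from the coordinates.
    Returns the corrected table and the estimated trajectory in nm.

    ``blur_sd_px`` defaults to one oversampled pixel: just enough
    smoothing to suppress shot noise without widening the correlation
    peak, which would degrade the sub-pixel shift estimate.
    """
    if blur_sd_px is None:
        blur_sd_px = 1.0 / oversampling
    if table.n_frames < 2 * segment_frames:
        raise ValueError(
            f"need >= 2 segments: n_frames={table.n_frames} < "
            f"2 x segment_frames={segment_frames}; record a longer movie or "
            "use a smaller segment size"
        )
    bounds = _segment_bounds(table.n_frames, segment_frames)
    n_seg = len(bounds)
    frames = table.df["frame"].to_numpy()
    xy = table.xy_px()
    spectra = []
    for start, stop in bounds:
        lo, hi = np.searchsorted(frames, [start, stop])
        img = render_image(xy[lo:hi], table.fov_px, oversampling, blur_sd_px)
        spectra.append(np.fft.fftn(img.data))
    pairs, shifts = [], []
    for i in range(n_seg - 1):
        for j in range(i + 1, n_seg):
            shift, _, _ = phase_cross_correlation(
                spectra[i], spectra[j], upsample_factor=upsample_factor,
                space="fourier", normalization=None,
            )
            # shift registers segment j onto i => drift(j) - drift(i) (row, col)
            d_px = -np.array([shift[1], shift[0]]) / oversampling
            if np.all(np.abs(d_px) <= max_pair_shift_px):
                pairs.append((i, j))
                shifts.append(d_px)
    if not pairs:
        raise RuntimeError("no usable pairwise segment shifts")
    seg_drift = _solve_redundant(n_seg, pairs, np.asarray(shifts))
    mids = np.array([(start + stop - 1) / 2.0 for start, stop in bounds])
    all_frames = np.arange(table.n_frames)
    per_frame = np.column_stack([
        np.interp(all_frames, mids, seg_drift[:, 0]),
        np.interp(all_frames, mids, seg_drift[:, 1]),
    ])
    per_frame -= per_frame[0]
    df = table.df.copy()
    df["x"] = df["x"] - per_frame[frames, 0]
    df["y"] = df["y"] - per_frame[frames, 1]
    est = DriftTrajectory(per_frame * table.pixel_size_nm)
    note = (f"rcc_correct: segments={n_seg} oversampling={oversampling} "
            f"pairs_used={len(pairs)}")
    return table.with_df(df, note), est


@dataclass
class Pick:
    """A circular pick around one structure."""

    center_px: np.ndarray       # (2,) x, y in camera pixels
    diameter_px: float
    members: np.ndarray         # indices into the table

    def __post_init__(self) -> None:
        if self.diameter_px <= 0:
            raise ValueError("diameter_px must be positive")
        self.center_px = np.asarray(self.center_px, dtype=float)
        self.members = np.asarray(self.members, dtype=int)


def _pick_at(xy: np.ndarray, tree: cKDTree, center: np.ndarray,
             diameter_px: float, refine: int = 1) -> Pick:
    """Build a pick at ``center``, refining the centre on its members."""
    center = np.asarray(center, dtype=float)
    r = diameter_px / 2.0
    idx = np.array(tree.query_ball_point(center, r), dtype=int)
    for _ in range(refine):
        if len(idx) == 0:
            break
        center = xy[idx].mean(axis=0)
        idx = np.array(tree.query_ball_point(center, r), dtype=int)
    return Pick(center, diameter_px, np.sort(idx))


def _pick_stats(xy: np.ndarray, pick: Pick) -> tuple[float, float]:
    n = len(pick.members)
    if n == 0:
        return 0.0, 0.0
    pts = xy[pick.members]
    spread = float(np.sqrt(np.mean(np.sum((pts - pts.mean(axis=0)) ** 2, axis=1))))
    return float(n), spread


def auto_seed_picks(table: LocalizationTable, n_seeds: int = 20,
                    diameter_px: float = 1.5, oversampling: int = 4,
                    blur_sd_px: float = 0.5) -> list[Pick]:
    """Stand-in for manual seed picking: typical density maxima.

    Detects all prominent maxima and keeps ``n_seeds`` evenly spaced in
    intensity rank between the 10th and 90th percentile — a human picks
    structures spanning the typical variability, skipping the dimmest
    fragments and the brightest (often overlapping) spots.
    """
    img = render_image(table, oversampling=oversampling, blur_sd_px=blur_sd_px)
    min_dist = max(int(round(diameter_px * oversampling)), 1)
    peaks = peak_local_max(img.data, min_distance=min_dist, threshold_rel=0.05)
    if len(peaks) > n_seeds:
        intensities = img.data[peaks[:, 0], peaks[:, 1]]
        rank = np.argsort(intensities, kind="stable")
        lo, hi = int(0.1 * len(rank)), int(np.ceil(0.9 * len(rank))) - 1
        sel = np.unique(np.linspace(lo, hi, n_seeds).round().astype(int))
        peaks = peaks[rank[sel]]
    xy = table.xy_px()
    tree = cKDTree(xy) if len(xy) else None
    picks = []
    for row, col in peaks:
        center = np.array([(col + 0.5) / oversampling,
                           (row + 0.5) / oversampling])
        if tree is not None:
            picks.append(_pick_at(xy, tree, center, diameter_px))
    return [p for p in picks if len(p.members)]


def pick_similar(table: LocalizationTable, seeds: list[Pick],
                 diameter_px: float = 1.5, std_factor: float = 1.6,
                 oversampling: int = 4, blur_sd_px: float = 0.5,
                 ) -> list[Pick]:
    """Find every structure statistically similar to the seed picks.

    Candidate centres are local density maxima of the rendered image; a
    candidate is accepted when its localization count and radial spread
    both lie within mean +/- ``std_factor`` x sd of the seed statistics.
    Count sd is floored at sqrt(mean) and 8% of the mean (counting and
    blinking noise), spread sd at 8% of the mean, so that near-identical
    seeds still admit a tolerance band.  Seed picks are always returned.
    """
    if len(seeds) < 2:
        raise ValueError("need at least 2 seed picks")
    xy = table.xy_px()
    tree = cKDTree(xy)
    stats = np.array([_pick_stats(xy, p) for p in seeds])
    mean_n, mean_s = stats.mean(axis=0)
    sd_n = max(stats[:, 0].std(), np.sqrt(max(mean_n, 1.0)), 0.08 * mean_n)
    sd_s = max(stats[:, 1].std(), 0.08 * max(mean_s, 1e-6))
    lo_n, hi_n = mean_n - std_factor * sd_n, mean_n + std_factor * sd_n
    lo_s, hi_s = mean_s - std_factor * sd_s, mean_s + std_factor * sd_s

    img = render_image(table, oversampling=oversampling, blur_sd_px=blur_sd_px)
    min_dist = max(int(round(0.75 * diameter_px * oversampling)), 1)
    peaks = peak_local_max(img.data, min_distance=min_dist, threshold_rel=0.02)
    accepted: list[Pick] = list(seeds)
    centers = [p.center_px for p in seeds]
    for row, col in peaks:
        center = np.array([(col + 0.5) / oversampling,
                           (row + 0.5) / oversampling])
        if centers and np.min(np.linalg.norm(np.array(centers) - center, axis=1)) \
                < diameter_px / 2.0:
            continue
        cand = _pick_at(xy, tree, center, diameter_px)
        if centers and np.min(np.linalg.norm(
                np.array(centers) - cand.center_px, axis=1)) < diameter_px / 2.0:
            continue
        n, s = _pick_stats(xy, cand)
        if lo_n <= n <= hi_n and lo_s <= s <= hi_s:
            accepted.append(cand)
            centers.append(cand.center_px)
    return accepted


def undrift_picked(table: LocalizationTable, picks: list[Pick],
                   window_frames: int = 200, smooth_sigma_windows: float = 2.0,
                   ) -> tuple[LocalizationTable, DriftTrajectory]:
    """Refine drift from the time-resolved centroids of picked structures.

    Per frame window, the displacement of each pick's localizations from
    that pick's overall centroid is averaged over picks (weighted by
    localization count); windows without data inherit interpolated values;
    the window series is Gaussian-smoothed and interpolated per frame.

    The trajectory is anchored at its count-weighted mean — the gauge in
    which the pick centroids are defined.  Anchoring at frame 0 instead
    would propagate the first window's sampling noise into a constant
    offset of every corrected coordinate.
    """
    if not picks:
        raise ValueError("need at least one pick")
    n_w = int(np.ceil(table.n_frames / window_frames))
    frames = table.df["frame"].to_numpy()
    xy = table.xy_px()
    acc = np.zeros((n_w, 2))
    cnt = np.zeros(n_w)
    for pick in picks:
        if len(pick.members) == 0:
            continue
        pts = xy[pick.members]
        centroid = pts.mean(axis=0)
        w = frames[pick.members] // window_frames
        disp = pts - centroid
        np.add.at(acc, w, disp)
        np.add.at(cnt, w, 1)
    have = cnt > 0
    if not have.any():
        raise ValueError("picks contain no localizations")
    win_drift = np.full((n_w, 2), np.nan)
    win_drift[have] = acc[have] / cnt[have, None]
    idx = np.arange(n_w)
    for axis in range(2):
        win_drift[~have, axis] = np.interp(idx[~have], idx[have],
                                           win_drift[have, axis])
    if smooth_sigma_windows > 0 and n_w > 2:
        win_drift = gaussian_filter1d(win_drift, sigma=smooth_sigma_windows,
                                      axis=0, mode="nearest")
    mids = idx * window_frames + (window_frames - 1) / 2.0
    mids[-1] = (idx[-1] * window_frames + table.n_frames - 1) / 2.0
    all_frames = np.arange(table.n_frames)
    per_frame = np.column_stack([
        np.interp(all_frames, mids, win_drift[:, 0]),
        np.interp(all_frames, mids, win_drift[:, 1]),
    ])
    weights = cnt / cnt.sum()
    per_frame -= (win_drift * weights[:, None]).sum(axis=0)
    df = table.df.copy()
    df["x"] = df["x"] - per_frame[frames, 0]
    df["y"] = df["y"] - per_frame[frames, 1]
    est = DriftTrajectory(per_frame * table.pixel_size_nm)
    note = f"undrift_picked: picks={len(picks)} window={window_frames}"
    return table.with_df(df, note), est
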