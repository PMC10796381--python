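"""Synthetic DNA-PAINT data generator for origami nanorod experiments.

Generates localization tables, per-rod ground truth and a companion
widefield reference (Cy5) image with the statistical structure the
quantification pipeline assumes:

* rod-like DNA origami structures scattered over the field of view, each
  carrying ``n_sites`` designed protein positions spaced ``site_spacing_nm``
  apart along the rod axis;
* Bernoulli site labeling — each designed site carries a protein conjugate
  with probability ``labeling_p``;
* each conjugated protein presents ``docking_per_site`` docking strands;
  an imager strand binds and unbinds each docking strand in alternating
  geometric dark/bright runs (memoryless binding, frame-quantized camera);
* one localization per bright frame, displaced by stage drift and by
  isotropic Gaussian localization noise;
* sparse false localizations uniform over the field and the acquisition;
* a diffraction-limited reference image in which every rod contributes a
  fixed number of fluorophores spread along its midline, independent of
  how many protein sites are occupied.

All coordinates inside this module are nanometres unless a name says
otherwise; the emitted :class:`~paintquant.io.LocalizationTable` is in
camera-pixel units, converted at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LocalizationTable

__all__ = [
    "NanorodDesign",
    "AcquisitionConfig",
    "KineticsConfig",
    "Nanorod",
    "GroundTruthField",
    "DriftTrajectory",
    "sample_field",
    "simulate_drift",
    "simulate_localizations",
    "render_cy5",
]


@dataclass(frozen=True)
class NanorodDesign:
    """Geometry of one origami rod design.

    Parameters
    ----------
    n_sites:
        Number of designed protein positions (0 for the empty control rod).
    site_spacing_nm:
        Centre-to-centre distance between adjacent designed positions.
    docking_per_site:
        Docking strands presented by each protein conjugate.
    cy5_count:
        Reference fluorophores built into every rod, occupancy-independent.
    overhang_nm:
        Structural rod material extending past the outermost sites on each
        end; only affects the rod footprint and the reference-dye layout.
    """

    n_sites: int
    site_spacing_nm: float = 28.0
    docking_per_site: int = 2
    cy5_count: int = 6
    overhang_nm: float = 15.0

    def __post_init__(self) -> None:
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")
        if self.n_sites >= 2 and self.site_spacing_nm <= 0:
            raise ValueError("site_spacing_nm must be > 0 for multi-site designs")
        if self.docking_per_site < 1:
            raise ValueError("docking_per_site must be >= 1")
        if self.cy5_count < 0:
            raise ValueError("cy5_count must be >= 0")

    @property
    def rod_length_nm(self) -> float:
        span = max(self.n_sites - 1, 0) * self.site_spacing_nm
        return span + 2.0 * self.overhang_nm


@dataclass(frozen=True)
class AcquisitionConfig:
    """Camera/acquisition geometry of a PAINT movie."""

    fov_px: int = 64
    pixel_size_nm: float = 87.0
    n_frames: int = 12000
    exposure_s: float = 0.3

    def __post_init__(self) -> None:
        if self.fov_px <= 0 or self.pixel_size_nm <= 0:
            raise ValueError("fov_px and pixel_size_nm must be positive")
        if self.n_frames <= 0 or self.exposure_s <= 0:
            raise ValueError("n_frames and exposure_s must be positive")

    @property
    def fov_nm(self) -> float:
        return self.fov_px * self.pixel_size_nm

    @property
    def area_um2(self) -> float:
        return (self.fov_nm / 1000.0) ** 2


@dataclass(frozen=True)
class KineticsConfig:
    """Imager binding kinetics and localization noise model.

    ``mean_dark_frames``/``mean_bright_frames`` are the means of the
    geometric (support >= 1) dark/bright run lengths per docking strand.
    The defaults give one ~1-frame binding event per strand per 200 frames,
    i.e. about 120 localizations per site over a 12000-frame movie with two
    docking strands per protein.
    """

    mean_dark_frames: float = 199.0
    mean_bright_frames: float = 1.0
    photons_mean: float = 3000.0
    photons_sigma_ln: float = 0.3
    precision_nm: float = 5.0
    false_loc_rate: float = 0.01  # spurious localizations / frame / um^2
    psf_sigma_px: float = 0.9
    width_jitter: float = 0.05

    def __post_init__(self) -> None:
        if self.mean_dark_frames <= 0 or self.mean_bright_frames <= 0:
            raise ValueError("mean dark/bright frame counts must be positive")
        if self.precision_nm <= 0:
            raise ValueError("precision_nm must be positive")
        if self.false_loc_rate < 0:
            raise ValueError("false_loc_rate must be >= 0")
        if self.photons_mean <= 0:
            raise ValueError("photons_mean must be positive")


@dataclass(frozen=True)
class Nanorod:
    """Ground truth for a single rod."""

    center_nm: np.ndarray        # (2,)
    orientation_rad: float
    bend_angle_rad: float
    site_positions_nm: np.ndarray  # (n_sites, 2)
    site_occupied: np.ndarray      # (n_sites,) bool


@dataclass
class GroundTruthField:
    """A simulated field of rods with known per-site occupancy."""

    design: NanorodDesign
    acq: AcquisitionConfig
    rods: list[Nanorod]
    labeling_p: float
    seed: int

    @property
    def n_rods(self) -> int:
        return len(self.rods)

    def occupied_sites(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flatten occupied sites to (positions_nm, rod_ids, site_ids)."""
        pos, rid, sid = [], [], []
        for r, rod in enumerate(self.rods):
            occ = np.flatnonzero(rod.site_occupied)
            if occ.size:
                pos.append(rod.site_positions_nm[occ])
                rid.append(np.full(occ.size, r))
                sid.append(occ)
        if not pos:
            return (np.empty((0, 2)), np.empty(0, dtype=int), np.empty(0, dtype=int))
        return np.concatenate(pos), np.concatenate(rid), np.concatenate(sid)

    def to_json_dict(self) -> dict:
        return {
            "design": {
                "n_sites": self.design.n_sites,
                "site_spacing_nm": self.design.site_spacing_nm,
                "docking_per_site": self.design.docking_per_site,
                "cy5_count": self.design.cy5_count,
                "overhang_nm": self.design.overhang_nm,
            },
            "labeling_p": self.labeling_p,
            "seed": self.seed,
            "rods": [
                {
                    "center_nm": rod.center_nm.tolist(),
                    "orientation_rad": rod.orientation_rad,
                    "bend_angle_rad": rod.bend_angle_rad,
                    "site_positions_nm": rod.site_positions_nm.tolist(),
                    "site_occupied": rod.site_occupied.astype(int).tolist(),
                }
                for rod in self.rods
            ],
        }


@dataclass(frozen=True)
class DriftTrajectory:
    """Per-frame stage displacement in nm; frame 0 is the origin."""

    displacement_nm: np.ndarray  # (n_frames, 2)

    def __post_init__(self) -> None:
        d = np.asarray(self.displacement_nm, dtype=float)
        if d.ndim != 2 or d.shape[1] != 2 or d.shape[0] < 1:
            raise ValueError("displacement_nm must have shape (n_frames, 2)")
        object.__setattr__(self, "displacement_nm", d)

    @property
    def n_frames(self) -> int:
        return self.displacement_nm.shape[0]

    @classmethod
    def zero(cls, n_frames: int) -> "DriftTrajectory":
        return cls(np.zeros((n_frames, 2)))

    def rms_nm(self) -> float:
        return float(np.sqrt(np.mean(np.sum(self.displacement_nm**2, axis=1))))


def _rod_site_layout(design: NanorodDesign, bend_angle_rad: float,
                     orientation_rad: float) -> np.ndarray:
    """Site positions of one rod, centred at the origin.

    The rod is a polyline with a single kink at its midpoint: the first
    half runs along ``orientation_rad``, the second half is rotated by
    ``bend_angle_rad``.  With zero bend all sites are exactly collinear.
    """
    n = design.n_sites
    if n == 0:
        return np.empty((0, 2))
    t = np.arange(n) * design.site_spacing_nm       # arclength from site 0
    t_mid = t[-1] / 2.0 if n > 1 else 0.0
    u1 = np.array([np.cos(orientation_rad), np.sin(orientation_rad)])
    phi = orientation_rad + bend_angle_rad
    u2 = np.array([np.cos(phi), np.sin(phi)])
    first = np.minimum(t, t_mid)[:, None] * u1
    second = np.maximum(t - t_mid, 0.0)[:, None] * u2
    pos = first + second
    return pos - pos.mean(axis=0)


def sample_field(design: NanorodDesign, acq: AcquisitionConfig,
                 density_per_um2: float, labeling_p: float,
                 bend_sd_rad: float = 0.0, seed: int = 0,
                 margin_nm: float = 30.0) -> GroundTruthField:
    """Scatter rods over the field of view with Bernoulli site labeling.

    The rod count is Poisson with mean ``density_per_um2`` times the field
    area; orientations are uniform; every rod lies fully inside the field
    with ``margin_nm`` to spare; each designed site is occupied
    independently with probability ``labeling_p``.
    """
    if density_per_um2 < 0:
        raise ValueError("density_per_um2 must be >= 0")
    if not 0.0 <= labeling_p <= 1.0:
        raise ValueError("labeling_p must be in [0, 1]")
    if bend_sd_rad < 0:
        raise ValueError("bend_sd_rad must be >= 0")
    rng = np.random.default_rng(seed)
    n_rods = int(rng.poisson(density_per_um2 * acq.area_um2))
    half = design.rod_length_nm / 2.0 + margin_nm
    lo, hi = half, acq.fov_nm - half
    if hi <= lo:
        raise ValueError(
            f"field of view {acq.fov_nm:.0f} nm too small for rods of "
            f"length {design.rod_length_nm:.0f} nm plus margin"
        )
    rods: list[Nanorod] = []
    for _ in range(n_rods):
        center = rng.uniform(lo, hi, size=2)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        bend = rng.normal(0.0, bend_sd_rad) if bend_sd_rad > 0 else 0.0
        sites = _rod_site_layout(design, bend, theta) + center
        occupied = rng.random(design.n_sites) < labeling_p
        rods.append(Nanorod(center, theta, bend, sites, occupied))
    return GroundTruthField(design, acq, rods, labeling_p, seed)


def simulate_drift(n_frames: int, step_sd_nm: float, seed: int = 0) -> DriftTrajectory:
    """Cumulative 2-D Gaussian random walk anchored at (0, 0)."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if step_sd_nm < 0:
        raise ValueError("step_sd_nm must be >= 0")
    if step_sd_nm == 0:
        return DriftTrajectory.zero(n_frames)
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, step_sd_nm, size=(n_frames - 1, 2))
    disp = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
    return DriftTrajectory(disp)


def _geometric_mean(rng: np.random.Generator, mean: float, size) -> np.ndarray:
    """Geometric run lengths (support >= 1) with the requested mean."""
    p = 1.0 / max(mean, 1.0)
    return rng.geometric(p, size=size)


def _strand_bright_frames(rng: np.random.Generator, n_strands: int,
                          n_frames: int, kin: KineticsConfig
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Bright frame indices for every strand.

    Returns (frames, strand_index) flat arrays.  Each strand alternates
    dark -> bright -> dark ... with geometric run lengths, starting dark.
    """
    if n_strands == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    cycle = kin.mean_dark_frames + kin.mean_bright_frames
    # enough cycles that running past n_frames is vanishingly unlikely
    n_cycles = int(np.ceil(n_frames / cycle * 2.0)) + 20
    dark = _geometric_mean(rng, kin.mean_dark_frames, (n_strands, n_cycles))
    bright = _geometric_mean(rng, kin.mean_bright_frames, (n_strands, n_cycles))
    cyc_end = np.cumsum(dark + bright, axis=1)
    b_start = cyc_end - bright
    # expand each bright run [b_start, cyc_end) into individual frames
    lens = bright.ravel()
    starts = b_start.ravel()
    reps = np.repeat(starts, lens)
    offs = np.arange(lens.sum()) - np.repeat(np.cumsum(lens) - lens, lens)
    frames = reps + offs
    strand = np.repeat(np.repeat(np.arange(n_strands), n_cycles), lens)
    keep = frames < n_frames
    return frames[keep].astype(int), strand[keep]


def simulate_localizations(gt: GroundTruthField, acq: AcquisitionConfig,
                           kin: KineticsConfig,
                           drift: DriftTrajectory | None = None,
                           seed: int = 0) -> LocalizationTable:
    """Emit the localization table a spot-fitting stage would produce.

    Every occupied site carries ``docking_per_site`` docking strands; each
    strand blinks independently and contributes one localization per bright
    frame at the true site position plus the frame's drift plus isotropic
    Gaussian noise of sd ``precision_nm`` per axis.  Reported per-axis
    precision is ``precision_nm * sqrt(photons_mean / photons)``.  Hidden
    truth columns (``rod_id``, ``site_id``; -1 for false localizations) are
    carried for testing and stripped on export.
    """
    if drift is None:
        drift = DriftTrajectory.zero(acq.n_frames)
    if drift.n_frames != acq.n_frames:
        raise ValueError(
            f"drift trajectory length {drift.n_frames} != n_frames {acq.n_frames}"
        )
    rng = np.random.default_rng(seed)
    site_pos, rod_ids, site_ids = gt.occupied_sites()
    n_strands = site_pos.shape[0] * gt.design.docking_per_site

    frames, strand = _strand_bright_frames(rng, n_strands, acq.n_frames, kin)
    site_of_strand = strand // gt.design.docking_per_site if n_strands else strand
    true_xy = site_pos[site_of_strand] if n_strands else np.empty((0, 2))
    xy = (true_xy
          + drift.displacement_nm[frames]
          + rng.normal(0.0, kin.precision_nm, size=true_xy.shape))
    lab_rod = rod_ids[site_of_strand] if n_strands else np.empty(0, dtype=int)
    lab_site = site_ids[site_of_strand] if n_strands else np.empty(0, dtype=int)

    # sparse false localizations, uniform in space and time
    n_false = rng.poisson(kin.false_loc_rate * acq.area_um2 * acq.n_frames)
    f_frames = rng.integers(0, acq.n_frames, size=n_false)
    f_xy = rng.uniform(0.0, acq.fov_nm, size=(n_false, 2))

    all_frames = np.concatenate([frames, f_frames])
    all_xy = np.vstack([xy, f_xy]) if (len(xy) or n_false) else np.empty((0, 2))
    all_rod = np.concatenate([lab_rod, np.full(n_false, -1)])
    all_site = np.concatenate([lab_site, np.full(n_false, -1)])

    n = all_frames.size
    mu_ln = np.log(kin.photons_mean) - 0.5 * kin.photons_sigma_ln**2
    photons = rng.lognormal(mu_ln, kin.photons_sigma_ln, size=n)
    lp_nm = kin.precision_nm * np.sqrt(kin.photons_mean / photons)
    lp_px = lp_nm / acq.pixel_size_nm
    widths = kin.psf_sigma_px * (1.0 + rng.normal(0.0, kin.width_jitter, size=(n, 2)))
    widths = np.abs(widths)
    bg = np.abs(rng.normal(50.0, 10.0, size=n))

    df = pd.DataFrame({
        "frame": all_frames.astype(np.int64),
        "x": all_xy[:, 0] / acq.pixel_size_nm,
        "y": all_xy[:, 1] / acq.pixel_size_nm,
        "photons": photons,
        "sx": widths[:, 0],
        "sy": widths[:, 1],
        "bg": bg,
        "lpx": lp_px,
        "lpy": lp_px.copy(),
        "rod_id": all_rod.astype(np.int64),
        "site_id": all_site.astype(np.int64),
    })
    df = df.sort_values("frame", kind="stable").reset_index(drop=True)
    return LocalizationTable(
        df=df,
        pixel_size_nm=acq.pixel_size_nm,
        n_frames=acq.n_frames,
        fov_px=acq.fov_px,
        provenance=[f"simulated seed={seed} rods={gt.n_rods} "
                    f"design={gt.design.n_sites}x@{gt.design.site_spacing_nm}nm"],
    )


def _cy5_positions(rod: Nanorod, design: NanorodDesign) -> np.ndarray:
    """Reference-dye positions spread evenly along the rod midline."""
    n = design.cy5_count
    if n == 0:
        return np.empty((0, 2))
    length = design.rod_length_nm
    t = (np.arange(n) + 0.5) / n * length        # arclength along the rod
    t_mid = length / 2.0
    u1 = np.array([np.cos(rod.orientation_rad), np.sin(rod.orientation_rad)])
    phi = rod.orientation_rad + rod.bend_angle_rad
    u2 = np.array([np.cos(phi), np.sin(phi)])
    pos = (np.minimum(t, t_mid)[:, None] * u1
           + np.maximum(t - t_mid, 0.0)[:, None] * u2)
    return pos - pos.mean(axis=0) + rod.center_nm


def render_cy5(gt: GroundTruthField, acq: AcquisitionConfig,
               psf_sigma_nm: float = 150.0, background: float = 100.0,
               noise_sd: float = 5.0, spot_intensity: float = 120.0,
               seed: int = 0) -> np.ndarray:
    """Diffraction-limited reference image of the field.

    Every rod contributes ``cy5_count`` Gaussian spots of width
    ``psf_sigma_nm`` along its midline regardless of protein occupancy, so
    empty rods remain detectable.  Returns a float image (fov_px, fov_px);
    convert with :func:`paintquant.io.write_tiff` for 16-bit output.
    """
    if psf_sigma_nm <= 0:
        raise ValueError("psf_sigma_nm must be positive")
    rng = np.random.default_rng(seed)
    img = np.full((acq.fov_px, acq.fov_px), float(background))
    sigma_px = psf_sigma_nm / acq.pixel_size_nm
    win = max(int(np.ceil(4 * sigma_px)), 2)
    # pixel i spans [i, i+1) camera px; its centre is i + 0.5
    for rod in gt.rods:
        for pos in _cy5_positions(rod, gt.design):
            cx, cy = pos / acq.pixel_size_nm - 0.5
            x0, x1 = int(np.floor(cx)) - win, int(np.floor(cx)) + win + 1
            y0, y1 = int(np.floor(cy)) - win, int(np.floor(cy)) + win + 1
            x0, x1 = max(x0, 0), min(x1, acq.fov_px)
            y0, y1 = max(y0, 0), min(y1, acq.fov_px)
            if x0 >= x1 or y0 >= y1:
                continue
            xs = np.arange(x0, x1)
            ys = np.arange(y0, y1)
            gx = np.exp(-0.5 * ((xs - cx) / sigma_px) ** 2)
            gy = np.exp(-0.5 * ((ys - cy) / sigma_px) ** 2)
            img[y0:y1, x0:x1] += spot_intensity * np.outer(gy, gx)
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, None)
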