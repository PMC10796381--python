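# Methods

## The measurement problem

A rod-shaped DNA origami presents n designed protein sites in a line,
28 nm apart (designs with 1–4 sites) or 14 nm apart (the 8-site design).
Each site is occupied by a protein conjugate with some labeling
efficiency p < 1, so the realized functionalization state of an
individual rod is a Binomial(n, p) draw. DNA-PAINT imaging resolves the
individual sites: each conjugate carries two docking strands, imager
strands bind transiently, and every bright frame yields one localization
near the site. The pipeline's job is to recover, per structure, how many
designed sites are occupied — including structures with zero proteins,
which are invisible in the PAINT channel and are detected only through
six reference (Cy5) dyes built into every rod.

## Synthetic data model

The generator is the package's testbed; its defaults define the study
conditions.

* **Field**: rod count ~ Poisson(density × area) at 0.9 rods/µm²,
  uniform positions (rods kept fully inside the field with a 30 nm
  margin) and orientations. Denser fields are not used because the
  diffraction-limited reference spots (PSF σ = 150 nm → ~500 nm
  footprint) become unsegmentable; 0.9/µm² already produces a realistic
  share of merged structures that the discard rules must handle.
* **Geometry**: sites spaced exactly by the design; rod curvature is a
  single mid-rod kink with Gaussian angle (default sd 0.1 rad ≈ 6°,
  mostly straight rods with an occasional visibly bent one — the
  population the linearity filter exists for).
* **Labeling**: i.i.d. Bernoulli(p) per site, default p = 0.9.
* **Kinetics**: per docking strand, alternating geometric dark/bright
  run lengths (memoryless binding quantized to frames), means 199 and 1
  frames. Over the default 12000-frame movie (300 ms exposure) this
  gives ≈ 60 localizations per strand, ≈ 120 per occupied site.
* **Localizations**: true site position + per-frame drift + isotropic
  Gaussian noise (default σ = 5 nm per axis). Photons are lognormal
  (mean 3000, σ_ln 0.3); the *reported* precision is
  σ·sqrt(photons_mean/photons), so reported and realized precision
  differ slightly, as in real fitting output. Spot widths are the
  nominal PSF sigma (0.9 px) with 5% jitter. False localizations are
  uniform in space and time at 0.01 /frame/µm².
* **Reference image**: every rod contributes six Gaussian spots
  (σ = 150 nm) spread along its midline regardless of occupancy, on a
  constant background with Gaussian read noise, on the 87 nm camera
  grid.

What the generator does **not** emulate: camera frames and spot fitting
(localizations are emitted directly), multi-emitter events within a
site, photobleaching or imager depletion, non-uniform background,
axial (z) structure, and optical aberrations. Passing tests therefore
demonstrate the correctness of the *analysis* given the stated
statistical structure, not robustness to every artifact of real
hardware.

Coordinates: localization tables are in camera pixels (pixel i spans
[i, i+1)); everything downstream of detection works in nm via the
87 nm pixel size.

## Pipeline stages and numerical choices

**Filtering.** Keep rows with reported precision ≤ 0.15 px (≈ 13 nm)
and fitted width ≤ 1.62 px (1.8 × the nominal PSF sigma); the width rule
is the proxy for multi-event localizations (two emitters fit as one wide
spot). Both thresholds are configuration values.

**RCC drift correction.** Frames are split into 200-frame segments;
each segment is rendered at 8× oversampling with a 1-oversampled-pixel
Gaussian blur. Every segment pair's relative shift is measured by
upsampled-DFT cross-correlation (plain correlation, no spectral
whitening — sparse histograms make phase correlation unstable); heavier
blurring is deliberately avoided because it widens the correlation peak
and degraded the sub-pixel estimate several-fold in our measurements.
Pair shifts above 3 px are dropped; per-segment drift is solved by least
squares over the redundant pair measurements with segment 0 anchored at
zero, and interpolated linearly between segment midpoints. On the
default dense test field this recovers a 0.05 nm/frame random walk with
< 1 nm RMS error.

**Picked refinement.** Structures similar to ~20 seed picks (1.5 px
diameter; similarity band mean ± 1.6 sd on localization count and radial
spread, with sd floors for counting noise) are tracked over 200-frame
windows; the count-weighted mean displacement of pick members from each
pick's centroid, smoothed with a 2-window Gaussian, is subtracted. The
refinement trajectory is anchored at its count-weighted mean — the gauge
in which pick centroids are defined. Anchoring it at frame 0 would turn
the first window's sampling noise (≈ 1.4 nm at default pick statistics)
into a constant offset of every coordinate; a constant offset neither
blurs nor shifts any *relative* measurement, but it would dominate the
reported residual. Automatic seeding picks maxima spread evenly across
the 10th–90th intensity percentiles, emulating a person choosing
representative structures rather than the brightest ones.

**Structure detection.** The reference image is min-max normalized and
thresholded against the local 15×15 px mean plus 0.15 of the dynamic
range (high enough that a signal-free image yields nothing; reference
spots are ~6× background so sensitivity is unaffected); a plus-shaped
binary opening removes speckles, and components with 2–200 px area
become contours. The PAINT channel is rendered at camera resolution,
binarized at ≥ 5 localizations/px, dilated by one pixel ("pixel
inflation", joining fragmented clusters) and size-filtered (4–80 px).
Reference and PAINT contours merge when their centre distance is below
0.9 × the radius sum; matching is globally nearest-first so the result
is independent of input order. Every reference contour yields exactly
one ROI (PAINT coordinates when matched, reference-only otherwise); all
ROIs share the dataset-mean PAINT contour radius; each localization
joins the nearest containing ROI (ties to the lower id).

**Distance calibration.** Per two-site ROI, DBSCAN (eps 3 nm,
min_samples 20) finds the localization clusters and rejects background.
The drafted defaults of eps 10 nm / min_samples 10 resolve the 28 nm
spacing but merge the two clouds at 14 nm with 5 nm precision; eps must
stay below roughly half the smallest spacing, and min_samples between
the in-disc counts at the inter-site saddle and at a site centre (16 and
21 for these conditions). Raw DBSCAN centroids are biased toward each
other by the cloud overlap (−1.5 nm at 14 nm spacing, measured), so the
two most populous clusters' centroids only *initialize* an EM fit of two
isotropic Gaussians plus a uniform background component over all ROI
localizations; the distance between the EM means is the per-structure
measurement (unbiased at both spacings and robust to false
localizations; `refine=False` restores the raw centroid distance). The
distance distribution is then histogram-fit with a single Gaussian
(Freedman–Diaconis bins, initialized at the median and MAD sd; median
fallback on non-convergence).

**Linearity score.** Unit vectors between adjacent detected positions
are sign-aligned with, and expressed in, the pattern's principal
direction frame (closed-form 2×2 eigenvector); the score is the mean of
the two component standard deviations. Evaluating in the principal
frame makes the score invariant under global rotation, translation and
scaling — the literal "sd of x and y components with a fixed sign
convention" is not rotation invariant, which would make the cutoff
depend on rod orientation. Zero iff the chain is straight. The cutoff
is taken on 4-site structures with exactly four detected positions: the
empirical CDF is smoothed (bandwidth 5% of the score range, grid padded
by three bandwidths), and the cutoff is the first zero crossing of the
second derivative after the first prominent density peak *at which the
density has fallen below half its peak* — the valley between the
straight bulk and the bent tail. Without the density condition,
sampling wiggles inside an all-straight population produce a spurious
early cutoff. If no such crossing exists the 90th percentile is used.

**Counting.** Each ROI's localizations are rendered at 5 nm/px (2 nm
for the 14 nm-spacing design — the render must sample the spacing
several-fold), blurred with the dataset's median localization precision,
and peak-normalized. Maxima above 0.2 with mutual separation ≥ 0.5 ×
reference distance are candidate positions; positions whose nearest
neighbour is beyond 3.5 × the reference distance are removed as strays
(3.5, not lower: a 4-site rod with only the two end sites occupied has a
legitimate 3× gap). Positions are ordered end-to-end via the distance
matrix (mutually farthest pair = ends, nearest-neighbour chaining from
the lower-index end). Structures with more positions than designed, or
scoring above the linearity cutoff, are discarded. A site grid anchored
at position one, stepped by the reference distance along the detected
axis (orientation chosen to minimize total position-to-grid residual,
ties keeping detected order), defines putative regions of radius 0.4 ×
reference distance; empty regions are re-scanned for maxima above 0.12
of peak (a lower threshold than detection, but above the ≈ 0.056
neighbour-tail level at a region edge with 28 nm spacing and ~7 nm
effective blur, which produced false rescues at more permissive
settings). Occupancy = occupied grid sites; reference-only ROIs count
as occupancy 0; fractions are aggregated over accepted + zero
structures, discards tallied separately.

## Protocols and problem sizes

`paintquant.protocols` fixes the standard runs: distance calibration on
≥ 300 two-site rods (220 px field) at 5 nm precision; counting protocols
on ≈ 200–230 rods per design (180 px field) at 2 nm precision ("high
SNR" — long, bright acquisitions), with calibrations derived from
matching 2-site and 4-site datasets at the same spacing; drift recovery
on a dense 32 px field with a 0.05 nm/frame random walk over 12000
frames. These sizes give sub-0.1 nm standard errors on the fitted
reference distance and ~100+ counted structures per distribution while
keeping any single protocol under a few seconds of compute.

## Known limitations

* ROIs formed from merged reference contours between close rods can pass
  the filters with partial, under-counted patterns; at the default
  density this contributes a small excess of low-occupancy states
  (visible as state-1/2 inflation of a few percent against the labeling
  binomial). Lower densities remove it.
* The counting stage assumes a single rod per ROI and a straight site
  grid; it does not attempt to split doubles or follow bent rods (both
  are discarded by design).
* With 5 nm precision the 14 nm spacing is at the edge of what
  density-based clustering can separate; the EM refinement recovers the
  distance, but per-structure yield drops to ~60% of ROIs. Counting at
  14 nm uses 2 nm precision.
* The empty (0-site) design is detected purely through the reference
  channel; its occupancy is 0 by construction and carries no PAINT
  evidence.
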