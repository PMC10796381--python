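"""Origami structure detection from the reference channel and PAINT data.

Structures are found twice: in the diffraction-limited reference (Cy5)
image — which sees every rod regardless of protein occupancy — and in a
low-resolution rendering of the PAINT localizations, which sees only rods
carrying at least one protein.  The two contour sets are merged: where a
PAINT contour overlaps a reference contour (centre distance below 90% of
the radius sum by default) the PAINT coordinates win; reference contours
with no PAINT counterpart become candidate zero-protein structures.  All
regions of interest share one radius, the dataset-mean PAINT contour
radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, binary_opening
from scipy.spatial import cKDTree
from skimage.filters import threshold_local
from skimage.measure import label, regionprops

from .drift import render_image
from .io import LocalizationTable

__all__ = [
    "Contour",
    "OrigamiROI",
    "detect_cy5_contours",
    "detect_paint_contours",
    "merge_contours",
    "assign_localizations",
]


@dataclass(frozen=True)
class Contour:
    """One segmented object in a common nm coordinate frame."""

    center_nm: tuple[float, float]
    radius_nm: float
    area_nm2: float
    source: str  # "CY5" | "PAINT"

    def __post_init__(self) -> None:
        if self.radius_nm <= 0:
            raise ValueError("radius_nm must be positive")
        if self.source not in ("CY5", "PAINT"):
            raise ValueError("source must be 'CY5' or 'PAINT'")


@dataclass
class OrigamiROI:
    """Circular region of interest around one origami structure."""

    id: int
    center_nm: np.ndarray      # (2,)
    radius_nm: float
    source: str                # "PAINT" | "CY5_ONLY"
    members: np.ndarray        # indices into the localization table

    def __post_init__(self) -> None:
        self.center_nm = np.asarray(self.center_nm, dtype=float)
        self.members = np.asarray(self.members, dtype=int)


def detect_cy5_contours(image: np.ndarray, pixel_size_nm: float,
                        block_px: int = 15, offset: float = 0.15,
                        min_area_px: float = 2.0, max_area_px: float = 200.0,
                        ) -> list[Contour]:
    """Segment the reference image by adaptive thresholding.

    The image is min-max normalized; pixels exceeding the local mean over
    a ``block_px`` neighbourhood by more than ``offset`` are foreground;
    specks below ``min_area_px`` are removed; connected components with
    area inside [min_area_px, max_area_px] become contours with centroid
    centre and radius sqrt(area / pi).  A uniform image yields no
    contours.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    lo, hi = img.min(), img.max()
    if hi - lo <= 0:
        return []
    norm = (img - lo) / (hi - lo)
    block = block_px if block_px % 2 == 1 else block_px + 1
    thresh = threshold_local(norm, block_size=block, method="mean",
                             offset=-offset)
    binary = norm > thresh
    # noise removal: isolated threshold speckles die under a plus-shaped opening
    binary = binary_opening(binary, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool))
    contours = []
    for region in regionprops(label(binary)):
        if not (min_area_px <= region.area <= max_area_px):
            continue
        row, col = region.centroid
        contours.append(Contour(
            center_nm=((col + 0.5) * pixel_size_nm, (row + 0.5) * pixel_size_nm),
            radius_nm=float(np.sqrt(region.area / np.pi) * pixel_size_nm),
            area_nm2=float(region.area * pixel_size_nm**2),
            source="CY5",
        ))
    return contours


def detect_paint_contours(table: LocalizationTable, oversampling_low: int = 1,
                          count_threshold: int = 5, min_area_px: float = 4.0,
                          max_area_px: float = 80.0) -> list[Contour]:
    """Segment a low-resolution rendering of the PAINT localizations.

    The count image is binarized at ``count_threshold`` localizations per
    low-resolution pixel, inflated by a one-pixel binary dilation to join
    fragmented clusters, and connected components inside the size range
    (areas in camera px^2) become contours.
    """
    if len(table) == 0:
        return []
    img = render_image(table, oversampling=oversampling_low)
    binary = img.data >= count_threshold
    binary = binary_dilation(binary, structure=np.ones((3, 3), dtype=bool))
    os = oversampling_low
    px = table.pixel_size_nm
    contours = []
    for region in regionprops(label(binary)):
        area_campx = region.area / os**2
        if not (min_area_px <= area_campx <= max_area_px):
            continue
        row, col = region.centroid
        # oversampled bin centre -> camera px -> nm
        cx = (col + 0.5) / os * px
        cy = (row + 0.5) / os * px
        contours.append(Contour(
            center_nm=(cx, cy),
            radius_nm=float(np.sqrt(area_campx / np.pi) * px),
            area_nm2=float(area_campx * px**2),
            source="PAINT",
        ))
    return contours


def merge_contours(cy5: list[Contour], paint: list[Contour],
                   overlap_factor: float = 0.9,
                   roi_radius_nm: float | None = None) -> list[OrigamiROI]:
    """Combine the two contour sets into one ROI per reference contour.

    Each reference contour is matched to at most one PAINT contour whose
    centre lies within ``overlap_factor`` x (radius sum); matching is
    globally nearest-first, so the result does not depend on input order.
    Matched ROIs take the PAINT centre (source "PAINT"); unmatched ones
    keep the reference centre (source "CY5_ONLY", candidate zero-protein
    structures).  All ROIs get the dataset-mean PAINT contour radius
    unless ``roi_radius_nm`` overrides it.
    """
    if roi_radius_nm is None:
        if paint:
            roi_radius_nm = float(np.mean([c.radius_nm for c in paint]))
        elif cy5:
            roi_radius_nm = float(np.mean([c.radius_nm for c in cy5]))
        else:
            return []
    pairs = []
    for i, c in enumerate(cy5):
        for j, p in enumerate(paint):
            d = float(np.hypot(c.center_nm[0] - p.center_nm[0],
                               c.center_nm[1] - p.center_nm[1]))
            if d < overlap_factor * (c.radius_nm + p.radius_nm):
                pairs.append((d, i, j))
    pairs.sort()
    match: dict[int, int] = {}
    used_paint: set[int] = set()
    for d, i, j in pairs:
        if i in match or j in used_paint:
            continue
        match[i] = j
        used_paint.add(j)
    entries = []
    for i, c in enumerate(cy5):
        if i in match:
            center = paint[match[i]].center_nm
            source = "PAINT"
        else:
            center = c.center_nm
            source = "CY5_ONLY"
        entries.append((center, source))
    # deterministic, input-order-independent ids
    entries.sort(key=lambda e: (round(e[0][1], 1), round(e[0][0], 1)))
    return [
        OrigamiROI(k, np.array(center), roi_radius_nm, source,
                   np.empty(0, dtype=int))
        for k, (center, source) in enumerate(entries)
    ]


def assign_localizations(table: LocalizationTable, rois: list[OrigamiROI],
                         ) -> list[OrigamiROI]:
    """Group localizations into the ROIs they fall in.

    Each localization joins the ROI with the nearest centre among those
    whose radius contains it; exact ties go to the lower ROI id;
    localizations inside no ROI stay ungrouped.
    """
    if not rois:
        return []
    xy = table.xy_nm()
    centers = np.array([r.center_nm for r in rois])
    radii = np.array([r.radius_nm for r in rois])
    members: list[list[int]] = [[] for _ in rois]
    if len(xy):
        tree = cKDTree(centers)
        k = min(2, len(rois))
        dist, idx = tree.query(xy, k=k)
        if k == 1:
            dist, idx = dist[:, None], idx[:, None]
        for loc_i in range(len(xy)):
            best = -1
            for cand in range(k):
                r = int(idx[loc_i, cand])
                if dist[loc_i, cand] <= radii[r]:
                    if best < 0:
                        best = r
                    elif (abs(dist[loc_i, cand] - dist[loc_i, 0]) < 1e-9
                          and rois[r].id < rois[best].id):
                        best = r
            if best >= 0:
                members[best].append(loc_i)
    return [replace_members(r, np.array(m, dtype=int)) for r, m in zip(rois, members)]


def replace_members(roi: OrigamiROI, members: np.ndarray) -> OrigamiROI:
    return OrigamiROI(roi.id, roi.center_nm.copy(), roi.radius_nm, roi.source,
                      members)
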