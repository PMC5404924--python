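"""Double-label classification of detected nuclei.

A detected γ-synuclein⁺ nucleus is called an RGC when the ring-shaped
region centered on the nucleus border is majority-positive for TUJ-1
(βIII-tubulin): strictly more than 50 % of the ring pixels must exceed
the Otsu threshold of the TUJ-1 channel.  Large elongated TUJ-1-bright
connected components (axon bundles) are masked out first; ring pixels
falling inside a bundle are removed from the denominator, and a cell
whose ring is majority-bundle cannot be scored at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label, regionprops
from skimage.morphology import dilation, disk, opening as binary_opening

from .detection import NucleusDetection

__all__ = [
    "DegenerateHistogramError",
    "RingRegion",
    "BundleMask",
    "CellCall",
    "otsu_threshold",
    "detect_axon_bundles",
    "make_ring_region",
    "classify_cell",
    "classify_cells",
]


class DegenerateHistogramError(ValueError):
    """Raised when a region has fewer than two distinct intensities."""


@dataclass(frozen=True)
class RingRegion:
    """Annular pixel set around one nucleus.

    The ring covers distances ``inner_radius_um <= d < inner_radius_um +
    ring_width_um`` from the (sub-pixel) center, measured in µm between
    pixel centers.
    """

    center_row_px: float
    center_col_px: float
    inner_radius_um: float
    ring_width_um: float
    rows: np.ndarray = field(repr=False)
    cols: np.ndarray = field(repr=False)

    @property
    def n_pixels(self) -> int:
        return int(self.rows.size)


@dataclass(frozen=True)
class BundleMask:
    """Binary mask of axon-bundle regions excluded from ring scoring."""

    mask: np.ndarray
    min_area_um2: float
    min_elongation: float


@dataclass(frozen=True)
class CellCall:
    """Per-detection double-label decision.

    ``ring_positive_fraction`` is NaN when the cell could not be scored
    (ring majority-covered by an axon bundle).
    """

    detection_id: int
    ring_positive_fraction: float
    n_ring_pixels_considered: int
    excluded_by_bundle: bool
    is_rgc_positive: bool


def otsu_threshold(
    channel: np.ndarray,
    region_mask: np.ndarray | None = None,
    n_bins: int = 256,
) -> float:
    """Otsu's threshold of the intensities inside ``region_mask``.

    Builds an ``n_bins`` histogram over the observed intensity range and
    returns the threshold maximizing the between-class variance, on the
    intensity scale (the upper edge of the last bin assigned to the lower
    class).  Pixels strictly above the returned value are "positive".
    Ties are broken toward the lowest threshold.

    Raises
    ------
    DegenerateHistogramError
        If the region holds fewer than two distinct values.
    """
    values = np.asarray(channel, dtype=float)
    if region_mask is not None:
        values = values[np.asarray(region_mask, dtype=bool)]
    values = values.ravel()
    if values.size == 0:
        raise DegenerateHistogramError("empty region")
    vmin = float(values.min())
    vmax = float(values.max())
    if vmin == vmax:
        raise DegenerateHistogramError(
            "degenerate histogram: region has a single intensity value"
        )
    counts, edges = np.histogram(values, bins=n_bins, range=(vmin, vmax))
    counts = counts.astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])

    w0 = np.cumsum(counts)                      # pixels in bins [0, k]
    w1 = w0[-1] - w0
    m = np.cumsum(counts * centers)
    mu0 = np.divide(m, w0, out=np.zeros_like(m), where=w0 > 0)
    mu1 = np.divide(m[-1] - m, w1, out=np.zeros_like(m), where=w1 > 0)
    # split after bin k: classes [0..k] / [k+1..]; k ranges over 0..n_bins-2
    between = (w0 * w1 * (mu0 - mu1) ** 2)[:-1]
    k = int(np.argmax(between))                 # first maximum -> lowest threshold
    return float(edges[k + 1])


def detect_axon_bundles(
    tuj1_binary: np.ndarray,
    pixel_size_um: float,
    min_area_um2: float = 500.0,
    min_elongation: float = 1.0,
    ring_width_um: float = 2.0,
    opening_radius_um: float = 2.5,
) -> BundleMask:
    """Find large contiguous TUJ-1-positive regions (axon bundles).

    The binarized TUJ-1 channel is opened with a disk of radius
    ``opening_radius_um``, which erases the thin somatic rings (a few µm
    thick) while leaving the wider axon bundles; 8-connected components
    of the opened mask are kept when their area is at least
    ``min_area_um2`` *and* their major/minor axis ratio is at least
    ``min_elongation``.  Because bundles that cross or radiate from a
    common hub merge into components whose moment-based axis ratio is
    near 1, the elongation gate is disabled by default (1.0) and the
    thin-structure suppression is done by the opening; raise it only
    for images with large compact non-bundle artifacts.  The kept mask
    is dilated by one ring width so that rings adjacent to a bundle are
    protected from partial contamination.
    """
    tuj1_binary = np.asarray(tuj1_binary, dtype=bool)
    out = np.zeros_like(tuj1_binary)
    if not tuj1_binary.any():
        return BundleMask(out, min_area_um2, min_elongation)
    if opening_radius_um > 0:
        r_open = max(1, round(opening_radius_um / pixel_size_um))
        tuj1_binary = binary_opening(tuj1_binary, disk(r_open))
        if not tuj1_binary.any():
            return BundleMask(out, min_area_um2, min_elongation)
    labels = label(tuj1_binary, connectivity=2)
    px_area = pixel_size_um**2
    for prop in regionprops(labels):
        if prop.area * px_area < min_area_um2:
            continue
        minor = prop.axis_minor_length
        elong = math.inf if minor == 0 else prop.axis_major_length / minor
        if elong < min_elongation:
            continue
        out[labels == prop.label] = True
    if out.any() and ring_width_um > 0:
        r = max(1, round(ring_width_um / pixel_size_um))
        out = dilation(out, disk(r))
    return BundleMask(out, min_area_um2, min_elongation)


def make_ring_region(
    center_row_px: float,
    center_col_px: float,
    inner_radius_um: float,
    ring_width_um: float,
    shape: tuple[int, int],
    pixel_size_um: float,
) -> RingRegion:
    """Pixel set of the annulus at the nucleus border, clipped to the image."""
    r_in = inner_radius_um / pixel_size_um
    r_out = (inner_radius_um + ring_width_um) / pixel_size_um
    r0 = max(0, int(math.floor(center_row_px - r_out - 1)))
    r1 = min(shape[0], int(math.ceil(center_row_px + r_out + 2)))
    c0 = max(0, int(math.floor(center_col_px - r_out - 1)))
    c1 = min(shape[1], int(math.ceil(center_col_px + r_out + 2)))
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(rr - center_row_px, cc - center_col_px)
    inside = (d >= r_in) & (d < r_out)
    return RingRegion(
        center_row_px=center_row_px,
        center_col_px=center_col_px,
        inner_radius_um=inner_radius_um,
        ring_width_um=ring_width_um,
        rows=rr[inside].astype(np.intp),
        cols=cc[inside].astype(np.intp),
    )


def classify_cell(
    det: NucleusDetection,
    tuj1_binary: np.ndarray,
    bundles: BundleMask,
    ring_width_um: float,
    pixel_size_um: float,
    detection_id: int = 0,
) -> CellCall:
    """Score one detection with the strict >50 % ring rule.

    Ring pixels inside the bundle mask are removed from consideration.
    When more than half of the ring lies in a bundle (or no ring pixel
    survives) the cell is flagged ``excluded_by_bundle`` and its fraction
    is undefined (NaN); an excluded cell is never positive.
    """
    if ring_width_um <= 0:
        raise ValueError("ring_width_um must be positive")
    tuj1_binary = np.asarray(tuj1_binary, dtype=bool)
    ring = make_ring_region(
        det.center_row_px,
        det.center_col_px,
        det.radius_um,
        ring_width_um,
        tuj1_binary.shape,
        pixel_size_um,
    )
    n_total = ring.n_pixels
    if n_total == 0:
        return CellCall(detection_id, float("nan"), 0, True, False)
    in_bundle = bundles.mask[ring.rows, ring.cols]
    n_bundle = int(in_bundle.sum())
    n_considered = n_total - n_bundle
    if n_bundle > 0.5 * n_total or n_considered == 0:
        return CellCall(detection_id, float("nan"), n_considered, True, False)
    positive = tuj1_binary[ring.rows, ring.cols] & ~in_bundle
    frac = float(positive.sum()) / n_considered
    return CellCall(detection_id, frac, n_considered, False, frac > 0.5)


def classify_cells(
    detections: list[NucleusDetection],
    tuj1_binary: np.ndarray,
    bundles: BundleMask,
    ring_width_um: float,
    pixel_size_um: float,
) -> list[CellCall]:
    """Classify every detection; order-independent (pure per-cell rule)."""
    return [
        classify_cell(det, tuj1_binary, bundles, ring_width_um, pixel_size_um, i)
        for i, det in enumerate(detections)
    ]
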