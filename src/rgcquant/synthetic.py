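"""Synthetic two-channel whole-mount retina images with ground truth.

No raw retina scans are available for this assay, so every pipeline
stage is validated against simulated specimens.  A synthetic retina is
a large disk of tissue with four radial incisions ("leaves", mimicking
the flattening cuts of a real whole mount) containing:

* double-positive RGCs — a bright nucleus disk in the γ-synuclein
  channel plus a TUJ-1-positive ring at the nucleus border;
* displaced amacrine cells — γ-synuclein⁺ nucleus but *no* TUJ-1 ring
  (the confounder the double-label rule exists to reject);
* elongated TUJ-1-bright stripes emulating axon bundles;
* a multiplicative illumination gradient and additive Gaussian noise
  (with an optional Poisson shot component).

Ground truth records every planted cell with exact coordinates, class
and band membership (computed with the same band operation the pipeline
uses), so detection and classification can be scored exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import (
    DEFAULT_EDGE_OFFSET_UM,
    DEFAULT_THICKNESS_UM,
    CalibratedImage,
    compute_sampling_band,
)

__all__ = [
    "PackingError",
    "SyntheticSpec",
    "GroundTruthCell",
    "generate_retina",
    "generate_pair",
    "truth_to_frame",
]

RGC = "RGC_double_positive"
AMACRINE = "amacrine_single_positive"

# Extra rendered ring half-width (px) beyond the nominal annulus, so that
# every classifier ring pixel sees full intensity despite anti-aliasing
# and sub-pixel centers.
_RING_PAD_PX = 1.0


class PackingError(RuntimeError):
    """Raised when the requested cells cannot be placed without overlap."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Scene description for one synthetic retina.

    Geometry is given in µm and rendered at ``pixel_size_um``.  The
    tissue is a disk of radius ``tissue_radius_um`` (default 92 % of the
    half image extent) with ``n_leaves`` parallel-sided radial incisions
    of width ``incision_width_um`` reaching ``incision_depth_frac`` of
    the radius inward from the rim.
    """

    image_height_px: int = 1024
    image_width_px: int = 1024
    pixel_size_um: float = 0.46
    n_leaves: int = 4
    n_rgc: int = 0
    n_amacrine: int = 0
    nucleus_radius_um: float = 4.0
    nucleus_radius_dispersion_um: float = 0.4
    soma_ring_width_um: float = 2.0
    n_bundles: int = 0
    bundle_width_um: float = 10.0
    rgc_intensity: float = 600.0
    amacrine_intensity: float = 600.0
    bundle_intensity: float = 450.0
    background_intensity: float = 100.0
    noise_sigma: float = 20.0
    poisson_gain: float = 0.0
    illumination_gradient: float = 0.2
    survival_fraction: float = 1.0
    seed: int = 0
    tissue_radius_um: float | None = None
    incision_width_um: float = 40.0
    incision_depth_frac: float = 0.6
    min_center_spacing_um: float | None = None
    boundary_smoothing_um: float = 5.0
    placement: str = "band"             # "band" | "tissue"
    band_edge_offset_um: float = DEFAULT_EDGE_OFFSET_UM
    band_thickness_um: float = DEFAULT_THICKNESS_UM

    def __post_init__(self) -> None:
        positive = {
            "pixel_size_um": self.pixel_size_um,
            "nucleus_radius_um": self.nucleus_radius_um,
            "soma_ring_width_um": self.soma_ring_width_um,
            "bundle_width_um": self.bundle_width_um,
            "incision_width_um": self.incision_width_um,
            "band_edge_offset_um": self.band_edge_offset_um,
            "band_thickness_um": self.band_thickness_um,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.image_height_px < 8 or self.image_width_px < 8:
            raise ValueError("image must be at least 8x8 px")
        if not 0.0 <= self.survival_fraction <= 1.0:
            raise ValueError("survival_fraction must be in [0, 1]")
        if not 0.0 <= self.illumination_gradient <= 1.0:
            raise ValueError("illumination_gradient must be in [0, 1]")
        if min(self.n_rgc, self.n_amacrine, self.n_bundles) < 0:
            raise ValueError("cell and bundle counts must be non-negative")
        if self.noise_sigma < 0 or self.nucleus_radius_dispersion_um < 0:
            raise ValueError("noise_sigma and dispersion must be non-negative")
        if not 0 < self.incision_depth_frac < 1:
            raise ValueError("incision_depth_frac must be in (0, 1)")
        if self.placement not in ("band", "tissue"):
            raise ValueError("placement must be 'band' or 'tissue'")
        if self.boundary_smoothing_um < 0:
            raise ValueError("boundary_smoothing_um must be non-negative")

    @property
    def tissue_radius_px(self) -> float:
        if self.tissue_radius_um is not None:
            return self.tissue_radius_um / self.pixel_size_um
        return 0.46 * min(self.image_height_px, self.image_width_px)

    @property
    def spacing_um(self) -> float:
        if self.min_center_spacing_um is not None:
            return self.min_center_spacing_um
        return 2.0 * self.nucleus_radius_um


@dataclass(frozen=True)
class GroundTruthCell:
    id: int
    center_row_px: float
    center_col_px: float
    nucleus_radius_px: float
    cell_class: str
    in_band: bool


def _tissue_mask(spec: SyntheticSpec) -> np.ndarray:
    h, w = spec.image_height_px, spec.image_width_px
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    radius = spec.tissue_radius_px
    rr, cc_grid = np.mgrid[0:h, 0:w]
    dy = rr - cr
    dx = cc_grid - cc
    mask = dy**2 + dx**2 <= radius**2

    # Parallel-sided radial slits from the rim inward; the inner end is a
    # semicircular cap of radius incision_width/2, so every concavity has
    # curvature radius >= 20 um (default) and survives morphological
    # closing unchanged.
    half_w = 0.5 * spec.incision_width_um / spec.pixel_size_um
    r_start = (1.0 - spec.incision_depth_frac) * radius
    for k in range(spec.n_leaves):
        theta = 2.0 * np.pi * k / max(spec.n_leaves, 1)
        uy, ux = np.sin(theta), np.cos(theta)
        # distance of each pixel to the segment {t*(uy,ux): t in [r_start, 2*radius]}
        t = dy * uy + dx * ux
        t_clip = np.clip(t, r_start, 2.0 * radius)
        d2 = (dy - t_clip * uy) ** 2 + (dx - t_clip * ux) ** 2
        mask &= d2 > half_w**2
    if spec.boundary_smoothing_um > 0:
        # Regularize the boundary at the same scale the pipeline's tissue
        # recovery uses; closing is idempotent, so the recovered mask can
        # match this one exactly on noiseless renders.
        from skimage.morphology import closing, disk

        r = max(1, round(spec.boundary_smoothing_um / spec.pixel_size_um))
        mask = closing(mask, disk(r))
    return mask


def _disk_coverage(dist: np.ndarray, radius_px: float) -> np.ndarray:
    """Anti-aliased disk: fractional pixel coverage at the rim."""
    return np.clip(radius_px + 0.5 - dist, 0.0, 1.0)


def _paint_disk(img: np.ndarray, row: float, col: float, radius_px: float,
                amplitude: float) -> None:
    r0 = max(0, int(np.floor(row - radius_px - 2)))
    r1 = min(img.shape[0], int(np.ceil(row + radius_px + 3)))
    c0 = max(0, int(np.floor(col - radius_px - 2)))
    c1 = min(img.shape[1], int(np.ceil(col + radius_px + 3)))
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(rr - row, cc - col)
    img[r0:r1, c0:c1] += amplitude * _disk_coverage(d, radius_px)


def _paint_ring(img: np.ndarray, row: float, col: float, r_in_px: float,
                r_out_px: float, amplitude: float) -> None:
    r0 = max(0, int(np.floor(row - r_out_px - 2)))
    r1 = min(img.shape[0], int(np.ceil(row + r_out_px + 3)))
    c0 = max(0, int(np.floor(col - r_out_px - 2)))
    c1 = min(img.shape[1], int(np.ceil(col + r_out_px + 3)))
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(rr - row, cc - col)
    cov = _disk_coverage(d, r_out_px) - _disk_coverage(d, r_in_px)
    img[r0:r1, c0:c1] += amplitude * np.clip(cov, 0.0, 1.0)


def _place_cells(spec: SyntheticSpec, tissue: np.ndarray, band_mask: np.ndarray,
                 rng: np.random.Generator) -> list[tuple[float, float, float, str]]:
    n_total = spec.n_rgc + spec.n_amacrine
    if n_total == 0:
        return []
    # Centers must keep the whole soma ring inside the tissue.
    clearance_um = (spec.nucleus_radius_um + 3 * spec.nucleus_radius_dispersion_um
                    + spec.soma_ring_width_um + 2.0)
    from scipy import ndimage as _ndi

    interior = _ndi.distance_transform_edt(tissue) * spec.pixel_size_um >= clearance_um
    if spec.placement == "band":
        interior &= band_mask
    rows, cols = np.nonzero(interior)
    if rows.size == 0:
        raise PackingError("tissue interior too small for any cell")
    spacing_px = spec.spacing_um / spec.pixel_size_um

    placed: list[tuple[float, float, float, str]] = []
    classes = [RGC] * spec.n_rgc + [AMACRINE] * spec.n_amacrine
    max_attempts = 2000 * n_total
    attempts = 0
    centers = np.empty((0, 2))
    for cls in classes:
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise PackingError(
                    f"cannot place {n_total} cells with spacing "
                    f">= {spec.spacing_um} um inside the tissue "
                    f"(placed {len(placed)}); reduce counts or spacing"
                )
            i = rng.integers(rows.size)
            row = rows[i] + rng.uniform(-0.5, 0.5)
            col = cols[i] + rng.uniform(-0.5, 0.5)
            if centers.size:
                d2 = ((centers - (row, col)) ** 2).sum(axis=1)
                if d2.min() < spacing_px**2:
                    continue
            radius_um = float(np.clip(
                rng.normal(spec.nucleus_radius_um,
                           spec.nucleus_radius_dispersion_um),
                0.5 * spec.nucleus_radius_um,
                1.5 * spec.nucleus_radius_um,
            ))
            placed.append((row, col, radius_um / spec.pixel_size_um, cls))
            centers = np.vstack([centers, (row, col)])
            break
    return placed


def _paint_bundles(tuj1: np.ndarray, spec: SyntheticSpec, tissue: np.ndarray,
                   rng: np.random.Generator) -> None:
    if spec.n_bundles == 0:
        return
    h, w = tuj1.shape
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    radius = spec.tissue_radius_px
    rr, cc_grid = np.mgrid[0:h, 0:w]
    half_w = 0.5 * spec.bundle_width_um / spec.pixel_size_um
    for _ in range(spec.n_bundles):
        # chord through the disk: random direction + offset from center
        theta = rng.uniform(0, 2 * np.pi)
        offset = rng.uniform(-0.6, 0.6) * radius
        uy, ux = np.sin(theta), np.cos(theta)
        # line: points p with ((p-c) . normal) == offset
        d_line = np.abs((rr - cr) * -ux + (cc_grid - cc) * uy - offset)
        cov = np.clip(half_w + 0.5 - d_line, 0.0, 1.0)
        tuj1 += spec.bundle_intensity * cov * tissue


def generate_retina(
    spec: SyntheticSpec,
) -> tuple[CalibratedImage, list[GroundTruthCell], np.ndarray]:
    """Render one synthetic retina.

    Returns the calibrated two-channel image, the ground-truth cell
    table and the exact tissue mask.  Deterministic for a fixed spec
    (the seed drives all randomness).  Raises :class:`PackingError` when
    the requested cells cannot be placed without center overlap.
    """
    rng = np.random.default_rng(spec.seed)
    tissue = _tissue_mask(spec)
    tissue_f = tissue.astype(float)
    band = compute_sampling_band(
        tissue, spec.pixel_size_um,
        spec.band_edge_offset_um, spec.band_thickness_um,
    )

    syn = spec.background_intensity * tissue_f
    tuj = spec.background_intensity * tissue_f

    cells = _place_cells(spec, tissue, band.mask, rng)
    ring_w_px = spec.soma_ring_width_um / spec.pixel_size_um
    for row, col, r_px, cls in cells:
        amp = (spec.rgc_intensity if cls == RGC else spec.amacrine_intensity)
        _paint_disk(syn, row, col, r_px, amp - spec.background_intensity)
        if cls == RGC:
            _paint_ring(
                tuj, row, col,
                r_px - _RING_PAD_PX,
                r_px + ring_w_px + _RING_PAD_PX,
                spec.rgc_intensity - spec.background_intensity,
            )
    _paint_bundles(tuj, spec, tissue, rng)

    if spec.illumination_gradient > 0:
        ramp = 1.0 - spec.illumination_gradient * (
            np.arange(spec.image_width_px) / max(spec.image_width_px - 1, 1)
        )
        syn *= ramp
        tuj *= ramp
    if spec.poisson_gain > 0:
        syn = rng.poisson(np.clip(syn, 0, None) * spec.poisson_gain) / spec.poisson_gain
        tuj = rng.poisson(np.clip(tuj, 0, None) * spec.poisson_gain) / spec.poisson_gain
    if spec.noise_sigma > 0:
        syn = np.clip(syn + rng.normal(0, spec.noise_sigma, syn.shape), 0, None)
        tuj = np.clip(tuj + rng.normal(0, spec.noise_sigma, tuj.shape), 0, None)

    truth = []
    for i, (row, col, r_px, cls) in enumerate(cells):
        ri, ci = int(round(row)), int(round(col))
        truth.append(GroundTruthCell(i, row, col, r_px, cls, bool(band.mask[ri, ci])))

    image = CalibratedImage(syn, tuj, spec.pixel_size_um)
    return image, truth, tissue


def generate_pair(
    spec: SyntheticSpec,
) -> tuple[
    tuple[CalibratedImage, list[GroundTruthCell], np.ndarray],
    tuple[CalibratedImage, list[GroundTruthCell], np.ndarray],
]:
    """Render a (crushed, uncrushed) specimen pair for one animal.

    The uncrushed retina carries ``n_rgc`` RGCs; the crushed retina an
    independent draw of ``round(survival_fraction * n_rgc)`` RGCs.
    Amacrine counts are identical in both (amacrine cells are not lost
    by the injury, which is what makes them a confounder).
    """
    ss = np.random.SeedSequence(spec.seed)
    seed_crushed, seed_uncrushed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)
    )
    n_crushed = round(spec.survival_fraction * spec.n_rgc)
    crushed = generate_retina(
        dataclasses.replace(spec, n_rgc=n_crushed, seed=seed_crushed)
    )
    uncrushed = generate_retina(
        dataclasses.replace(spec, seed=seed_uncrushed)
    )
    return crushed, uncrushed


def truth_to_frame(truth: list[GroundTruthCell]) -> pd.DataFrame:
    """Ground truth as a DataFrame (columns match the CSV export)."""
    return pd.DataFrame(
        [
            {
                "id": c.id,
                "row": c.center_row_px,
                "col": c.center_col_px,
                "radius_px": c.nucleus_radius_px,
                "cell_class": c.cell_class,
                "in_band": c.in_band,
            }
            for c in truth
        ],
        columns=["id", "row", "col", "radius_px", "cell_class", "in_band"],
    )
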