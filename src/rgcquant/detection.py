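"""Nucleus detection by the fast radial symmetry transform (FRST).

Bright, approximately circular γ-synuclein⁺ nuclei are localized with a
gradient-voting radial symmetry operator: every pixel with a
sufficiently strong gradient casts a vote ``r`` pixels along its
gradient direction; pixels receiving many coherent votes (centers of
bright blobs of radius ``r``) accumulate a high symmetry response.
Responses are computed per candidate radius, smoothed, and averaged.

Conventions: coordinates are 0-based ``(row, col)``; all physical
parameters are micrometres and converted to pixels once via the image
pixel size.  Votes falling outside the image are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "FRSTParams",
    "SymmetryMap",
    "NucleusDetection",
    "radial_symmetry_transform",
    "detect_nuclei",
]

# Orientation-projection saturation of the classical transform: votes at a
# pixel beyond this count do not increase the response further.
_KAPPA_SMALL = 8.0   # radius n == 1 px
_KAPPA = 9.9         # radius n > 1 px


@dataclass(frozen=True)
class FRSTParams:
    """Transform parameters.

    Parameters
    ----------
    radii_um:
        Candidate nucleus radii in µm, strictly positive, ascending.
    alpha:
        Radial-strictness exponent; larger values demand more coherent
        voting (more circular blobs).
    gradient_threshold_frac:
        Gradients below this fraction of the maximum gradient magnitude
        are ignored (noise floor).
    polarity:
        ``"bright"`` detects bright blobs (votes cast along the gradient,
        which points inward at the rim of a bright disk), ``"dark"``
        detects dark blobs, ``"both"`` responds to either.
    smoothing_sigma_um:
        Optional Gaussian pre-smoothing of the input channel.
    """

    radii_um: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0, 6.0)
    alpha: float = 2.0
    gradient_threshold_frac: float = 0.05
    polarity: str = "bright"
    smoothing_sigma_um: float = 0.0

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.radii_um)
        if len(radii) == 0:
            raise ValueError("radii_um must be nonempty")
        if any(r <= 0 for r in radii) or list(radii) != sorted(radii):
            raise ValueError("radii_um must be strictly positive and ascending")
        object.__setattr__(self, "radii_um", radii)
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0 <= self.gradient_threshold_frac < 1:
            raise ValueError("gradient_threshold_frac must be in [0, 1)")
        if self.polarity not in ("bright", "dark", "both"):
            raise ValueError("polarity must be bright, dark or both")
        if self.smoothing_sigma_um < 0:
            raise ValueError("smoothing_sigma_um must be non-negative")


@dataclass(frozen=True)
class SymmetryMap:
    """Aggregate radial-symmetry response plus the best radius per pixel."""

    values: np.ndarray = field(repr=False)
    per_radius_argmax: np.ndarray = field(repr=False)
    pixel_size_um: float = 1.0


@dataclass(frozen=True)
class NucleusDetection:
    """One candidate nucleus: sub-pixel-free center, radius and score."""

    center_row_px: float
    center_col_px: float
    radius_um: float
    symmetry_score: float


def _vote(
    accum_o: np.ndarray,
    accum_m: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    mags: np.ndarray,
    sign: float,
) -> None:
    shape = accum_o.shape
    ok = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
    np.add.at(accum_o, (rows[ok], cols[ok]), sign)
    np.add.at(accum_m, (rows[ok], cols[ok]), sign * mags[ok])


def radial_symmetry_transform(
    channel: np.ndarray,
    params: FRSTParams,
    pixel_size_um: float,
) -> SymmetryMap:
    """Compute the multi-radius radial symmetry response of one channel.

    For each radius the orientation projection (vote counts) and
    magnitude projection (summed gradient magnitudes) are accumulated at
    the affected pixels, saturated at the classical κ, normalized, and
    combined as ``(O/κ)**alpha * M/(κ·mean|g|)``; the per-radius response
    is smoothed with a Gaussian of σ = radius/4 and the aggregate map is
    the mean over radii.  Normalizing the magnitude projection by the
    mean above-threshold gradient magnitude makes the response invariant
    to linear intensity scaling.

    A constant image yields an all-zero map (no gradients), not an error.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    img = np.asarray(channel, dtype=float)
    if not np.isfinite(img).all():
        raise ValueError("channel must be finite")
    if params.smoothing_sigma_um > 0:
        img = ndimage.gaussian_filter(
            img, params.smoothing_sigma_um / pixel_size_um, mode="nearest"
        )

    gy, gx = np.gradient(img)
    mag = np.hypot(gy, gx)
    gmax = float(mag.max())
    radii_px = [max(1, int(round(r / pixel_size_um))) for r in params.radii_um]
    zero = np.zeros_like(img)
    if gmax == 0.0:
        return SymmetryMap(zero, np.full(img.shape, params.radii_um[0]), pixel_size_um)

    sel = mag > params.gradient_threshold_frac * gmax
    rows, cols = np.nonzero(sel)
    mags = mag[rows, cols]
    mean_mag = float(mags.mean())
    uy = gy[rows, cols] / mags
    ux = gx[rows, cols] / mags

    stack = np.empty((len(radii_px),) + img.shape)
    for i, n in enumerate(radii_px):
        o_proj = np.zeros_like(img)
        m_proj = np.zeros_like(img)
        pr = rows + np.round(n * uy).astype(np.intp)
        pc = cols + np.round(n * ux).astype(np.intp)
        nr = rows - np.round(n * uy).astype(np.intp)
        nc = cols - np.round(n * ux).astype(np.intp)
        if params.polarity == "bright":
            _vote(o_proj, m_proj, pr, pc, mags, 1.0)
        elif params.polarity == "dark":
            _vote(o_proj, m_proj, nr, nc, mags, 1.0)
        else:
            _vote(o_proj, m_proj, pr, pc, mags, 1.0)
            _vote(o_proj, m_proj, nr, nc, mags, -1.0)
        kappa = _KAPPA_SMALL if n == 1 else _KAPPA
        o_clip = np.clip(np.abs(o_proj), None, kappa)
        f = (o_clip / kappa) ** params.alpha * (np.abs(m_proj) / (kappa * mean_mag))
        stack[i] = ndimage.gaussian_filter(f, sigma=0.25 * n, mode="constant")

    values = stack.mean(axis=0)
    best = np.asarray(params.radii_um)[np.argmax(stack, axis=0)]
    return SymmetryMap(values, best, pixel_size_um)


def detect_nuclei(
    sym: SymmetryMap,
    band,
    min_separation_um: float,
    score_threshold: float,
) -> list[NucleusDetection]:
    """Pick nuclei as band-restricted local maxima of the symmetry map.

    Local maxima (8-neighborhood, plateaus allowed) inside the sampling
    band with score >= ``score_threshold`` are accepted greedily in
    descending score order, subject to pairwise center separation of at
    least ``min_separation_um``; ties are broken by (row, col) order.
    An empty list is a valid result.
    """
    values = sym.values
    band_mask = np.asarray(band.mask, dtype=bool)
    if band_mask.shape != values.shape:
        raise ValueError("symmetry map and band shapes differ")
    local_max = values == ndimage.maximum_filter(values, size=3, mode="nearest")
    cand = local_max & band_mask & (values >= score_threshold)
    rows, cols = np.nonzero(cand)
    if rows.size == 0:
        return []
    scores = values[rows, cols]
    order = np.lexsort((cols, rows, -scores))
    rows, cols, scores = rows[order], cols[order], scores[order]

    min_sep_px = min_separation_um / sym.pixel_size_um
    kept_r: list[int] = []
    kept_c: list[int] = []
    detections: list[NucleusDetection] = []
    for r, c, s in zip(rows, cols, scores):
        if kept_r:
            d2 = (np.array(kept_r) - r) ** 2 + (np.array(kept_c) - c) ** 2
            if d2.min() < min_sep_px**2:
                continue
        kept_r.append(int(r))
        kept_c.append(int(c))
        detections.append(
            NucleusDetection(
                center_row_px=float(r),
                center_col_px=float(c),
                radius_um=float(sym.per_radius_argmax[r, c]),
                symmetry_score=float(s),
            )
        )
    return detections
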