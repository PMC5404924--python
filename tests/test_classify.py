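"""Otsu thresholding, bundle masking and the strict >50 % ring rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rgcquant as rq
from rgcquant.classify import (
    BundleMask,
    DegenerateHistogramError,
    classify_cell,
    classify_cells,
    detect_axon_bundles,
    make_ring_region,
    otsu_threshold,
)
from rgcquant.detection import NucleusDetection

from _oracles import otsu_bruteforce


# --- Otsu -----------------------------------------------------------------

def test_otsu_separates_two_delta_histogram():
    values = np.concatenate([np.full(500, 10.0), np.full(500, 200.0)])
    thr = otsu_threshold(values.reshape(20, 50))
    assert 10.0 < thr < 200.0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    n=st.integers(16, 400),
    n_bins=st.sampled_from([16, 64, 256]),
)
def test_otsu_equals_exhaustive_sweep(seed, n, n_bins):
    rng = np.random.default_rng(seed)
    kind = seed % 3
    if kind == 0:
        values = rng.normal(100, 20, n)
    elif kind == 1:
        values = np.concatenate([rng.normal(50, 5, n), rng.normal(150, 10, n)])
    else:
        values = rng.exponential(30, n)
    if values.min() == values.max():
        return
    assert otsu_threshold(values, None, n_bins) == pytest.approx(
        otsu_bruteforce(values, n_bins)
    )


def test_otsu_binarization_affine_equivariant():
    rng = np.random.default_rng(3)
    values = np.concatenate([rng.normal(40, 6, 300), rng.normal(120, 9, 200)])
    mask1 = values > otsu_threshold(values)
    mapped = 3.5 * values + 11.0
    mask2 = mapped > otsu_threshold(mapped)
    assert np.array_equal(mask1, mask2)


def test_otsu_agrees_with_skimage_within_one_bin():
    from skimage.filters import threshold_otsu

    rng = np.random.default_rng(5)
    values = np.concatenate([rng.normal(50, 5, 4000), rng.normal(150, 10, 2000)])
    ours = otsu_threshold(values)
    ref = threshold_otsu(values, nbins=256)
    bin_width = (values.max() - values.min()) / 256
    assert abs(ours - ref) <= bin_width


def test_otsu_constant_region_raises():
    with pytest.raises(DegenerateHistogramError):
        otsu_threshold(np.full((10, 10), 3.0))


def test_otsu_respects_region_mask():
    img = np.zeros((20, 20))
    img[:10] = 100.0
    region = np.zeros((20, 20), dtype=bool)
    region[:10] = True
    with pytest.raises(DegenerateHistogramError):
        otsu_threshold(img, region)           # constant inside the region


# --- bundle detection -----------------------------------------------------

def _stripe_and_rings():
    """10 µm x 400 µm stripe plus small isolated rings, at 1 µm/px."""
    field = np.zeros((512, 512), dtype=bool)
    field[250:260, 50:450] = True
    for cy, cx in [(100, 100), (100, 400), (400, 120), (420, 390)]:
        rr, cc = np.mgrid[cy - 8:cy + 9, cx - 8:cx + 9]
        d = np.hypot(rr - cy, cc - cx)
        field[cy - 8:cy + 9, cx - 8:cx + 9] |= (d >= 4) & (d < 7)
    return field


def test_bundle_mask_keeps_stripe_drops_rings():
    field = _stripe_and_rings()
    bundles = detect_axon_bundles(field, 1.0, min_area_um2=500.0,
                                  min_elongation=4.0)
    assert bundles.mask[252:258, 100:400].all()
    assert not bundles.mask[80:120, 80:120].any()      # ring region untouched


def test_bundle_mask_empty_input():
    empty = np.zeros((64, 64), dtype=bool)
    assert not detect_axon_bundles(empty, 1.0).mask.any()


def test_bundle_min_area_dominates():
    field = _stripe_and_rings()
    bundles = detect_axon_bundles(field, 1.0, min_area_um2=1e12)
    assert not bundles.mask.any()


def test_crossing_bundles_still_masked():
    """Two crossing stripes merge into one low-elongation component."""
    field = np.zeros((512, 512), dtype=bool)
    field[250:260, 50:450] = True
    field[50:450, 250:260] = True
    bundles = detect_axon_bundles(field, 1.0)
    assert bundles.mask[252:258, 100:400].all()
    assert bundles.mask[100:400, 252:258].all()


# --- ring classification --------------------------------------------------

def _ring_setup(ring_positive_count, shape=(120, 120), pixel_size=0.5):
    """Binary TUJ-1 field with exactly k positive pixels in the test ring."""
    det = NucleusDetection(60.0, 60.0, 5.0, 1.0)
    ring = make_ring_region(60.0, 60.0, 5.0, 2.0, shape, pixel_size)
    binary = np.zeros(shape, dtype=bool)
    binary[ring.rows[:ring_positive_count], ring.cols[:ring_positive_count]] = True
    return det, ring, binary


def test_exactly_half_positive_ring_is_negative():
    det, ring, binary = _ring_setup(0)
    assert ring.n_pixels % 2 == 0
    binary[ring.rows[: ring.n_pixels // 2],
           ring.cols[: ring.n_pixels // 2]] = True
    empty = BundleMask(np.zeros_like(binary), 500.0, 1.0)
    call = classify_cell(det, binary, empty, 2.0, 0.5)
    assert call.ring_positive_fraction == 0.5
    assert not call.is_rgc_positive


def test_fully_positive_ring_is_positive():
    det, ring, binary = _ring_setup(0)
    binary[ring.rows, ring.cols] = True
    empty = BundleMask(np.zeros_like(binary), 500.0, 1.0)
    call = classify_cell(det, binary, empty, 2.0, 0.5)
    assert call.ring_positive_fraction == 1.0
    assert call.is_rgc_positive


def test_empty_ring_is_negative():
    det, _, binary = _ring_setup(0)
    empty = BundleMask(np.zeros_like(binary), 500.0, 1.0)
    call = classify_cell(det, binary, empty, 2.0, 0.5)
    assert call.ring_positive_fraction == 0.0
    assert not call.is_rgc_positive


def test_ring_fully_inside_bundle_is_excluded():
    det, _, binary = _ring_setup(0)
    binary[:] = True
    bundles = BundleMask(np.ones_like(binary), 500.0, 1.0)
    call = classify_cell(det, binary, bundles, 2.0, 0.5)
    assert call.excluded_by_bundle
    assert not call.is_rgc_positive
    assert np.isnan(call.ring_positive_fraction)


def test_partial_bundle_overlap_removes_pixels_from_denominator():
    det, ring, binary = _ring_setup(0)
    binary[ring.rows, ring.cols] = True       # fully positive ring
    bundle_mask = np.zeros_like(binary)
    k = ring.n_pixels // 4                    # cover a quarter of the ring
    bundle_mask[ring.rows[:k], ring.cols[:k]] = True
    call = classify_cell(det, binary, BundleMask(bundle_mask, 500.0, 1.0),
                         2.0, 0.5)
    assert not call.excluded_by_bundle
    assert call.n_ring_pixels_considered == ring.n_pixels - k
    assert call.ring_positive_fraction == 1.0


def test_classification_is_order_independent():
    rng = np.random.default_rng(0)
    binary = rng.random((200, 200)) > 0.5
    dets = [NucleusDetection(40.0 + 30 * i, 60.0 + 20 * i, 4.0, 1.0)
            for i in range(4)]
    empty = BundleMask(np.zeros_like(binary), 500.0, 1.0)
    calls = classify_cells(dets, binary, empty, 2.0, 1.0)
    calls_rev = classify_cells(dets[::-1], binary, empty, 2.0, 1.0)
    for c, cr in zip(calls, calls_rev[::-1]):
        assert c.ring_positive_fraction == cr.ring_positive_fraction
        assert c.is_rgc_positive == cr.is_rgc_positive


def test_ring_region_matches_distance_definition():
    ring = make_ring_region(50.0, 50.0, 4.0, 2.0, (100, 100), 1.0)
    d = np.hypot(ring.rows - 50.0, ring.cols - 50.0)
    assert np.all((d >= 4.0) & (d < 6.0))
    assert ring.n_pixels > 0
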