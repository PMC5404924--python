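"""Counting, normalization, t-test and Grubbs outlier screening."""

import numpy as np
import pandas as pd
import pytest

from rgcquant.classify import CellCall
from rgcquant.regions import SamplingBand
from rgcquant.survival import (
    GroupComparison,
    RetinaCount,
    compare_groups,
    grubbs_test,
    normalize_survival,
    score_table_stats,
    summarize_retina,
)


def _calls(n_positive, n_total, n_excluded=0):
    calls = []
    for i in range(n_total):
        excluded = i >= n_total - n_excluded
        positive = (i < n_positive) and not excluded
        calls.append(CellCall(i, 1.0 if positive else 0.0, 50, excluded,
                              positive))
    return calls


def _band(area_px=10_000):
    mask = np.zeros((200, 200), dtype=bool)
    mask.flat[:area_px] = True
    return SamplingBand(mask)


def test_summarize_counts_positive_calls():
    count = summarize_retina(_calls(7, 10), _band(), 1.0, "m1", "crushed")
    assert count.n_double_positive == 7
    assert count.n_detected == 10
    assert count.density_per_mm2 == pytest.approx(7 / (10_000 * 1e-6))


def test_summarize_empty_calls():
    count = summarize_retina([], _band(), 1.0, "m1", "uncrushed")
    assert count.n_double_positive == 0
    assert count.n_detected == 0
    assert count.band_area_um2 > 0


def test_excluded_cells_in_detected_but_never_positive():
    count = summarize_retina(_calls(5, 10, n_excluded=4), _band(), 1.0,
                             "m1", "crushed")
    assert count.n_detected == 10
    assert count.n_double_positive == 5


def test_bundle_mask_shrinks_scoreable_area():
    band = _band(10_000)
    bundle = np.zeros((200, 200), dtype=bool)
    bundle.flat[:2_000] = True
    count = summarize_retina(_calls(3, 5), band, 1.0, "m1", "crushed",
                             bundle_mask=bundle)
    assert count.band_area_um2 == pytest.approx(8_000.0)


def _count(n_pos, area=10_000.0, condition="crushed"):
    return RetinaCount("m1", condition, n_pos, n_pos, area)


def test_normalization_ratio():
    res = normalize_survival(_count(42), _count(100, condition="uncrushed"))
    assert res.survival_percent == pytest.approx(42.0)


def test_normalization_identity():
    res = normalize_survival(_count(77), _count(77, condition="uncrushed"))
    assert res.survival_percent == pytest.approx(100.0)


def test_normalization_scale_free():
    base = normalize_survival(_count(40), _count(80, condition="uncrushed"))
    scaled = normalize_survival(_count(120), _count(240, condition="uncrushed"))
    assert base.survival_percent == pytest.approx(scaled.survival_percent)


def test_normalization_undefined_for_zero_uncrushed():
    with pytest.raises(ZeroDivisionError):
        normalize_survival(_count(10), _count(0, condition="uncrushed"))


def test_auto_normalization_switches_to_density():
    crushed = _count(50, area=5_000.0)
    uncrushed = _count(100, area=10_000.0, condition="uncrushed")
    auto = normalize_survival(crushed, uncrushed, method="auto")
    density = normalize_survival(crushed, uncrushed, method="density")
    count_based = normalize_survival(crushed, uncrushed, method="count")
    assert auto.survival_percent == pytest.approx(density.survival_percent)
    assert density.survival_percent == pytest.approx(100.0)
    assert count_based.survival_percent == pytest.approx(50.0)


def test_survival_may_exceed_100_percent():
    res = normalize_survival(_count(110), _count(100, condition="uncrushed"))
    assert res.survival_percent == pytest.approx(110.0)


# --- group comparison -----------------------------------------------------

def test_pooled_t_matches_hand_computation():
    res = compare_groups([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
    assert res.t_statistic == pytest.approx(-12.24744871391589)
    assert res.degrees_of_freedom == 4
    assert res.p_value == pytest.approx(2.552167494419268e-4)
    assert res.sem_a == pytest.approx(1.0 / np.sqrt(3))


def test_identical_groups_give_p_one():
    res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.t_statistic == 0.0
    assert res.p_value == pytest.approx(1.0)


def test_group_swap_flips_t_keeps_p():
    a, b = [1.0, 3.0, 5.0, 6.0], [2.0, 4.0, 9.0]
    r1 = compare_groups(a, b)
    r2 = compare_groups(b, a)
    assert r1.t_statistic == pytest.approx(-r2.t_statistic)
    assert r1.p_value == pytest.approx(r2.p_value)


def test_constant_groups_equal_means_p_one():
    res = compare_groups([5.0, 5.0], [5.0, 5.0, 5.0])
    assert res.p_value == 1.0


def test_constant_groups_unequal_means_error():
    with pytest.raises(ZeroDivisionError):
        compare_groups([0.0, 0.0, 0.0], [5.0, 5.0, 5.0])


def test_too_small_groups_rejected():
    with pytest.raises(ValueError):
        compare_groups([1.0], [2.0, 3.0])


# --- Grubbs ---------------------------------------------------------------

def test_grubbs_flags_gross_outlier():
    assert grubbs_test([1.0, 1.0, 1.0, 1.0, 100.0], 0.05) == 4


def test_grubbs_clears_uniform_spread():
    assert grubbs_test([1.0, 2.0, 3.0, 4.0, 5.0], 0.05) is None


def test_grubbs_constant_list_errors():
    with pytest.raises(ZeroDivisionError):
        grubbs_test([2.0, 2.0, 2.0])


def test_grubbs_needs_three_values():
    with pytest.raises(ValueError):
        grubbs_test([1.0, 2.0])


# --- ordinal degeneration scores -----------------------------------------

def _score_frame(a, b):
    return pd.DataFrame({
        "score": list(a) + list(b),
        "group": ["wt"] * len(a) + ["cko"] * len(b),
    })


def test_score_stats_match_hand_computation():
    res = score_table_stats(_score_frame([2, 3, 3], [4, 4, 5]))
    assert isinstance(res, GroupComparison)
    assert res.t_statistic == pytest.approx(-3.5355339059327373)
    assert res.p_value == pytest.approx(0.024110110551390906)


def test_extreme_score_separation_is_significant():
    res = score_table_stats(_score_frame([0, 0, 0, 1], [5, 5, 5, 4]))
    assert res.p_value < 1e-4


def test_identical_score_distributions_give_p_one():
    res = score_table_stats(_score_frame([2, 3, 3], [2, 3, 3]))
    assert res.p_value == pytest.approx(1.0)


def test_out_of_range_scores_rejected():
    with pytest.raises(ValueError):
        score_table_stats(_score_frame([2, 3, 6], [4, 4, 5]))
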