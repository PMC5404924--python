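"""Survival quantification and group statistics.

Per-retina double-positive counts are normalized crushed / uncrushed
within each animal to a survival percentage; groups are compared with a
two-tailed pooled-variance Student t-test, and single outliers may be
flagged with Grubbs' test (α = 0.05), matching the original analysis
protocol.  An imported table of ordinal 0–5 degeneration scores (the
blinded manual assessment) is run through the same comparison
machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import CellCall
from .regions import SamplingBand

__all__ = [
    "RetinaCount",
    "SurvivalResult",
    "GroupComparison",
    "summarize_retina",
    "normalize_survival",
    "compare_groups",
    "grubbs_test",
    "score_table_stats",
]


@dataclass(frozen=True)
class RetinaCount:
    specimen_id: str
    condition: str                      # "crushed" | "uncrushed"
    n_double_positive: int
    n_detected: int
    band_area_um2: float

    def __post_init__(self) -> None:
        if self.condition not in ("crushed", "uncrushed"):
            raise ValueError("condition must be 'crushed' or 'uncrushed'")
        if not 0 <= self.n_double_positive <= self.n_detected:
            raise ValueError("need 0 <= n_double_positive <= n_detected")
        if self.band_area_um2 <= 0:
            raise ValueError("band_area_um2 must be positive")

    @property
    def density_per_mm2(self) -> float:
        return self.n_double_positive / (self.band_area_um2 * 1e-6)


@dataclass(frozen=True)
class SurvivalResult:
    animal_id: str
    survival_percent: float
    group: str = ""


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float


def summarize_retina(
    calls: list[CellCall],
    band: SamplingBand,
    pixel_size_um: float,
    specimen_id: str,
    condition: str,
    bundle_mask: np.ndarray | None = None,
) -> RetinaCount:
    """Count double-positive calls for one retina.

    Cells excluded by the axon-bundle mask appear in ``n_detected`` but
    can never contribute to ``n_double_positive``.  When ``bundle_mask``
    is given, the reported band area is the *scoreable* area (band minus
    bundle pixels): cells under a bundle cannot be scored, so densities
    over the scoreable area are unbiased by bundle coverage, whereas raw
    counts drop with it.
    """
    area_px = band.area_px
    if bundle_mask is not None:
        area_px = int((band.mask & ~np.asarray(bundle_mask, dtype=bool)).sum())
    return RetinaCount(
        specimen_id=specimen_id,
        condition=condition,
        n_double_positive=sum(c.is_rgc_positive for c in calls),
        n_detected=len(calls),
        band_area_um2=area_px * pixel_size_um**2,
    )


def normalize_survival(
    crushed: RetinaCount,
    uncrushed: RetinaCount,
    animal_id: str | None = None,
    method: str = "auto",
) -> SurvivalResult:
    """Survival of one animal: crushed count as % of its uncrushed retina.

    ``method``: ``"count"`` uses raw double-positive counts, ``"density"``
    divides each count by its band area first, ``"auto"`` (default)
    switches to density when the two band areas differ by more than 10 %.
    Values above 100 % are possible and preserved.
    """
    if method not in ("auto", "count", "density"):
        raise ValueError("method must be auto, count or density")
    if uncrushed.n_double_positive == 0:
        raise ZeroDivisionError(
            "undefined normalization: uncrushed retina has zero "
            "double-positive cells"
        )
    if method == "auto":
        rel = abs(crushed.band_area_um2 - uncrushed.band_area_um2)
        method = "density" if rel > 0.10 * uncrushed.band_area_um2 else "count"
    if method == "count":
        pct = 100.0 * crushed.n_double_positive / uncrushed.n_double_positive
    else:
        pct = 100.0 * crushed.density_per_mm2 / uncrushed.density_per_mm2
    return SurvivalResult(
        animal_id=animal_id or crushed.specimen_id,
        survival_percent=pct,
    )


def compare_groups(
    a: list[float] | np.ndarray,
    b: list[float] | np.ndarray,
    group_a: str = "a",
    group_b: str = "b",
) -> GroupComparison:
    """Two-tailed pooled-variance (Student) t-test between two groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups must be finite")
    df = a.size + b.size - 2
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            t_stat, p = 0.0, 1.0
        else:
            raise ZeroDivisionError(
                "zero pooled variance with unequal means: t undefined"
            )
    else:
        res = stats.ttest_ind(a, b, equal_var=True)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=float(stats.sem(a)),
        sem_b=float(stats.sem(b)),
        t_statistic=t_stat,
        degrees_of_freedom=float(df),
        p_value=p,
    )


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value G_crit(n, alpha)."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))


def grubbs_test(values: list[float] | np.ndarray, alpha: float = 0.05) -> int | None:
    """Flag at most one outlier with the two-sided Grubbs test.

    Returns the index of the most extreme value if its studentized
    deviation G = max|x - mean| / sd exceeds the critical value at the
    given significance, else None.  Applied once: iterative removal is a
    caller decision, not the default.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs' test needs at least 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError("Grubbs' test undefined for constant values")
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = dev[idx] / sd
    if g > grubbs_critical_value(x.size, alpha):
        return idx
    return None


def score_table_stats(
    scores: pd.DataFrame,
    score_col: str = "score",
    group_col: str = "group",
) -> GroupComparison:
    """Compare two groups of ordinal 0–5 degeneration scores.

    The blinded axon-degeneration score is imported data (the scoring
    itself is manual); it is compared with the same pooled t-test used
    for survival percentages.
    """
    vals = scores[score_col].to_numpy()
    if not np.isin(vals, np.arange(6)).all():
        raise ValueError("scores must be integers in 0..5")
    groups = scores[group_col].unique()
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(groups)}")
    a = scores.loc[scores[group_col] == groups[0], score_col].to_numpy(float)
    b = scores.loc[scores[group_col] == groups[1], score_col].to_numpy(float)
    return compare_groups(a, b, str(groups[0]), str(groups[1]))
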