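"""Per-field metrics, robust per-chamber aggregation and study statistics.

Metrics follow the reporting conventions of the assay: pathology area and
fragment count are normalised to 0.25 mm² of analysed ROI, and pathology is
alternatively expressed as a percentage of the neurite (βIII-tubulin) area.
Per chamber and device, the median of the (typically 10) field values is
taken after iterative two-sided Grubbs outlier removal.  Time trends are
ordinary least-squares regressions reported with F(1, n−2), p and R²; group
comparisons use the Mann-Whitney U test; propagation efficiency is the
ratio of unseeded- to seeded-chamber pathology.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .geometry import DeviceGeometry
from .segment import Fragment

__all__ = [
    "FieldMetrics",
    "ChamberSummary",
    "TrendFit",
    "GroupComparison",
    "summarize_field",
    "grubbs_outliers",
    "grubbs_critical_value",
    "aggregate_chamber",
    "mean_difference",
    "mann_whitney_u",
    "linear_trend",
    "propagation_ratio",
]

METRIC_NAMES = ("area_per_qmm2", "frags_per_qmm2", "pct_neurite")


@dataclass
class FieldMetrics:
    """Metrics of a single imaged field, normalised to 0.25 mm² of ROI."""

    image_id: str
    roi_area_mm2: float
    area_per_qmm2: float
    frags_per_qmm2: float
    pct_neurite: float  # NaN when the neurite area is zero
    neurite_area_um2: float
    n_fragments: int


@dataclass
class ChamberSummary:
    """Grubbs-filtered per-metric medians for one chamber of one device."""

    device_id: str
    chamber: str
    n_fields: int
    medians: dict[str, float]
    n_used: dict[str, int]
    excluded: dict[str, list[str]]  # metric -> excluded image_ids


@dataclass
class TrendFit:
    slope: float
    intercept: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    r_squared: float


@dataclass
class GroupComparison:
    mean_a: float
    mean_b: float
    mean_difference: float
    u_stat: float
    p_value: float


def summarize_field(
    fragments: list[Fragment],
    roi_mask: np.ndarray,
    neurite_mask: np.ndarray,
    geometry: DeviceGeometry,
    *,
    pixel_size: float | None = None,
    image_id: str = "",
) -> FieldMetrics:
    """Normalised pathology metrics for one field.

    Fragments whose centroid pixel lies inside ``roi_mask`` contribute; area
    and count are scaled by ``0.25 / ROI_area_mm2``.  The percent-of-neurite
    metric relates raw in-ROI fragment area to the neurite mask area within
    the ROI and is NaN (flagged, not an error) when that area is zero.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("empty ROI")
    px = geometry.pixel_size if pixel_size is None else float(pixel_size)
    roi_area_mm2 = roi_mask.sum() * px**2 / 1e6

    raw_area = 0.0
    count = 0
    for frag in fragments:
        r = min(max(int(round(frag.centroid_px[0])), 0), roi_mask.shape[0] - 1)
        c = min(max(int(round(frag.centroid_px[1])), 0), roi_mask.shape[1] - 1)
        if roi_mask[r, c]:
            raw_area += frag.area_um2
            count += 1

    scale = 0.25 / roi_area_mm2
    neurite_area_um2 = float((np.asarray(neurite_mask, bool) & roi_mask).sum()) * px**2
    pct = 100.0 * raw_area / neurite_area_um2 if neurite_area_um2 > 0 else float("nan")
    return FieldMetrics(
        image_id=image_id,
        roi_area_mm2=roi_area_mm2,
        area_per_qmm2=raw_area * scale,
        frags_per_qmm2=count * scale,
        pct_neurite=pct,
        neurite_area_um2=neurite_area_um2,
        n_fragments=count,
    )


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value G_crit for sample size ``n``.

    Built from the Student-t quantile at ``alpha / (2n)`` with n−2 degrees
    of freedom:  G = (n−1)/√n · √(t² / (n−2+t²)).
    """
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))


def grubbs_outliers(
    values,
    alpha: float = 0.05,
    *,
    iterative: bool = True,
    min_keep: int = 7,
) -> list[int]:
    """Indices of values excluded by the (iterative) two-sided Grubbs test.

    Each pass computes G = max|xᵢ − x̄|/s and removes the most extreme value
    if G exceeds the critical value; passes repeat on the reduced sample
    until nothing is flagged, the sample would shrink below ``min_keep``
    (for 10-field chambers this caps removals), or ``iterative`` is False.
    Zero-variance samples contain no outliers.
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1 or len(vals) < 3:
        raise ValueError("Grubbs test needs at least 3 values")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    active = list(range(len(vals)))
    excluded: list[int] = []
    while len(active) >= max(3, min_keep):
        x = vals[active]
        s = x.std(ddof=1)
        if s == 0 or not np.isfinite(s):
            break
        dev = np.abs(x - x.mean())
        k = int(np.argmax(dev))
        g = dev[k] / s
        if g > grubbs_critical_value(len(active), alpha):
            excluded.append(active.pop(k))
        else:
            break
        if not iterative:
            break
    return sorted(excluded)


def aggregate_chamber(
    fields: list[FieldMetrics],
    alpha: float = 0.05,
    *,
    device_id: str = "",
    chamber: str = "",
    iterative: bool = True,
    min_keep: int = 7,
) -> ChamberSummary:
    """Per-metric Grubbs-filtered median over the fields of one chamber.

    Outlier sets are determined independently per metric, so a field that is
    extreme in area but not in count still contributes to the count median.
    """
    if len(fields) < 3:
        raise ValueError("need at least 3 fields per chamber")
    medians: dict[str, float] = {}
    n_used: dict[str, int] = {}
    excluded: dict[str, list[str]] = {}
    for metric in METRIC_NAMES:
        pairs = [
            (f.image_id, getattr(f, metric))
            for f in fields
            if np.isfinite(getattr(f, metric))
        ]
        if len(pairs) < 3:
            medians[metric] = float("nan")
            n_used[metric] = len(pairs)
            excluded[metric] = []
            continue
        vals = [v for _, v in pairs]
        out = grubbs_outliers(vals, alpha, iterative=iterative, min_keep=min_keep)
        keep = [v for i, v in enumerate(vals) if i not in out]
        medians[metric] = float(np.median(keep))
        n_used[metric] = len(keep)
        excluded[metric] = [pairs[i][0] for i in out]
    return ChamberSummary(
        device_id=device_id,
        chamber=chamber,
        n_fields=len(fields),
        medians=medians,
        n_used=n_used,
        excluded=excluded,
    )


def mean_difference(group_a, group_b) -> float:
    """mean(A) − mean(B); errors on an empty group."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("groups must be non-empty")
    return float(a.mean() - b.mean())


def mann_whitney_u(group_a, group_b) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two unpaired samples.

    The p-value is exact (full enumeration of the U distribution) for small
    untied samples (n₁+n₂ <= 16), otherwise a normal approximation with tie
    and continuity correction.  Identical constant samples return p = 1
    with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn(
            "all values identical across both groups; p = 1",
            RuntimeWarning,
            stacklevel=2,
        )
        return GroupComparison(
            mean_a=float(a.mean()),
            mean_b=float(b.mean()),
            mean_difference=0.0,
            u_stat=a.size * b.size / 2.0,
            p_value=1.0,
        )
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (a.size + b.size <= 16 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return GroupComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        mean_difference=float(a.mean() - b.mean()),
        u_stat=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
    )


def linear_trend(t_weeks, y) -> TrendFit:
    """OLS fit of y on time with F(1, n−2) inference.

    F = (R²/(1−R²))·(n−2); p comes from the F distribution.  Degenerate
    time vectors (all equal) are rejected.
    """
    t = np.asarray(t_weeks, dtype=float)
    yv = np.asarray(y, dtype=float)
    if t.size != yv.size or t.size < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(t) == 0:
        raise ValueError("time values must not all be equal")
    n = t.size
    if np.ptp(yv) == 0:  # constant response: zero slope, no explained variance
        return TrendFit(
            slope=0.0, intercept=float(yv[0]), f_stat=0.0,
            df=(1, n - 2), p_value=1.0, r_squared=0.0,
        )
    fit = stats.linregress(t, yv)
    r2 = fit.rvalue**2
    if r2 >= 1.0:
        f_stat = float("inf")
        p = 0.0
    else:
        f_stat = (r2 / (1.0 - r2)) * (n - 2)
        p = float(stats.f.sf(f_stat, 1, n - 2))
    return TrendFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        f_stat=float(f_stat),
        df=(1, n - 2),
        p_value=p,
        r_squared=float(r2),
    )


def slope_confidence_interval(t_weeks, y, level: float = 0.95) -> tuple[float, float]:
    """Two-sided confidence interval for the OLS slope."""
    t = np.asarray(t_weeks, dtype=float)
    yv = np.asarray(y, dtype=float)
    fit = stats.linregress(t, yv)
    tq = stats.t.ppf(0.5 + level / 2, t.size - 2)
    return (fit.slope - tq * fit.stderr, fit.slope + tq * fit.stderr)


def propagation_ratio(unseeded, seeded, metric: str = "area_per_qmm2") -> float:
    """Unseeded-side pathology divided by seeded-side pathology.

    Accepts :class:`ChamberSummary` objects or bare numbers.  A device whose
    seeded-side level is zero has no defined ratio: NaN is returned with a
    warning so the device can be excluded from ratio statistics rather than
    silently dropped.
    """
    u = unseeded.medians[metric] if isinstance(unseeded, ChamberSummary) else float(unseeded)
    s = seeded.medians[metric] if isinstance(seeded, ChamberSummary) else float(seeded)
    if s <= 0:
        warnings.warn(
            "seeded-chamber metric is zero: propagation ratio undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return u / s
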