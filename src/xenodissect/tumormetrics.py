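"""Tumour volume, growth delay, and stereological necrosis point counting.

Calliper measurements give minor/major axes (a, b) in mm; volume is the
classic ellipsoid approximation V = 0.52 a^2 b.  Growth is summarised as a
fraction of each mouse's pre-treatment (day-0) volume, and the growth delay
is the day on which the treated group-mean relative volume, having dipped
below 1 after treatment, climbs back to 1 (linear interpolation between
measurement days).

Necrotic area fraction on a binary section mask is estimated by point
counting: a square grid (default 80 um spacing) is overlaid and the
percentage of grid intersections falling on necrotic pixels is reported.
The default grid offset is half a spacing in both axes, never an image
corner, avoiding edge-alignment artefacts; the offset can be randomised,
which makes the estimator unbiased in expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# Volume and growth
# ---------------------------------------------------------------------------

def tumour_volume(a: float, b: float) -> float:
    """Ellipsoid volume V = 0.52 a^2 b (mm^3), a = minor and b = major axis.

    Swapped axes are canonicalised with a warning.
    """
    if not (a > 0 and b > 0):
        raise ValueError(f"axes must be positive, got a={a}, b={b}")
    if a > b:
        warnings.warn(f"minor axis {a} > major axis {b}; swapping")
        a, b = b, a
    return 0.52 * a * a * b


def relative_growth(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-mouse and group-mean relative volume series.

    ``records`` needs columns mouse_id, group, day, a_mm, b_mm with treatment
    at day 0.  Each mouse's series is V(t)/V(0); mice without a day-0
    measurement are excluded with a warning.  Returns (per_mouse, group_mean)
    where group_mean carries mean and s.e.m. per (group, day).
    """
    required = {"mouse_id", "group", "day", "a_mm", "b_mm"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"growth records missing columns {sorted(missing)}")
    rows = []
    for mouse_id, sub in records.groupby("mouse_id", sort=False):
        sub = sub.sort_values("day")
        day0 = sub[sub["day"] == 0]
        if day0.empty:
            warnings.warn(f"mouse {mouse_id!r} has no day-0 measurement; excluded")
            continue
        v0 = tumour_volume(float(day0["a_mm"].iloc[0]), float(day0["b_mm"].iloc[0]))
        for _, r in sub.iterrows():
            v = tumour_volume(float(r["a_mm"]), float(r["b_mm"]))
            rows.append({
                "mouse_id": mouse_id,
                "group": r["group"],
                "day": float(r["day"]),
                "volume_mm3": v,
                "relative_volume": v / v0,
            })
    per_mouse = pd.DataFrame(rows)
    if per_mouse.empty:
        raise ValueError("no mouse has a day-0 measurement")
    grouped = per_mouse.groupby(["group", "day"])["relative_volume"]
    group_mean = grouped.agg(
        mean="mean",
        sem=lambda v: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0,
        n="count",
    ).reset_index()
    return per_mouse, group_mean


def growth_delay(mean_series: pd.DataFrame) -> float:
    """Days for a treated group-mean relative-volume series to regrow to 1.0.

    ``mean_series`` needs columns day and mean, starting at (0, 1.0).  The
    delay is the first post-minimum upward crossing of 1.0, linearly
    interpolated between measurement days; 0.0 if the series never drops
    below 1.0, NaN (censored at the last day) if it drops but never returns.
    """
    s = mean_series.sort_values("day").reset_index(drop=True)
    days = s["day"].to_numpy(float)
    vals = s["mean"].to_numpy(float)
    if len(days) == 0 or days[0] != 0.0 or abs(vals[0] - 1.0) > 1e-9:
        raise ValueError("series must start at day 0 with relative volume 1.0")
    if np.all(vals >= 1.0):
        return 0.0
    imin = int(np.argmin(vals))
    for i in range(imin, len(days) - 1):
        if vals[i] < 1.0 <= vals[i + 1]:
            t0, t1 = days[i], days[i + 1]
            y0, y1 = vals[i], vals[i + 1]
            return float(t0 + (t1 - t0) * (1.0 - y0) / (y1 - y0))
    return float("nan")  # not reached: censored at the last measurement day


# ---------------------------------------------------------------------------
# Necrosis point counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NecrosisGridConfig:
    """Stereological grid for necrosis point counting.

    ``spacing_um`` is the grid intersection spacing (default 80 um),
    ``um_per_pixel`` the mask's pixel size.  ``offset_um`` defaults to half a
    spacing in both axes.  When a tissue mask is supplied the denominator
    counts only grid points over tissue (montages include background).
    """

    spacing_um: float = 80.0
    um_per_pixel: float = 1.0
    offset_um: tuple[float, float] | None = None  # (y, x); default (s/2, s/2)

    def __post_init__(self) -> None:
        if self.spacing_um <= 0 or self.um_per_pixel <= 0:
            raise ValueError("spacing and pixel size must be positive")


def necrosis_fraction(
    mask: np.ndarray,
    cfg: NecrosisGridConfig,
    tissue_mask: np.ndarray | None = None,
) -> float:
    """Percent of grid intersections over necrotic pixels.

    Grid points sit at (offset + i * s, offset + j * s) in um; each maps to
    the pixel containing it.  Points outside the tissue mask (when given) are
    excluded from the denominator.  The result is invariant to jointly
    rescaling the spacing and the pixel size.
    """
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    s_px = cfg.spacing_um / cfg.um_per_pixel
    if s_px < 1.0:
        raise ValueError("grid spacing is below one pixel; the grid oversamples")
    oy_um, ox_um = cfg.offset_um if cfg.offset_um is not None else (
        cfg.spacing_um / 2.0, cfg.spacing_um / 2.0
    )
    oy = oy_um / cfg.um_per_pixel
    ox = ox_um / cfg.um_per_pixel
    ys = np.arange(oy, h, s_px)
    xs = np.arange(ox, w, s_px)
    if len(ys) == 0 or len(xs) == 0:
        raise ValueError("grid has no intersections inside the image")
    yi = np.floor(ys).astype(int)
    xi = np.floor(xs).astype(int)
    grid_hits = mask[np.ix_(yi, xi)]
    if tissue_mask is not None:
        tissue = np.asarray(tissue_mask).astype(bool)[np.ix_(yi, xi)]
        total = int(tissue.sum())
        if total == 0:
            raise ValueError("no grid intersections fall on tissue")
        necrotic = int((grid_hits & tissue).sum())
    else:
        total = grid_hits.size
        necrotic = int(grid_hits.sum())
    return 100.0 * necrotic / total


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    summary: pd.DataFrame       # group, mean, sem, n
    f_statistic: float
    p: float
    tukey: pd.DataFrame         # group_a, group_b, p_adj


def group_compare(values_per_group: dict[str, np.ndarray]) -> GroupComparison:
    """Mean +/- s.e.m. per group, one-way ANOVA, and Tukey HSD pairwise p.

    Classic fixed-effects ANOVA from sums of squares; the Tukey honestly-
    significant-difference p-values come from the studentised-range
    distribution.  Identical groups give F = 0 and p = 1.
    """
    if len(values_per_group) < 2:
        raise ValueError("need at least two groups")
    groups = {g: np.asarray(v, dtype=float) for g, v in values_per_group.items()}
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than two values")
    names = list(groups)
    arrays = [groups[g] for g in names]
    summary = pd.DataFrame({
        "group": names,
        "mean": [float(np.mean(v)) for v in arrays],
        "sem": [float(np.std(v, ddof=1) / np.sqrt(len(v))) for v in arrays],
        "n": [len(v) for v in arrays],
    })
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in arrays)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in arrays)
    df_between = len(arrays) - 1
    df_within = sum(len(v) for v in arrays) - len(arrays)
    if ss_within == 0:
        f = 0.0 if ss_between == 0 else float("inf")
        p = 1.0 if ss_between == 0 else 0.0
    else:
        f = (ss_between / df_between) / (ss_within / df_within)
        p = float(stats.f.sf(f, df_between, df_within))
    tukey_res = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append({
                "group_a": names[i],
                "group_b": names[j],
                "p_adj": float(tukey_res.pvalue[i, j]),
            })
    return GroupComparison(summary, float(f), p, pd.DataFrame(rows))


def timepoint_tests(
    per_mouse: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-timepoint Welch t between treated and untreated relative volumes,
    Bonferroni-corrected over timepoints.

    A deliberate, documented simplification of the usual repeated-measures
    two-way ANOVA for growth curves.
    """
    days = sorted(per_mouse["day"].unique())
    rows = []
    for day in days:
        sub = per_mouse[per_mouse["day"] == day]
        u = sub.loc[sub["group"] == "untreated", "relative_volume"].to_numpy(float)
        t = sub.loc[sub["group"] == "treated", "relative_volume"].to_numpy(float)
        if len(u) < 2 or len(t) < 2 or day == 0:
            continue
        p = float(stats.ttest_ind(t, u, equal_var=False).pvalue)
        rows.append({"day": day, "p": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
        out["significant"] = out["p_bonferroni"] <= alpha
    return out


__all__ = [
    "GroupComparison",
    "NecrosisGridConfig",
    "group_compare",
    "growth_delay",
    "necrosis_fraction",
    "relative_growth",
    "timepoint_tests",
    "tumour_volume",
]
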