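"""Two-group differential expression with an empirical-Bayes moderated t.

Per probe set the pooled residual variance s^2 (d_g = n1 + n2 - 2 df) is
shrunk toward a prior s0^2 carrying d0 prior df, estimated across all probe
sets by fitting a scaled inverse-chi-square distribution to the observed
variances via the moments of log s^2 (digamma / trigamma inversion).  The
moderated statistic

    t_mod = (mean_treated - mean_untreated) / sqrt(s_tilde^2 (1/n1 + 1/n2)),
    s_tilde^2 = (d0 s0^2 + d_g s^2) / (d0 + d_g)

is referred to a t distribution with d0 + d_g df.  Selection follows the
classic rule: two-sided P < 0.05 and fold change >= 1.5 up or down, on the
raw group-mean log2 difference (no shrinkage of the effect size).  Raw
P-values are the default -- the historical convention for this design -- with
a Benjamini-Hochberg adjusted column emitted alongside for modern use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .iotables import ProbesetMap
from .preprocess import ExpressionMatrix


@dataclass(frozen=True)
class EBayesPrior:
    """Scaled inverse-chi-square prior on the residual variances."""

    s0_squared: float
    d0: float  # may be +inf (all variances equal) or 0 (no moderation)

    def __post_init__(self) -> None:
        if not self.s0_squared > 0:
            raise ValueError("s0_squared must be positive")
        if self.d0 < 0:
            raise ValueError("d0 must be >= 0")


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration on 1/y."""
    if x <= 0:
        raise ValueError("trigamma_inverse needs a positive argument")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return y


def fit_ebayes_prior(s2: np.ndarray, d_g: int) -> EBayesPrior:
    """Estimate (s0^2, d0) from per-probe-set residual variances.

    Matches the moments of log s^2 under s^2 ~ s0^2 * chi^2_{d0} scaled /
    F-like mixing: e = log s^2 - digamma(d_g/2) + log(d_g/2) has mean
    log s0^2 + digamma(d0/2) - log(d0/2) and excess variance trigamma(d0/2)
    beyond trigamma(d_g/2).  If the empirical variance of e does not exceed
    trigamma(d_g/2), the variances are consistent with a single common value
    and d0 = +inf.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 10:
        raise ValueError("need at least 10 probe sets with positive variance")
    if d_g < 1:
        raise ValueError("residual df must be >= 1")
    if np.ptp(s2) == 0:  # all variances identical: degenerate prior
        return EBayesPrior(s0_squared=float(s2[0]), d0=math.inf)
    z = np.log(s2)
    e = z - float(special.digamma(d_g / 2.0)) + math.log(d_g / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, d_g / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_squared = math.exp(
            emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
        )
    else:
        d0 = math.inf
        s0_squared = math.exp(emean)
    return EBayesPrior(s0_squared=s0_squared, d0=d0)


def moderated_t(
    expr: ExpressionMatrix,
    groups: dict[str, list[str]],
    prior: EBayesPrior | None = None,
) -> pd.DataFrame:
    """Moderated-t differential expression, treated minus untreated.

    ``groups`` maps 'untreated' and 'treated' to sample-id lists (each n >= 2).
    With ``prior=None`` the prior is fitted from this matrix's variances;
    passing ``EBayesPrior(s0, 0)`` recovers the ordinary pooled two-sample t.
    Returns one row per probe set with log2fc, fold_change, direction, t_mod,
    p, BH-adjusted p and a ``flagged`` column for degenerate variances.
    """
    for g in ("untreated", "treated"):
        if g not in groups or len(groups[g]) < 2:
            raise ValueError(f"group {g!r} needs at least two samples")
    x1 = expr.values[groups["untreated"]].to_numpy(dtype=float)
    x2 = expr.values[groups["treated"]].to_numpy(dtype=float)
    n1, n2 = x1.shape[1], x2.shape[1]
    d_g = n1 + n2 - 2

    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / d_g

    if prior is None:
        prior = fit_ebayes_prior(s2, d_g)

    if math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_squared)
        df_total = np.inf
    else:
        s2_post = (prior.d0 * prior.s0_squared + d_g * s2) / (prior.d0 + d_g)
        df_total = prior.d0 + d_g

    log2fc = m2 - m1
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    flagged = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(flagged, np.nan, log2fc / np.where(se == 0, np.nan, se))
        t_mod = np.where((log2fc == 0) & ~flagged, 0.0, t_mod)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p = np.where(np.isnan(t_mod), np.nan, p)

    out = pd.DataFrame({
        "probeset_id": expr.probeset_ids,
        "mean_untreated": m1,
        "mean_treated": m2,
        "log2fc": log2fc,
        "fold_change": 2.0 ** np.abs(log2fc),
        "direction": np.where(log2fc >= 0, "up", "down"),
        "s2": s2,
        "t_mod": t_mod,
        "df_total": df_total,
        "p": p,
        "p_bh": benjamini_hochberg(p),
        "flagged": flagged,
    })
    return out


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values; NaNs pass through untouched."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv)
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def select_de(
    results: pd.DataFrame, p_thresh: float = 0.05, fc_thresh: float = 1.5
) -> pd.DataFrame:
    """Apply the P < p_thresh AND fold change >= fc_thresh rule.

    Adds a ``selected`` column and returns the table ranked by p, with the
    direction column partitioning up- from down-regulated probe sets.
    """
    out = results.copy()
    out["selected"] = (out["p"] < p_thresh) & (out["fold_change"] >= fc_thresh)
    out["selected"] &= out["p"].notna()
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


@dataclass
class DESummary:
    """Headline counts of a selected DE list, in the style of a results text:
    probe sets up/down, how many map to known transcripts vs uncharacterised
    ESTs, and how many are redundant probe sets for an already-counted
    transcript."""

    n_selected: int
    n_up: int
    n_down: int
    up_mapped: int
    up_est: int
    down_mapped: int
    down_est: int
    duplicates_up: int
    duplicates_down: int


def summarize_de(selected: pd.DataFrame, pm: ProbesetMap) -> DESummary:
    sel = selected[selected["selected"]] if "selected" in selected else selected
    counts = {}
    dups = {}
    for direction in ("up", "down"):
        sub = sel[sel["direction"] == direction]
        syms = [pm.symbol_of(ps) for ps in sub["probeset_id"]]
        mapped = sum(1 for s in syms if s)
        est = sum(1 for s in syms if not s)
        seen: dict[str, int] = {}
        for s in syms:
            if s:
                seen[s] = seen.get(s, 0) + 1
        dup = sum(c - 1 for c in seen.values())
        counts[direction] = (len(sub), mapped, est)
        dups[direction] = dup
    return DESummary(
        n_selected=len(sel),
        n_up=counts["up"][0],
        n_down=counts["down"][0],
        up_mapped=counts["up"][1],
        up_est=counts["up"][2],
        down_mapped=counts["down"][1],
        down_est=counts["down"][2],
        duplicates_up=dups["up"],
        duplicates_down=dups["down"],
    )


def top_heatmap_matrix(
    results: pd.DataFrame, expr: ExpressionMatrix, n_top: int = 25
) -> pd.DataFrame:
    """Heat-map-ready matrix of the most significant probe sets.

    Takes the ``n_top`` probe sets by P-value and returns their expression
    submatrix with rows and columns ordered by average-linkage hierarchical
    clustering on correlation distance, so similar probe sets and similar
    arrays sit together.
    """
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import pdist

    top = results.sort_values("p", kind="mergesort")["probeset_id"].head(n_top)
    sub = expr.values.loc[top]

    def _order(mat: np.ndarray) -> np.ndarray:
        if mat.shape[0] < 3:
            return np.arange(mat.shape[0])
        d = pdist(mat, metric="correlation")
        d = np.nan_to_num(d, nan=1.0)
        return hierarchy.leaves_list(hierarchy.linkage(d, method="average"))

    row_order = _order(sub.to_numpy())
    col_order = _order(sub.to_numpy().T)
    return sub.iloc[row_order, col_order]


def write_de_table(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")


__all__ = [
    "DESummary",
    "EBayesPrior",
    "benjamini_hochberg",
    "fit_ebayes_prior",
    "moderated_t",
    "select_de",
    "summarize_de",
    "top_heatmap_matrix",
    "trigamma_inverse",
    "write_de_table",
]
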