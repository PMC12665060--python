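"""Group-level MTIS statistics.

Scores are z-scaled once over all cells pooled (preserving between-group
differences), then compared between sample groups with two-sided Wilcoxon
rank-sum tests — overall and within each cell type — and summarized as
per-(cell type, group) means and cumulative sums. A 2-D density landscape
bins the mean score over an embedding.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CellAnnotation
from .covariate_de import benjamini_hochberg

__all__ = [
    "GroupComparison",
    "DensityGrid",
    "scale_values",
    "rank_sum_test",
    "group_celltype_summary",
    "density_landscape",
]

EXACT_LIMIT = 20  # exact rank-sum enumeration up to this combined n (tie-free)
ALPHA = 0.05


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float  # rank-sum W of sample a
    p_value: float
    scope: str  # "all-cells" or "cell-type:<label>"
    method: str  # "exact" or "normal-approx"

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass
class DensityGrid:
    x_edges: np.ndarray
    y_edges: np.ndarray
    value: np.ndarray  # mean score per bin, NaN where empty


def scale_values(x) -> np.ndarray:
    """Center and scale to unit sample variance ((x - mean) / sd, ddof=1)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to scale")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot scale constant input (sd = 0)")
    return (x - x.mean()) / sd


def rank_sum_test(a, b, alternative: str = "two-sided", scope: str = "all-cells",
                  group_a: str = "a", group_b: str = "b") -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test.

    Uses exact enumeration when the combined sample size is at most 20 and
    there are no ties, and the normal approximation with tie and continuity
    corrections otherwise; the method used is recorded in the result.
    """
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is supported")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= EXACT_LIMIT and tie_free) else "normal-approx"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if method == "exact" else "asymptotic",
    )
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0  # U -> rank-sum W
    return GroupComparison(
        group_a, group_b, int(a.size), int(b.size), w, float(res.pvalue),
        scope, method,
    )


def _ann_frame(ann) -> pd.DataFrame:
    return ann.df if isinstance(ann, CellAnnotation) else ann


def group_celltype_summary(mtis: pd.DataFrame, ann) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise group comparisons and per-(cell type, group) summaries.

    MTIS is z-scaled once over all cells before any split. Comparisons are
    computed over all cells and within each cell type with at least two
    cells on both sides; thinner strata are recorded as skipped.
    Raw p values carry the 0.05 significance flag; a BH-adjusted column is
    emitted additionally.

    Parameters
    ----------
    mtis
        Table with columns ``cell_id`` and ``mtis``.
    ann
        :class:`CellAnnotation` (or equivalent frame) covering every scored
        cell.
    """
    adf = _ann_frame(ann)
    merged = mtis.merge(adf, on="cell_id", how="left", validate="one_to_one")
    unmatched = merged.loc[merged["group"].isna(), "cell_id"].tolist()
    if unmatched:
        raise ValueError(f"cells without annotation: {unmatched[:10]}")
    merged = merged.assign(scaled=scale_values(merged["mtis"].to_numpy()))
    # pair order from the declared label set, so results are invariant to
    # the order cells arrive in
    if isinstance(ann, CellAnnotation):
        groups = [g for g in ann.groups if g in set(merged["group"])]
    else:
        groups = sorted(pd.unique(merged["group"]))

    rows = []
    scopes: list[tuple[str, pd.DataFrame]] = [("all-cells", merged)]
    for ct, sub in merged.groupby("cell_type", dropna=True, sort=True):
        scopes.append((f"cell-type:{ct}", sub))
    for scope, sub in scopes:
        for ga, gb in combinations(groups, 2):
            va = sub.loc[sub["group"] == ga, "scaled"].to_numpy()
            vb = sub.loc[sub["group"] == gb, "scaled"].to_numpy()
            if va.size < 2 or vb.size < 2:
                rows.append(
                    dict(scope=scope, group_a=ga, group_b=gb, n_a=va.size,
                         n_b=vb.size, statistic=np.nan, p_value=np.nan,
                         method="skipped", significant=False)
                )
                continue
            cmp = rank_sum_test(va, vb, scope=scope, group_a=ga, group_b=gb)
            rows.append(
                dict(scope=scope, group_a=ga, group_b=gb, n_a=cmp.n_a,
                     n_b=cmp.n_b, statistic=cmp.statistic, p_value=cmp.p_value,
                     method=cmp.method, significant=cmp.significant)
            )
    comparisons = pd.DataFrame(rows)
    tested = comparisons["p_value"].notna()
    q = np.full(len(comparisons), np.nan)
    if tested.any():
        q[tested.to_numpy()] = benjamini_hochberg(
            comparisons.loc[tested, "p_value"].to_numpy()
        )
    comparisons["q_bh"] = q

    summaries = (
        merged.groupby(["cell_type", "group"], dropna=True, sort=True)["scaled"]
        .agg(n="size", mean_mtis="mean", cum_mtis="sum")
        .reset_index()
    )
    return comparisons, summaries


def density_landscape(ann, mtis: pd.DataFrame, bins: int = 50) -> DensityGrid:
    """Mean MTIS per bin over the 2-D embedding bounding box."""
    adf = _ann_frame(ann)
    merged = mtis.merge(adf, on="cell_id", how="left")
    if merged.empty:
        edges = np.linspace(0.0, 1.0, bins + 1)
        return DensityGrid(edges, edges.copy(), np.full((bins, bins), np.nan))
    xy = merged[["embed_x", "embed_y"]].to_numpy(dtype=float)
    if np.isnan(xy).any():
        raise ValueError("embedding coordinates missing for some cells")
    x, y = xy[:, 0], xy[:, 1]

    def _edges(v):
        lo, hi = v.min(), v.max()
        if lo == hi:  # degenerate bounding box (e.g. a single cell)
            lo, hi = lo - 0.5, hi + 0.5
        return np.linspace(lo, hi, bins + 1)

    x_edges, y_edges = _edges(x), _edges(y)
    v = merged["mtis"].to_numpy(dtype=float)
    total, _, _ = np.histogram2d(x, y, bins=[x_edges, y_edges], weights=v)
    count, _, _ = np.histogram2d(x, y, bins=[x_edges, y_edges])
    with np.errstate(invalid="ignore"):
        value = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return DensityGrid(x_edges, y_edges, value)
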