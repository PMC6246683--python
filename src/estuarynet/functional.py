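"""Functional-profile normalization, hierarchy aggregation and group tests.

Tables carry counts for level-4 functions annotated with a four-level
category path. Depth normalization is a per-sample rescaling to a common
total (kept real-valued; no resampling), the default target being the
20,634,952 sequences-per-sample convention of the source annotation pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_fdr
from .io_tables import AbundanceTable, ValidationError

__all__ = [
    "DEFAULT_NORMALIZATION_TARGET",
    "SELECTED_CATEGORIES",
    "normalize_depth",
    "aggregate_level",
    "category_group_compare",
    "select_categories",
]

DEFAULT_NORMALIZATION_TARGET = 20_634_952

#: the six level-1 categories singled out for ecological interpretation:
#: core nutrient cycling plus the pollution-responsive categories
SELECTED_CATEGORIES = (
    "Nitrogen Metabolism",
    "Sulfur Metabolism",
    "Phosphorus Metabolism",
    "Stress Response",
    "Metabolism of Aromatic Compounds",
    "Plasmids and Transposable elements",
)


def normalize_depth(tab: AbundanceTable,
                    target_total: float = DEFAULT_NORMALIZATION_TARGET
                    ) -> AbundanceTable:
    """Scale each sample so its total equals ``target_total`` (real-valued)."""
    totals = tab.data.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise ValidationError(f"sample {bad!r} has zero total; cannot normalize")
    scaled = tab.data.mul(target_total / totals, axis=0)
    return AbundanceTable(scaled, tab.feature_meta)


def _require_levels(tab: AbundanceTable) -> pd.DataFrame:
    if tab.feature_meta is None:
        raise ValidationError("table has no level1..level4 feature metadata")
    meta = tab.feature_meta
    for lvl in ("level1", "level2", "level3", "level4"):
        if lvl not in meta.columns:
            raise ValidationError(f"feature metadata lacks column {lvl!r}")
        if meta[lvl].isna().any() or (meta[lvl].astype(str) == "").any():
            bad = meta.index[meta[lvl].isna() | (meta[lvl].astype(str) == "")][0]
            raise ValidationError(f"feature {bad!r} lacks a {lvl} label")
    return meta


def aggregate_level(tab: AbundanceTable, level: int) -> AbundanceTable:
    """Sum leaf counts over all features sharing the level-``level`` prefix."""
    if level not in (1, 2, 3, 4):
        raise ValueError("level must be 1..4")
    meta = _require_levels(tab)
    if level == 4:
        return tab
    key = meta[f"level{level}"]
    grouped = tab.data.T.groupby(key.loc[tab.data.columns]).sum().T
    path_cols = [f"level{i}" for i in range(1, level + 1)]
    agg_meta = (meta[path_cols].drop_duplicates(subset=f"level{level}")
                .set_index(f"level{level}", drop=False))
    agg_meta = agg_meta.loc[grouped.columns]
    return AbundanceTable(grouped, feature_meta=agg_meta)


def category_group_compare(cat: AbundanceTable, groups, test: str = "welch",
                           alpha: float = 0.05) -> pd.DataFrame:
    """Two-sample test per category on relative abundances, BH-adjusted.

    Default is a two-sided Welch t; ``test='mannwhitney'`` switches to the
    exact Mann–Whitney U. Categories with zero variance in both groups fall
    back to the rank test (noted in the ``test_used`` column).
    """
    if isinstance(groups, pd.Series):
        groups = groups.loc[cat.data.index]
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValidationError("category comparison needs exactly 2 groups")
    if min((g == lab).sum() for lab in labels) < 2:
        raise ValidationError("each group needs at least 2 samples")
    rel = cat.relative()
    a_idx, b_idx = g == labels[0], g == labels[1]
    rows = []
    for feature in rel.columns:
        a = rel.loc[a_idx, feature].to_numpy()
        b = rel.loc[b_idx, feature].to_numpy()
        used = test
        if test == "welch" and (a.std() == 0 and b.std() == 0):
            used = "mannwhitney"
        if used == "welch":
            res = stats.ttest_ind(a, b, equal_var=False)
        elif used == "mannwhitney":
            res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="exact")
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append({"category": feature,
                     f"mean_{labels[0]}": a.mean(),
                     f"mean_{labels[1]}": b.mean(),
                     "log2_fold": np.log2(b.mean() / a.mean())
                     if a.mean() > 0 and b.mean() > 0 else np.nan,
                     "statistic": float(res.statistic),
                     "p_raw": float(res.pvalue),
                     "test_used": used})
    out = pd.DataFrame(rows).set_index("category")
    out["p_adj"] = bh_fdr(out["p_raw"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    out.attrs["alpha"] = alpha
    out.attrs["groups"] = list(labels)
    return out


def select_categories(tab: AbundanceTable, names=SELECTED_CATEGORIES
                      ) -> AbundanceTable:
    """Restrict a leaf-level table to the named level-1 categories."""
    meta = _require_levels(tab)
    valid = set(meta["level1"])
    unknown = [n for n in names if n not in valid]
    if unknown:
        raise ValidationError(
            f"unknown level-1 categories {unknown}; valid: {sorted(valid)}")
    keep = meta.index[meta["level1"].isin(names)]
    keep = [f for f in tab.data.columns if f in set(keep)]
    return tab.subset_features(keep)
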