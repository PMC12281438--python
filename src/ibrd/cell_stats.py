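"""Per-biopsy T-cell cluster frequencies and between-group tests.

Cluster labels are inputs (clustering itself is upstream); this module turns
cell-level records into relative-frequency compositions and tests them with
Kruskal-Wallis followed by Dunn's mean-rank post-hoc comparisons with
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, round_half_away


def cluster_frequencies(cells: pd.DataFrame) -> pd.DataFrame:
    """Biopsy x cluster matrix of relative cell frequencies (rows sum to 1)."""
    if cells.empty:
        raise ValueError("empty cell table")
    counts = pd.crosstab(cells["biopsy_id"], cells["cluster"])
    totals = counts.sum(axis=1)
    empty = totals.index[totals == 0].tolist()
    if empty:
        raise ValueError(f"biopsies without cells: {empty}")
    return counts.div(totals, axis=0)


def group_cluster_percentage(
    cells: pd.DataFrame, cluster: str, group: str, group_col: str = "activity"
) -> float:
    """Percentage of a group's cells belonging to one cluster, to two decimals."""
    in_group = cells[cells[group_col] == group]
    if in_group.empty:
        raise ValueError(f"empty group: {group}")
    frac = (in_group["cluster"] == cluster).mean()
    return round_half_away(100.0 * frac, 2)


def _dunn_posthoc(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Dunn's pairwise mean-rank comparisons with tie correction."""
    n = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    groups = np.unique(labels)
    mean_ranks = {g: ranks[labels == g].mean() for g in groups}
    sizes = {g: int((labels == g).sum()) for g in groups}
    rows = []
    for a, b in itertools.combinations(groups, 2):
        se = np.sqrt(
            (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b])
        )
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append(dict(group_a=a, group_b=b, z=z, p=p))
    return pd.DataFrame(rows)


def compare_frequencies(
    freqs: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Kruskal-Wallis across groups per cluster plus Dunn post-hoc.

    ``groups`` maps biopsy id -> group label.  BH adjustment of the post-hoc
    p-values is applied within each cluster's pairwise family.  Returns a
    long table with one row per (cluster, pair).
    """
    groups = groups.loc[freqs.index]
    labels = groups.to_numpy().astype(str)
    level_counts = pd.Series(labels).value_counts()
    if len(level_counts) < 2:
        raise ValueError("need at least 2 groups")
    small = level_counts[level_counts < 2]
    if not small.empty:
        raise ValueError(f"groups with < 2 biopsies: {list(small.index)}")

    out = []
    for cluster in freqs.columns:
        values = freqs[cluster].to_numpy(dtype=float)
        samples = [values[labels == g] for g in level_counts.index]
        try:
            kw_stat, kw_p = stats.kruskal(*samples)
        except ValueError:  # all values identical
            kw_stat, kw_p = 0.0, 1.0
        posthoc = _dunn_posthoc(values, labels)
        posthoc["padj"] = bh_adjust(posthoc["p"].to_numpy())
        posthoc.insert(0, "cluster", cluster)
        posthoc["kw_stat"] = kw_stat
        posthoc["kw_p"] = kw_p
        out.append(posthoc)
    return pd.concat(out, ignore_index=True)


def attach_activity(cells: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Join activity labels onto a cell table via biopsy id."""
    merged = cells.merge(
        meta[["biopsy_id", "activity"]], on="biopsy_id", how="left", validate="m:1"
    )
    missing = merged["activity"].isna()
    if missing.any():
        bad = sorted(merged.loc[missing, "biopsy_id"].unique())
        raise ValueError(f"biopsies missing from metadata: {bad}")
    return merged
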