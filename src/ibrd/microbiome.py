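"""16S zOTU filtering, compositional transform and diversity statistics.

Operates on a zOTU x sample count table with semicolon-delimited taxonomy
strings.  The abundance/prevalence filter, centered log-ratio transform,
richness and Shannon-effective alpha-diversity, pairwise rank-sum
differential abundance and per-patient time-series means are implemented;
tree-based beta-diversity (UniFrac, NMDS, PERMANOVA) is out of scope.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    totals = table.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"samples with zero total counts: {bad}")
    return table / totals


def filter_zotus(
    table: pd.DataFrame,
    min_relab: float = 0.0025,
    max_prev: float = 0.10,
    conjunctive: bool = True,
) -> pd.DataFrame:
    """Remove spurious low-signal zOTUs.

    A zOTU is removed iff its relative abundance stays below ``min_relab``
    in every sample AND its prevalence (fraction of samples with a nonzero
    count) is at most ``max_prev``.  Set ``conjunctive=False`` for the
    either-condition variant.
    """
    if table.shape[1] < 1:
        raise ValueError("empty table")
    relab = relative_abundance(table)
    low_everywhere = (relab < min_relab).all(axis=1)
    low_prev = (table > 0).mean(axis=1) <= max_prev
    remove = (low_everywhere & low_prev) if conjunctive else (low_everywhere | low_prev)
    return table.loc[~remove]


def clr_transform(table: pd.DataFrame) -> pd.DataFrame:
    """Centered log-ratio per sample.

    Zeros are replaced by half the smallest nonzero proportion of that
    sample, followed by renormalization, which preserves exact per-sample
    scale invariance.  Rows of the result (samples) sum to zero.
    """
    relab = relative_abundance(table).to_numpy(dtype=float)
    out = np.empty_like(relab)
    for j in range(relab.shape[1]):
        p = relab[:, j].copy()
        zero = p == 0
        if zero.any():
            nonzero_min = p[~zero].min()
            p[zero] = nonzero_min / 2.0
            p = p / p.sum()
        logs = np.log(p)
        out[:, j] = logs - logs.mean()
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def alpha_diversity(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample richness and Shannon-effective number of zOTUs."""
    values = table.to_numpy(dtype=float)
    totals = values.sum(axis=0)
    if (totals == 0).any():
        bad = list(table.columns[totals == 0])
        raise ValueError(f"all-zero samples: {bad}")
    richness = (values > 0).sum(axis=0)
    props = values / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(props > 0, props * np.log(props), 0.0)
    shannon_eff = np.exp(-plogp.sum(axis=0))
    return pd.DataFrame(
        {"richness": richness, "shannon_effective": shannon_eff},
        index=table.columns,
    )


def differential_abundance(
    table: pd.DataFrame, groups: pd.Series, use_clr: bool = False
) -> pd.DataFrame:
    """Two-sided rank-sum tests of each taxon between every pair of groups.

    Operates on relative abundances by default (CLR optionally); BH is
    applied over the full taxon x group-pair family.
    """
    groups = groups.loc[table.columns].astype(str)
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 groups")
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"groups with < 2 samples: {list(small.index)}")
    data = clr_transform(table) if use_clr else relative_abundance(table)
    rows = []
    for a, b in itertools.combinations(sorted(counts.index), 2):
        mat_a = data.loc[:, (groups == a).to_numpy()].to_numpy()
        mat_b = data.loc[:, (groups == b).to_numpy()].to_numpy()
        for i, taxon in enumerate(table.index):
            x, y = mat_a[i], mat_b[i]
            if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
                stat, p = np.nan, np.nan
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
            rows.append(dict(zotu=taxon, group_a=a, group_b=b, statistic=stat, p=p))
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out


def timeseries_patient_means(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    phases: tuple[str, ...] = ("active", "EH"),
    activity_col: str = "activity",
) -> pd.DataFrame:
    """Per-patient, per-phase mean relative abundance across locations.

    Patients missing any requested phase are excluded with a warning.
    Output is long-format (patient, phase, zotu, mean_relab), suitable for
    paired trajectory plots.
    """
    relab = relative_abundance(table)
    meta_idx = meta.set_index("biopsy_id")
    info = meta_idx.loc[relab.columns, ["patient_id", activity_col]]
    rows = []
    for patient, sub in info.groupby("patient_id"):
        present = {ph: sub.index[sub[activity_col] == ph] for ph in phases}
        if any(len(ids) == 0 for ids in present.values()):
            warnings.warn(
                f"patient {patient} missing a phase; excluded", stacklevel=2
            )
            continue
        for ph, ids in present.items():
            means = relab[ids].mean(axis=1)
            for zotu, value in means.items():
                rows.append(
                    dict(patient=patient, phase=ph, zotu=zotu, mean_relab=value)
                )
    return pd.DataFrame(rows, columns=["patient", "phase", "zotu", "mean_relab"])
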