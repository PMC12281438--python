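"""Bipartite Spearman correlation network between two modalities.

Correlates every feature of one matrix (e.g. persistent-gene expression)
with every feature of another (e.g. T-cell cluster frequencies) across
matched biopsies, zeroes non-significant coefficients, and selects features
by network degree.  Within-modality correlations are never computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust


@dataclass
class BipartiteNetwork:
    rho: pd.DataFrame
    p: pd.DataFrame
    padj: pd.DataFrame
    adjacency: pd.DataFrame
    mode: str
    alpha: float


def match_samples(meta_a: pd.DataFrame, meta_b: pd.DataFrame) -> list[str]:
    """Sorted intersection of biopsy ids present in both modalities."""
    shared = sorted(set(meta_a["biopsy_id"]) & set(meta_b["biopsy_id"]))
    if not shared:
        raise ValueError("no matched samples between modalities")
    return shared


def spearman_bipartite(
    X: pd.DataFrame, Y: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All pairwise Spearman correlations between rows of X and rows of Y.

    Both matrices are features x samples over the same sample order.
    Average ranks; two-sided p via the t approximation.  Constant rows give
    NaN entries (with a warning) rather than an arbitrary coefficient.
    """
    if list(X.columns) != list(Y.columns):
        raise ValueError("X and Y must share the same matched sample order")
    n = X.shape[1]
    if n < 4:
        raise ValueError("too few matched samples (need >= 4)")

    def _ranked(mat: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        values = mat.to_numpy(dtype=float)
        ranks = stats.rankdata(values, axis=1)
        constant = values.std(axis=1) == 0
        centered = ranks - ranks.mean(axis=1, keepdims=True)
        norm = np.sqrt((centered**2).sum(axis=1))
        norm[norm == 0] = 1.0
        return centered / norm[:, None], constant

    rx, const_x = _ranked(X)
    ry, const_y = _ranked(Y)
    if const_x.any() or const_y.any():
        warnings.warn(
            f"constant features give undefined correlations: "
            f"{int(const_x.sum())} in X, {int(const_y.sum())} in Y",
            stacklevel=2,
        )
    rho = rx @ ry.T
    rho = np.clip(rho, -1.0, 1.0)
    rho[const_x, :] = np.nan
    rho[:, const_y] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    p[np.isnan(rho)] = np.nan
    rho_df = pd.DataFrame(rho, index=X.index, columns=Y.index)
    p_df = pd.DataFrame(p, index=X.index, columns=Y.index)
    return rho_df, p_df


def threshold_network(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    mode: str = "fdr",
    alpha: float = 0.05,
) -> BipartiteNetwork:
    """Zero non-significant coefficients.

    mode="fdr": BH over all defined feature pairs jointly; entries with
    padj > alpha are zeroed (strictly greater, so padj == alpha survives).
    mode="nominal": entries with raw p >= alpha are zeroed; padj is still
    reported for highlighting.
    """
    if mode not in ("fdr", "nominal"):
        raise ValueError(f"unknown mode: {mode}")
    padj = pd.DataFrame(
        bh_adjust(p.to_numpy()), index=p.index, columns=p.columns
    )
    if mode == "fdr":
        keep = padj.to_numpy() <= alpha
    else:
        keep = p.to_numpy() < alpha
    keep &= np.isfinite(rho.to_numpy())
    adjacency = rho.where(pd.DataFrame(keep, index=rho.index, columns=rho.columns), 0.0)
    adjacency = adjacency.fillna(0.0)
    return BipartiteNetwork(rho=rho, p=p, padj=padj, adjacency=adjacency, mode=mode, alpha=alpha)


def select_features(
    net: BipartiteNetwork, side: str = "A", min_degree: int = 1
) -> list[str]:
    """Features with at least ``min_degree`` significant cross-modal edges,
    ordered by degree then by strongest |rho|."""
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")
    if side not in ("A", "B"):
        raise ValueError("side must be 'A' (rows) or 'B' (columns)")
    adj = net.adjacency if side == "A" else net.adjacency.T
    degree = (adj != 0).sum(axis=1)
    strength = adj.abs().max(axis=1)
    chosen = degree[degree >= min_degree]
    order = pd.DataFrame({"degree": chosen, "strength": strength.loc[chosen.index]})
    order = order.sort_values(["degree", "strength"], ascending=False, kind="mergesort")
    return order.index.tolist()


def network_long_form(net: BipartiteNetwork) -> pd.DataFrame:
    """Long-form edge table (feature_a, feature_b, rho, p, padj, kept)."""
    records = []
    for a in net.rho.index:
        for b in net.rho.columns:
            records.append(
                dict(
                    feature_a=a,
                    feature_b=b,
                    rho=net.rho.at[a, b],
                    p=net.p.at[a, b],
                    padj=net.padj.at[a, b],
                    kept=bool(net.adjacency.at[a, b] != 0),
                )
            )
    return pd.DataFrame(records)
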