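"""Bulk differential expression and persistent-gene selection.

Normalization is median-of-ratios; the differential test is an ordinary
linear model on log2(normalized count + 1) with covariate adjustment and a
two-sided t-test on the contrast coefficient, adjusted by Benjamini-Hochberg.
An externally computed DE table (e.g. from a negative-binomial engine) can be
substituted anywhere a DeTable is accepted — the thresholding and persistence
logic is engine-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust


@dataclass(frozen=True)
class DeThresholds:
    """DEG selection bounds: |log2FC| >= 2 (inclusive) and padj < 0.05 (strict)."""

    lfc_up: float = 2.0
    lfc_down: float = -2.0
    alpha: float = 0.05
    min_total_count: int = 5

    def __post_init__(self):
        if not (self.lfc_up > 0 > self.lfc_down):
            raise ValueError("require lfc_up > 0 > lfc_down")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For genes with strictly positive counts in every sample, the factor of a
    sample is the median of count / geometric-mean-across-samples.
    """
    values = counts.to_numpy(dtype=float)
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("cannot normalize: no gene with positive counts in every sample")
    ref = values[all_positive]
    geo_mean = np.exp(np.mean(np.log(ref), axis=1))
    factors = np.median(ref / geo_mean[:, None], axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_log_expression(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(normalized count + 1) working expression matrix.

    Counts are put on a common scale by median-of-ratios size factors and
    expressed per million of the geometric-mean effective library, so the
    matrix is exactly invariant to rescaling all columns by a constant.
    Used for correlation networks and PCA scoring.
    """
    sf = size_factors(counts)
    effective = counts / sf
    lib = np.exp(np.mean(np.log(effective.sum(axis=0))))
    return np.log2(effective / lib * 1e6 + 1.0)


def _design_matrix(
    meta: pd.DataFrame, contrast_col: np.ndarray, covariates: list[str]
) -> tuple[np.ndarray, list[str]]:
    blocks = [np.ones((len(meta), 1)), contrast_col[:, None].astype(float)]
    names = ["intercept", "contrast"]
    for cov in covariates:
        if cov not in meta.columns:
            raise ValueError(f"covariate column not in metadata: {cov}")
        dummies = pd.get_dummies(meta[cov].astype(str), drop_first=True, dtype=float)
        blocks.append(dummies.to_numpy())
        names.extend(f"{cov}[{c}]" for c in dummies.columns)
    X = np.hstack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify which covariate breaks identifiability
        base = np.hstack(blocks[:2])
        for cov, block in zip(covariates, blocks[2:]):
            trial = np.hstack([base, block])
            if np.linalg.matrix_rank(trial) < trial.shape[1]:
                raise ValueError(f"covariate confounded with contrast: {cov}")
            base = trial
        raise ValueError("singular design matrix")
    return X, names


def differential_test(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    contrast: tuple[str, str],
    covariates: list[str] | None = None,
    activity_col: str = "activity",
    min_total_count: int = 5,
) -> pd.DataFrame:
    """Covariate-adjusted linear-model DE between two activity levels.

    ``contrast = (test, reference)``: log2fc > 0 means higher in the test
    level.  Genes with total count below ``min_total_count`` are dropped
    before testing.  Returns a DeTable with columns base_mean, log2fc, p,
    padj indexed by gene id.
    """
    covariates = list(covariates or [])
    test_level, ref_level = contrast
    labels = meta[activity_col].astype(str)
    keep = labels.isin([test_level, ref_level]).to_numpy()
    for level in (test_level, ref_level):
        if (labels == level).sum() < 2:
            raise ValueError(f"contrast level absent or has < 2 samples: {level}")
    sub_meta = meta.loc[keep].reset_index(drop=True)
    sub_counts = counts.loc[:, meta.loc[keep, "biopsy_id"]]

    total = sub_counts.sum(axis=1)
    tested = sub_counts.loc[total >= min_total_count]
    if tested.empty:
        raise ValueError("no gene passes the count filter")

    expr = normalized_log_expression(tested).to_numpy()
    is_test = (sub_meta[activity_col].astype(str) == test_level).to_numpy()
    X, _ = _design_matrix(sub_meta, is_test, covariates)

    n, p_dim = X.shape
    # one least-squares solve for all genes at once
    beta, _, _, _ = np.linalg.lstsq(X, expr.T, rcond=None)
    resid = expr.T - X @ beta
    df = n - p_dim
    sigma2 = (resid**2).sum(axis=0) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 1e-300))
    log2fc = beta[1]
    tstat = log2fc / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)

    return pd.DataFrame(
        {
            "base_mean": tested.mean(axis=1).to_numpy(),
            "log2fc": log2fc,
            "p": pvals,
            "padj": bh_adjust(pvals),
        },
        index=tested.index,
    )


def select_degs(
    de: pd.DataFrame, thresholds: DeThresholds = DeThresholds()
) -> tuple[set[str], set[str]]:
    """Apply DEG bounds: fold-change inclusive, adjusted p strict."""
    sig = de["padj"] < thresholds.alpha
    up = set(de.index[(de["log2fc"] >= thresholds.lfc_up) & sig])
    down = set(de.index[(de["log2fc"] <= thresholds.lfc_down) & sig])
    return up, down


def persistent_sets(
    up_active: set[str],
    down_active: set[str],
    up_eh: set[str],
    down_eh: set[str],
) -> tuple[set[str], set[str]]:
    """Persistent DEGs: significant in the same direction in both the
    active-vs-control and EH-vs-control contrasts."""
    return up_active & up_eh, down_active & down_eh
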