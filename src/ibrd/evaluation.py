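"""Signature robustness and covariate-controlled validation.

Two complementary checks of a disease signature: (1) a random-gene-set null
— repeated PCAs on gene sets drawn from the pool of disease-regulated genes,
summarized by centroid distances of each disease group to the control
centroid on the PC1-PC2 plane and tested with a one-sample Wilcoxon; and
(2) per-PC linear mixed models with a random patient intercept to confirm
group separation while controlling for treatment and biopsy location.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import spawn_rng
from .scoring import fit_pca


@dataclass
class NullConfig:
    n_draws: int = 200
    set_size: int = 81
    pool: list[str] = field(default_factory=list)
    seed: int = 0


def centroid_distances(
    pc_scores: pd.DataFrame, labels: pd.Series, ref_label: str
) -> pd.Series:
    """Euclidean distance of each group centroid to the reference centroid
    on the first two components."""
    labels = labels.loc[pc_scores.index].astype(str)
    if ref_label not in set(labels):
        raise ValueError(f"reference group absent: {ref_label}")
    xy = pc_scores.iloc[:, :2].to_numpy(dtype=float)
    ref = xy[(labels == ref_label).to_numpy()].mean(axis=0)
    out = {}
    for group in sorted(set(labels) - {ref_label}):
        centroid = xy[(labels == group).to_numpy()].mean(axis=0)
        out[group] = float(np.linalg.norm(centroid - ref))
    return pd.Series(out, name="centroid_distance")


def random_signature_null(
    expr: pd.DataFrame,
    labels: pd.Series,
    config: NullConfig,
    ref_label: str = "non-IBD",
) -> pd.DataFrame:
    """Centroid-distance null from repeated random gene-set PCAs.

    Each draw samples ``set_size`` genes without replacement from the pool,
    fits a scaled PCA on all samples, and records per-group centroid
    distances to the reference plus the PC1/PC2 explained variances.
    """
    pool = [g for g in config.pool]
    missing = [g for g in pool if g not in expr.index]
    if missing:
        raise ValueError(f"pool genes absent from expression: {missing[:5]}")
    if config.set_size > len(pool):
        raise ValueError("set_size exceeds pool size")
    rows = []
    for draw in range(config.n_draws):
        rng = spawn_rng(config.seed, "null-draw", draw)
        genes = list(rng.choice(pool, size=config.set_size, replace=False))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model, scores = fit_pca(expr.loc[genes], scale=True)
        dists = centroid_distances(
            pd.DataFrame(scores[:, :2], index=expr.columns), labels, ref_label
        )
        for group, dist in dists.items():
            rows.append(
                dict(
                    draw=draw,
                    group=group,
                    distance=dist,
                    pc1_var=float(model.explained[0]),
                    pc2_var=float(model.explained[1]),
                )
            )
    return pd.DataFrame(rows, columns=["draw", "group", "distance", "pc1_var", "pc2_var"])


def one_sample_wilcoxon(values, reference: float, alternative: str = "two-sided") -> float:
    """Two-sided signed-rank test of values against a reference median.

    Zero differences are dropped (their count is warned about); the exact
    distribution is used for n <= 25 without ties in |difference|, otherwise
    the normal approximation with continuity correction.
    """
    d = np.asarray(values, dtype=float) - float(reference)
    n_zero = int((d == 0).sum())
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero; test undefined")
    if n_zero:
        warnings.warn(f"dropped {n_zero} zero differences", stacklevel=2)
    abs_d = np.abs(d)
    has_ties = len(np.unique(abs_d)) < len(abs_d)
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        d, alternative=alternative, method=method, correction=(method == "approx")
    )
    return float(res.pvalue)


def fit_pc_lmm(
    pc_scores: pd.DataFrame,
    meta: pd.DataFrame,
    fixed: list[str] | None = None,
    group_col: str = "patient_id",
    n_pcs: int | None = None,
) -> pd.DataFrame:
    """Per-PC REML mixed model with a random patient intercept.

    Model: PC ~ fixed effects + (1 | patient).  Default fixed effects are
    disease status (activity), anti-TNF flag and location.  P-values are
    Wald tests from the REML fit, Bonferroni-corrected over the number of
    PCs tested (capped at 1).  For the disease-phenotype variant (CD vs UC),
    pass ``fixed=["phenotype", "anti_tnf", "location"]`` on a table with
    controls excluded.
    """
    import statsmodels.formula.api as smf

    fixed = list(fixed or ["activity", "anti_tnf", "location"])
    meta_idx = meta.set_index("biopsy_id")
    data = meta_idx.loc[pc_scores.index, fixed + [group_col]].copy()
    for col in fixed + [group_col]:
        if data[col].nunique() < 2 and col != group_col:
            raise ValueError(f"factor with a single level: {col}")
    if data[group_col].nunique() < 2:
        raise ValueError("need at least 2 patients")

    n_pcs = n_pcs or pc_scores.shape[1]
    terms = " + ".join(
        f"C({c})" if not pd.api.types.is_numeric_dtype(data[c]) else c for c in fixed
    )
    rows = []
    for j in range(n_pcs):
        data["pc"] = pc_scores.iloc[:, j].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(f"pc ~ {terms}", data, groups=data[group_col])
            fit = model.fit(reml=True)
        for name in fit.fe_params.index:
            if name == "Intercept":
                continue
            p = float(fit.pvalues[name])
            rows.append(
                dict(
                    pc=j + 1,
                    term=name,
                    estimate=float(fit.fe_params[name]),
                    stat=float(fit.tvalues[name]),
                    p=p,
                    padj=min(1.0, p * n_pcs),
                )
            )
    return pd.DataFrame(rows)
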