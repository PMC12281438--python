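"""IBrD scoring: signature PCA, principal-curve pseudotime, projection.

The score of a biopsy is its arc-length position along a single-lineage
principal curve fitted through the leading principal components of the
signature-gene expression matrix, oriented so that non-IBD controls sit at
the low end and min/max-normalized to [0, 1] over the training samples
(0 = no residual disease, 1 = active inflammation).  A frozen model — gene
list, standardization constants, rotation, polyline, pseudotime extrema and
orientation — projects new cohorts without refitting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess


@dataclass
class PcaModel:
    gene_ids: list[str]
    means: np.ndarray
    sds: np.ndarray
    rotation: np.ndarray  # genes x components, orthonormal columns
    explained: np.ndarray  # variance proportions

    def transform(self, expr: pd.DataFrame) -> np.ndarray:
        """Standardize columns-as-samples by the stored constants and rotate."""
        missing = [g for g in self.gene_ids if g not in expr.index]
        if missing:
            raise ValueError(f"missing signature genes: {missing}")
        mat = expr.loc[self.gene_ids].to_numpy(dtype=float).T
        if not np.all(np.isfinite(mat)):
            raise ValueError("non-finite expression values")
        z = (mat - self.means) / self.sds
        return z @ self.rotation


@dataclass
class Curve:
    vertices: np.ndarray  # ordered polyline vertices in k-dim PC space
    arc_lengths: np.ndarray  # cumulative arc length per vertex
    pseudotimes: np.ndarray  # per-training-sample arc-length position


def fit_pca(expr: pd.DataFrame, scale: bool = True) -> tuple[PcaModel, np.ndarray]:
    """PCA of samples in signature-gene space (genes are rows of ``expr``).

    Zero-variance genes are dropped with a warning before fitting.  Returns
    the model and the sample scores (samples x components).
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    mat = expr.to_numpy(dtype=float).T  # samples x genes
    sds_all = mat.std(axis=0, ddof=1)
    keep = sds_all > 0
    if not keep.all():
        dropped = [g for g, k in zip(expr.index, keep) if not k]
        warnings.warn(f"dropping zero-variance genes: {dropped}", stacklevel=2)
        mat = mat[:, keep]
    gene_ids = [g for g, k in zip(expr.index, keep) if k]
    if len(gene_ids) < 2:
        raise ValueError("need at least 2 genes with variance")
    means = mat.mean(axis=0)
    sds = mat.std(axis=0, ddof=1) if scale else np.ones(mat.shape[1])
    z = (mat - means) / sds
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    var = s**2
    model = PcaModel(
        gene_ids=gene_ids,
        means=means,
        sds=sds,
        rotation=vt.T,
        explained=var / var.sum(),
    )
    scores = u * s
    return model, scores


def choose_k(explained: np.ndarray, threshold: float = 0.80) -> int:
    """Smallest number of leading components whose cumulative explained
    variance reaches the threshold."""
    explained = np.asarray(explained, dtype=float)
    if explained.size == 0:
        raise ValueError("empty explained-variance vector")
    cum = np.cumsum(explained)
    reached = np.nonzero(cum >= threshold - 1e-12)[0]
    return int(reached[0]) + 1 if reached.size else explained.size


def _project_to_polyline(
    points: np.ndarray, vertices: np.ndarray, arc_lengths: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Orthogonal projection of points onto a polyline.

    Returns (projected points, arc-length positions, total squared distance).
    Ties in distance resolve to the smaller arc length (first minimum).
    """
    if len(vertices) == 1:
        proj = np.repeat(vertices, len(points), axis=0)
        d2 = ((points - proj) ** 2).sum(axis=1)
        return proj, np.zeros(len(points)), float(d2.sum())
    starts = vertices[:-1]
    vecs = vertices[1:] - starts
    seg_len2 = (vecs**2).sum(axis=1)
    safe_len2 = np.where(seg_len2 > 0, seg_len2, 1.0)
    diff = points[:, None, :] - starts[None, :, :]
    t = np.einsum("nsk,sk->ns", diff, vecs) / safe_len2
    t = np.clip(t, 0.0, 1.0)
    proj = starts[None, :, :] + t[:, :, None] * vecs[None, :, :]
    d2 = ((points[:, None, :] - proj) ** 2).sum(axis=2)
    best = np.argmin(d2, axis=1)  # first minimum -> smallest arc length
    idx = np.arange(len(points))
    lam = arc_lengths[best] + t[idx, best] * np.sqrt(seg_len2[best])
    return proj[idx, best], lam, float(d2[idx, best].sum())


def _polyline_from_vertices(vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop consecutive duplicate vertices and compute cumulative arc length."""
    step = np.sqrt(((np.diff(vertices, axis=0)) ** 2).sum(axis=1))
    keep = np.concatenate([[True], step > 0])
    vertices = vertices[keep]
    step = np.sqrt(((np.diff(vertices, axis=0)) ** 2).sum(axis=1))
    return vertices, np.concatenate([[0.0], np.cumsum(step)])


def principal_curve(
    points: np.ndarray,
    span: float = 0.6,
    tol: float = 1e-3,
    max_iter: int = 10,
) -> Curve:
    """Hastie-Stuetzle principal curve through a k-dimensional point cloud.

    Initialized with the first principal component line, then alternating
    (a) orthogonal projection of the points onto the current polyline,
    (b) coordinate-wise local-linear (lowess) smoothing against arc length,
    (c) reparameterization by cumulative arc length, until the relative
    change in total squared orthogonal distance falls below ``tol`` or
    ``max_iter`` is reached.  The iterate whose objective would increase is
    rejected, so the reported objective is non-increasing.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n, k = points.shape
    if n < 5:
        raise ValueError("need at least 5 points")
    if not np.all(np.isfinite(points)):
        raise ValueError("non-finite input points")

    center = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - center, full_matrices=False)
    direction = vt[0]
    lam = (points - center) @ direction
    order = np.argsort(lam, kind="mergesort")
    vertices, arcs = _polyline_from_vertices(
        center + lam[order, None] * direction[None, :]
    )
    _, lam_cur, d2_cur = _project_to_polyline(points, vertices, arcs)

    for _ in range(max_iter):
        order = np.argsort(lam_cur, kind="mergesort")
        lam_sorted = lam_cur[order]
        smoothed = np.empty((n, k))
        for dim in range(k):
            smoothed[:, dim] = lowess(
                points[order, dim],
                lam_sorted,
                frac=span,
                it=0,
                return_sorted=False,
            )
        new_vertices, new_arcs = _polyline_from_vertices(smoothed)
        if len(new_vertices) < 2:
            break
        _, lam_new, d2_new = _project_to_polyline(points, new_vertices, new_arcs)
        if d2_new > d2_cur:
            break  # keep the previous (better) curve
        converged = d2_cur > 0 and abs(d2_cur - d2_new) / d2_cur < tol
        vertices, arcs, lam_cur, d2_cur = new_vertices, new_arcs, lam_new, d2_new
        if converged:
            break
    return Curve(vertices=vertices, arc_lengths=arcs, pseudotimes=lam_cur)


@dataclass
class IbrdModel:
    """Frozen scoring model: everything needed to score a new cohort."""

    pca: PcaModel
    k: int
    curve: Curve
    t_min: float
    t_max: float
    orientation: int  # +1: raw arc length increases with disease; -1: flipped
    variance_threshold: float = 0.80

    def _normalize(self, t: np.ndarray) -> np.ndarray:
        span = self.t_max - self.t_min
        raw = (t - self.t_min) / span
        return raw if self.orientation == 1 else 1.0 - raw

    def score(self, expr: pd.DataFrame) -> pd.DataFrame:
        """Project samples of ``expr`` (genes x samples) onto the frozen
        trajectory.  Scores outside [0, 1] are reported unclamped with an
        ``out_of_range`` flag."""
        coords = self.pca.transform(expr)[:, : self.k]
        _, t, _ = _project_to_polyline(
            coords, self.curve.vertices, self.curve.arc_lengths
        )
        values = self._normalize(t)
        return pd.DataFrame(
            {
                "ibrd": values,
                "out_of_range": (values < 0) | (values > 1),
            },
            index=expr.columns,
        )

    # ---- lossless JSON serialization -------------------------------------
    def to_dict(self) -> dict:
        return dict(
            gene_ids=self.pca.gene_ids,
            means=self.pca.means.tolist(),
            sds=self.pca.sds.tolist(),
            rotation=self.pca.rotation.tolist(),
            explained=self.pca.explained.tolist(),
            k=self.k,
            vertices=self.curve.vertices.tolist(),
            arc_lengths=self.curve.arc_lengths.tolist(),
            pseudotimes=self.curve.pseudotimes.tolist(),
            t_min=self.t_min,
            t_max=self.t_max,
            orientation=self.orientation,
            variance_threshold=self.variance_threshold,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "IbrdModel":
        pca = PcaModel(
            gene_ids=list(d["gene_ids"]),
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            rotation=np.asarray(d["rotation"], dtype=float),
            explained=np.asarray(d["explained"], dtype=float),
        )
        curve = Curve(
            vertices=np.asarray(d["vertices"], dtype=float),
            arc_lengths=np.asarray(d["arc_lengths"], dtype=float),
            pseudotimes=np.asarray(d["pseudotimes"], dtype=float),
        )
        return cls(
            pca=pca,
            k=int(d["k"]),
            curve=curve,
            t_min=float(d["t_min"]),
            t_max=float(d["t_max"]),
            orientation=int(d["orientation"]),
            variance_threshold=float(d["variance_threshold"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "IbrdModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_ibrd(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    signature: list[str],
    variance_threshold: float = 0.80,
    control_label: str = "non-IBD",
    activity_col: str = "activity",
    span: float = 0.6,
    tol: float = 1e-3,
    max_iter: int = 10,
    orient_low: list[str] | None = None,
) -> tuple[IbrdModel, pd.DataFrame]:
    """Fit the full scoring model on a training cohort.

    Composes scaled PCA on the signature genes, the 80%-variance component
    cut, and the principal curve on the leading scores; orients the
    pseudotime so the control group's mean sits at the low end (or the
    samples named in ``orient_low`` for cohorts without controls) and
    normalizes to [0, 1] over the training samples.
    """
    missing = [g for g in signature if g not in expr.index]
    if missing:
        raise ValueError(f"signature genes absent from expression: {missing}")
    sig_expr = expr.loc[signature]
    pca, scores = fit_pca(sig_expr, scale=True)
    k = choose_k(pca.explained, variance_threshold)
    curve = principal_curve(scores[:, :k], span=span, tol=tol, max_iter=max_iter)

    t = curve.pseudotimes
    sample_ids = list(expr.columns)
    if orient_low is not None:
        low_mask = np.isin(sample_ids, list(orient_low))
    else:
        meta_idx = meta.set_index("biopsy_id")
        low_mask = (
            meta_idx.loc[sample_ids, activity_col].astype(str) == control_label
        ).to_numpy()
    if not low_mask.any():
        raise ValueError(
            "no control samples for orientation; pass orient_low explicitly"
        )
    orientation = 1 if t[low_mask].mean() <= t[~low_mask].mean() else -1

    model = IbrdModel(
        pca=pca,
        k=k,
        curve=curve,
        t_min=float(t.min()),
        t_max=float(t.max()),
        orientation=orientation,
        variance_threshold=variance_threshold,
    )
    if model.t_max <= model.t_min:
        raise ValueError("degenerate trajectory: all pseudotimes equal")
    training = pd.DataFrame(
        {
            "ibrd": model._normalize(t),
            "out_of_range": np.zeros(len(t), dtype=bool),
        },
        index=sample_ids,
    )
    return model, training


def project_samples(model: IbrdModel, expr_new: pd.DataFrame) -> pd.DataFrame:
    """Score a new cohort with a frozen model (no refitting)."""
    return model.score(expr_new)
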