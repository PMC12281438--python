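"""End-to-end pipeline driver.

Stage order follows the analysis design: differential expression on the two
contrasts -> persistent gene sets -> cluster frequencies -> bipartite
network and signature selection -> IBrD model fit and scoring -> random-
signature null -> per-PC mixed model.  Each stage writes its artifact to
the output directory and a manifest records inputs, outputs and checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import bulk_de, cell_stats, crossmodal, evaluation, scoring
from .io import write_gene_list

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    de_thresholds: bulk_de.DeThresholds = field(default_factory=bulk_de.DeThresholds)
    covariates: tuple[str, ...] = ("batch", "location")
    network_mode: str = "fdr"
    network_alpha: float = 0.05
    min_degree: int = 1
    variance_threshold: float = 0.80
    curve_span: float = 0.6
    curve_tol: float = 1e-3
    curve_max_iter: int = 10
    null_draws: int = 200
    seed: int = 0


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    cells: pd.DataFrame,
    outdir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Run DE -> persistence -> frequencies -> network -> IBrD -> null -> LMM.

    Returns a result dict with the in-memory artifacts; files are written
    under ``outdir`` together with ``manifest.json``.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"stages": [], "seed": config.seed}
    results: dict = {}

    def stage(name, fn):
        start = time.time()
        try:
            value = fn()
        except Exception as exc:  # surface the failing stage
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        manifest["stages"].append({"stage": name, "seconds": round(time.time() - start, 3)})
        logger.info("stage %s done in %.2fs", name, time.time() - start)
        return value

    # --- differential expression, both contrasts -------------------------
    def _de():
        de_a = bulk_de.differential_test(
            counts, meta, ("active", "non-IBD"), covariates=list(config.covariates),
            min_total_count=config.de_thresholds.min_total_count,
        )
        de_e = bulk_de.differential_test(
            counts, meta, ("EH", "non-IBD"), covariates=list(config.covariates),
            min_total_count=config.de_thresholds.min_total_count,
        )
        de_a.to_csv(outdir / "de_active_vs_control.tsv", sep="\t")
        de_e.to_csv(outdir / "de_eh_vs_control.tsv", sep="\t")
        return de_a, de_e

    de_active, de_eh = stage("differential_expression", _de)

    def _persist():
        up_a, dn_a = bulk_de.select_degs(de_active, config.de_thresholds)
        up_e, dn_e = bulk_de.select_degs(de_eh, config.de_thresholds)
        up, down = bulk_de.persistent_sets(up_a, dn_a, up_e, dn_e)
        write_gene_list(sorted(up), outdir / "persistent_up.txt")
        write_gene_list(sorted(down), outdir / "persistent_down.txt")
        pool = sorted(up_a | dn_a | up_e | dn_e)
        write_gene_list(pool, outdir / "regulated_pool.txt")
        return up, down, pool

    persistent_up, persistent_down, pool = stage("persistent_sets", _persist)
    results["persistent_up"] = persistent_up
    results["persistent_down"] = persistent_down
    results["regulated_pool"] = pool

    def _freqs():
        freqs = cell_stats.cluster_frequencies(cells)
        freqs.to_csv(outdir / "frequencies.tsv", sep="\t")
        return freqs

    freqs = stage("cluster_frequencies", _freqs)
    results["frequencies"] = freqs

    def _network():
        matched = crossmodal.match_samples(
            meta[meta["biopsy_id"].isin(counts.columns)],
            pd.DataFrame({"biopsy_id": freqs.index}),
        )
        expr = bulk_de.normalized_log_expression(counts)
        sig_genes = sorted(persistent_up)
        if not sig_genes:
            raise ValueError("no persistent up-regulated genes to correlate")
        rho, p = crossmodal.spearman_bipartite(
            expr.loc[sig_genes, matched], freqs.loc[matched].T
        )
        net = crossmodal.threshold_network(
            rho, p, mode=config.network_mode, alpha=config.network_alpha
        )
        crossmodal.network_long_form(net).to_csv(
            outdir / "network.tsv", sep="\t", index=False
        )
        selected = crossmodal.select_features(net, side="A", min_degree=config.min_degree)
        write_gene_list(selected, outdir / "selected_features.txt")
        return net, selected, expr

    network, signature, expr = stage("crossmodal_network", _network)
    results["signature"] = signature

    def _ibrd():
        model, training = scoring.fit_ibrd(
            expr,
            meta,
            signature,
            variance_threshold=config.variance_threshold,
            span=config.curve_span,
            tol=config.curve_tol,
            max_iter=config.curve_max_iter,
        )
        model.save(outdir / "model.json")
        training.to_csv(outdir / "scores.tsv", sep="\t")
        return model, training

    model, training_scores = stage("ibrd_fit", _ibrd)
    results["model"] = model
    results["scores"] = training_scores

    def _null():
        labels = meta.set_index("biopsy_id")["activity"]
        # draws sized to the signature so null PCAs are directly comparable
        null_cfg = evaluation.NullConfig(
            n_draws=config.null_draws,
            set_size=min(len(signature), len(pool)),
            pool=pool,
            seed=config.seed,
        )
        null = evaluation.random_signature_null(expr, labels, null_cfg)
        null.to_csv(outdir / "null_distances.tsv", sep="\t", index=False)
        _, sig_scores = scoring.fit_pca(expr.loc[signature], scale=True)
        sig_dist = evaluation.centroid_distances(
            pd.DataFrame(sig_scores[:, :2], index=expr.columns), labels, "non-IBD"
        )
        wilcoxon = {}
        for group in sig_dist.index:
            draws = null.loc[null["group"] == group, "distance"].to_numpy()
            if len(draws) and not (draws == sig_dist[group]).all():
                wilcoxon[group] = evaluation.one_sample_wilcoxon(draws, sig_dist[group])
        (outdir / "wilcoxon.json").write_text(json.dumps(wilcoxon, indent=1))
        return null, sig_dist

    null_table, signature_distances = stage("random_signature_null", _null)
    results["null_distances"] = null_table
    results["signature_distances"] = signature_distances

    def _lmm():
        sig_model, sig_scores = scoring.fit_pca(expr.loc[signature], scale=True)
        pcs = pd.DataFrame(
            sig_scores[:, :2], index=expr.columns, columns=["PC1", "PC2"]
        )
        lmm = evaluation.fit_pc_lmm(pcs, meta)
        lmm.to_csv(outdir / "lmm_results.tsv", sep="\t", index=False)
        return lmm

    results["lmm"] = stage("pc_lmm", _lmm)

    for path in sorted(outdir.glob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest.setdefault("outputs", {})[path.name] = _checksum(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    results["manifest"] = manifest
    return results
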