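"""Paired-chain TCR clonotype calling and clonal-expansion statistics.

A clonotype is the exact pair of alpha- and beta-chain CDR3 nucleotide
sequences; cells missing either chain are excluded, and when a cell carries
multiple contigs of one chain only the highest-UMI contig is kept.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EXPANSION_THRESHOLDS = (1, 5, 10, 20)


def call_clonotypes(
    contigs: pd.DataFrame, require_productive: bool = True
) -> pd.DataFrame:
    """Cells with exactly one alpha and one beta CDR3, keyed into clonotypes.

    Duplicate (barcode, chain, cdr3_nt) rows are collapsed with summed UMIs
    (with a warning); within a cell and chain the highest-UMI contig wins,
    ties broken by the lexicographically smallest sequence.  Clonotype ids
    are assigned per unique (cdr3a_nt, cdr3b_nt) pair and clone_size counts
    the retained cells carrying that pair.
    """
    df = contigs.copy()
    if require_productive and "productive" in df.columns:
        df = df[df["productive"].astype(bool)]
    bad_chain = ~df["chain"].isin(["TRA", "TRB"])
    if bad_chain.any():
        raise ValueError(f"unknown chain labels: {sorted(df.loc[bad_chain, 'chain'].unique())}")

    dup_mask = df.duplicated(subset=["barcode", "chain", "cdr3_nt"], keep=False)
    if dup_mask.any():
        logger.warning(
            "collapsing %d duplicate (barcode, chain, cdr3) contig rows",
            int(dup_mask.sum()),
        )
        df = (
            df.groupby(["barcode", "chain", "cdr3_nt"], as_index=False)
            .agg(umis=("umis", "sum"))
        )
    # best contig per (cell, chain): highest UMIs, tie -> smallest sequence
    df = df.sort_values(
        ["barcode", "chain", "umis", "cdr3_nt"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    best = df.drop_duplicates(subset=["barcode", "chain"], keep="first")
    wide = best.pivot(index="barcode", columns="chain", values="cdr3_nt")
    for chain in ("TRA", "TRB"):
        if chain not in wide.columns:
            wide[chain] = np.nan
    paired = wide.dropna(subset=["TRA", "TRB"]).rename(
        columns={"TRA": "cdr3a_nt", "TRB": "cdr3b_nt"}
    )
    if paired.empty:
        return pd.DataFrame(
            columns=["cell_id", "clonotype_id", "cdr3a_nt", "cdr3b_nt", "clone_size"]
        )
    pair_key = paired["cdr3a_nt"] + "|" + paired["cdr3b_nt"]
    codes, _ = pd.factorize(pair_key.sort_values().to_numpy())  # stable ids by sequence order
    id_map = dict(zip(pair_key.sort_values().to_numpy(), codes))
    clonotype_id = pair_key.map(lambda k: f"ct{id_map[k] + 1:05d}")
    sizes = clonotype_id.value_counts()
    out = pd.DataFrame(
        {
            "cell_id": paired.index,
            "clonotype_id": clonotype_id.to_numpy(),
            "cdr3a_nt": paired["cdr3a_nt"].to_numpy(),
            "cdr3b_nt": paired["cdr3b_nt"].to_numpy(),
        }
    )
    out["clone_size"] = out["clonotype_id"].map(sizes).astype(int)
    return out.reset_index(drop=True)


def expansion_summary(
    clonotypes: pd.DataFrame, thresholds: tuple[int, ...] = EXPANSION_THRESHOLDS
) -> pd.DataFrame:
    """Cells and unique clonotypes in each strict expansion class (> t)."""
    if clonotypes.empty:
        raise ValueError("empty clonotype table")
    unique_sizes = clonotypes.drop_duplicates("clonotype_id")["clone_size"]
    rows = []
    for t in thresholds:
        rows.append(
            dict(
                threshold=t,
                n_cells=int((clonotypes["clone_size"] > t).sum()),
                n_clonotypes=int((unique_sizes > t).sum()),
            )
        )
    return pd.DataFrame(rows)


def coverage_per_cluster(
    cells: pd.DataFrame, clonotypes: pd.DataFrame
) -> pd.Series:
    """Percentage of each cluster's cells with a called paired TCR."""
    with_tcr = set(clonotypes["cell_id"]) if not clonotypes.empty else set()
    covered = cells["cell_id"].isin(with_tcr)
    return (
        covered.groupby(cells["cluster"]).mean() * 100.0
    ).rename("tcr_coverage_pct")


def shared_clonotypes(
    clonotypes: pd.DataFrame,
    partition: pd.Series,
    min_size: int = 2,
) -> dict[frozenset, int]:
    """Venn-region counts of expanded clonotypes across groups.

    ``partition`` maps cell id -> group label.  A clonotype belongs to a
    group if any retained cell of that group carries it and its overall
    clone_size >= min_size; each unique clonotype counts once per group.
    The returned dict maps each nonempty group subset (Venn cell) to the
    number of clonotypes present in exactly those groups.
    """
    labels = clonotypes["cell_id"].map(partition)
    if labels.isna().any():
        bad = clonotypes.loc[labels.isna(), "cell_id"].head().tolist()
        raise ValueError(f"unlabeled cells, e.g.: {bad}")
    expanded = clonotypes[clonotypes["clone_size"] >= min_size]
    groups = sorted(partition.dropna().unique().astype(str))
    membership: dict[str, set[str]] = {g: set() for g in groups}
    for ct, lab in zip(expanded["clonotype_id"], labels.loc[expanded.index].astype(str)):
        membership[lab].add(ct)
    out: dict[frozenset, int] = {}
    for r in range(1, len(groups) + 1):
        for subset in itertools.combinations(groups, r):
            inside = set.intersection(*(membership[g] for g in subset))
            outside = set.union(
                *(membership[g] for g in groups if g not in subset), set()
            )
            out[frozenset(subset)] = len(inside - outside)
    return out
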