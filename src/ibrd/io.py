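"""Validated table readers and writers.

Counts are accepted as a dense TSV (genes as rows, first column gene ids,
header of sample ids) or as an MTX triplet with row/column name files.
All ids are carried as strings; row order is preserved.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io

CONTIG_COLUMNS = ["barcode", "biopsy", "chain", "cdr3_nt", "umis", "productive"]
CELL_COLUMNS = ["cell_id", "biopsy_id", "cluster"]
META_COLUMNS = ["biopsy_id", "patient_id", "activity"]


class SchemaError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Dense TSV count matrix; integral nonnegative values enforced."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = np.where(~df.map(lambda v: isinstance(v, (int, np.integer))).to_numpy())
        row = int(bad[0][0]) + 2 if len(bad[0]) else "?"
        raise SchemaError(f"non-numeric count cell near row {row} of {path}")
    if (values < 0).any() or not np.allclose(values, np.round(values)):
        raise SchemaError(f"counts must be nonnegative integers: {path}")
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise SchemaError(f"duplicate gene or sample ids in {path}")
    return df.astype(int)


def read_counts_mtx(
    mtx_path: str | Path, genes_path: str | Path, samples_path: str | Path
) -> pd.DataFrame:
    """MTX triplet plus one-id-per-line row/column name files."""
    mat = scipy.io.mmread(mtx_path)
    genes = Path(genes_path).read_text().split()
    samples = Path(samples_path).read_text().split()
    dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
    if dense.shape != (len(genes), len(samples)):
        raise SchemaError(
            f"MTX shape {dense.shape} does not match {len(genes)} genes x {len(samples)} samples"
        )
    return pd.DataFrame(dense.astype(int), index=genes, columns=samples)


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, META_COLUMNS, "metadata")
    if "anti_tnf" in df.columns:
        df["anti_tnf"] = df["anti_tnf"].isin(["True", "true", "1"])
    return df


def read_cells(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, CELL_COLUMNS, "cell table")
    if df["cell_id"].duplicated().any():
        raise SchemaError("duplicate cell ids")
    return df


def read_contigs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, CONTIG_COLUMNS, "contig table")
    df["umis"] = pd.to_numeric(df["umis"], errors="raise")
    return df


def read_zotus(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """zOTU TSV: first column ids, last column taxonomy, counts between."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "taxonomy" not in df.columns:
        raise SchemaError("zOTU table missing 'taxonomy' column")
    taxonomy = df.pop("taxonomy").astype(str)
    counts = df.astype(int)
    if (counts.to_numpy() < 0).any():
        raise SchemaError("negative zOTU counts")
    return counts, taxonomy


def read_gene_list(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("\n".join(str(g) for g in genes) + "\n")
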