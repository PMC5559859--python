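"""Delimited-text I/O for matrices, partitions, and run configuration.

Matrices are stored as CSV/TSV with a header row of feature ids and a leading
column of sample ids.  Partitions are two-column text files (gene_id,
cluster label, 1-based).  Configuration echoes are flat key=value files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("ancut")

__all__ = ["read_matrix", "write_matrix", "read_partition", "write_partition",
           "write_config", "read_config", "write_dataset"]


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_matrix(path) -> pd.DataFrame:
    """Read a samples-by-features matrix with ids; comma or tab inferred.

    Missing cells are imputed by the column mean (count logged).  Non-numeric
    cells and duplicated ids are rejected with their location.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"{path}: duplicated feature ids {dups}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicated sample ids {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"{path}: duplicated feature ids {dups}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                raise ValueError(
                    f"{path}: non-numeric cell at row {bad.idxmax()!r}, "
                    f"column {col!r}")
            df[col] = coerced
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        logger.warning("%s: imputed %d missing cell(s) by column mean",
                       path, n_missing)
        df = df.fillna(df.mean(axis=0))
        if df.isna().any().any():
            empty = df.columns[df.isna().any()].tolist()
            raise ValueError(f"{path}: all-missing column(s) {empty}")
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df.to_csv(path, sep=sep)


def write_partition(gene_ids, labels, path) -> None:
    """Two-column gene_id, cluster (1-based) text file."""
    labels = np.asarray(labels)
    with open(path, "w") as fh:
        fh.write("gene_id\tcluster\n")
        for gid, lab in zip(gene_ids, labels):
            fh.write(f"{gid}\t{int(lab) + 1}\n")


def read_partition(path):
    """Returns (gene_ids, labels) with labels converted back to 0-based."""
    df = pd.read_csv(path, sep="\t")
    return df["gene_id"].tolist(), df["cluster"].to_numpy(dtype=int) - 1


def write_config(mapping: dict, path) -> None:
    with open(path, "w") as fh:
        for key, value in mapping.items():
            fh.write(f"{key}={value}\n")


def read_config(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out


def write_dataset(dataset, outdir) -> None:
    """Persist a simulated dataset: Y, X, the true partition, and config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(dataset.Y, outdir / "expression.csv")
    write_matrix(dataset.X, outdir / "regulators.csv")
    write_partition(dataset.Y.columns, dataset.true_labels,
                    outdir / "true_partition.tsv")
    cfg = dataset.config
    if cfg is not None:
        write_config({k: getattr(cfg, k) for k in
                      ("n", "p", "q", "q0", "rho", "h", "scheme",
                       "noise_sd", "seed")},
                     outdir / "config.txt")
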