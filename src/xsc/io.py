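"""Readers and writers for the pipeline's on-disk formats.

Count matrices travel as 10x-style Matrix Market triplets
(``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``) or as dense TSV;
annotations and ortholog tables as TSV; gene sets as GMT; result tables as
TSV with a fixed column order.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix, GeneSetCollection, OrthologTable, validate_cell_table

logger = logging.getLogger(__name__)

#: Fixed column order for exported marker / DEG tables.
MARKER_COLUMNS = ("gene", "group", "logFC", "p", "p_adj", "pct_1", "pct_2")


def _collapse_duplicate_genes(x: sp.csr_matrix, genes: np.ndarray) -> tuple[sp.csr_matrix, np.ndarray]:
    """Sum rows sharing a symbol, keeping first-occurrence order."""
    seen: dict[str, int] = {}
    order: list[str] = []
    for g in genes:
        if g not in seen:
            seen[g] = len(order)
            order.append(g)
    if len(order) == len(genes):
        return x, genes
    n_dup = len(genes) - len(order)
    logger.warning("collapsing %d duplicate gene symbols by summation", n_dup)
    rows = np.array([seen[g] for g in genes])
    agg = sp.csr_matrix(
        (np.ones(len(genes)), (rows, np.arange(len(genes)))),
        shape=(len(order), len(genes)),
    )
    return sp.csr_matrix(agg @ x), np.array(order, dtype=object)


def read_counts(path: str | Path, format: str = "mtx_dir", *, species: str = "",
                namespace: str = "source") -> CountMatrix:
    """Read a gene × cell count matrix.

    ``mtx_dir`` expects ``matrix.mtx`` (genes × cells), ``features.tsv``
    (one symbol per line, first column) and ``barcodes.tsv``. ``dense_tsv``
    expects genes as rows (index column) and cells as columns. Duplicate
    gene symbols are collapsed by elementwise summation with a warning.
    """
    path = Path(path)
    if format == "mtx_dir":
        x = sp.csr_matrix(scipy.io.mmread(path / "matrix.mtx"))
        genes = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].astype(str).to_numpy()
        cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str).to_numpy()
    elif format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        x = sp.csr_matrix(df.to_numpy())
        genes = df.index.astype(str).to_numpy()
        cells = df.columns.astype(str).to_numpy()
    else:
        raise ValueError(f"unknown format {format!r}")
    if x.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {x.shape} does not match id lists "
            f"({len(genes)} genes, {len(cells)} cells)"
        )
    x, genes = _collapse_duplicate_genes(x, np.asarray(genes, dtype=object))
    return CountMatrix(x=x, genes=genes, cells=cells, species=species, namespace=namespace)


def write_counts(m: CountMatrix, path: str | Path) -> None:
    """Write a matrix as a 10x-style Matrix Market directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(m.x))
    pd.Series(m.genes).to_csv(path / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(m.cells).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return validate_cell_table(table)


def write_annotations(table: pd.DataFrame, path: str | Path) -> None:
    validate_cell_table(table)
    table.to_csv(path, sep="\t", index=False)


def read_orthologs(path: str | Path, *, species: str = "",
                   source_col: str = "source_symbol",
                   human_col: str = "human_symbol") -> OrthologTable:
    """Read a BioMart-export-style two-column ortholog TSV.

    Rows with a blank symbol on either side are dropped and counted.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in (source_col, human_col):
        if col not in df.columns:
            raise ValueError(f"ortholog table {path} missing column {col!r}")
    df = df.rename(columns={source_col: "source_symbol", human_col: "human_symbol"})
    n0 = len(df)
    df = df[(df["source_symbol"] != "") & (df["human_symbol"] != "")]
    if len(df) < n0:
        logger.warning("dropped %d ortholog rows with blank symbols", n0 - len(df))
    return OrthologTable(pairs=df.reset_index(drop=True), species=species)


def write_orthologs(table: OrthologTable, path: str | Path) -> None:
    table.pairs.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: tab-separated ``name  description  gene...`` lines.

    Set order is preserved; empty gene fields are dropped; duplicate set
    names or lines with fewer than three fields are rejected.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has <3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = genes
    return GeneSetCollection(sets=sets, provenance=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_marker_table(table: pd.DataFrame, path: str | Path) -> None:
    """Export a marker/DEG table with the fixed public column order."""
    missing = [c for c in MARKER_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"marker table missing columns: {missing}")
    extra = [c for c in table.columns if c not in MARKER_COLUMNS]
    table[list(MARKER_COLUMNS) + extra].to_csv(path, sep="\t", index=False, float_format="%.6g")
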