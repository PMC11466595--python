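"""Core in-memory containers shared by all pipeline stages.

The unit of analysis is a sparse gene × cell matrix keyed by gene *symbol*
(case-sensitive strings; no stable numeric IDs are assumed), a per-cell
metadata table aligned to its columns, a per-species ortholog table mapping
source symbols to human symbols, and named gene-set collections.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: Required columns of a cell metadata table.
CELL_COLUMNS = ("cell_id", "species", "sample", "cell_type", "sex", "condition")

SEX_VALUES = ("male", "female", "unknown")
CONDITION_VALUES = ("healthy", "asthma")


@dataclass
class CountMatrix:
    """Sparse gene × cell expression matrix tagged with species and namespace.

    Parameters
    ----------
    x
        Sparse matrix, rows are genes, columns are cells. Values are
        non-negative UMI counts (``space == "counts"``) or log-normalized
        expression (``space == "lognorm"``).
    genes, cells
        Unique gene symbols / cell barcodes matching the matrix rows/columns.
    species
        Species label, e.g. ``"human"`` or ``"mouse"``.
    namespace
        ``"source"`` for native gene symbols, ``"human"`` after ortholog
        conversion (human data is born in the ``"human"`` namespace).
    """

    x: sp.csr_matrix
    genes: np.ndarray
    cells: np.ndarray
    species: str
    namespace: str = "source"
    space: str = "counts"

    def __post_init__(self) -> None:
        self.x = sp.csr_matrix(self.x)
        self.genes = np.asarray(self.genes, dtype=object)
        self.cells = np.asarray(self.cells, dtype=object)
        if self.x.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"matrix shape {self.x.shape} inconsistent with "
                f"{len(self.genes)} genes / {len(self.cells)} cells"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols in matrix")
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell barcodes in matrix")
        if self.namespace not in ("source", "human"):
            raise ValueError(f"unknown namespace {self.namespace!r}")
        if self.space not in ("counts", "lognorm"):
            raise ValueError(f"unknown space {self.space!r}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gene_index(self, symbols: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.genes)}
        missing = [s for s in symbols if s not in lookup]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}...")
        return np.array([lookup[s] for s in symbols], dtype=int)

    def cell_index(self, barcodes: Iterable[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cells)}
        missing = [b for b in barcodes if b not in lookup]
        if missing:
            raise KeyError(f"cells absent from matrix: {missing[:5]}...")
        return np.array([lookup[b] for b in barcodes], dtype=int)

    def subset_genes(self, symbols: Sequence[str]) -> "CountMatrix":
        idx = self.gene_index(symbols)
        return replace(self, x=self.x[idx], genes=self.genes[idx])

    def subset_cells(self, barcodes: Sequence[str]) -> "CountMatrix":
        idx = self.cell_index(barcodes)
        return replace(self, x=self.x[:, idx], cells=self.cells[idx])

    def dense(self) -> np.ndarray:
        return np.asarray(self.x.todense())


def validate_cell_table(table: pd.DataFrame, matrix: CountMatrix | None = None) -> pd.DataFrame:
    """Check a cell metadata table: required columns, value domains, and
    (optionally) exact alignment with a matrix's columns."""
    missing = [c for c in CELL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    if table["cell_id"].duplicated().any():
        raise ValueError("duplicate cell_id in cell table")
    bad_sex = set(table["sex"]) - set(SEX_VALUES)
    if bad_sex:
        raise ValueError(f"invalid sex values: {sorted(bad_sex)}")
    bad_cond = set(table["condition"]) - set(CONDITION_VALUES)
    if bad_cond:
        raise ValueError(f"invalid condition values: {sorted(bad_cond)}")
    if table["cell_type"].isna().any():
        raise ValueError("missing cell_type after annotation join")
    if matrix is not None:
        if set(table["cell_id"]) != set(matrix.cells):
            raise ValueError("cell table ids do not match matrix columns")
    return table


def align_cell_table(table: pd.DataFrame, matrix: CountMatrix) -> pd.DataFrame:
    """Return the table reordered to the matrix's column order."""
    validate_cell_table(table, matrix)
    return table.set_index("cell_id").loc[matrix.cells].reset_index()


@dataclass
class OrthologTable:
    """Many-to-many source-symbol → human-symbol map for one species."""

    pairs: pd.DataFrame  # columns: source_symbol, human_symbol
    species: str

    def __post_init__(self) -> None:
        need = {"source_symbol", "human_symbol"}
        if not need.issubset(self.pairs.columns):
            raise ValueError(f"ortholog table needs columns {sorted(need)}")
        self.pairs = self.pairs[["source_symbol", "human_symbol"]].copy()
        if self.pairs.duplicated().any():
            self.pairs = self.pairs.drop_duplicates(ignore_index=True)
        if (self.pairs["source_symbol"] == "").any() or (self.pairs["human_symbol"] == "").any():
            raise ValueError("empty symbols in ortholog table")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class GeneSetCollection:
    """Ordered, uniquely named collection of gene-symbol sets (GMT semantics)."""

    sets: dict[str, list[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with `universe`; drop emptied sets."""
        uni = set(universe)
        kept = {
            name: [g for g in genes if g in uni]
            for name, genes in self.sets.items()
        }
        kept = {n: g for n, g in kept.items() if g}
        return GeneSetCollection(sets=kept, provenance=self.provenance)
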