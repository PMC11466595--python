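"""Quality filtering and log-normalization of droplet count matrices.

Low-quality cells are removed first (library size below a floor, or
mitochondrial fraction above a ceiling), then genes detected in too few of
the remaining cells. Normalization is the standard per-cell depth scaling:
``ln(1 + scale_factor * count / cell_total)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class QCParams:
    """Cell/gene quality thresholds.

    Defaults follow common droplet practice: ≥200 UMIs per cell, each gene
    detected in ≥3 cells, and at most 10% mitochondrial counts (the
    stringent end of the usual 10–30% range; raise per dataset as needed).
    Mitochondrial genes are recognized by symbol prefix.
    """

    min_umi_per_cell: int = 200
    min_cells_per_gene: int = 3
    max_mito_fraction: float = 0.10
    mito_prefixes: tuple[str, ...] = ("MT-", "mt-", "Mt-")

    def __post_init__(self) -> None:
        if self.min_umi_per_cell <= 0 or self.min_cells_per_gene <= 0:
            raise ValueError("QC thresholds must be positive")
        if not 0 < self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in (0, 1]")


@dataclass
class NormParams:
    scale_factor: float = 10_000.0  # counts-per-scale_factor before log1p (natural log)

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")


def qc_filter(
    m: CountMatrix,
    table: pd.DataFrame,
    params: QCParams = QCParams(),
    exclude_cells: set[str] | None = None,
) -> tuple[CountMatrix, pd.DataFrame, dict]:
    """Apply cell-level then gene-level quality filters.

    Cells failing the UMI floor or the mitochondrial ceiling (strict >)
    are removed first, as is any precomputed exclusion list (e.g. doublets
    called upstream); genes detected in fewer than ``min_cells_per_gene``
    of the surviving cells are removed second. Returns the filtered matrix,
    the matching cell table, and a report of removal counts.
    """
    if m.space != "counts":
        raise ValueError("qc_filter expects a count-space matrix")
    totals = np.asarray(m.x.sum(axis=0)).ravel()
    is_mito = np.array([g.startswith(params.mito_prefixes) for g in m.genes])
    mito_counts = (
        np.asarray(m.x[is_mito].sum(axis=0)).ravel() if is_mito.any() else np.zeros(m.n_cells)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)

    low_umi = totals < params.min_umi_per_cell
    high_mito = mito_frac > params.max_mito_fraction
    excluded = (
        np.array([c in exclude_cells for c in m.cells])
        if exclude_cells
        else np.zeros(m.n_cells, dtype=bool)
    )
    keep_cells = ~(low_umi | high_mito | excluded)
    if not keep_cells.any():
        raise ValueError("qc_filter removed every cell")

    mx = m.x[:, keep_cells]
    detected = np.asarray((mx > 0).sum(axis=1)).ravel()
    keep_genes = detected >= params.min_cells_per_gene

    report = {
        "cells_in": int(m.n_cells),
        "cells_low_umi": int(low_umi.sum()),
        "cells_high_mito": int((high_mito & ~low_umi).sum()),
        "cells_excluded_list": int((excluded & ~low_umi & ~high_mito).sum()),
        "cells_out": int(keep_cells.sum()),
        "genes_in": int(m.n_genes),
        "genes_low_detection": int((~keep_genes).sum()),
        "genes_out": int(keep_genes.sum()),
    }
    logger.info("qc_filter %s: %s", m.species, report)

    out = replace(m, x=sp.csr_matrix(mx[keep_genes]), genes=m.genes[keep_genes],
                  cells=m.cells[keep_cells])
    kept_ids = set(out.cells)
    table_out = table[table["cell_id"].isin(kept_ids)].reset_index(drop=True)
    return out, table_out, report


def normalize(m: CountMatrix, params: NormParams = NormParams()) -> CountMatrix:
    """Depth-normalize and log-transform: ``ln(1 + sf * count / total)``."""
    if m.space != "counts":
        raise ValueError("normalize expects a count-space matrix")
    totals = np.asarray(m.x.sum(axis=0)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cells with zero total counts: {list(m.cells[zero[:5]])}")
    x = sp.csc_matrix(m.x, dtype=float)
    scale = params.scale_factor / totals
    x = x @ sp.diags(scale)
    x.data = np.log1p(x.data)
    return replace(m, x=sp.csr_matrix(x), space="lognorm")
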