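"""Marker-gene and DEG detection with the stringent three-part filter.

Per-gene two-group comparisons use the two-sided Wilcoxon rank-sum test
(exact enumeration for small groups, tie-corrected normal approximation
otherwise) and a count-scale log2 fold change. A gene is retained only if
|fold-change| > 1.5, adjusted p < 0.05, and it is detected in more than
25% of cells in at least one of the two groups.

Contexts: one-vs-rest per cell type ("celltype"), female vs male within
each cell type ("sex"), and asthma vs healthy within each cell type
("condition"). The accumulated-logFC volcano statistic sums a gene's
significant per-cell-type fold changes and counts those cell types.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix

logger = logging.getLogger(__name__)

#: |log2 fold-change| threshold equivalent to a 1.5-fold change.
LOG2FC_THRESHOLD = math.log2(1.5)
PADJ_THRESHOLD = 0.05
PCT_THRESHOLD = 0.25

#: Group sizes below this use exact enumeration instead of the normal
#: approximation.
EXACT_MAX_N = 8

_CONTEXTS = {
    "celltype": None,
    "sex": ("female", "male"),
    "condition": ("asthma", "healthy"),
}


def rank_sum_test(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (p, rank-sum statistic).

    For min group size below 8 the p-value is computed by exhaustive
    enumeration of all label splits of the pooled sample (ties handled via
    midranks; two-sided tail counts splits whose rank sum deviates from
    its null mean at least as much as observed). Larger groups use the
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0, float(scipy.stats.rankdata(pooled)[: len(a)].sum())
    ranks = scipy.stats.rankdata(pooled)
    w_obs = float(ranks[: len(a)].sum())
    if min(len(a), len(b)) < EXACT_MAX_N:
        n, na = len(pooled), len(a)
        mu = na * (n + 1) / 2
        dev_obs = abs(w_obs - mu)
        hits = total = 0
        for idx in combinations(range(n), na):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= dev_obs - 1e-9:
                hits += 1
        return hits / total, w_obs
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue), w_obs


def log2_fold_change(group_a, group_b) -> float:
    """Count-scale log2 fold change of A over B from log-normalized values.

    Values are back-transformed with expm1, averaged per group, and a
    pseudocount of 1 keeps the ratio finite:
    ``log2((mean(expm1 a) + 1) / (mean(expm1 b) + 1))``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    return float(np.log2((np.expm1(a).mean() + 1) / (np.expm1(b).mean() + 1)))


def bh_adjust(p_values, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: Benjamini–Hochberg (default) or Bonferroni."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    raise ValueError(f"unknown adjustment {method!r}")


def passes_filter(table: pd.DataFrame) -> pd.Series:
    """Boolean mask of rows passing the three-part retention filter."""
    return (
        (table["logFC"].abs() > LOG2FC_THRESHOLD)
        & (table["p_adj"] < PADJ_THRESHOLD)
        & (table[["pct_1", "pct_2"]].max(axis=1) > PCT_THRESHOLD)
    )


def _vectorized_test(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Per-gene two-sided rank-sum p for gene × cell blocks of two groups."""
    na, nb = xa.shape[1], xb.shape[1]
    if min(na, nb) < EXACT_MAX_N:
        return np.array([rank_sum_test(xa[g], xb[g])[0] for g in range(xa.shape[0])])
    with np.errstate(invalid="ignore"):
        res = scipy.stats.mannwhitneyu(xa, xb, alternative="two-sided",
                                       method="asymptotic", axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    # constant genes: the statistic degenerates; define p = 1
    tied = (np.ptp(xa, axis=1) == 0) & (np.ptp(xb, axis=1) == 0) & (xa[:, 0] == xb[:, 0])
    p[tied] = 1.0
    return np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)


def _compare_groups(x: np.ndarray, genes, group: str, mask_a, mask_b,
                    p_adjust: str) -> pd.DataFrame:
    xa, xb = x[:, mask_a], x[:, mask_b]
    p = _vectorized_test(xa, xb)
    ea, eb = np.expm1(xa).mean(axis=1), np.expm1(xb).mean(axis=1)
    logfc = np.log2((ea + 1) / (eb + 1))
    out = pd.DataFrame({
        "gene": genes,
        "group": group,
        "logFC": logfc,
        "p": p,
        "p_adj": bh_adjust(p, method=p_adjust),
        "pct_1": (xa > 0).mean(axis=1),
        "pct_2": (xb > 0).mean(axis=1),
    })
    return out


def find_markers(
    m: CountMatrix,
    table: pd.DataFrame,
    context: str = "celltype",
    *,
    p_adjust: str = "bh",
    min_cells: int = 3,
    filtered: bool = True,
) -> pd.DataFrame:
    """Marker / DEG tables for one species.

    ``celltype`` runs one-vs-rest per cell type (positive logFC = up in
    the type). ``sex`` compares female vs male and ``condition`` asthma
    vs healthy, within each cell type; the ``group`` column then names the
    cell type and logFC is signed toward the first label. Adjustment is
    applied across genes within each comparison. Groups below
    ``min_cells`` are skipped with a warning. With ``filtered=True`` only
    rows passing the retention filter are returned.
    """
    if m.space != "lognorm":
        raise ValueError("find_markers expects a log-normalized matrix")
    if context not in _CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    meta = table.set_index("cell_id").loc[list(m.cells)]
    x = m.dense()
    types = meta["cell_type"].to_numpy()
    pieces: list[pd.DataFrame] = []

    if context == "celltype":
        for ct in sorted(pd.unique(types)):
            mask = types == ct
            if mask.sum() < min_cells or (~mask).sum() < min_cells:
                logger.warning("skipping cell type %r: group below %d cells", ct, min_cells)
                continue
            pieces.append(_compare_groups(x, m.genes, ct, mask, ~mask, p_adjust))
    else:
        label_1, label_2 = _CONTEXTS[context]
        col = "sex" if context == "sex" else "condition"
        labels = meta[col].to_numpy()
        for ct in sorted(pd.unique(types)):
            mask_a = (types == ct) & (labels == label_1)
            mask_b = (types == ct) & (labels == label_2)
            if mask_a.sum() < min_cells or mask_b.sum() < min_cells:
                logger.warning("skipping cell type %r: a %s group below %d cells",
                               ct, col, min_cells)
                continue
            pieces.append(_compare_groups(x, m.genes, ct, mask_a, mask_b, p_adjust))

    if not pieces:
        return pd.DataFrame(columns=["gene", "group", "logFC", "p", "p_adj", "pct_1", "pct_2"])
    out = pd.concat(pieces, ignore_index=True)
    if filtered:
        out = out[passes_filter(out)].reset_index(drop=True)
    return out


def common_markers(tables: dict[str, pd.DataFrame], top_n: int = 5) -> dict[str, dict]:
    """Cross-species marker catalogs per cell type.

    For each cell type present in every species' table: the intersection
    of retained marker genes, genes retained in exactly one species, and
    the top ``top_n`` common genes ranked by the conservative minimum
    |logFC| across species. Cell types missing from some species are
    reported separately and excluded from the common computation.
    """
    species = sorted(tables)
    per_sp_types = {sp: set(tables[sp]["group"]) for sp in species}
    shared = set.intersection(*per_sp_types.values()) if species else set()
    skipped = sorted(set.union(*per_sp_types.values()) - shared) if species else []
    out: dict[str, dict] = {}
    for ct in sorted(shared):
        gene_sets = {
            sp: set(tables[sp].loc[tables[sp]["group"] == ct, "gene"]) for sp in species
        }
        common = set.intersection(*gene_sets.values())
        counts: dict[str, int] = {}
        for sp in species:
            for g in gene_sets[sp]:
                counts[g] = counts.get(g, 0) + 1
        specific = {
            sp: sorted(g for g in gene_sets[sp] if counts[g] == 1) for sp in species
        }
        min_fc = {}
        for g in common:
            fcs = [
                tables[sp].loc[(tables[sp]["group"] == ct) & (tables[sp]["gene"] == g),
                               "logFC"].abs().max()
                for sp in species
            ]
            min_fc[g] = min(fcs)
        top = sorted(common, key=lambda g: (-min_fc[g], g))[:top_n]
        out[ct] = {"common": sorted(common), "specific": specific, "top_common": top}
    if skipped:
        out["_skipped_cell_types"] = skipped
    return out


def volcano_summary(table: pd.DataFrame, top_n: int = 5) -> tuple[pd.DataFrame, list[str]]:
    """Accumulated-logFC summary of a filtered per-cell-type DEG table.

    Per gene: the sum of its signed log2 fold changes over the cell types
    where it passed the filter, and the count of those cell types. Genes
    significant nowhere are absent. Returns the summary sorted by
    |accumulated| descending and the top ``top_n`` gene names.
    """
    if table.empty:
        return (
            pd.DataFrame(columns=["gene", "accumulated_logFC", "n_significant_types", "direction"]),
            [],
        )
    grouped = table.groupby("gene", sort=True).agg(
        accumulated_logFC=("logFC", "sum"),
        n_significant_types=("logFC", "size"),
    ).reset_index()
    grouped["direction"] = np.where(grouped["accumulated_logFC"] >= 0, "up", "down")
    grouped = grouped.sort_values(
        "accumulated_logFC", key=lambda s: s.abs(), ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    return grouped, grouped["gene"].head(top_n).tolist()
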