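"""Simplified regulon inference and per-cell activity.

A regulon is a transcription factor (TF) plus inferred target genes. The
workflow mirrors the SCENIC idea at reduced scope: (1) co-expression
importance of each TF for each candidate target from a seeded tree-ensemble
regression (deterministic squared-Spearman fallback available); (2) target
retention requires both an importance above threshold and a *positive*
correlation with the TF — repressive edges and motif-database pruning are
deliberately out of scope, with a slot for a user-supplied TF→candidate
prior table instead; (3) per-cell activity is the normalized area under
the recovery curve of regulon genes along the cell's expression ranking,
up to a top-rank cutoff (AUCell-style), bounded in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.ensemble import ExtraTreesRegressor

from ._rng import child_seed, substream
from .containers import CountMatrix
from .similarity import choose_correlation

logger = logging.getLogger(__name__)


@dataclass
class RegulonSet:
    """Per-TF target lists with importance weights, for one species."""

    regulons: dict[str, pd.DataFrame]  # TF -> DataFrame(target, weight, correlation)
    species: str
    params: dict = field(default_factory=dict)

    def tfs(self) -> list[str]:
        return sorted(self.regulons)

    def targets(self, tf: str) -> list[str]:
        return self.regulons[tf]["target"].tolist()


def infer_importance(
    m: CountMatrix,
    tf_list: list[str],
    seed: int = 0,
    method: str = "trees",
    n_trees: int = 50,
    prior: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """TF → target co-expression importance (TF rows, target columns).

    ``trees``: each non-TF gene is regressed on all TF expressions with a
    seeded extra-trees ensemble; the TF's importance for that target is
    its impurity-based feature importance (non-negative, summing to ~1 per
    target). ``correlation``: squared Spearman correlation, deterministic.
    An optional prior table (columns tf, target) restricts which TF→target
    importances are kept; others are zeroed.
    """
    tfs = [tf for tf in tf_list if tf in set(m.genes)]
    if not tfs:
        raise ValueError("no TFs from the list are present in the matrix")
    if m.n_cells < 30:
        raise ValueError("need at least 30 cells for importance inference")
    tfs = sorted(tfs)
    targets = sorted(set(m.genes) - set(tfs))
    x_tf = m.subset_genes(tfs).dense().T  # cells × TFs
    x_tg = m.subset_genes(targets).dense()  # targets × cells

    weights = np.zeros((len(tfs), len(targets)))
    if method == "trees":
        for j, target in enumerate(targets):
            y = x_tg[j]
            if np.ptp(y) == 0:
                continue  # constant gene: no signal, zero importance
            model = ExtraTreesRegressor(
                n_estimators=n_trees,
                max_features="sqrt",
                random_state=child_seed(seed, "genie", target),
                n_jobs=1,
            )
            model.fit(x_tf, y)
            weights[:, j] = model.feature_importances_
    elif method == "correlation":
        for j in range(len(targets)):
            y = x_tg[j]
            if np.ptp(y) == 0:
                continue
            with np.errstate(invalid="ignore"):
                rho = np.array([
                    scipy.stats.spearmanr(x_tf[:, i], y).statistic for i in range(len(tfs))
                ])
            weights[:, j] = np.nan_to_num(rho) ** 2
    else:
        raise ValueError(f"unknown method {method!r}")

    out = pd.DataFrame(weights, index=tfs, columns=targets)
    if prior is not None:
        allowed = set(zip(prior["tf"], prior["target"]))
        mask = np.array([
            [(tf, tg) in allowed for tg in targets] for tf in tfs
        ])
        out = out.where(mask, 0.0)
    return out


def calibrate_min_weight(
    m: CountMatrix, tf_list: list[str], seed: int = 0, method: str = "trees",
    n_trees: int = 50, quantile: float = 0.99,
) -> pd.Series:
    """Null-based per-TF importance thresholds.

    Every TF's expression is shuffled across cells so no true
    co-expression survives, importances are re-inferred, and each TF gets
    the chosen quantile of its own null importance distribution — TFs
    differ in how much spurious importance they soak up, so a single
    global cutoff would be biased toward the noisiest TF.
    """
    tfs = sorted(tf for tf in tf_list if tf in set(m.genes))
    rng = substream(seed, "calibrate")
    x = m.dense()
    idx = {g: i for i, g in enumerate(m.genes)}
    for tf in tfs:
        x[idx[tf]] = rng.permutation(x[idx[tf]])
    null_m = CountMatrix(x=x, genes=m.genes, cells=m.cells,
                         species=m.species, namespace=m.namespace, space=m.space)
    null_w = infer_importance(null_m, tfs, seed=seed, method=method, n_trees=n_trees)
    return null_w.quantile(quantile, axis=1)


def build_regulons(
    weights: pd.DataFrame,
    m: CountMatrix,
    min_weight: float | pd.Series,
    min_targets: int = 10,
) -> RegulonSet:
    """Retain targets with importance ≥ threshold and positive Spearman
    correlation with their TF; drop TFs with fewer than ``min_targets``.

    ``min_weight`` may be a scalar or a per-TF Series (as produced by
    :func:`calibrate_min_weight`).
    """
    idx = {g: i for i, g in enumerate(m.genes)}
    x = m.dense()
    regulons: dict[str, pd.DataFrame] = {}
    for tf in weights.index:
        tf_min = float(min_weight[tf]) if isinstance(min_weight, pd.Series) else float(min_weight)
        tf_expr = x[idx[tf]]
        rows = []
        for target in weights.columns:
            w = float(weights.loc[tf, target])
            if target == tf or w < tf_min:
                continue
            with np.errstate(invalid="ignore"):
                rho = scipy.stats.spearmanr(tf_expr, x[idx[target]]).statistic
            if np.isnan(rho) or rho <= 0:
                continue
            rows.append({"target": target, "weight": w, "correlation": float(rho)})
        if len(rows) >= min_targets:
            df = pd.DataFrame(rows).sort_values(
                ["weight", "target"], ascending=[False, True], kind="mergesort"
            ).reset_index(drop=True)
            regulons[tf] = df
    return RegulonSet(
        regulons=regulons,
        species=m.species,
        params={"min_weight": min_weight, "min_targets": min_targets},
    )


def auc_activity(
    m: CountMatrix,
    regulons: RegulonSet,
    rank_threshold_frac: float = 0.05,
    tie_seed: int = 0,
) -> pd.DataFrame:
    """Per-cell regulon activity from the gene-rank recovery curve.

    Genes are ranked per cell by descending expression (ties broken by a
    seeded jitter far below the data resolution). With cutoff
    ``R = ceil(frac · n_genes)``, the activity is the area under the
    cumulative regulon-gene recovery step curve over ranks 1..R, divided
    by the maximum achievable area, so values lie in [0, 1]. Regulons with
    no targets present in the matrix are omitted with a warning.
    """
    if not 0 < rank_threshold_frac <= 1:
        raise ValueError("rank_threshold_frac must be in (0, 1]")
    x = m.dense().astype(float)
    rng = substream(tie_seed, "aucell")
    x = x + rng.uniform(0, 1e-9, size=x.shape)
    # rank positions per cell: ranks[g, c] = 0 for the most expressed gene
    order = np.argsort(-x, axis=0, kind="stable")
    ranks = np.empty_like(order)
    cols = np.arange(x.shape[1])[None, :]
    ranks[order, np.broadcast_to(cols, order.shape)] = np.arange(x.shape[0])[:, None]

    R = int(np.ceil(rank_threshold_frac * m.n_genes))
    idx = {g: i for i, g in enumerate(m.genes)}
    rows, names = [], []
    for tf in regulons.tfs():
        present = [g for g in {tf, *regulons.targets(tf)} if g in idx]
        n_missing = len({tf, *regulons.targets(tf)}) - len(present)
        if n_missing:
            logger.warning("regulon %s: %d genes absent from matrix", tf, n_missing)
        if not present:
            logger.warning("regulon %s: no genes present, activity undefined", tf)
            continue
        gidx = np.array([idx[g] for g in present])
        gr = ranks[gidx]  # member ranks per cell, 0-based
        # area under the recovery step curve: a member at 0-based rank r
        # raises the curve for the remaining (R - r) unit-width steps
        area = np.where(gr < R, R - gr, 0).sum(axis=0)
        m_eff = len(present)
        max_area = sum(R - r for r in range(min(m_eff, R)))
        rows.append(area / max_area)
        names.append(tf)
    return pd.DataFrame(rows, index=names, columns=m.cells)


def cross_species_regulons(sets: dict[str, RegulonSet]) -> tuple[dict[str, int], list[str]]:
    """Venn partition of inferred TFs across species, plus the common list.

    Returns region counts keyed by "+"-joined species subsets (every
    non-empty subset of species appears, counting TFs inferred in exactly
    that subset) and the TFs present in all species.
    """
    species = sorted(sets)
    membership: dict[str, set[str]] = {}
    for sp in species:
        for tf in sets[sp].tfs():
            membership.setdefault(tf, set()).add(sp)
    counts: dict[str, int] = {}
    for r in range(1, len(species) + 1):
        for combo in combinations(species, r):
            key = "+".join(combo)
            counts[key] = sum(1 for tfs in membership.values() if tfs == set(combo))
    common = sorted(tf for tf, sps in membership.items() if len(sps) == len(species))
    return counts, common


def regulon_activity_correlation(
    activities: dict[str, pd.DataFrame],
    tables: dict[str, pd.DataFrame],
    level: str = "cell_type",
    reference: str = "human",
) -> pd.DataFrame:
    """Correlate mean common-TF activity per cell group against the reference.

    For each cell group at the chosen annotation level, each species'
    per-TF mean activity vector (over the TFs inferred in *all* species)
    is correlated with the reference species' vector; the method is chosen
    by the normality gate. Rows with p ≥ 0.05 are flagged ``not_shown``.
    Groups absent from a species are skipped and reported in the log.
    """
    if reference not in activities:
        raise ValueError(f"reference species {reference!r} missing")
    common_tfs = sorted(set.intersection(*(set(a.index) for a in activities.values())))
    if len(common_tfs) < 3:
        raise ValueError("fewer than 3 TFs common to all species")

    def group_means(sp: str) -> pd.DataFrame:
        act = activities[sp].loc[common_tfs]
        meta = tables[sp].set_index("cell_id").loc[list(act.columns), level]
        return act.T.groupby(meta.to_numpy()).mean().T  # TFs × groups

    means = {sp: group_means(sp) for sp in activities}
    ref = means[reference]
    rows = []
    for sp in sorted(activities):
        if sp == reference:
            continue
        for group in ref.columns:
            if group not in means[sp].columns:
                logger.warning("group %r absent in %s: skipped", group, sp)
                continue
            a = ref[group].to_numpy()
            b = means[sp][group].to_numpy()
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                logger.warning("constant activity vector for %r in %s/%s", group, reference, sp)
                continue
            method = choose_correlation(a, b)
            if method == "pearson":
                r, p = scipy.stats.pearsonr(a, b)
            else:
                r, p = scipy.stats.spearmanr(a, b)
            rows.append({
                "species": sp, "group": group, "method": method,
                "r": float(r), "p": float(p), "not_shown": bool(p >= 0.05),
            })
    return pd.DataFrame(rows)
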