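"""Cross-species similarity: pseudo-profiles, the Mantel permutation test,
gene-set module scoring, and normality-gated correlation.

A *pseudo-profile* summarizes a species as, per (cell type, gene), the mean
log-normalized expression and the fraction of sampled cells expressing the
gene. Species are compared by (1) the Mantel test between their within-
species cell-type distance matrices and (2) correlation of gene-set module
scores, with Pearson vs Spearman chosen by a Shapiro–Wilk normality gate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
import scipy.spatial.distance
import scipy.stats

from ._rng import substream
from .containers import CountMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class PseudoProfile:
    """Cell-type × gene summary of a normalized matrix.

    ``mean`` and ``pct`` are DataFrames indexed by cell type with gene
    columns; ``pct`` is the detection fraction in [0, 1].
    """

    mean: pd.DataFrame
    pct: pd.DataFrame
    species: str

    def __post_init__(self) -> None:
        if not self.mean.index.equals(self.pct.index) or not self.mean.columns.equals(self.pct.columns):
            raise ValueError("mean and pct grids differ")

    def restrict(self, genes: list[str], cell_types: list[str]) -> "PseudoProfile":
        return PseudoProfile(
            mean=self.mean.loc[cell_types, genes],
            pct=self.pct.loc[cell_types, genes],
            species=self.species,
        )


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int


def pseudo_profile(m: CountMatrix, table: pd.DataFrame, cells: list[str]) -> PseudoProfile:
    """Mean expression and detection fraction per cell type over `cells`."""
    if m.space != "lognorm":
        raise ValueError("pseudo_profile expects a log-normalized matrix")
    sub = m.subset_cells(cells)
    types = table.set_index("cell_id").loc[list(sub.cells), "cell_type"]
    x = sub.dense()
    rows_mean, rows_pct, index = [], [], []
    for ct in sorted(types.unique()):
        mask = (types == ct).to_numpy()
        if not mask.any():
            raise ValueError(f"empty selection for cell type {ct!r}")
        block = x[:, mask]
        rows_mean.append(block.mean(axis=1))
        rows_pct.append((block > 0).mean(axis=1))
        index.append(ct)
    return PseudoProfile(
        mean=pd.DataFrame(rows_mean, index=index, columns=sub.genes),
        pct=pd.DataFrame(rows_pct, index=index, columns=sub.genes),
        species=m.species,
    )


def _zscale_columns(block: np.ndarray) -> np.ndarray:
    """Standardize each feature (gene) across cell types; zero-variance
    features carry no pattern information and are set to 0."""
    mu = block.mean(axis=0, keepdims=True)
    sd = block.std(axis=0, keepdims=True)
    sd[sd == 0] = np.inf
    return (block - mu) / sd


def profile_distance(p: PseudoProfile, feature: str = "both",
                     metric: str = "correlation") -> pd.DataFrame:
    """Distance between cell-type feature vectors.

    ``feature`` selects the mean-expression block, the detection block, or
    their concatenation ("both"). The default metric is correlation
    distance, ``1 − Pearson r`` between type feature vectors, which is
    insensitive to per-type scale and far more stable under finite-cell
    sampling noise than a Euclidean embedding; ``euclidean`` (on per-gene
    z-scaled features) is kept as an alternative. Result is square,
    symmetric, zero-diagonal.
    """
    if len(p.mean.index) < 3:
        raise ValueError("need at least 3 cell types for a distance matrix")
    blocks = {"expr": p.mean.to_numpy(float), "pct": p.pct.to_numpy(float)}
    if feature == "both":
        raw = np.hstack([blocks["expr"], blocks["pct"]])
    elif feature in blocks:
        raw = blocks[feature]
    else:
        raise ValueError(f"unknown feature {feature!r}")
    if not np.isfinite(raw).all():
        raise ValueError("non-finite profile features")
    if metric == "correlation":
        if (raw.std(axis=1) == 0).any():
            raise ValueError("constant type profile: correlation distance undefined")
        d = 1.0 - np.corrcoef(raw)
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2.0
    elif metric == "euclidean":
        feats = (np.hstack([_zscale_columns(b) for b in blocks.values()])
                 if feature == "both" else _zscale_columns(raw))
        d = scipy.spatial.distance.squareform(scipy.spatial.distance.pdist(feats))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return pd.DataFrame(d, index=p.mean.index, columns=p.mean.index)


def _tri(d: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(d.shape[0], k=-1)
    return d[i, j]


def _check_distance(d: np.ndarray) -> None:
    if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] < 3:
        raise ValueError("distance matrix must be square with dimension >= 3")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix not symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix diagonal not zero")


def mantel(dA, dB, n_perm: int = 999, seed: int = 0) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    r is the Pearson correlation of the lower-triangle entries; the
    one-sided p-value counts simultaneous row/column permutations of the
    second matrix whose r meets or exceeds the observed one, with the +1
    correction ``p = (1 + #{r_perm >= r}) / (n_perm + 1)``.
    """
    dA = np.asarray(dA, dtype=float)
    dB = np.asarray(dB, dtype=float)
    _check_distance(dA)
    _check_distance(dB)
    if dA.shape != dB.shape:
        raise ValueError("distance matrices differ in dimension")
    a = _tri(dA)
    b = _tri(dB)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a distance triangle; Mantel r undefined")

    az = (a - a.mean()) / a.std()
    r_obs = float(np.dot(az, (b - b.mean()) / b.std()) / len(a))

    n = dA.shape[0]
    rng = substream(seed, "mantel")
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    i, j = np.tril_indices(n, k=-1)
    perm_entries = dB[perms[:, i], perms[:, j]]  # (n_perm, n_pairs)
    pe = perm_entries - perm_entries.mean(axis=1, keepdims=True)
    sd = pe.std(axis=1)
    sd[sd == 0] = np.inf
    r_perm = (pe / sd[:, None]) @ az / len(a)
    p = (1 + int(np.sum(r_perm >= r_obs - 1e-12))) / (n_perm + 1)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm, seed=seed)


def mantel_exact(dA, dB) -> tuple[float, float]:
    """Exhaustive-permutation Mantel p (all n! relabelings); small n only."""
    dA = np.asarray(dA, dtype=float)
    dB = np.asarray(dB, dtype=float)
    _check_distance(dA)
    _check_distance(dB)
    n = dA.shape[0]
    a = _tri(dA)
    az = (a - a.mean()) / a.std()
    i, j = np.tril_indices(n, k=-1)

    def _r(perm):
        b = dB[np.ix_(perm, perm)][i, j]
        return float(np.dot(az, (b - b.mean()) / b.std()) / len(a))

    r_obs = _r(np.arange(n))
    rs = [_r(np.array(p)) for p in permutations(range(n))]
    p = sum(r >= r_obs - 1e-12 for r in rs) / len(rs)
    return r_obs, p


def species_similarity(
    profiles: dict[str, PseudoProfile],
    n_perm: int = 999,
    seed: int = 0,
    feature: str = "both",
    reference: str = "human",
) -> pd.DataFrame:
    """Pairwise Mantel similarity between species pseudo-profiles.

    All profiles must share the same (cell type, gene) grid. Rows pairing
    the reference species come first, sorted by descending r.
    """
    names = sorted(profiles)
    grid = (tuple(profiles[names[0]].mean.index), tuple(profiles[names[0]].mean.columns))
    for nm in names[1:]:
        if (tuple(profiles[nm].mean.index), tuple(profiles[nm].mean.columns)) != grid:
            raise ValueError(f"profile grid for {nm!r} differs")
    dists = {nm: profile_distance(profiles[nm], feature).to_numpy() for nm in names}
    rows = []
    for a, b in combinations(names, 2):
        res = mantel(dists[a], dists[b], n_perm=n_perm, seed=seed)
        rows.append({"species_a": a, "species_b": b, "r": res.r, "p": res.p, "n_perm": n_perm})
    out = pd.DataFrame(rows)
    out["vs_reference"] = (out["species_a"] == reference) | (out["species_b"] == reference)
    out = out.sort_values(
        ["vs_reference", "r"], ascending=[False, False], kind="mergesort"
    ).reset_index(drop=True)
    return out


def module_scores(
    m: CountMatrix,
    sets: GeneSetCollection,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell gene-set scores against expression-matched controls.

    Genes are ranked by mean expression across cells and split into
    ``n_bins`` equal-frequency bins. For each set gene, ``n_ctrl`` control
    genes are drawn from its bin (with replacement when the bin is
    smaller); the cell's score is the mean over set genes minus the mean
    over the pooled controls. Returns a set × cell DataFrame.
    """
    if m.space != "lognorm":
        raise ValueError("module_scores expects a log-normalized matrix")
    if m.n_genes < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} genes")
    n_before = len(sets)
    sets = sets.restrict(m.genes)
    if len(sets) < n_before:
        logger.warning("dropped %d gene sets empty after intersection", n_before - len(sets))
    if not sets.sets:
        raise ValueError("all gene sets empty after intersecting with matrix genes")

    x = m.dense()
    gene_mean = x.mean(axis=1)
    order = np.argsort(gene_mean, kind="stable")
    ranks = np.empty(m.n_genes, dtype=int)
    ranks[order] = np.arange(m.n_genes)
    bin_of = ranks * n_bins // m.n_genes  # equal-frequency bins by mean expression
    bins = {b: np.flatnonzero(bin_of == b) for b in range(n_bins)}

    gene_idx = {g: i for i, g in enumerate(m.genes)}
    scores = np.zeros((len(sets.sets), m.n_cells))
    for si, (name, genes) in enumerate(sets.sets.items()):
        rng = substream(seed, "module_scores", name)
        set_idx = np.array([gene_idx[g] for g in genes])
        ctrl_idx: list[np.ndarray] = []
        for gi in set_idx:
            pool = bins[bin_of[gi]]
            take = rng.choice(pool, size=n_ctrl, replace=len(pool) < n_ctrl)
            ctrl_idx.append(take)
        ctrl = np.concatenate(ctrl_idx)
        scores[si] = x[set_idx].mean(axis=0) - x[ctrl].mean(axis=0)
    return pd.DataFrame(scores, index=list(sets.sets), columns=m.cells)


def choose_correlation(x, y) -> str:
    """Pick Pearson vs Spearman by Shapiro–Wilk normality of both vectors.

    Pearson only when both samples look normal (SW p > 0.05 for each);
    a constant vector has no defined normality test and falls back to
    Spearman with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    for v in (x, y):
        if np.ptp(v) == 0:
            warnings.warn("constant vector: normality undefined, using Spearman")
            return "spearman"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        px = scipy.stats.shapiro(x).pvalue
        py = scipy.stats.shapiro(y).pvalue
    return "pearson" if (px > 0.05 and py > 0.05) else "spearman"


def hallmark_correlation(scores_a: pd.Series, scores_b: pd.Series) -> tuple[str, float, float]:
    """Correlate two species' per-set (or per set × type) mean module scores.

    The method is selected by :func:`choose_correlation`; returns
    ``(method, r, two-sided p)``.
    """
    if len(scores_a) != len(scores_b):
        raise ValueError("score vectors differ in length")
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    method = choose_correlation(a, b)
    if method == "pearson":
        r, p = scipy.stats.pearsonr(a, b)
    else:
        r, p = scipy.stats.spearmanr(a, b)
    return method, float(r), float(p)
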