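"""Over-representation analysis of gene lists against gene-set collections.

The test is the hypergeometric upper tail: with a universe of N genes of
which K belong to the set and a query of n genes of which k hit the set,
``p = P(X >= k)``. q-values are Benjamini–Hochberg across all tested sets;
terms are retained at q < 0.05.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats

from .containers import GeneSetCollection
from .markers import bh_adjust

logger = logging.getLogger(__name__)

Q_THRESHOLD = 0.05


def hypergeom_enrich(
    query, universe, sets: GeneSetCollection, min_universe: int = 10
) -> pd.DataFrame:
    """Hypergeometric over-representation of `query` within `universe`.

    Query genes outside the universe are dropped with a warning; set
    membership is intersected with the universe. Sets with no query hits
    are reported with p = 1 and never retained. Returns one row per set
    with k, n, K, N, p, q and a ``retained`` flag (q < 0.05 and k > 0).
    """
    uni = set(universe)
    if len(uni) < min_universe:
        raise ValueError(f"universe must contain at least {min_universe} genes")
    q_raw = set(query)
    outside = q_raw - uni
    if outside:
        logger.warning("dropping %d query genes outside the universe", len(outside))
    q = q_raw & uni
    if not q:
        raise ValueError("query empty after intersecting with the universe")

    N, n = len(uni), len(q)
    rows = []
    for name, genes in sets.sets.items():
        members = set(genes) & uni
        K = len(members)
        k = len(q & members)
        p = 1.0 if k == 0 else float(scipy.stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "k": k, "n": n, "K": K, "N": N, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["retained"] = (out["q"] < Q_THRESHOLD) & (out["k"] > 0)
    return out


def common_terms(
    results: dict[str, dict[str, pd.DataFrame]], top_n: int = 5
) -> dict[str, dict]:
    """Per cell type, terms retained in *every* species.

    ``results[species][cell_type]`` are :func:`hypergeom_enrich` tables.
    Top terms are ordered by the worst-case (maximum) p across species,
    ascending, ties by name.
    """
    species = sorted(results)
    if not species:
        return {}
    all_types = sorted(set.union(*(set(results[sp]) for sp in species)))
    out: dict[str, dict] = {}
    for ct in all_types:
        if not all(ct in results[sp] for sp in species):
            continue
        retained = {
            sp: set(results[sp][ct].loc[results[sp][ct]["retained"], "set"])
            for sp in species
        }
        common = set.intersection(*retained.values())
        worst_p = {}
        for term in common:
            worst_p[term] = max(
                float(results[sp][ct].set_index("set").loc[term, "p"]) for sp in species
            )
        top = sorted(common, key=lambda t: (worst_p[t], t))[:top_n]
        out[ct] = {"n_common": len(common), "common": sorted(common), "top": top}
    return out
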