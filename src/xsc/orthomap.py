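"""Ortholog remapping of a nonhuman matrix into the human gene namespace.

Three cases are distinguished on the ortholog table restricted to genes
actually present in the matrix:

* one-to-one — the source row is renamed to its human symbol;
* many-to-one — several source rows map to one human symbol and are summed
  per cell (UMI mass aggregated);
* one-to-many — one source row maps to several human symbols and is copied
  to each of them.

Fans are expanded first; anything then landing on the same human symbol is
summed, which makes the whole conversion a single sparse linear operator.
Conversion is defined on counts; normalization is re-applied afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp

from .containers import CountMatrix, OrthologTable

logger = logging.getLogger(__name__)


@dataclass
class MappingPlan:
    """Classification of a matrix's genes against an ortholog table."""

    one_to_one: list[tuple[str, str]]          # (source, human)
    many_to_one: dict[str, list[str]]          # human -> sorted sources
    one_to_many: dict[str, list[str]]          # source -> sorted humans
    unmapped_source: list[str]
    species: str = ""

    def summary(self) -> dict:
        return {
            "species": self.species,
            "one_to_one": len(self.one_to_one),
            "many_to_one_groups": len(self.many_to_one),
            "one_to_many_fans": len(self.one_to_many),
            "unmapped_source": len(self.unmapped_source),
        }

    def source_genes(self) -> set[str]:
        mapped = {s for s, _ in self.one_to_one}
        for sources in self.many_to_one.values():
            mapped.update(sources)
        mapped.update(self.one_to_many)
        return mapped


def build_plan(genes: list[str], table: OrthologTable) -> MappingPlan:
    """Classify matrix genes into the three mapping cases.

    Classification is computed on the restriction of the table to genes
    present in the matrix. A source gene with several human targets is
    one-to-many even if one of those targets also receives other sources;
    grouping into many-to-one happens only among single-target sources.
    """
    if len(set(genes)) != len(genes):
        raise ValueError("matrix gene list contains duplicates")
    present = set(genes)
    sub = table.pairs[table.pairs["source_symbol"].isin(present)]

    targets: dict[str, set[str]] = {}
    for src, hum in zip(sub["source_symbol"], sub["human_symbol"]):
        targets.setdefault(src, set()).add(hum)

    one_to_many = {s: sorted(ts) for s, ts in targets.items() if len(ts) > 1}
    single = {s: next(iter(ts)) for s, ts in targets.items() if len(ts) == 1}

    by_human: dict[str, list[str]] = {}
    for src, hum in single.items():
        by_human.setdefault(hum, []).append(src)
    one_to_one = sorted((srcs[0], hum) for hum, srcs in by_human.items() if len(srcs) == 1)
    many_to_one = {hum: sorted(srcs) for hum, srcs in by_human.items() if len(srcs) > 1}

    unmapped = sorted(present - set(targets))
    return MappingPlan(
        one_to_one=one_to_one,
        many_to_one=dict(sorted(many_to_one.items())),
        one_to_many=dict(sorted(one_to_many.items())),
        unmapped_source=unmapped,
        species=table.species,
    )


def convert_matrix(m: CountMatrix, plan: MappingPlan) -> CountMatrix:
    """Apply a mapping plan, yielding a matrix in the human namespace.

    Implemented as one sparse 0/1 aggregation operator ``A`` (human ×
    source) applied to the matrix: renames, per-cell sums, and fan copies
    all at once; unmapped source rows are dropped with a logged count.
    """
    mapped = plan.source_genes()
    unknown = mapped - set(m.genes)
    if unknown:
        raise ValueError(f"plan references genes absent from matrix: {sorted(unknown)[:5]}")

    contrib: dict[str, list[str]] = {}
    for src, hum in plan.one_to_one:
        contrib.setdefault(hum, []).append(src)
    for hum, sources in plan.many_to_one.items():
        contrib.setdefault(hum, []).extend(sources)
    for src, humans in plan.one_to_many.items():
        for hum in humans:
            contrib.setdefault(hum, []).append(src)

    human_genes = sorted(contrib)
    src_index = {g: i for i, g in enumerate(m.genes)}
    rows, cols = [], []
    for hi, hum in enumerate(human_genes):
        for src in contrib[hum]:
            rows.append(hi)
            cols.append(src_index[src])
    op = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(human_genes), m.n_genes)
    )
    n_dropped = len(plan.unmapped_source)
    if n_dropped:
        logger.info("convert_matrix %s: dropped %d unmapped source genes", m.species, n_dropped)
    return replace(
        m,
        x=sp.csr_matrix(op @ m.x),
        genes=np.array(human_genes, dtype=object),
        namespace="human",
    )


def common_genes(matrices: list[CountMatrix]) -> list[str]:
    """Sorted intersection of gene symbols across human-namespace matrices."""
    if len(matrices) < 2:
        raise ValueError("need at least two matrices")
    for m in matrices:
        if m.namespace != "human":
            raise ValueError(f"matrix for {m.species!r} is not in the human namespace")
    common = set(matrices[0].genes)
    for m in matrices[1:]:
        common &= set(m.genes)
    return sorted(common)
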