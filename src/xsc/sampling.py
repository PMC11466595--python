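"""Seeded, balanced downsampling of shared cells across species.

For every cell type present in all species, the same number of cells is
drawn uniformly without replacement from each species; if any species has
fewer cells than requested, the draw size for that type is lowered to the
minimum availability across species. One global seed spawns an independent
substream per (species, cell type) block, so adding a species or type never
perturbs the other blocks' selections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream


@dataclass
class SamplePlan:
    """Record of a balanced downsampling: which cells, per (species, type)."""

    n_requested: int
    seed: int
    blocks: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def n_taken(self, cell_type: str) -> int:
        sizes = {len(ids) for (sp, ct), ids in self.blocks.items() if ct == cell_type}
        if len(sizes) != 1:
            raise ValueError(f"inconsistent block sizes for {cell_type!r}")
        return sizes.pop()

    def cells_for(self, species: str) -> list[str]:
        out: list[str] = []
        for (sp, _ct), ids in sorted(self.blocks.items()):
            if sp == species:
                out.extend(ids)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_requested": self.n_requested,
            "seed": self.seed,
            "blocks": {f"{sp}|{ct}": ids for (sp, ct), ids in sorted(self.blocks.items())},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SamplePlan":
        payload = json.loads(Path(path).read_text())
        blocks = {tuple(k.split("|", 1)): v for k, v in payload["blocks"].items()}
        return cls(n_requested=payload["n_requested"], seed=payload["seed"], blocks=blocks)


def shared_cell_types(tables: dict[str, pd.DataFrame]) -> list[str]:
    """Cell types with at least one cell in every species, sorted."""
    if len(tables) < 2:
        raise ValueError("need cell tables for at least two species")
    sets = [set(t["cell_type"]) for t in tables.values()]
    common = set.intersection(*sets)
    return sorted(common)


def downsample(tables: dict[str, pd.DataFrame], n: int, seed: int) -> SamplePlan:
    """Draw up to `n` cells per shared cell type from every species.

    Deterministic in `seed`; draws are independent across (species, type)
    blocks. Within a block the candidate pool is sorted by cell id before
    drawing, so the selection does not depend on table row order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    types = shared_cell_types(tables)
    if not types:
        raise ValueError("no cell types shared across species")

    plan = SamplePlan(n_requested=n, seed=seed)
    for ct in types:
        avail = {
            sp: sorted(t.loc[t["cell_type"] == ct, "cell_id"])
            for sp, t in tables.items()
        }
        if any(len(ids) == 0 for ids in avail.values()):
            raise ValueError(f"cell type {ct!r} empty in some species despite being shared")
        take = min(n, min(len(ids) for ids in avail.values()))
        for sp, ids in avail.items():
            rng = substream(seed, "downsample", sp, ct)
            chosen = rng.choice(len(ids), size=take, replace=False)
            plan.blocks[(sp, ct)] = [ids[i] for i in sorted(chosen)]
    return plan
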