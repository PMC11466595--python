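import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import xsc


def make_matrix(values, genes=None, cells=None, species="human", namespace="human",
                space="counts"):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{j}" for j in range(values.shape[1])]
    return xsc.CountMatrix(x=sp.csr_matrix(values), genes=np.array(genes, dtype=object),
                           cells=np.array(cells, dtype=object), species=species,
                           namespace=namespace, space=space)


def make_cell_table(cells, cell_types, species="human", sex=None, condition=None):
    n = len(cells)
    return pd.DataFrame({
        "cell_id": cells,
        "species": species,
        "sample": f"{species}_s1",
        "cell_type": cell_types,
        "sex": sex if sex is not None else ["female"] * n,
        "condition": condition if condition is not None else ["healthy"] * n,
    })


@pytest.fixture(scope="session")
def recovery_sim():
    """Clean-background four-species dataset with planted effects (shared
    across recovery tests; generation is deterministic)."""
    return xsc.generate(xsc.recovery_config(seed=7))


@pytest.fixture(scope="session")
def recovery_analysis(recovery_sim):
    """QC'd, converted, log-normalized matrices + tables for each species."""
    ds = xsc.dataset_from_sim(recovery_sim)
    norm, tables, conv = {}, {}, {}
    for species in ds.counts:
        filtered, table, _ = xsc.qc_filter(ds.counts[species], ds.cells[species])
        norm[species] = xsc.normalize(filtered)
        tables[species] = table
    for species, m in norm.items():
        if m.namespace == "human":
            conv[species] = m
        else:
            raw = (ds.counts[species].subset_genes(list(m.genes))
                   .subset_cells(list(m.cells)))
            plan = xsc.build_plan(list(raw.genes), ds.orthologs[species])
            conv[species] = xsc.normalize(xsc.convert_matrix(raw, plan))
    return {"dataset": ds, "converted": conv, "tables": tables,
            "truth": recovery_sim.truth}
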