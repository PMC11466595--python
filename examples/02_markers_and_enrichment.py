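"""Marker detection under the stringent filter, and over-representation.

Uses the clean-background recovery study: ten 4-fold markers are planted
per cell type, detected one-vs-rest with the Wilcoxon rank-sum test, and
retained only at |fold change| > 1.5, BH-adjusted p < 0.05 and detection
in >25% of cells of one group. The retained markers are then tested for
over-representation in the planted gene sets (hypergeometric, q < 0.05).
"""

import xsc

sim = xsc.generate(xsc.recovery_config(seed=2, cells_per_type=60))
ds = xsc.dataset_from_sim(sim)
converted, tables = xsc.preprocess_and_convert(ds)

markers = xsc.find_markers(converted["human"], tables["human"], "celltype")
planted = sim.truth["markers"]
print(f"retained marker rows (human): {len(markers)}")

ct = "ciliated"
query = markers.loc[(markers["group"] == ct) & (markers["logFC"] > 0), "gene"]
enr = xsc.hypergeom_enrich(list(query), list(converted["human"].genes),
                           ds.gene_sets).set_index("set")
print(f"\n{ct}: {len(query)} up-markers, {len(planted[ct])} planted")
for name in (f"MARKERS_{ct}", "REGULON_G0702"):
    row = enr.loc[name]
    print(f"  {name:<18} k={row['k']}/{row['K']}  q={row['q']:.2e}  "
          f"retained={row['retained']}")
print("\nBoth planted ciliated programs — the marker set and the ciliated-")
print("active regulon — are recovered as over-represented at q < 0.05.")
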