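"""Simplified regulon inference and AUC recovery-curve activity.

Three TF-driven co-expression programs are planted (vascular, myeloid,
airway-epithelial). Tree-ensemble importances link each candidate target
to TFs; targets are retained above a per-TF null-calibrated importance
threshold and only with positive TF correlation; per-cell activity is the
normalized area under the regulon-gene recovery curve over the top 5% of
each cell's expression ranking.
"""

import numpy as np
import xsc

sim = xsc.generate(xsc.recovery_config(seed=3, cells_per_type=60))
ds = xsc.dataset_from_sim(sim)
converted, tables = xsc.preprocess_and_convert(ds)

species = "human"
m, table = converted[species], tables[species]
markers = xsc.find_markers(m, table, "celltype")
keep = sorted((set(markers["gene"]) | set(ds.tf_catalog)) & set(m.genes))
sub = m.subset_genes(keep)

weights = xsc.infer_importance(sub, ds.tf_catalog, seed=3, n_trees=50)
thresholds = xsc.calibrate_min_weight(sub, ds.tf_catalog, seed=3, n_trees=50)
regulons = xsc.build_regulons(weights, sub, min_weight=thresholds)
activity = xsc.auc_activity(sub, regulons, tie_seed=3)

types = table.set_index("cell_id").loc[list(activity.columns), "cell_type"]
print(f"inferred regulons: {regulons.tfs()} (planted: {sorted(sim.truth['regulons'])})")
for tf in regulons.tfs():
    active = sim.truth["regulon_active_types"].get(tf, [])
    vals = activity.loc[tf]
    med_in = np.median(vals[types.isin(active).to_numpy()]) if active else float("nan")
    med_out = np.median(vals[~types.isin(active).to_numpy()])
    n_true = len(set(regulons.targets(tf)) & set(sim.truth["regulons"].get(tf, [])))
    print(f"  {tf}: {len(regulons.targets(tf))} targets ({n_true} planted), "
          f"median activity {med_in:.2f} in active types vs {med_out:.2f} elsewhere")
print("\nActivity separates active from inactive cell types; decoy TFs in")
print("the catalog form no regulon.")
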