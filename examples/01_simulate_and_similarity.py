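"""Cross-species similarity on a synthetic four-species lung atlas.

Generates human plus three species at increasing divergence (0.05, 0.2,
0.4), converts each species into the human gene namespace through its
ortholog table, samples 25 cells per shared cell type, and compares
species by (a) the Mantel correlation of cell-type pseudo-profile
distances and (b) Spearman/Pearson correlation of hallmark-style
module scores.
"""

import xsc

ds = xsc.dataset_from_sim(xsc.generate(xsc.default_config(seed=1)))
out = xsc.similarity_summary(ds, sample_n=25, n_perm=199, seed=1)

print(f"common genes after ortholog conversion: {out['n_common_genes']}")
print("\nMantel r vs human (higher = closer transcriptome):")
for species, r in sorted(out["mantel_r"].items(), key=lambda kv: -kv[1]):
    print(f"  {species:<8} r = {r:.3f}")
print("\nmodule-score correlation vs human:")
for species, r in sorted(out["hallmark_r"].items(), key=lambda kv: -kv[1]):
    print(f"  {species:<8} r = {r:.3f}")
print("\nBoth orderings should track the configured divergence: the least")
print("diverged species (macaque, 0.05) is most human-like, the most")
print("diverged (rat, 0.4) least.")
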