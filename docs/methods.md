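# Methods

`xsc` implements a cross-species single-cell transcriptome comparison
workflow of the kind used to ask how faithfully animal lungs — and animal
asthma models — mirror the human airway: which cell-type expression
programs, marker genes, regulatory factors and sex effects are conserved,
and which are species-specific. This note describes each component's
model and assumptions, the synthetic data generator that provides ground
truth, the tunable parameters, and the design decisions taken where the
problem was genuinely open.

## Preprocessing

Cells are filtered before genes: a cell is removed if its UMI total is
below `min_umi_per_cell` (default 200) or its mitochondrial count
fraction exceeds `max_mito_fraction` (strict `>`; default 0.10, the
stringent end of the 10–30% range used in practice — droplet preparations
differ widely in ambient mitochondrial content, so this is per-dataset
configurable). Genes detected in fewer than `min_cells_per_gene`
(default 3) of the *surviving* cells are then removed; the cell-first
order is a convention, fixed here so the gene filter sees the final cell
population. Doublet removal is out of scope; `qc_filter` accepts a
precomputed exclusion list instead. Normalization is the standard
depth-scaling log transform, `x = ln(1 + s·c/C)` with scale factor
`s = 10,000` and `C` the cell's total counts. It is idempotent under
depth changes and preserves within-cell gene ranking.

## Ortholog conversion

Nonhuman matrices are mapped into the human gene namespace by a
three-case rule computed on the ortholog table restricted to genes
present in the matrix:

* **one-to-one** — rename the row;
* **many-to-one** — several source symbols map to one human symbol; the
  rows are summed per cell (sum is the only aggregation that preserves
  UMI semantics);
* **one-to-many** — one source symbol maps to several human symbols; the
  row is copied to each.

Fans are classified first; a source gene with several human targets is
one-to-many even when one of those targets also receives other sources,
and everything landing on the same human symbol is summed afterwards.
This makes the whole conversion a single sparse 0/1 linear operator,
testable as such: total counts of mapped non-fan genes are conserved
exactly, and a fan gene's total is multiplied by its fan-out exactly.
Unmapped genes are dropped (only converted genes can be compared).
Conversion is defined on counts; normalization is (re-)applied
afterwards. Cross-species analyses then restrict to the sorted
intersection of human-namespace gene sets.

## Balanced sampling

For each cell type present in every species, `n` cells (default 25) are
drawn uniformly without replacement per species; when a species has
fewer, the draw for that type is lowered to the minimum availability so
all species contribute equally. One global seed spawns an independent
RNG substream per (species, cell type) block, keyed by a stable hash, so
adding a species or type never changes the other blocks' draws. Plans
serialize to JSON for exact replay.

## Pseudo-profiles and Mantel similarity

A species is summarized by its *pseudo-profile*: per (cell type, gene),
the mean log-normalized expression and the fraction of sampled cells
expressing the gene. Species are compared through within-species
cell-type distance matrices: the Mantel statistic r is the Pearson
correlation of the lower-triangle entries of two such matrices, and its
one-sided p-value comes from simultaneous row/column permutations of the
second matrix with the add-one rule `p = (1 + #{r_perm ≥ r_obs})/(n_perm
+ 1)` (999 permutations by default; p can never be 0). An exhaustive-
enumeration variant over all `n!` relabelings serves as the oracle for
small matrices.

The distance construction is the largest open design choice in the
workflow, and two variants are provided. The default is **correlation
distance**, `1 − Pearson r` between cell-type feature vectors over the
concatenated mean-expression and detection blocks. A z-scaled Euclidean
embedding is available as `metric="euclidean"`, but it was rejected as
the default on evidence: under 25-cell sampling noise its Mantel r
fluctuated by ±0.1 across replicate samplings, and its distances are, to
first order, invariant to per-gene expression shifts between species —
it measures mostly noise. Correlation distance is scale-free per type
and was stable (per-seed spread below 0.05) with a high noise ceiling.

## Module scores and the correlation gate

A gene set is scored per cell as the mean expression of its genes minus
the mean of expression-matched controls: genes are ranked by mean
expression across cells and cut into `n_bins = 24` equal-frequency bins;
each set gene draws `n_ctrl = 100` controls from its own bin (with
replacement only when the bin is smaller). Scores are exactly invariant
to adding a constant to all genes of a cell, and a constant matrix
scores zero everywhere. Control draws use one substream per set name, so
set order is irrelevant.

Species are compared by correlating per-(set, cell type) mean scores.
The correlation method is gated on normality: Shapiro–Wilk on both
vectors, Pearson only when both have p > 0.05, otherwise Spearman; a
constant vector has no defined normality test and falls back to Spearman
with a warning. The 0.05 gate follows the workflow's global two-sided
significance convention.

## Markers and DEGs

Per-gene two-group comparisons use the two-sided Wilcoxon rank-sum test:
exact enumeration over all label splits (midranks for ties; the
two-sided tail counts splits whose rank sum deviates from its null mean
at least as much as observed) when the smaller group has fewer than 8
observations, and the tie-corrected normal approximation above that.
Fold change is computed on the count scale with a pseudocount:
`log2((mean(expm1 a)+1)/(mean(expm1 b)+1))`, antisymmetric by
construction. A row is retained only if

* |fold change| > 1.5, i.e. |log2FC| > log2 1.5 ≈ 0.585,
* adjusted p < 0.05 (Benjamini–Hochberg across genes within each group
  comparison by default; Bonferroni available — the underlying toolchain
  convention is ambiguous, so both are exposed),
* the gene is detected in more than 25% of cells in at least one of the
  two groups (max of the two percentages).

Contexts: one-vs-rest per cell type (markers), female vs male within
each cell type (sex DEGs, logFC signed toward female), asthma vs healthy
within each cell type (condition DEGs, signed toward asthma). Under a
null simulation with no planted effects the full filter retains under 5%
of genes on average. Cross-species catalogs intersect retained genes per
cell type (common), collect genes retained in exactly one species
(species-specific), and rank common genes conservatively by their
minimum |log2FC| across species. The sex-DEG *volcano summary*
accumulates, per gene, the signed log2FC over the cell types where it
passed the filter and counts those cell types.

## Over-representation

Hypergeometric upper tail: with a universe of N genes, K of them in the
set, and a query of n genes hitting k, `p = Σ_{j≥k} C(K,j)C(N−K,n−j)/
C(N,n)`; q-values are BH across all tested sets, retention at q < 0.05,
and k = 0 reports p = 1 and is never retained. The universe is the
expressed (post-QC) gene list of the matrix that produced the query —
the statistically defensible background for expression-derived queries —
rather than an annotation-wide default. Cross-species common terms are
counted per cell type as the intersection of retained term names, with
top terms ordered by their worst-case (maximum) p across species.

## Regulons

A deliberately simplified SCENIC-style procedure. (1) *Importance*: each
candidate target gene is regressed on the expression of the TFs from a
user-supplied catalog with a seeded extra-trees ensemble (50 trees,
√-feature subsampling); the importance of TF→target is the impurity-based
feature importance. A deterministic squared-Spearman fallback exists.
(2) *Retention*: a target joins a TF's regulon only if its importance
reaches the threshold **and** it correlates positively (Spearman) with
the TF; TFs with fewer than `min_targets = 10` surviving targets are
dropped. Motif-database pruning is replaced by the positive-correlation
filter plus an optional user-supplied TF→candidate prior table; only
activating regulons are modeled. The importance threshold is
null-calibrated per TF: every TF's expression is permuted across cells,
importances are re-inferred, and each TF keeps the 0.99 quantile of its
own null distribution — TFs differ in how much spurious importance they
absorb, so a global cutoff would be biased toward the noisiest TF.
(3) *Activity*: per cell, genes are ranked by descending expression
(ties broken by seeded jitter far below data resolution); with cutoff
`R = ⌈0.05·G⌉`, activity is the area under the cumulative regulon-gene
recovery curve over ranks 1..R divided by its maximum, hence in [0, 1],
reaching 1 when all members occupy the top ranks and 0 when none is in
the top R. Cross-species comparison intersects inferred TF sets (Venn
partition plus common list) and correlates per-cell-group mean activity
of the common TFs against the reference species through the normality
gate, flagging rows with p ≥ 0.05 as not shown.

## The synthetic generator

The generator emulates the statistical structure the workflow assumes,
with full ground truth. Counts are gamma-Poisson (negative binomial,
shared dispersion α = 0.3, variance μ + αμ²) with lognormal library
sizes (mean 2,000 UMIs, σ = 0.3). The mean for gene g, cell c of type t
in species s is

```
μ = L_c · w / Σ_g w,   w = b_g · P_gt · D_gts · 2^(planted effects) · regulon factor
```

* `b_g` — lognormal baseline (σ = 1). Planted genes are floored at the
  median baseline (effects on undetectable genes are untestable);
  regulon genes at the 75th percentile, since co-expression is invisible
  at the shot-noise floor and the regulons worth recovering are strong
  programs.
* `P_gt` — a species-shared cell-type program, `exp(τ·u_gt − τ²/2)` with
  τ = 0.5: every gene varies across cell types, as in real data. Without
  it, only markers carry type structure and profile distances are
  noise-dominated.
* `D_gts` — species divergence, `exp(σ_s·z_gts − σ_s²/2)` with
  `σ_s = 2.5 · divergence_s`, drawn per (gene, cell type, species).
  Drawing drift per gene alone would be invisible to the comparison: a
  per-gene factor is an additive constant in log space and cancels in
  between-type contrasts. Divergence 0 reproduces the reference means
  exactly. The scale 2.5 was calibrated once, on the final generator,
  so the default divergence grid (0.05 / 0.2 / 0.4) spans strong-to-weak
  similarity at 25 sampled cells per type with reliably recoverable
  ordering on both comparison routes.
* Planted effects: ten 4-fold (log2FC = 2) markers per cell type;
  sex-biased genes including an "XIST-like" landmark expressed only in
  females of designated species (and zeroed entirely elsewhere);
  condition-responsive genes concentrated in club cells; three regulons
  whose TF (×2^2.5) and targets (×2^2) are co-modulated by a shared
  per-cell lognormal latent (σ = 0.8) in their active cell types.
* Ortholog structure: human genes are partitioned 70/15/15% into
  one-to-one, many-to-one (two source symbols sharing the human gene's
  expression) and one-to-many (one source symbol expressing the average
  of two human genes) cases; planted genes stay one-to-one so truth is
  preserved across namespaces. A config that lists a planted marker as a
  one-to-many split is rejected.

The default study has 4 species (divergences 0 / 0.05 / 0.2 / 0.4), 18
shared lung cell types (the 8-type variant gave too few distance pairs
for a stable Mantel r), 60 cells per type and 800 genes — sizes chosen
so a full pipeline run takes about a minute on one CPU and the 20-seed
ordering study a few minutes. The *recovery* configuration (for
marker / sex / regulon recovery) uses 100 cells per type, switches the
shared type program off and makes divergences near-zero (but distinct):
divergence drift produces genuine differential expression, so precision
against the planted marker list is only well-defined on a clean
background; recovery metrics additionally exclude sex/condition/regulon
genes from the candidate pool for the same reason. The *condition*
configuration labels half the cells asthma and plants the response in
club (12 genes) and ciliated (3 genes) cells of every species except the
most diverged one — an animal model that fails to mirror the human
response. The focus-set score comparison centers each species' asthma
cells on its own healthy-cell mean per cell type before testing against
the reference, which cancels divergence drift and isolates the response.

What the generator does **not** emulate: doublets, ambient RNA,
batch/donor structure, spatial effects, realistic gene-gene correlation
beyond the planted regulons, repressive regulation, and paralog-specific
expression inside fan groups. Passing tests therefore demonstrate that
the statistics and bookkeeping behave as specified under a faithful
droplet-count model — not that the pipeline's biological conclusions on
real data are correct.

## Numerical and reproducibility choices

All randomness flows from explicit integer seeds through named,
hash-keyed substreams (`xsc._rng`), so independent blocks never share
draws and adding a block never perturbs another. Identical config and
seed reproduce every output table byte for byte. Ties: module-score
binning uses stable ranking; AUC ranking breaks ties with seeded jitter
of amplitude 1e-9; top-term and top-marker orderings break ties by name.
Degenerate inputs fail loudly: empty QC results, zero-total cells,
zero-variance distance triangles, constant vectors in the normality
gate, regulons with no present targets.

## Limitations

The Mantel input construction and several toolchain defaults are
documented conventions, not recoverable facts about any particular
published analysis. The rank-sum normal approximation is used from group
size 8, which is conventional but approximate near the boundary.
Regulon inference models only activation and inherits the tree
ensemble's bias toward high-variance features, mitigated but not removed
by per-TF null calibration. The generator's divergence model is a
single-parameter lognormal pattern drift; real cross-species divergence
is structured (lineage-specific genes, compositional shifts) and will
not match its statistics.
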