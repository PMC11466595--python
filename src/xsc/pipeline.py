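"""End-to-end orchestration of the cross-species comparison.

Three entry points mirror the three study designs: the healthy
cross-species run (QC → ortholog conversion → balanced sampling →
pseudo-profile Mantel similarity → module-score correlation → markers →
enrichment → regulons), the sex-stratified run (proportions, sex DEGs,
accumulated-logFC volcano, enrichment), and the condition run restricted
to club and ciliated cells. Every artifact is written as TSV/JSON/GMT
under the output directory, together with a manifest of stage outputs,
parameters and seeds: config plus seeds fully determine the outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from . import io as xio
from .containers import CountMatrix, GeneSetCollection, OrthologTable
from .enrichment import common_terms, hypergeom_enrich
from .markers import common_markers, find_markers, volcano_summary
from .orthomap import build_plan, common_genes, convert_matrix
from .preprocess import NormParams, QCParams, normalize, qc_filter
from .regulons import (auc_activity, build_regulons, calibrate_min_weight,
                       cross_species_regulons, infer_importance,
                       regulon_activity_correlation)
from .sampling import downsample, shared_cell_types
from .similarity import (hallmark_correlation, module_scores, pseudo_profile,
                         species_similarity)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class Dataset:
    """Input bundle: per-species counts, annotations, ortholog tables,
    gene sets and the TF catalog. The reference species is in the human
    namespace and needs no ortholog table."""

    counts: dict[str, CountMatrix]
    cells: dict[str, pd.DataFrame]
    orthologs: dict[str, OrthologTable]
    gene_sets: GeneSetCollection
    tf_catalog: list[str]
    reference: str = "human"


def dataset_from_sim(sim) -> Dataset:
    return Dataset(
        counts=sim.counts,
        cells=sim.cells,
        orthologs=sim.orthologs,
        gene_sets=sim.gene_sets,
        tf_catalog=list(sim.truth.get("tf_catalog", [])),
        reference=sim.truth["species"][0],
    )


def load_dataset(directory: str | Path, reference: str = "human") -> Dataset:
    """Load a fixture directory written by :func:`xsc.simulate.write_fixture`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    counts, cells, orthologs = {}, {}, {}
    for species, entry in manifest["species"].items():
        counts[species] = xio.read_counts(directory / entry["counts"], "mtx_dir",
                                          species=species,
                                          namespace=entry.get("namespace", "source"))
        cells[species] = xio.read_annotations(directory / entry["cells"])
        if "orthologs" in entry:
            orthologs[species] = xio.read_orthologs(directory / entry["orthologs"],
                                                    species=species)
    gene_sets = xio.read_gmt(directory / manifest["gene_sets"])
    tf_rel = manifest.get("tf_catalog")
    tf_catalog = (
        [ln.strip() for ln in (directory / tf_rel).read_text().splitlines() if ln.strip()]
        if tf_rel else []
    )
    return Dataset(counts=counts, cells=cells, orthologs=orthologs,
                   gene_sets=gene_sets, tf_catalog=tf_catalog, reference=reference)


@dataclass
class RunConfig:
    """All tunables of a pipeline run; seeds are explicit, never wall-clock."""

    out_dir: str = "xsc_out"
    seed: int = 0
    qc: QCParams = field(default_factory=QCParams)
    norm: NormParams = field(default_factory=NormParams)
    sample_n: int = 25
    n_perm: int = 199
    module_bins: int = 24
    module_ctrl: int = 100
    p_adjust: str = "bh"
    regulon_method: str = "trees"
    regulon_trees: int = 50
    regulon_min_weight: float | None = None   # None -> null-calibrated
    regulon_min_targets: int = 10
    regulon_calibration_quantile: float = 0.99
    regulon_top_markers: int = 10   # top |logFC| markers per group fed to inference
    rank_threshold_frac: float = 0.05
    condition_cell_types: tuple[str, ...] = ("club", "ciliated")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        qc = QCParams(**raw.pop("qc", {}))
        norm = NormParams(**raw.pop("norm", {}))
        cfg = cls(qc=qc, norm=norm, **raw)
        return cfg

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["qc"] = asdict(self.qc)
        d["norm"] = asdict(self.norm)
        return d


class _Run:
    """Shared bookkeeping: output dir, manifest, stage registry."""

    def __init__(self, config: RunConfig, kind: str):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {"run": kind, "config": config.to_jsonable(), "stages": {}}

    def record(self, stage: str, files: list[Path], **info) -> None:
        logger.info("stage %s done: %s", stage, info)
        self.manifest["stages"][stage] = {
            "outputs": [str(Path(f).relative_to(self.out)) for f in files], **info,
        }

    def finish(self) -> dict:
        path = self.out / "manifest.json"
        path.write_text(json.dumps(self.manifest, indent=1, sort_keys=True))
        return self.manifest


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def _preprocess_all(ds: Dataset, run: _Run):
    """QC + normalization per species (stage 1)."""
    cfg = run.config
    norm_m, tables, reports = {}, {}, {}
    for sp in sorted(ds.counts):
        filtered, table, report = qc_filter(ds.counts[sp], ds.cells[sp], cfg.qc)
        norm_m[sp] = normalize(filtered, cfg.norm)
        tables[sp] = table
        reports[sp] = report
    path = run.out / "preprocess_report.json"
    _write_json(path, reports)
    run.record("preprocess", [path], species=sorted(ds.counts))
    return norm_m, tables


def _convert_all(ds: Dataset, norm_m, run: _Run):
    """Ortholog conversion to the human namespace, then re-normalization
    (conversion is defined on counts; stage 2)."""
    cfg = run.config
    converted, summaries = {}, {}
    for sp, m in norm_m.items():
        if sp == ds.reference or m.namespace == "human":
            converted[sp] = m
            continue
        # redo conversion in count space: qc-filtered counts are recoverable
        # from the normalized matrix's gene/cell lists against the input
        raw = ds.counts[sp].subset_genes(list(m.genes)).subset_cells(list(m.cells))
        plan = build_plan(list(raw.genes), ds.orthologs[sp])
        conv = convert_matrix(raw, plan)
        converted[sp] = normalize(conv, cfg.norm)
        summaries[sp] = plan.summary()
    path = run.out / "mapping_plans.json"
    _write_json(path, summaries)
    run.record("orthomap", [path], **{sp: s for sp, s in summaries.items()})
    return converted


def _similarity_stages(ds: Dataset, converted, tables, run: _Run):
    """Shared types, balanced sampling, profiles, Mantel table, module
    scores and hallmark correlations (stages 3–8)."""
    cfg = run.config
    genes = common_genes(list(converted.values()))
    shared = shared_cell_types(tables)
    path_sh = run.out / "shared_cell_types.json"
    _write_json(path_sh, {"cell_types": shared, "n_common_genes": len(genes)})
    run.record("shared_types", [path_sh], n_types=len(shared), n_common_genes=len(genes))

    plan = downsample(tables, n=cfg.sample_n, seed=cfg.seed)
    path_pl = run.out / "sample_plan.json"
    plan.to_json(path_pl)
    run.record("downsample", [path_pl], n_requested=cfg.sample_n)

    profiles, prof_paths = {}, []
    for sp, m in converted.items():
        sub = m.subset_genes(genes)
        prof = pseudo_profile(sub, tables[sp], plan.cells_for(sp))
        profiles[sp] = prof
        p1 = run.out / f"profile_mean_{sp}.tsv"
        p2 = run.out / f"profile_pct_{sp}.tsv"
        prof.mean.to_csv(p1, sep="\t", float_format=_FLOAT_FMT)
        prof.pct.to_csv(p2, sep="\t", float_format=_FLOAT_FMT)
        prof_paths += [p1, p2]
    run.record("profiles", prof_paths, n_genes=len(genes))

    sim_table = species_similarity(profiles, n_perm=cfg.n_perm, seed=cfg.seed,
                                   reference=ds.reference)
    path_m = run.out / "mantel_similarity.tsv"
    sim_table.to_csv(path_m, sep="\t", index=False, float_format=_FLOAT_FMT)
    run.record("mantel", [path_m], n_perm=cfg.n_perm)

    score_means, score_paths = {}, []
    for sp, m in converted.items():
        sub = m.subset_genes(genes).subset_cells(plan.cells_for(sp))
        scores = module_scores(sub, ds.gene_sets, n_bins=cfg.module_bins,
                               n_ctrl=cfg.module_ctrl, seed=cfg.seed)
        meta = tables[sp].set_index("cell_id").loc[list(scores.columns), "cell_type"]
        by_type = scores.T.groupby(meta.to_numpy()).mean().T  # sets × types
        score_means[sp] = by_type
        p = run.out / f"module_scores_{sp}.tsv"
        by_type.to_csv(p, sep="\t", float_format=_FLOAT_FMT)
        score_paths.append(p)
    run.record("module_scores", score_paths,
               n_sets=len(score_means[ds.reference].index))

    ref_vec = score_means[ds.reference].stack()
    rows = []
    for sp in sorted(converted):
        if sp == ds.reference:
            continue
        vec = score_means[sp].stack().reindex(ref_vec.index)
        method, r, p = hallmark_correlation(ref_vec, vec)
        rows.append({"species": sp, "method": method, "r": r, "p": p})
    hall = pd.DataFrame(rows).sort_values("r", ascending=False, kind="mergesort")
    path_h = run.out / "hallmark_correlation.tsv"
    hall.to_csv(path_h, sep="\t", index=False, float_format=_FLOAT_FMT)
    run.record("hallmark_correlation", [path_h])
    return genes, shared, plan, profiles, sim_table, score_means, hall


def _marker_stages(ds: Dataset, converted, tables, run: _Run):
    """Per-species marker tables, cross-species catalogs, enrichment
    (stages 9–11)."""
    cfg = run.config
    marker_tables, paths = {}, []
    for sp, m in converted.items():
        mt = find_markers(m, tables[sp], "celltype", p_adjust=cfg.p_adjust)
        marker_tables[sp] = mt
        p = run.out / f"markers_{sp}.tsv"
        xio.write_marker_table(mt, p)
        paths.append(p)
    run.record("markers", paths,
               counts={sp: int(len(t)) for sp, t in marker_tables.items()})

    catalogs = common_markers(marker_tables)
    path_c = run.out / "marker_catalogs.json"
    _write_json(path_c, catalogs)
    run.record("common_markers", [path_c])

    enr: dict[str, dict[str, pd.DataFrame]] = {}
    for sp, mt in marker_tables.items():
        universe = list(converted[sp].genes)
        enr[sp] = {}
        for ct in sorted(set(mt["group"])):
            query = mt.loc[mt["group"] == ct, "gene"].tolist()
            if not query:
                continue
            enr[sp][ct] = hypergeom_enrich(query, universe, ds.gene_sets)
    terms = common_terms(enr)
    path_e = run.out / "enrichment_common_terms.json"
    _write_json(path_e, terms)
    run.record("enrichment", [path_e])
    return marker_tables, catalogs, enr, terms


def _top_marker_genes(table: pd.DataFrame, per_group: int) -> set[str]:
    """Union of the strongest markers (by |logFC|) per group."""
    if table.empty:
        return set()
    ranked = table.reindex(table["logFC"].abs().sort_values(ascending=False).index)
    return set(ranked.groupby("group", sort=False).head(per_group)["gene"])


def _regulon_stages(ds: Dataset, converted, tables, plan, marker_tables, run: _Run):
    """Regulon inference, activity, cross-species comparison (stage 12)."""
    cfg = run.config
    reg_sets, activities, paths = {}, {}, []
    for sp, m in converted.items():
        marker_genes = _top_marker_genes(marker_tables[sp], cfg.regulon_top_markers)
        keep = sorted((set(marker_genes) | set(ds.tf_catalog)) & set(m.genes))
        sub = m.subset_genes(keep).subset_cells(plan.cells_for(sp))
        weights = infer_importance(sub, ds.tf_catalog, seed=cfg.seed,
                                   method=cfg.regulon_method, n_trees=cfg.regulon_trees)
        min_w = cfg.regulon_min_weight
        if min_w is None:
            min_w = calibrate_min_weight(sub, ds.tf_catalog, seed=cfg.seed,
                                         method=cfg.regulon_method,
                                         n_trees=cfg.regulon_trees,
                                         quantile=cfg.regulon_calibration_quantile)
        reg = build_regulons(weights, sub, min_weight=min_w,
                             min_targets=cfg.regulon_min_targets)
        reg_sets[sp] = reg
        if reg.regulons:
            act = auc_activity(sub, reg, rank_threshold_frac=cfg.rank_threshold_frac,
                               tie_seed=cfg.seed)
            activities[sp] = act
        gmt = GeneSetCollection(
            sets={tf: reg.targets(tf) for tf in reg.tfs()} or {"EMPTY": ["none"]},
            provenance=f"regulons_{sp}",
        )
        p = run.out / f"regulons_{sp}.gmt"
        xio.write_gmt(gmt, p)
        paths.append(p)

    venn, common_tfs = cross_species_regulons(reg_sets)
    path_v = run.out / "regulon_venn.json"
    _write_json(path_v, {"venn": venn, "common_tfs": common_tfs})
    paths.append(path_v)

    act_corr = pd.DataFrame()
    if len(common_tfs) >= 3 and len(activities) == len(converted):
        act_corr = regulon_activity_correlation(activities, tables,
                                                level="cell_type",
                                                reference=ds.reference)
    path_a = run.out / "regulon_activity_correlation.tsv"
    act_corr.to_csv(path_a, sep="\t", index=False, float_format=_FLOAT_FMT)
    paths.append(path_a)
    run.record("regulons", paths, common_tfs=common_tfs)
    return reg_sets, activities, venn, common_tfs, act_corr


def preprocess_and_convert(ds: Dataset, qc: QCParams | None = None,
                           norm: NormParams | None = None):
    """QC, normalize and ortholog-convert every species (no file output).

    Returns ``(converted, tables)``: human-namespace log-normalized
    matrices and the matching cell tables.
    """
    qc = qc or QCParams()
    norm = norm or NormParams()
    converted, tables = {}, {}
    for sp in sorted(ds.counts):
        filtered, table, _ = qc_filter(ds.counts[sp], ds.cells[sp], qc)
        tables[sp] = table
        if sp == ds.reference or ds.counts[sp].namespace == "human":
            converted[sp] = normalize(filtered, norm)
        else:
            plan = build_plan(list(filtered.genes), ds.orthologs[sp])
            converted[sp] = normalize(convert_matrix(filtered, plan), norm)
    return converted, tables


def similarity_summary(ds: Dataset, sample_n: int = 25, n_perm: int = 199,
                       seed: int = 0) -> dict:
    """Both similarity routes against the reference, without file output.

    Runs QC → conversion → balanced sampling → pseudo-profile Mantel and
    module-score correlation; returns per-species Mantel r, hallmark r,
    and the common-gene count.
    """
    converted, tables = preprocess_and_convert(ds)
    genes = common_genes(list(converted.values()))
    plan = downsample(tables, n=sample_n, seed=seed)
    profiles = {
        sp: pseudo_profile(m.subset_genes(genes), tables[sp], plan.cells_for(sp))
        for sp, m in converted.items()
    }
    sim_table = species_similarity(profiles, n_perm=n_perm, seed=seed,
                                   reference=ds.reference)
    ref = ds.reference
    mantel_r = {}
    for _, row in sim_table.iterrows():
        if ref in (row["species_a"], row["species_b"]):
            other = row["species_b"] if row["species_a"] == ref else row["species_a"]
            mantel_r[other] = float(row["r"])
    score_means = {}
    for sp, m in converted.items():
        sub = m.subset_genes(genes).subset_cells(plan.cells_for(sp))
        scores = module_scores(sub, ds.gene_sets, seed=seed)
        meta = tables[sp].set_index("cell_id").loc[list(scores.columns), "cell_type"]
        score_means[sp] = scores.T.groupby(meta.to_numpy()).mean().T
    ref_vec = score_means[ref].stack()
    hallmark_r = {}
    for sp in converted:
        if sp == ref:
            continue
        _, r, _ = hallmark_correlation(ref_vec,
                                       score_means[sp].stack().reindex(ref_vec.index))
        hallmark_r[sp] = float(r)
    return {"mantel_r": mantel_r, "hallmark_r": hallmark_r,
            "n_common_genes": len(genes), "mantel_table": sim_table}
HEALTHY_STAGES = (
    "preprocess", "orthomap", "shared_types", "downsample", "profiles",
    "mantel", "module_scores", "hallmark_correlation", "markers",
    "common_markers", "enrichment", "regulons",
)


def run_healthy_comparison(ds: Dataset, config: RunConfig) -> dict:
    """Full healthy cross-species comparison; returns a report dict."""
    if len(ds.counts) < 2:
        raise ValueError("need at least two species")
    run = _Run(config, "healthy_comparison")
    norm_m, tables = _preprocess_all(ds, run)
    converted = _convert_all(ds, norm_m, run)
    genes, shared, plan, profiles, sim_table, score_means, hall = \
        _similarity_stages(ds, converted, tables, run)
    marker_tables, catalogs, enr, terms = _marker_stages(ds, converted, tables, run)
    reg_sets, activities, venn, common_tfs, act_corr = \
        _regulon_stages(ds, converted, tables, plan, marker_tables, run)
    manifest = run.finish()
    ref = ds.reference
    vs_ref = sim_table[(sim_table["species_a"] == ref) | (sim_table["species_b"] == ref)]
    return {
        "manifest": manifest,
        "n_common_genes": len(genes),
        "shared_cell_types": shared,
        "mantel_vs_reference": {
            (r["species_b"] if r["species_a"] == ref else r["species_a"]): r["r"]
            for _, r in vs_ref.iterrows()
        },
        "mantel_table": sim_table,
        "hallmark_correlation": hall,
        "marker_counts": {sp: int(len(t)) for sp, t in marker_tables.items()},
        "marker_catalogs": catalogs,
        "common_terms": terms,
        "common_tfs": common_tfs,
        "regulon_venn": venn,
        "regulon_activity_correlation": act_corr,
    }


def run_sex_comparison(ds: Dataset, config: RunConfig) -> dict:
    """Sex-stratified run: proportions, sex DEGs, volcano, enrichment."""
    run = _Run(config, "sex_comparison")
    norm_m, tables = _preprocess_all(ds, run)
    converted = _convert_all(ds, norm_m, run)

    usable = {}
    for sp, t in tables.items():
        sexes = set(t["sex"]) - {"unknown"}
        if len(sexes) < 2:
            logger.warning("species %s has single-sex data: excluded", sp)
            continue
        usable[sp] = t
    if len(usable) < 2:
        raise ValueError("fewer than two species with both sexes")

    props = {}
    for sp, t in usable.items():
        tab = (
            t.groupby(["sex", "cell_type"]).size().unstack(fill_value=0)
            .apply(lambda row: row / row.sum(), axis=1)
        )
        props[sp] = tab
    path_p = run.out / "sex_proportions.tsv"
    pd.concat(props, names=["species", "sex"]).to_csv(path_p, sep="\t",
                                                      float_format=_FLOAT_FMT)
    run.record("sex_proportions", [path_p], species=sorted(usable))

    deg_tables, volcanoes, tops = {}, {}, {}
    paths = []
    for sp in sorted(usable):
        degs = find_markers(converted[sp], usable[sp], "sex", p_adjust=config.p_adjust)
        deg_tables[sp] = degs
        summary, top = volcano_summary(degs)
        volcanoes[sp] = summary
        tops[sp] = top
        p1 = run.out / f"sex_degs_{sp}.tsv"
        p2 = run.out / f"sex_volcano_{sp}.tsv"
        xio.write_marker_table(degs, p1)
        summary.to_csv(p2, sep="\t", index=False, float_format=_FLOAT_FMT)
        paths += [p1, p2]
    run.record("sex_degs", paths, top5={sp: tops[sp] for sp in tops})

    enr: dict[str, dict[str, pd.DataFrame]] = {}
    for sp, degs in deg_tables.items():
        universe = list(converted[sp].genes)
        enr[sp] = {}
        for ct in sorted(set(degs["group"])):
            query = degs.loc[degs["group"] == ct, "gene"].tolist()
            if query:
                enr[sp][ct] = hypergeom_enrich(query, universe, ds.gene_sets)
    terms = common_terms(enr)
    path_e = run.out / "sex_enrichment_common_terms.json"
    _write_json(path_e, terms)
    run.record("sex_enrichment", [path_e])
    manifest = run.finish()
    return {
        "manifest": manifest,
        "proportions": props,
        "sex_deg_counts": {sp: int(len(t)) for sp, t in deg_tables.items()},
        "volcano": volcanoes,
        "volcano_top5": tops,
        "common_terms": terms,
    }


def _stars(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else "ns"


def run_condition_comparison(ds: Dataset, config: RunConfig,
                             focus_sets: tuple[str, ...] = ("CONDITION_RESPONSE",)) -> dict:
    """Healthy-vs-asthma run restricted to the configured cell types.

    Similarity is computed on a (cell type × condition) grid so the Mantel
    distance matrices have enough groups; module scores of the focus sets
    are compared species-vs-reference with rank-sum significance stars;
    condition DEGs, enrichment and DEG-derived regulons follow.
    """
    run = _Run(config, "condition_comparison")
    norm_m, tables = _preprocess_all(ds, run)
    converted = _convert_all(ds, norm_m, run)

    restricted_m, restricted_t = {}, {}
    for sp in sorted(converted):
        t = tables[sp]
        keep = t[t["cell_type"].isin(config.condition_cell_types)].reset_index(drop=True)
        if keep.empty or len(set(keep["condition"])) < 2:
            logger.warning("species %s lacks restricted cells or conditions: excluded", sp)
            continue
        restricted_t[sp] = keep
        restricted_m[sp] = converted[sp].subset_cells(list(keep["cell_id"]))
    if len(restricted_m) < 2:
        raise ValueError("fewer than two species after cell-type restriction")

    genes = common_genes(list(restricted_m.values()))
    # composite grouping (cell type × condition) for sampling + profiles
    combo_t = {}
    for sp, t in restricted_t.items():
        t2 = t.copy()
        t2["cell_type"] = t2["cell_type"] + "|" + t2["condition"]
        combo_t[sp] = t2
    plan = downsample(combo_t, n=config.sample_n, seed=config.seed)
    profiles = {
        sp: pseudo_profile(restricted_m[sp].subset_genes(genes), combo_t[sp],
                           plan.cells_for(sp))
        for sp in restricted_m
    }
    sim_table = species_similarity(profiles, n_perm=config.n_perm, seed=config.seed,
                                   reference=ds.reference)
    path_m = run.out / "condition_mantel.tsv"
    sim_table.to_csv(path_m, sep="\t", index=False, float_format=_FLOAT_FMT)
    run.record("condition_mantel", [path_m], n_common_genes=len(genes))

    score_cells, score_means = {}, {}
    for sp in restricted_m:
        sub = restricted_m[sp].subset_genes(genes).subset_cells(plan.cells_for(sp))
        scores = module_scores(sub, ds.gene_sets, n_bins=config.module_bins,
                               n_ctrl=config.module_ctrl, seed=config.seed)
        score_cells[sp] = scores
        meta = combo_t[sp].set_index("cell_id").loc[list(scores.columns), "cell_type"]
        score_means[sp] = scores.T.groupby(meta.to_numpy()).mean().T

    ref = ds.reference
    ref_vec = score_means[ref].stack()
    rows = []
    for sp in sorted(restricted_m):
        if sp == ref:
            continue
        vec = score_means[sp].stack().reindex(ref_vec.index)
        method, r, p = hallmark_correlation(ref_vec, vec)
        rows.append({"species": sp, "method": method, "r": r, "p": p})
    hall = pd.DataFrame(rows)
    path_h = run.out / "condition_hallmark.tsv"
    hall.to_csv(path_h, sep="\t", index=False, float_format=_FLOAT_FMT)
    run.record("condition_hallmark", [path_h])

    # species-vs-reference comparison of focus-set *responses*: each
    # asthma cell's score is centered on its species' healthy-cell mean
    # for the same cell type, so species-level expression drift cancels
    # and only the disease response is compared
    def _asthma_scores(sp: str, set_name: str) -> np.ndarray:
        s = score_cells[sp].loc[set_name]
        meta = restricted_t[sp].set_index("cell_id").loc[list(s.index)]
        cond = meta["condition"].to_numpy()
        ctype = meta["cell_type"].to_numpy()
        centered = np.empty(len(s))
        vals = s.to_numpy()
        for ct in np.unique(ctype):
            healthy = vals[(ctype == ct) & (cond == "healthy")]
            base = healthy.mean() if len(healthy) else 0.0
            centered[ctype == ct] = vals[ctype == ct] - base
        return centered[cond == "asthma"]

    focus_rows = []
    present_focus = [s for s in focus_sets if s in ds.gene_sets.sets]
    for set_name in present_focus:
        if set_name not in score_cells[ref].index:
            continue
        ref_scores = _asthma_scores(ref, set_name)
        for sp in sorted(restricted_m):
            if sp == ref:
                continue
            sp_scores = _asthma_scores(sp, set_name)
            stat = scipy.stats.mannwhitneyu(sp_scores, ref_scores,
                                            alternative="two-sided",
                                            method="asymptotic")
            focus_rows.append({
                "set": set_name, "species": sp, "p": float(stat.pvalue),
                "stars": _stars(float(stat.pvalue)),
                "median_diff": float(np.median(sp_scores) - np.median(ref_scores)),
            })
    focus = pd.DataFrame(focus_rows)
    path_f = run.out / "condition_focus_scores.tsv"
    focus.to_csv(path_f, sep="\t", index=False, float_format=_FLOAT_FMT)
    run.record("condition_focus_scores", [path_f], sets=present_focus)

    deg_tables, paths = {}, []
    for sp in sorted(restricted_m):
        degs = find_markers(restricted_m[sp], restricted_t[sp], "condition",
                            p_adjust=config.p_adjust)
        deg_tables[sp] = degs
        p = run.out / f"condition_degs_{sp}.tsv"
        xio.write_marker_table(degs, p)
        paths.append(p)
    deg_counts = {
        sp: {ct: int((t["group"] == ct).sum()) for ct in config.condition_cell_types}
        for sp, t in deg_tables.items()
    }
    run.record("condition_degs", paths, counts=deg_counts)

    enr: dict[str, dict[str, pd.DataFrame]] = {}
    for sp, degs in deg_tables.items():
        universe = list(restricted_m[sp].genes)
        enr[sp] = {}
        for ct in sorted(set(degs["group"])):
            query = degs.loc[degs["group"] == ct, "gene"].tolist()
            if query:
                enr[sp][ct] = hypergeom_enrich(query, universe, ds.gene_sets)
    terms = common_terms(enr)
    path_e = run.out / "condition_enrichment_common_terms.json"
    _write_json(path_e, terms)
    run.record("condition_enrichment", [path_e])

    reg_sets = {}
    for sp in sorted(restricted_m):
        deg_genes = _top_marker_genes(deg_tables[sp], config.regulon_top_markers)
        keep = sorted((set(deg_genes) | set(ds.tf_catalog)) & set(restricted_m[sp].genes))
        sub = restricted_m[sp].subset_genes(keep)
        if sub.n_cells < 30 or len(keep) <= len(ds.tf_catalog):
            logger.warning("species %s: too few DEGs/cells for regulon inference", sp)
            continue
        weights = infer_importance(sub, ds.tf_catalog, seed=config.seed,
                                   method=config.regulon_method,
                                   n_trees=config.regulon_trees)
        min_w = config.regulon_min_weight
        if min_w is None:
            min_w = calibrate_min_weight(sub, ds.tf_catalog, seed=config.seed,
                                         method=config.regulon_method,
                                         n_trees=config.regulon_trees,
                                         quantile=config.regulon_calibration_quantile)
        reg_sets[sp] = build_regulons(weights, sub, min_weight=min_w,
                                      min_targets=min(config.regulon_min_targets, 5))
    venn, common_tfs = cross_species_regulons(reg_sets) if reg_sets else ({}, [])
    path_v = run.out / "condition_regulon_venn.json"
    _write_json(path_v, {"venn": venn, "common_tfs": common_tfs})
    run.record("condition_regulons", [path_v], common_tfs=common_tfs)

    manifest = run.finish()
    return {
        "manifest": manifest,
        "n_common_genes": len(genes),
        "mantel_table": sim_table,
        "hallmark_correlation": hall,
        "focus_scores": focus,
        "deg_counts": deg_counts,
        "common_terms": terms,
        "regulon_venn": venn,
        "common_tfs": common_tfs,
    }
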