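"""Synthetic multi-species single-cell datasets with known ground truth.

The generator emulates the statistical structure of a cross-species
droplet scRNA-seq comparison: 2–4 species share a panel of cell types;
counts follow a negative-binomial model with lognormal library sizes;
each nonhuman species' per-(gene, cell type) means drift away from the
human means by a lognormal perturbation whose spread is proportional to a
configured divergence (0 = identical to human), so divergence distorts the
expression pattern across types rather than only the per-gene scale;
cell-type markers, sex-biased genes
(including an "XIST-like" gene expressed only in females of designated
species), condition-responsive genes, and TF-driven co-expression blocks
are planted multiplicatively; and each species' matrix is emitted in its
own gene namespace together with an ortholog table containing one-to-one,
many-to-one, and one-to-many cases. Everything planted is recorded in a
truth record so downstream recovery can be scored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._rng import substream
from .containers import CountMatrix, OrthologTable, GeneSetCollection
from . import io as xio

logger = logging.getLogger(__name__)


@dataclass
class SexEffect:
    """A planted sex-biased gene: 2**log2fc in the given sex.

    ``exclusive=True`` silences the gene entirely in the other sex (and in
    species outside ``species``), mimicking an XIST-like female landmark.
    """

    gene: str
    cell_types: tuple[str, ...] | str = "all"
    log2fc: float = 2.0
    sex: str = "female"
    species: tuple[str, ...] | str = "all"
    exclusive: bool = False


@dataclass
class ConditionEffect:
    """A planted disease-responsive gene within selected cell types."""

    gene: str
    cell_types: tuple[str, ...] | str = "all"
    log2fc: float = 2.0
    condition: str = "asthma"
    species: tuple[str, ...] | str = "all"


@dataclass
class RegulonSpec:
    """A TF plus targets co-activated in the TF's active cell types.

    In active-type cells a shared lognormal latent activity multiplies
    both the TF (scaled by 2**strength) and its targets (scaled by
    2**(0.8·strength)), inducing positive TF–target co-expression.
    """

    tf: str
    targets: tuple[str, ...]
    strength: float = 1.5
    active_types: tuple[str, ...] = ()


@dataclass
class SimConfig:
    species: tuple[str, ...]
    divergence: dict[str, float]
    cell_types: dict[str, int]               # cells per type, per species
    n_genes: int
    marker_spec: dict[str, tuple[int, float]]  # type -> (n markers, log2fc)
    sex_spec: list[SexEffect] = field(default_factory=list)
    condition_spec: list[ConditionEffect] = field(default_factory=list)
    regulon_spec: list[RegulonSpec] = field(default_factory=list)
    ortholog_case_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    one_to_many_genes: tuple[str, ...] | None = None  # explicit fan members
    marker_genes: dict[str, tuple[str, ...]] | None = None  # explicit markers
    nb_dispersion: float = 0.3
    library_size_mean: float = 2000.0
    library_size_sigma: float = 0.3
    baseline_sigma: float = 1.0
    n_samples: int = 2
    condition_fraction: float = 0.0          # fraction of cells labeled asthma
    divergence_sigma_scale: float = 2.5      # drift sigma = scale * divergence
    type_pattern_sigma: float = 0.5          # species-shared gene × type program
    regulon_latent_sigma: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if not 2 <= len(self.species) <= 4:
            raise ValueError("need 2–4 species")
        if set(self.divergence) != set(self.species):
            raise ValueError("divergence must cover exactly the species list")
        div = list(self.divergence.values())
        if any(not 0 <= d <= 1 for d in div):
            raise ValueError("divergence values must lie in [0, 1]")
        # ordering against the reference must be well-defined
        nonref = [self.divergence[s] for s in self.species[1:]]
        if len(set(nonref)) != len(nonref):
            raise ValueError("divergence values of the non-reference species must be distinct")
        if self.n_genes <= 0 or any(n <= 0 for n in self.cell_types.values()):
            raise ValueError("counts must be positive")
        if abs(sum(self.ortholog_case_fractions) - 1.0) > 1e-9:
            raise ValueError("ortholog case fractions must sum to 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.one_to_many_genes and self.marker_genes:
            clash = set(self.one_to_many_genes) & {
                g for genes in self.marker_genes.values() for g in genes
            }
            if clash:
                raise ValueError(
                    f"marker genes also listed as one-to-many splits: {sorted(clash)}"
                )


@dataclass
class SimOutput:
    counts: dict[str, CountMatrix]
    cells: dict[str, pd.DataFrame]
    orthologs: dict[str, OrthologTable]      # nonhuman species only
    gene_sets: GeneSetCollection
    truth: dict
    expected_weights: dict[str, pd.DataFrame]  # gene × cell-type mean weights


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def default_config(seed: int = 0, *, cells_per_type: int = 60,
                   condition_fraction: float = 0.0) -> SimConfig:
    """The standard four-species study conditions used throughout.

    Eighteen lung cell types (epithelial, endothelial, mesenchymal and
    immune compartments) shared by human plus three species at divergences
    0.05 / 0.2 / 0.4; 800 human genes; ten 4-fold markers per type; an
    XIST-like exclusive female gene in human and mouse plus two milder
    sex-biased genes; three 30-target regulons active in distinct
    compartments; asthma-responsive genes concentrated in club cells.
    """
    types = [
        "AT1", "AT2", "Bcell", "NK", "Tcell", "basal", "capillary", "ciliated",
        "club", "dendritic", "endothelial", "fibroblast", "goblet", "lymphatic",
        "macrophage", "monocyte", "pericyte", "smooth_muscle",
    ]
    genes = _gene_names(800)
    regulons = [
        RegulonSpec(tf=genes[700], targets=tuple(genes[600:630]), strength=2.5,
                    active_types=("endothelial", "capillary", "lymphatic")),
        RegulonSpec(tf=genes[701], targets=tuple(genes[630:660]), strength=2.5,
                    active_types=("macrophage", "monocyte", "dendritic")),
        RegulonSpec(tf=genes[702], targets=tuple(genes[660:690]), strength=2.5,
                    active_types=("ciliated", "basal")),
    ]
    sex = [
        SexEffect(gene=genes[780], cell_types="all", log2fc=4.0, sex="female",
                  species=("human", "mouse"), exclusive=True),
        SexEffect(gene=genes[781], cell_types=("club", "ciliated"), log2fc=2.0, sex="female"),
        SexEffect(gene=genes[782], cell_types=("macrophage", "Tcell"), log2fc=2.0, sex="male"),
    ]
    condition = (
        [ConditionEffect(gene=genes[750 + i], cell_types=("club",), log2fc=2.0)
         for i in range(12)]
        + [ConditionEffect(gene=genes[762 + i], cell_types=("ciliated",), log2fc=2.0)
           for i in range(3)]
    )
    return SimConfig(
        species=("human", "macaque", "mouse", "rat"),
        divergence={"human": 0.0, "macaque": 0.05, "mouse": 0.2, "rat": 0.4},
        cell_types={t: cells_per_type for t in types},
        n_genes=800,
        marker_spec={t: (10, 2.0) for t in types},
        sex_spec=sex,
        condition_spec=condition,
        regulon_spec=regulons,
        condition_fraction=condition_fraction,
        seed=seed,
    )


def recovery_config(seed: int = 0, *, cells_per_type: int = 100) -> SimConfig:
    """Study conditions for effect-recovery power checks.

    Like :func:`default_config` but with the species-shared gene × type
    program switched off, near-zero (though still distinct) divergences,
    and no condition contrast, so the only cell-type structure in any
    species is the planted markers and regulons: planted-effect recovery
    (marker precision/recall, sex volcano, regulon membership) is then
    well-defined against the truth record. 100 cells per type.
    """
    cfg = default_config(seed, cells_per_type=cells_per_type)
    cfg.type_pattern_sigma = 0.0
    cfg.divergence = {"human": 0.0, "macaque": 1e-3, "mouse": 2e-3, "rat": 3e-3}
    cfg.condition_spec = []
    return cfg


def condition_config(seed: int = 0, *, cells_per_type: int = 60) -> SimConfig:
    """Study conditions for the healthy-vs-asthma comparison.

    Same species and cell types as :func:`default_config`, half the cells
    labeled asthma, and the condition response planted in club (strongly)
    and ciliated (weakly) cells of every species except the most diverged
    one, which is left unresponsive — an animal model that fails to mirror
    the human response.
    """
    cfg = default_config(seed, cells_per_type=cells_per_type, condition_fraction=0.5)
    responsive = ("human", "macaque", "mouse")
    cfg.condition_spec = [
        ConditionEffect(gene=e.gene, cell_types=e.cell_types, log2fc=e.log2fc,
                        condition=e.condition, species=responsive)
        for e in cfg.condition_spec
    ]
    return cfg


def _planted_genes(config: SimConfig) -> set[str]:
    out: set[str] = set()
    for eff in config.sex_spec:
        out.add(eff.gene)
    for eff in config.condition_spec:
        out.add(eff.gene)
    for reg in config.regulon_spec:
        out.add(reg.tf)
        out.update(reg.targets)
    return out


def _assign_markers(config: SimConfig, genes: list[str],
                    reserved: set[str]) -> dict[str, list[str]]:
    if config.marker_genes is not None:
        return {t: list(g) for t, g in config.marker_genes.items()}
    rng = substream(config.seed, "assign_markers")
    pool = [g for g in genes if g not in reserved]
    rng.shuffle(pool)
    out: dict[str, list[str]] = {}
    pos = 0
    for ct in sorted(config.cell_types):
        n_mark, _ = config.marker_spec.get(ct, (0, 0.0))
        out[ct] = sorted(pool[pos:pos + n_mark])
        pos += n_mark
    if pos > len(pool):
        raise ValueError("not enough free genes to plant all markers")
    return out


def _assign_ortholog_cases(config: SimConfig, genes: list[str],
                           protected: set[str]) -> dict:
    """Partition human genes into mapping cases; protected genes stay 1:1."""
    f11, f_m2o, f_o2m = config.ortholog_case_fractions
    rng = substream(config.seed, "ortholog_cases")
    if config.one_to_many_genes is not None:
        fan_members = list(config.one_to_many_genes)
        clash = set(fan_members) & protected
        if clash:
            raise ValueError(f"planted genes listed as one-to-many splits: {sorted(clash)}")
    else:
        free = [g for g in genes if g not in protected]
        rng.shuffle(free)
        n_fan = int(round(f_o2m * len(genes) / 2)) * 2  # fans pair 2 human genes
        fan_members = free[:n_fan]
        free = free[n_fan:]
    n_m2o = int(round(f_m2o * len(genes)))
    if config.one_to_many_genes is not None:
        free = [g for g in genes if g not in protected and g not in set(fan_members)]
        rng.shuffle(free)
    many_to_one = sorted(free[:n_m2o])
    fan_pairs = [tuple(sorted(fan_members[i:i + 2])) for i in range(0, len(fan_members) - 1, 2)]
    in_special = set(many_to_one) | {g for p in fan_pairs for g in p}
    one_to_one = sorted(g for g in genes if g not in in_special)
    return {"one_to_one": one_to_one, "many_to_one": many_to_one, "fan_pairs": fan_pairs}


def _make_cells(config: SimConfig, species: str) -> pd.DataFrame:
    rows = []
    for ct in sorted(config.cell_types):
        n = config.cell_types[ct]
        rng = substream(config.seed, "cells", species, ct)
        sex = np.array(["female"] * (n // 2) + ["male"] * (n - n // 2), dtype=object)
        rng.shuffle(sex)
        n_asthma = int(round(config.condition_fraction * n))
        cond = np.array(["asthma"] * n_asthma + ["healthy"] * (n - n_asthma), dtype=object)
        rng.shuffle(cond)
        samples = rng.integers(1, config.n_samples + 1, size=n)
        for i in range(n):
            rows.append({
                "cell_id": f"{species}.{ct}.{i:04d}",
                "species": species,
                "sample": f"{species}_s{samples[i]}",
                "cell_type": ct,
                "sex": sex[i],
                "condition": cond[i],
            })
    return pd.DataFrame(rows)


def _applies(spec_field, value) -> bool:
    return spec_field == "all" or value in spec_field


def generate(config: SimConfig) -> SimOutput:
    """Draw a full multi-species dataset from the configured model.

    Per gene g, cell type t, species s the negative-binomial mean is
    ``baseline_g · drift_s(g, t) · 2^(marker effect) · 2^(sex/condition
    effects) · regulon factor``, scaled to a lognormal per-cell library
    size; ``drift_s(g, t) = exp(σ_s · z_gt − σ_s²/2)`` with
    ``σ_s = divergence_s · divergence_sigma_scale`` and a fixed
    standard-normal z per (gene, type, species), so divergence 0
    reproduces the human means exactly.
    """
    config.validate()
    genes = _gene_names(config.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    planted = _planted_genes(config)
    missing = planted - set(genes)
    if missing:
        raise ValueError(f"planted genes outside the gene list: {sorted(missing)[:5]}")

    markers = _assign_markers(config, genes, planted)
    protected = planted | {g for gs in markers.values() for g in gs}
    cases = _assign_ortholog_cases(config, genes, protected)

    # baseline relative expression, floored for planted genes so that
    # every planted effect acts on a detectably expressed gene; regulon
    # genes get a higher floor — regulatory programs worth recovering sit
    # on well-expressed genes, and co-expression is invisible at the
    # shot-noise floor
    rng_base = substream(config.seed, "baseline")
    baseline = rng_base.lognormal(mean=0.0, sigma=config.baseline_sigma, size=config.n_genes)
    floor = float(np.median(baseline))
    for g in protected:
        baseline[gene_pos[g]] = max(baseline[gene_pos[g]], floor)
    reg_floor = float(np.quantile(baseline, 0.75))
    for reg in config.regulon_spec:
        for g in (reg.tf, *reg.targets):
            baseline[gene_pos[g]] = max(baseline[gene_pos[g]], reg_floor)

    # per-type multiplicative marker effects (human namespace, all species)
    type_names = sorted(config.cell_types)
    type_effect = pd.DataFrame(1.0, index=genes, columns=type_names)
    for ct, marks in markers.items():
        _, log2fc = config.marker_spec.get(ct, (0, 0.0))
        for g in marks:
            type_effect.loc[g, ct] *= 2.0 ** log2fc

    # species-shared cell-type expression program: every gene varies across
    # types (as real transcriptomes do); divergence drifts relative to it
    tau = config.type_pattern_sigma
    rng_pat = substream(config.seed, "type_pattern")
    u = rng_pat.standard_normal((config.n_genes, len(type_names)))
    type_effect = type_effect * np.exp(tau * u - tau * tau / 2.0)

    counts_out: dict[str, CountMatrix] = {}
    cells_out: dict[str, pd.DataFrame] = {}
    orth_out: dict[str, OrthologTable] = {}
    expected: dict[str, pd.DataFrame] = {}

    for species in config.species:
        cells = _make_cells(config, species)
        n_cells = len(cells)
        # divergence acts per (gene, cell type): a drift constant across
        # types would cancel in between-type contrasts and leave profile
        # distances unchanged, so the perturbation must hit the pattern
        sig = config.divergence[species] * config.divergence_sigma_scale
        rng_drift = substream(config.seed, "drift", species)
        z = rng_drift.standard_normal((config.n_genes, len(type_names)))
        drift = np.exp(sig * z - sig * sig / 2.0)  # genes × types, mean 1
        drift_df = pd.DataFrame(drift, index=genes, columns=type_names)

        ct_arr = cells["cell_type"].to_numpy()
        sex_arr = cells["sex"].to_numpy()
        cond_arr = cells["condition"].to_numpy()
        w = np.empty((config.n_genes, n_cells))
        for ct in type_names:
            mask = ct_arr == ct
            col = baseline * drift_df[ct].to_numpy() * type_effect[ct].to_numpy()
            w[:, mask] = col[:, None]

        for eff in config.sex_spec:
            if not _applies(eff.species, species):
                if eff.exclusive:
                    w[gene_pos[eff.gene], :] = 0.0  # landmark absent in this species
                continue
            gi = gene_pos[eff.gene]
            in_type = np.array([_applies(eff.cell_types, t) for t in ct_arr])
            hit = in_type & (sex_arr == eff.sex)
            w[gi, hit] *= 2.0 ** eff.log2fc
            if eff.exclusive:
                w[gi, sex_arr != eff.sex] = 0.0

        for eff in config.condition_spec:
            if not _applies(eff.species, species):
                continue
            gi = gene_pos[eff.gene]
            in_type = np.array([_applies(eff.cell_types, t) for t in ct_arr])
            hit = in_type & (cond_arr == eff.condition)
            w[gi, hit] *= 2.0 ** eff.log2fc

        for reg in config.regulon_spec:
            rng_reg = substream(config.seed, "regulon", species, reg.tf)
            active = np.array([t in reg.active_types for t in ct_arr])
            latent = np.ones(n_cells)
            latent[active] = rng_reg.lognormal(mean=0.0, sigma=config.regulon_latent_sigma,
                                               size=int(active.sum()))
            tf_factor = np.where(active, (2.0 ** reg.strength) * latent, 1.0)
            tgt_factor = np.where(active, (2.0 ** (0.8 * reg.strength)) * latent ** 0.8, 1.0)
            w[gene_pos[reg.tf], :] *= tf_factor
            for tg in reg.targets:
                w[gene_pos[tg], :] *= tgt_factor

        # expected per-type mean weights (baseline · drift · marker effect):
        # the deterministic part of the model, used for exactness checks
        expected[species] = (type_effect * drift_df).mul(baseline, axis=0)

        # translate to the species' own namespace (the first configured
        # species is the reference and stays in the human namespace)
        if species == config.species[0]:
            src_genes, src_w = genes, w
            pairs = None
        else:
            src_genes, src_w, pairs = _to_source_namespace(species, genes, gene_pos, w, cases)

        rng_counts = substream(config.seed, "counts", species)
        lib_mu = np.log(config.library_size_mean) - config.library_size_sigma ** 2 / 2
        libs = rng_counts.lognormal(mean=lib_mu, sigma=config.library_size_sigma, size=n_cells)
        colsum = src_w.sum(axis=0)
        mu = src_w * (libs / colsum)[None, :]
        r = 1.0 / config.nb_dispersion
        lam = rng_counts.gamma(shape=r, scale=mu / r)
        counts = rng_counts.poisson(lam).astype(np.int32)

        counts_out[species] = CountMatrix(
            x=sp.csr_matrix(counts),
            genes=np.array(src_genes, dtype=object),
            cells=cells["cell_id"].to_numpy(),
            species=species,
            namespace="human" if pairs is None else "source",
        )
        cells_out[species] = cells
        if pairs is not None:
            orth_out[species] = OrthologTable(
                pairs=pd.DataFrame(pairs, columns=["source_symbol", "human_symbol"]),
                species=species,
            )

    gene_sets = _build_gene_sets(config, markers, genes)
    # TF catalog handed to regulon inference: planted TFs plus seeded decoy
    # entries that have no downstream targets (specificity control)
    rng_cat = substream(config.seed, "tf_catalog")
    decoy_pool = sorted(set(cases["one_to_one"]) - protected)
    n_decoys = min(5, len(decoy_pool))
    decoys = sorted(rng_cat.choice(decoy_pool, size=n_decoys, replace=False)) if n_decoys else []
    tf_catalog = sorted({r.tf for r in config.regulon_spec} | set(decoys))
    truth = {
        "species": list(config.species),
        "divergence": dict(config.divergence),
        "divergence_ordering": sorted(
            (s for s in config.species[1:]), key=lambda s: config.divergence[s]
        ),
        "cell_types": sorted(config.cell_types),
        "markers": {ct: sorted(gs) for ct, gs in markers.items()},
        "sex_genes": [asdict(e) for e in config.sex_spec],
        "condition_genes": [asdict(e) for e in config.condition_spec],
        "regulons": {r.tf: sorted(r.targets) for r in config.regulon_spec},
        "regulon_active_types": {r.tf: list(r.active_types) for r in config.regulon_spec},
        "ortholog_cases": {
            "one_to_one": cases["one_to_one"],
            "many_to_one": cases["many_to_one"],
            "one_to_many_pairs": [list(p) for p in cases["fan_pairs"]],
        },
        "tf_catalog": [str(t) for t in tf_catalog],
        "tf_decoys": [str(t) for t in decoys],
        "seed": config.seed,
    }
    return SimOutput(
        counts=counts_out, cells=cells_out, orthologs=orth_out,
        gene_sets=gene_sets, truth=truth, expected_weights=expected,
    )


def _to_source_namespace(species, genes, gene_pos, w, cases):
    """Express the human-namespace weight matrix in species symbols.

    One-to-one genes rename; many-to-one humans split their weight evenly
    across two source symbols; one-to-many fans express one source at the
    average weight of its two human targets.
    """
    prefix = species[:2]
    src_genes: list[str] = []
    rows: list[np.ndarray] = []
    pairs: list[tuple[str, str]] = []
    for h in cases["one_to_one"]:
        s = f"{prefix}_{h}"
        src_genes.append(s)
        rows.append(w[gene_pos[h]])
        pairs.append((s, h))
    for h in cases["many_to_one"]:
        for suffix in ("a", "b"):
            s = f"{prefix}_{h}{suffix}"
            src_genes.append(s)
            rows.append(w[gene_pos[h]] / 2.0)
            pairs.append((s, h))
    for h1, h2 in cases["fan_pairs"]:
        s = f"{prefix}_{h1}x{h2}"
        src_genes.append(s)
        rows.append((w[gene_pos[h1]] + w[gene_pos[h2]]) / 2.0)
        pairs.append((s, h1))
        pairs.append((s, h2))
    return src_genes, np.vstack(rows), pairs


def _build_gene_sets(config: SimConfig, markers: dict[str, list[str]],
                     genes: list[str]) -> GeneSetCollection:
    """Planted marker/regulon sets plus random hallmark-like sets."""
    sets: dict[str, list[str]] = {}
    for ct in sorted(markers):
        if markers[ct]:
            sets[f"MARKERS_{ct}"] = sorted(markers[ct])
    for reg in config.regulon_spec:
        sets[f"REGULON_{reg.tf}"] = sorted([reg.tf, *reg.targets])
    cond_genes = sorted({e.gene for e in config.condition_spec})
    if cond_genes:
        sets["CONDITION_RESPONSE"] = cond_genes
    rng = substream(config.seed, "random_sets")
    n_random = 30
    for i in range(n_random):
        picked = rng.choice(len(genes), size=15, replace=False)
        sets[f"SET_{i:02d}"] = sorted(genes[j] for j in picked)
    return GeneSetCollection(sets=sets, provenance="synthetic")


def write_fixture(out: SimOutput, directory: str | Path) -> dict:
    """Write a SimOutput as plain-text files; returns the manifest.

    Layout: per species a 10x-style Matrix Market directory and a cell
    TSV; per nonhuman species an ortholog TSV; one GMT of planted and
    random gene sets; truth and manifest as JSON.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    # manifest paths are relative to the fixture directory (relocatable)
    manifest: dict = {"species": {}}
    try:
        for species, m in out.counts.items():
            sp_dir = directory / species
            xio.write_counts(m, sp_dir / "counts")
            xio.write_annotations(out.cells[species], sp_dir / "cells.tsv")
            entry = {
                "counts": f"{species}/counts",
                "cells": f"{species}/cells.tsv",
                "namespace": m.namespace,
            }
            if species in out.orthologs:
                xio.write_orthologs(out.orthologs[species], sp_dir / "orthologs.tsv")
                entry["orthologs"] = f"{species}/orthologs.tsv"
            manifest["species"][species] = entry
        xio.write_gmt(out.gene_sets, directory / "gene_sets.gmt")
        (directory / "truth.json").write_text(json.dumps(out.truth, indent=1))
        (directory / "tf_catalog.txt").write_text(
            "\n".join(out.truth.get("tf_catalog", [])) + "\n"
        )
        manifest["gene_sets"] = "gene_sets.gmt"
        manifest["truth"] = "truth.json"
        manifest["tf_catalog"] = "tf_catalog.txt"
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except OSError as exc:
        raise OSError(f"failed writing fixture under {directory}: {exc}") from exc
    return manifest
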