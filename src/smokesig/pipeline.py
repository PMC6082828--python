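"""Configuration-driven end-to-end orchestration of the comparison pipeline.

``run_pipeline`` executes the full analysis graph on synthetic data (or on
user-supplied files):

    generate/load -> pool + QC -> differential expression per design ->
    signatures -> ortholog translation + chromosome filter ->
    pairwise and three-way overlaps -> enrichment matrix -> gene-set
    enrichment -> eQTL mapping -> GWAS follow-up

and returns a :class:`RunReport` whose counts mirror the written TSVs
exactly.  Every stage logs records in/out; every threshold (signature FDR
0.1, eQTL FDR 0.1, GWAS FDR 0.05, 1 Mb cis window, universe policy) is a
named config key.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from smokesig import __version__, io
from smokesig.diffexpr import DesignSpec, derive_signature, differential_expression
from smokesig.eqtl import gwas_followup, map_eqtls, select_top_per_probe
from smokesig.ortholog import filter_human_chromosomes, translate_signature
from smokesig.overlap import (
    coverage_percent,
    enrichment_matrix,
    geneset_enrichment,
    overlap_directional,
    overlap_three_way,
)
from smokesig.preprocess import (
    correct_batch,
    flag_outlier_samples,
    intersect_common_genes,
    qc_report,
    run_pca,
)
from smokesig.synthetic import (
    OrthologConfig,
    StudyConfig,
    generate_eqtl_dataset,
    generate_expression_study,
    generate_gmt,
    generate_gwas_summary,
    generate_ortholog_map,
)
from smokesig.types import ExpressionStudy, Signature

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "fdr": {"signature": 0.1, "eqtl": 0.1, "gwas": 0.05},
    "universe_policy": "intersection",
    "cis_window": 1_000_000,
    "outlier_k_sd": 3.0,
    "synthetic": {
        "ortholog": {
            "n_one_to_one": 1700,
            "n_one_to_two": 100,
            "n_many_to_one": 0,
            "n_mouse_unmapped": 100,
        },
        "mouse_short": {
            "n_cohorts": 3,
            "n_exposed": 4,
            "n_control": 4,
            "noise_sd": 0.5,
            "batch_shift_sd": 0.5,
        },
        "mouse_long": {
            "n_cohorts": 1,
            "n_exposed": 6,
            "n_control": 6,
            "noise_sd": 0.5,
            "batch_shift_sd": 0.5,
        },
        "human": {"n_exposed": 30, "n_control": 30, "noise_sd": 0.5, "batch_shift_sd": 0.0},
        "frac_de": 0.1,
        "effect_mean": 1.5,
        "effect_sd": 0.5,
        "shared_truth_fraction": 0.5,
        "eqtl": {
            "n_snps": 40,
            "n_genes": 25,
            "n_samples": 150,
            "n_true_eqtls": 8,
            "beta": 1.0,
            "maf": 0.3,
            "noise_sd": 0.2,
        },
        "gwas": {"n_associated": 3, "effect": 0.05, "se": 0.01},
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Default config, optionally merged with a YAML file and a dict."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        cfg = _merge(cfg, yaml.safe_load(Path(path).read_text()) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    for name, cut in cfg["fdr"].items():
        if not 0 < cut <= 1:
            raise ValueError(f"fdr cutoff {name} must lie in (0, 1]")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """All per-stage tables and counts of one pipeline run."""

    config: dict
    counts: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)
    signatures: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# synthetic world construction
# ---------------------------------------------------------------------------

def _cross_species_truth(omap, mouse_genes, human_genes, syn, rng):
    """Plant mouse and human effect tables with a shared-ortholog fraction."""
    frac_de = syn["frac_de"]
    n_mouse_de = int(round(frac_de * len(mouse_genes)))
    mouse_truth = pd.DataFrame(
        {"logfc": 0.0, "direction": 0, "shared": False}, index=pd.Index(mouse_genes, name="gene")
    )
    planted = rng.choice(mouse_genes, size=n_mouse_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_mouse_de)
    mags = np.maximum(
        np.abs(syn["effect_mean"] + syn["effect_sd"] * rng.standard_normal(n_mouse_de)), 0.05
    )
    mouse_truth.loc[planted, "logfc"] = signs * mags

    first_ortholog = omap.drop_duplicates("mouse_gene").set_index("mouse_gene")["human_gene"]
    mapped_planted = [g for g in planted if g in first_ortholog.index]
    n_shared = int(round(syn["shared_truth_fraction"] * len(mapped_planted)))
    shared_mouse = list(rng.choice(mapped_planted, size=n_shared, replace=False))
    mouse_truth.loc[shared_mouse, "shared"] = True

    human_truth = pd.DataFrame(
        {"logfc": 0.0, "direction": 0, "shared": False}, index=pd.Index(human_genes, name="gene")
    )
    shared_human = first_ortholog.loc[shared_mouse]
    human_truth.loc[shared_human, "logfc"] = mouse_truth.loc[shared_mouse, "logfc"].to_numpy()
    human_truth.loc[shared_human, "shared"] = True
    n_human_de = int(round(frac_de * len(human_genes)))
    n_private = max(0, n_human_de - len(shared_human))
    pool = human_truth.index.difference(shared_human)
    private = rng.choice(pool, size=min(n_private, len(pool)), replace=False)
    psigns = rng.choice([-1.0, 1.0], size=len(private))
    pmags = np.maximum(
        np.abs(syn["effect_mean"] + syn["effect_sd"] * rng.standard_normal(len(private))), 0.05
    )
    human_truth.loc[private, "logfc"] = psigns * pmags
    for t in (mouse_truth, human_truth):
        t["direction"] = np.sign(t["logfc"]).astype(int)
    return mouse_truth, human_truth


def generate_world(cfg: dict) -> dict:
    """Build the full synthetic study collection described by the config."""
    syn = cfg["synthetic"]
    seed = cfg["seed"]
    rng = np.random.default_rng(seed)

    omap = generate_ortholog_map(OrthologConfig(seed=seed, **syn["ortholog"]))
    mouse_genes = sorted(set(omap["mouse_gene"]) | set(omap.attrs["unmapped_mouse_genes"]))
    human_genes = sorted(set(omap["human_gene"]))
    mouse_truth, human_truth = _cross_species_truth(omap, mouse_genes, human_genes, syn, rng)

    def cohorts(block, prefix, truth, labels):
        out = []
        for i in range(block.get("n_cohorts", 1)):
            config = StudyConfig(
                n_genes=len(truth),
                n_exposed=block["n_exposed"],
                n_control=block["n_control"],
                frac_de=cfg["synthetic"]["frac_de"],
                effect_mean=syn["effect_mean"],
                effect_sd=syn["effect_sd"],
                noise_sd=block["noise_sd"],
                batch_shift_sd=block["batch_shift_sd"],
                seed=seed + 1000 * (i + 1) + sum(ord(ch) for ch in prefix) % 997,
                cohort=f"{prefix}{i + 1}",
                group_labels=labels,
            )
            study, _ = generate_expression_study(config, gene_ids=truth.index, truth=truth)
            out.append(study)
        return out

    world = {
        "omap": omap,
        "mouse_truth": mouse_truth,
        "human_truth": human_truth,
        "mouse_short": cohorts(syn["mouse_short"], "ms", mouse_truth, ("exposed", "control")),
        "mouse_long": cohorts(syn["mouse_long"], "ml", mouse_truth, ("exposed", "control")),
        "human": cohorts(syn["human"], "hu", human_truth, ("smoker", "never"))[0],
    }
    e = syn["eqtl"]
    world["eqtl"] = generate_eqtl_dataset(seed=seed + 77, **e)
    return world


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def _signature_from_cohorts(
    cohorts: list[ExpressionStudy],
    design: DesignSpec,
    fdr_cutoff: float,
    species: str,
    outlier_k_sd: float,
    counts: dict,
    label: str,
) -> tuple[Signature, pd.DataFrame, pd.DataFrame | None]:
    """Pool (if several cohorts), QC, batch-correct, DE, threshold."""
    if len(cohorts) > 1:
        pooled = correct_batch(intersect_common_genes(cohorts))
        # QC on batch-corrected data so cohort offsets do not masquerade
        # as sample outliers
        pca = run_pca(pooled, k=2)
        flagged = flag_outlier_samples(pca, k_sd=outlier_k_sd)
        qc = qc_report(pca, flagged)
        if flagged:
            logger.info("%s: excluding %d outlier samples: %s", label, len(flagged), flagged)
            pooled = correct_batch(
                pooled.subset_samples(
                    [s for s in pooled.sample_ids if s not in set(flagged)]
                )
            )
        counts[f"{label}_samples_excluded"] = len(flagged)
    else:
        pooled = cohorts[0]
        qc = None
        counts[f"{label}_samples_excluded"] = 0
    counts[f"{label}_genes_tested"] = pooled.n_genes
    counts[f"{label}_samples_used"] = pooled.n_samples
    de = differential_expression(pooled, design)
    sig = derive_signature(de, fdr_cutoff, species=species)
    counts[f"{label}_signature_size"] = len(sig)
    logger.info("%s: %d/%d genes at FDR < %s", label, len(sig), pooled.n_genes, fdr_cutoff)
    return sig, de, qc


def run_pipeline(cfg: dict | None = None) -> RunReport:
    """Execute the full synthetic end-to-end analysis; deterministic per seed."""
    cfg = load_config() if cfg is None else cfg
    report = RunReport(config=cfg)
    counts, tables = report.counts, report.tables
    sig_cut = cfg["fdr"]["signature"]
    k_sd = cfg["outlier_k_sd"]

    world = generate_world(cfg)
    omap = world["omap"]
    tables["ortholog_map"] = omap

    mouse_design = DesignSpec("group", ("exposed", "control"))
    human_design = DesignSpec("group", ("smoker", "never"))

    sig_ms, de_ms, qc_ms = _signature_from_cohorts(
        world["mouse_short"], mouse_design, sig_cut, "mouse", k_sd, counts, "mouse_short"
    )
    sig_ml, de_ml, _ = _signature_from_cohorts(
        world["mouse_long"], mouse_design, sig_cut, "mouse", k_sd, counts, "mouse_long"
    )
    sig_hu, de_hu, _ = _signature_from_cohorts(
        [world["human"]], human_design, sig_cut, "human", k_sd, counts, "human_smoking"
    )
    tables["de_mouse_short"] = de_ms
    tables["de_mouse_long"] = de_ml
    tables["de_human"] = de_hu
    if qc_ms is not None:
        tables["qc_mouse_short"] = qc_ms

    # ortholog translation + chromosome filter
    sig_ms_h = filter_human_chromosomes(translate_signature(sig_ms, omap), omap)
    sig_ml_h = filter_human_chromosomes(translate_signature(sig_ml, omap), omap)
    sig_hu_f = filter_human_chromosomes(sig_hu, omap)
    counts["mouse_short_translated"] = len(sig_ms_h)
    counts["mouse_long_translated"] = len(sig_ml_h)
    counts["human_filtered"] = len(sig_hu_f)
    report.signatures = {
        "mouse_short": sig_ms_h,
        "mouse_long": sig_ml_h,
        "human_smoking": sig_hu_f,
    }

    # overlaps
    pair_rows = []
    overlaps = {
        ("human_smoking", "mouse_short"): overlap_directional(sig_hu_f, sig_ms_h),
        ("human_smoking", "mouse_long"): overlap_directional(sig_hu_f, sig_ml_h),
        ("mouse_short", "mouse_long"): overlap_directional(sig_ms_h, sig_ml_h),
    }
    sizes = {"human_smoking": len(sig_hu_f), "mouse_short": len(sig_ms_h), "mouse_long": len(sig_ml_h)}
    for (na, nb), ov in overlaps.items():
        up, down, disc = ov.counts
        pair_rows.append(
            {
                "signature_a": na,
                "signature_b": nb,
                "shared": ov.n_shared,
                "concordant_up": up,
                "concordant_down": down,
                "discordant": disc,
                "pct_of_a": coverage_percent(ov.n_shared, sizes[na]) if sizes[na] else np.nan,
                "pct_of_b": coverage_percent(ov.n_shared, sizes[nb]) if sizes[nb] else np.nan,
            }
        )
    tables["overlap_pairwise"] = pd.DataFrame(pair_rows)
    three = overlap_three_way(sig_hu_f, sig_ms_h, sig_ml_h)
    tables["overlap_three_way"] = three.table
    counts["three_way_shared"] = three.n_shared
    counts["three_way_concordant_up"] = three.concordant_up
    counts["three_way_concordant_down"] = three.concordant_down
    counts["three_way_discordant"] = three.discordant

    # enrichment
    tables["enrichment_matrix"] = enrichment_matrix(
        report.signatures, cfg["universe_policy"]
    )
    gmt_universe = sorted(sig_hu_f.universe)
    gmt = generate_gmt(
        gmt_universe,
        seed=cfg["seed"] + 5,
        enriched_genes=sorted(three.table["gene"]) if three.n_shared else None,
    )
    query = set(three.table["gene"]) if three.n_shared else sig_hu_f.genes
    tables["geneset_enrichment"] = geneset_enrichment(query, gmt, set(gmt_universe))

    # eQTL + GWAS follow-up
    dosages, expr, snp_pos, gene_pos, eqtl_truth = world["eqtl"]
    records = map_eqtls(
        dosages, expr, snp_pos, gene_pos,
        fdr_cutoff=cfg["fdr"]["eqtl"], cis_window=cfg["cis_window"],
    )
    tables["eqtl_records"] = records
    counts["eqtl_pairs_tested"] = len(records)
    counts["eqtl_significant"] = int(records["significant"].sum())
    sig_records = records[records["significant"]]
    if sig_records.empty:
        logger.info("no significant eQTLs; skipping GWAS follow-up")
        top_snps = []
    else:
        top_snps = select_top_per_probe(sig_records)
    counts["top_eqtl_snps"] = len(top_snps)
    g = cfg["synthetic"]["gwas"]
    gwas = generate_gwas_summary(
        list(dosages.index), seed=cfg["seed"] + 99, **g
    )
    tables["gwas_summary"] = gwas
    if top_snps:
        follow = gwas_followup(top_snps, gwas, fdr_cutoff=cfg["fdr"]["gwas"])
        tables["gwas_followup"] = follow.table
        counts["gwas_flagged"] = int(follow.table["flagged"].sum())
        counts["gwas_missing"] = len(follow.missing)
    else:
        tables["gwas_followup"] = pd.DataFrame(
            columns=["snp", "effect", "se", "p_value", "fdr", "flagged"]
        )
        counts["gwas_flagged"] = 0
        counts["gwas_missing"] = 0

    return report


def write_report(report: RunReport, outdir) -> list[Path]:
    """Write every table as TSV plus a machine-readable run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in report.tables.items():
        path = outdir / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False)
        written.append(path)
    for name, sig in report.signatures.items():
        path = outdir / f"signature_{name}.tsv"
        io.write_signature(sig, path)
        written.append(path)
    manifest = {
        "config_hash": config_hash(report.config),
        "seed": report.config["seed"],
        "version": __version__,
        "counts": report.counts,
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(mpath)
    return written
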