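"""cis/trans eQTL mapping with fixed-effect meta-analysis and GWAS follow-up.

Every (SNP, gene) pair is tested by simple linear regression of log2
expression on additive genotype dosage, separately per cohort; per-cohort
slopes are combined by inverse-variance fixed-effect meta-analysis and a
single BH-FDR is applied across all tested pairs (cis and trans jointly).
A pair is cis when the SNP lies within 1 Mb of the gene's transcription
start site on the same chromosome (boundary inclusive), trans otherwise.

The follow-up stage takes the most significant eQTL per gene (deduplicated
SNP list), looks the SNPs up in a GWAS summary table and applies BH over
the submitted lookup list only — the multiplicity burden of a targeted
lookup, not of the genome-wide scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from smokesig.diffexpr import adjust_bh, meta_analyze_fixed
from smokesig.types import ExpressionStudy

logger = logging.getLogger(__name__)

CIS_WINDOW = 1_000_000


def cis_trans_labels(
    snp_pos: pd.DataFrame, gene_pos: pd.DataFrame, window: int = CIS_WINDOW
) -> pd.DataFrame:
    """All (snp, gene) pairs with a boolean cis flag (inclusive 1 Mb window)."""
    pairs = snp_pos.merge(gene_pos, how="cross", suffixes=("_snp", "_gene"))
    pairs["cis"] = (pairs["chrom_snp"] == pairs["chrom_gene"]) & (
        (pairs["pos"] - pairs["tss"]).abs() <= window
    )
    return pairs[["snp", "gene", "cis"]]


def _regress_all_pairs(
    dosages: pd.DataFrame, expression: ExpressionStudy
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-pair simple regression: slope, SE, valid mask.

    Returns (n_snps x n_genes) arrays.  Monomorphic SNPs get valid=False.
    """
    common = dosages.columns.intersection(expression.sample_ids)
    if len(common) < 3:
        raise ValueError("need at least 3 samples shared by genotypes and expression")
    G = dosages[common].to_numpy(dtype=float)  # snps x n
    Y = expression.values[common].to_numpy(dtype=float)  # genes x n
    n = len(common)
    Gc = G - G.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sxx = (Gc**2).sum(axis=1)  # per snp
    syy = (Yc**2).sum(axis=1)  # per gene
    valid_snp = sxx > 0
    sxx_safe = np.where(valid_snp, sxx, 1.0)
    sxy = Gc @ Yc.T  # snps x genes
    beta = sxy / sxx_safe[:, None]
    sse = syy[None, :] - beta * sxy
    sse = np.maximum(sse, 0.0)
    sigma2 = sse / (n - 2)
    se = np.sqrt(sigma2 / sxx_safe[:, None])
    valid = np.broadcast_to(valid_snp[:, None], beta.shape) & (se > 0)
    return beta, se, valid


def map_eqtls(
    genotypes: dict[str, pd.DataFrame] | pd.DataFrame,
    expression: dict[str, ExpressionStudy] | ExpressionStudy,
    snp_pos: pd.DataFrame,
    gene_pos: pd.DataFrame,
    fdr_cutoff: float = 0.1,
    cis_window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """Genome-wide eQTL scan: per-cohort regression, meta-analysis, joint BH.

    ``genotypes``/``expression`` may be single objects (one cohort) or
    dicts keyed by cohort.  Returns a table (snp, gene, cis, effect, se,
    p_value, fdr, significant) over every testable pair; pairs whose SNP
    is monomorphic in all cohorts are dropped with a logged count.
    """
    if not isinstance(genotypes, dict):
        genotypes = {"cohort1": genotypes}
        expression = {"cohort1": expression}
    if set(genotypes) != set(expression):
        raise ValueError("genotype and expression cohorts differ")

    cohorts = sorted(genotypes)
    first = genotypes[cohorts[0]]
    snps = first.index
    genes = expression[cohorts[0]].genes
    betas, ses, valids = [], [], []
    for c in cohorts:
        d = genotypes[c].loc[snps]
        vals = d.to_numpy(dtype=float)
        if vals.min() < 0 or vals.max() > 2:
            raise ValueError("dosages must lie in [0, 2]")
        b, s, v = _regress_all_pairs(d, expression[c])
        betas.append(b)
        ses.append(s)
        valids.append(v)

    beta = np.stack(betas, axis=-1)  # snps x genes x cohorts
    se = np.stack(ses, axis=-1)
    valid = np.stack(valids, axis=-1)
    any_valid = valid.any(axis=-1)
    n_dropped = int((~any_valid).sum())
    if n_dropped:
        logger.info("%d (snp, gene) pairs untestable (monomorphic in all cohorts)", n_dropped)

    flat_b = np.where(valid, beta, np.nan).reshape(-1, len(cohorts))
    flat_s = np.where(valid, se, np.nan).reshape(-1, len(cohorts))
    keep = any_valid.ravel()
    meta = meta_analyze_fixed(flat_b[keep], flat_s[keep])

    snp_grid, gene_grid = np.meshgrid(np.arange(len(snps)), np.arange(len(genes)), indexing="ij")
    records = pd.DataFrame(
        {
            "snp": np.asarray(snps)[snp_grid.ravel()[keep]],
            "gene": np.asarray(genes)[gene_grid.ravel()[keep]],
            "effect": meta.effect,
            "se": meta.se,
            "p_value": meta.p_value,
        }
    )
    records["fdr"] = adjust_bh(records["p_value"].to_numpy())
    records["significant"] = records["fdr"] < fdr_cutoff
    labels = cis_trans_labels(snp_pos, gene_pos, cis_window)
    records = records.merge(labels, on=["snp", "gene"], how="left")
    if records["cis"].isna().any():
        raise ValueError("positions missing for some tested (snp, gene) pairs")
    cols = ["snp", "gene", "cis", "effect", "se", "p_value", "fdr", "significant"]
    return records[cols].sort_values(["p_value", "snp", "gene"], kind="mergesort").reset_index(drop=True)


def select_top_per_probe(records: pd.DataFrame) -> list[str]:
    """The most significant eQTL SNP per gene/probe, deduplicated.

    Ties in p are broken by SNP id (lexicographic) for determinism; a SNP
    topping several genes appears once.  Returns a sorted SNP list.
    """
    if records.empty:
        raise ValueError("no eQTL records")
    ordered = records.sort_values(["gene", "p_value", "snp"], kind="mergesort")
    top = ordered.groupby("gene", sort=True).head(1)
    return sorted(top["snp"].unique())


@dataclass
class GwasFollowup:
    """Lookup of candidate SNPs in GWAS summary statistics."""

    table: pd.DataFrame  # snp, effect, se, p_value, fdr, flagged
    screened: pd.DataFrame  # rows with raw p < screen_p
    missing: list[str]


def gwas_followup(
    snps: list[str],
    gwas: pd.DataFrame,
    fdr_cutoff: float = 0.05,
    screen_p: float = 0.05,
) -> GwasFollowup:
    """BH over a targeted SNP lookup list; flag FDR < cutoff, screen raw p.

    SNPs absent from the summary table are reported in ``missing``, never
    silently dropped; the BH adjustment runs over the found lookups.
    Raises if no query SNP is present at all.
    """
    query = list(dict.fromkeys(snps))  # preserve order, dedupe
    found = gwas[gwas["snp"].isin(query)].drop_duplicates("snp").copy()
    missing = [s for s in query if s not in set(found["snp"])]
    if found.empty:
        raise ValueError("none of the query SNPs are present in the GWAS summary")
    if missing:
        logger.info("%d query SNPs missing from the GWAS summary", len(missing))
    found["fdr"] = adjust_bh(found["p_value"].to_numpy())
    found["flagged"] = found["fdr"] < fdr_cutoff
    found = found.sort_values(["p_value", "snp"], kind="mergesort").reset_index(drop=True)
    screened = found[found["p_value"] < screen_p].reset_index(drop=True)
    return GwasFollowup(found, screened, missing)
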