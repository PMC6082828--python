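"""Synthetic two-species expression studies with planted ground truth.

The generators emulate the structure of the real inputs — several small
smoke-exposure mouse cohorts on partially overlapping gene panels, a large
human cohort, a BioMart-style ortholog map with one-to-many relations, a
genotype/expression panel for eQTL mapping and a GWAS summary table —
without simulating raw array intensities.  Expression is drawn directly on
the log2 scale (the real arrays are RMA/fRMA-normalised log2 values);
cohort batch effects are additive gene-wise offsets.

Every generator is deterministic under a fixed seed, and every dataset is
returned together with a truth table that downstream analysis stages never
see (recovery tests compare analysis output against it afterwards).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from smokesig.types import ExpressionStudy

logger = logging.getLogger(__name__)

# Chromosome labels a BioMart-style export can carry; only 1-22/X/Y survive
# the downstream chromosome filter.
_HUMAN_CHROMS = [str(i) for i in range(1, 23)] + ["X", "Y", "MT", "scaffold-GL000195"]
_CHROM_WEIGHTS = np.array([10.0] * 22 + [3.0, 1.0, 0.5, 0.5])


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of one synthetic expression cohort.

    Defaults mirror a small smoke-exposure experiment: a few thousand
    measured genes, single-digit group sizes, ~10% of genes perturbed with
    log2 fold changes centred on 1.5 (the observed signature spans roughly
    0.7-4 in absolute logFC), residual noise of 0.5 log2 units and a
    cohort-level additive batch offset of comparable scale.
    """

    n_genes: int = 2000
    n_exposed: int = 4
    n_control: int = 4
    frac_de: float = 0.1
    effect_mean: float = 1.5
    effect_sd: float = 0.5
    noise_sd: float = 0.5
    batch_shift_sd: float = 0.5
    seed: int = 0
    cohort: str = "cohort1"
    group_labels: tuple[str, str] = ("exposed", "control")
    gene_prefix: str = "gene"

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_exposed < 1 or self.n_control < 1:
            raise ValueError("group sample counts must be positive")
        if not 0 <= self.frac_de <= 1:
            raise ValueError("frac_de must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass(frozen=True)
class OrthologConfig:
    """Multiplicity-class composition of a synthetic mouse-to-human ortholog map."""

    n_one_to_one: int = 1000
    n_one_to_two: int = 50
    n_mouse_unmapped: int = 50
    n_many_to_one: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_one_to_one", "n_one_to_two", "n_mouse_unmapped", "n_many_to_one"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def _make_truth(
    gene_ids: pd.Index, frac_de: float, effect_mean: float, effect_sd: float, rng
) -> pd.DataFrame:
    """Draw a planted-effect table: logfc (0 for nulls), direction, shared flag."""
    n_de = int(round(frac_de * len(gene_ids)))
    chosen = rng.choice(len(gene_ids), size=n_de, replace=False)
    logfc = np.zeros(len(gene_ids))
    signs = rng.choice([-1.0, 1.0], size=n_de)
    magnitudes = effect_mean + effect_sd * rng.standard_normal(n_de)
    # keep planted effects away from zero so direction is well defined
    magnitudes = np.maximum(np.abs(magnitudes), 0.05)
    logfc[chosen] = signs * magnitudes
    return pd.DataFrame(
        {
            "logfc": logfc,
            "direction": np.sign(logfc).astype(int),
            "shared": False,
        },
        index=gene_ids,
    )


def _simulate_from_truth(
    config: StudyConfig, truth: pd.DataFrame, rng
) -> ExpressionStudy:
    gene_ids = truth.index
    n = config.n_exposed + config.n_control
    exposed_label, control_label = config.group_labels
    sample_ids = [f"{config.cohort}_s{i:03d}" for i in range(n)]
    groups = [exposed_label] * config.n_exposed + [control_label] * config.n_control

    baseline = 7.0 + rng.standard_normal(len(gene_ids))
    batch = config.batch_shift_sd * rng.standard_normal(len(gene_ids))
    mat = (
        baseline[:, None]
        + batch[:, None]
        + config.noise_sd * rng.standard_normal((len(gene_ids), n))
    )
    mat[:, : config.n_exposed] += truth["logfc"].to_numpy()[:, None]

    values = pd.DataFrame(mat, index=gene_ids, columns=sample_ids)
    samples = pd.DataFrame(
        {"group": groups, "cohort": config.cohort},
        index=pd.Index(sample_ids, name="sample"),
    )
    return ExpressionStudy(values, samples)


def generate_expression_study(
    config: StudyConfig,
    gene_ids: pd.Index | list[str] | None = None,
    truth: pd.DataFrame | None = None,
) -> tuple[ExpressionStudy, pd.DataFrame]:
    """Simulate one cohort: exposed-group means shifted by planted log2 fold changes.

    Returns the study and its truth table.  ``gene_ids`` overrides the
    default panel (``gene0000``...); ``truth`` plants a caller-supplied
    effect table instead of drawing a fresh one (used by the multi-cohort
    and cross-species generators to share planted genes).
    """
    rng = np.random.default_rng(config.seed)
    if gene_ids is None:
        gene_ids = pd.Index(
            [f"{config.gene_prefix}{i:05d}" for i in range(config.n_genes)], name="gene"
        )
    else:
        gene_ids = pd.Index(gene_ids, name="gene")
    if truth is None:
        truth = _make_truth(
            gene_ids, config.frac_de, config.effect_mean, config.effect_sd, rng
        )
    else:
        truth = truth.loc[gene_ids]
    study = _simulate_from_truth(replace(config, n_genes=len(gene_ids)), truth, rng)
    return study, truth


def generate_multi_cohort(
    configs: list[StudyConfig],
    shared_truth_fraction: float = 1.0,
    gene_lists: list[list[str]] | None = None,
) -> list[tuple[ExpressionStudy, pd.DataFrame]]:
    """Simulate several cohorts whose planted genes partially coincide.

    A ``shared_truth_fraction`` of each cohort's planted budget is drawn
    once, from the genes common to all cohorts, and planted identically
    (same logFC) everywhere; the remainder is private per cohort.  Cohorts
    may measure different gene panels via ``gene_lists``.
    """
    if not configs:
        raise ValueError("need at least one cohort config")
    if not 0 <= shared_truth_fraction <= 1:
        raise ValueError("shared_truth_fraction must lie in [0, 1]")
    if len(configs) == 1 and gene_lists is None:
        # sharing is vacuous for a single cohort; reduce to the plain generator
        return [generate_expression_study(configs[0])]

    if gene_lists is None:
        panels = [
            pd.Index([f"{c.gene_prefix}{i:05d}" for i in range(c.n_genes)], name="gene")
            for c in configs
        ]
    else:
        panels = [pd.Index(gl, name="gene") for gl in gene_lists]

    common = panels[0]
    for p in panels[1:]:
        common = common.intersection(p)

    head = configs[0]
    rng = np.random.default_rng(head.seed + 104729)  # separate stream for sharing
    n_de_each = [int(round(c.frac_de * len(p))) for c, p in zip(configs, panels)]
    n_shared = int(round(shared_truth_fraction * min(n_de_each))) if n_de_each else 0
    n_shared = min(n_shared, len(common))
    shared_genes = pd.Index(
        sorted(rng.choice(common, size=n_shared, replace=False))
    )
    shared_signs = rng.choice([-1.0, 1.0], size=n_shared)
    shared_mags = np.maximum(
        np.abs(head.effect_mean + head.effect_sd * rng.standard_normal(n_shared)), 0.05
    )
    shared_logfc = pd.Series(shared_signs * shared_mags, index=shared_genes)

    out = []
    for config, panel, n_de in zip(configs, panels, n_de_each):
        crng = np.random.default_rng(config.seed)
        truth = pd.DataFrame(
            {"logfc": 0.0, "direction": 0, "shared": False}, index=panel
        )
        truth.loc[shared_genes, "logfc"] = shared_logfc
        truth.loc[shared_genes, "shared"] = True
        n_private = max(0, n_de - n_shared)
        candidates = panel.difference(shared_genes)
        private = crng.choice(candidates, size=min(n_private, len(candidates)), replace=False)
        signs = crng.choice([-1.0, 1.0], size=len(private))
        mags = np.maximum(
            np.abs(
                config.effect_mean + config.effect_sd * crng.standard_normal(len(private))
            ),
            0.05,
        )
        truth.loc[private, "logfc"] = signs * mags
        truth["direction"] = np.sign(truth["logfc"]).astype(int)
        study = _simulate_from_truth(replace(config, n_genes=len(panel)), truth, crng)
        out.append((study, truth))
    return out


def generate_ortholog_map(config: OrthologConfig) -> pd.DataFrame:
    """Build a mouse-to-human ortholog table with controlled multiplicity classes.

    Mouse genes partition into one-to-one, one-to-two, unmapped and
    many-to-one (two mouse genes sharing one human gene) classes; every
    human gene is assigned a chromosome label, mostly autosomal with
    occasional X/Y/MT/scaffold entries so the chromosome filter has work
    to do.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[tuple[str, str]] = []
    m = h = 0

    def next_mouse():
        nonlocal m
        m += 1
        return f"mm{m:05d}"

    def next_human():
        nonlocal h
        h += 1
        return f"HS{h:05d}"

    for _ in range(config.n_one_to_one):
        rows.append((next_mouse(), next_human()))
    for _ in range(config.n_one_to_two):
        mg = next_mouse()
        rows.append((mg, next_human()))
        rows.append((mg, next_human()))
    for _ in range(config.n_many_to_one):
        hg = next_human()
        rows.append((next_mouse(), hg))
        rows.append((next_mouse(), hg))
    unmapped = [next_mouse() for _ in range(config.n_mouse_unmapped)]

    omap = pd.DataFrame(rows, columns=["mouse_gene", "human_gene"])
    chrom_of = {
        hg: rng.choice(_HUMAN_CHROMS, p=_CHROM_WEIGHTS / _CHROM_WEIGHTS.sum())
        for hg in omap["human_gene"].unique()
    }
    omap["human_chromosome"] = omap["human_gene"].map(chrom_of)
    omap.attrs["unmapped_mouse_genes"] = unmapped
    return omap


def generate_eqtl_dataset(
    n_snps: int = 50,
    n_genes: int = 30,
    n_samples: int = 200,
    n_true_eqtls: int = 10,
    beta: float = 1.0,
    maf: float = 0.3,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, ExpressionStudy, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a genotype panel with planted expression QTLs.

    True eQTL ``i`` pairs SNP ``i`` with gene ``i``; pairs alternate
    between cis (SNP 0.5 Mb from the gene's TSS) and trans (different
    chromosome) placements so both labels occur by construction.  Returns
    (dosages, expression study, snp positions, gene positions, truth).
    """
    if not 0 < maf < 0.5:
        raise ValueError("maf must lie in (0, 0.5)")
    if n_true_eqtls > min(n_snps, n_genes):
        raise ValueError("n_true_eqtls cannot exceed n_snps or n_genes")
    rng = np.random.default_rng(seed)

    snp_ids = [f"rs{i:05d}" for i in range(n_snps)]
    gene_ids = pd.Index([f"HS{i:05d}" for i in range(n_genes)], name="gene")
    sample_ids = [f"ind{i:04d}" for i in range(n_samples)]

    dosage = rng.binomial(2, maf, size=(n_snps, n_samples)).astype(float)
    for i in range(n_snps):  # monomorphic SNPs carry no information; redraw
        tries = 0
        while np.ptp(dosage[i]) == 0:
            dosage[i] = rng.binomial(2, maf, size=n_samples)
            tries += 1
            if tries > 100:
                raise ValueError("cannot draw a polymorphic SNP; increase n_samples/maf")
    dosages = pd.DataFrame(dosage, index=pd.Index(snp_ids, name="snp"), columns=sample_ids)

    # gene TSSs 2 Mb apart on chr1/chr2 so cis windows never overlap two genes
    gene_pos = pd.DataFrame(
        {
            "gene": gene_ids,
            "chrom": ["chr1" if i % 2 == 0 else "chr2" for i in range(n_genes)],
            "tss": [2_000_000 * (i + 1) for i in range(n_genes)],
        }
    )
    snp_chrom, snp_bp = [], []
    for i in range(n_snps):
        if i < n_true_eqtls and i % 2 == 0:  # cis placement next to gene i
            snp_chrom.append(gene_pos.loc[i, "chrom"])
            snp_bp.append(int(gene_pos.loc[i, "tss"]) + 500_000)
        elif i < n_true_eqtls:  # trans: other chromosome
            snp_chrom.append("chr2" if gene_pos.loc[i, "chrom"] == "chr1" else "chr1")
            snp_bp.append(int(rng.integers(1, 1_000_000)))
        else:
            snp_chrom.append(rng.choice(["chr1", "chr2"]))
            snp_bp.append(int(rng.integers(1, 100_000_000)))
    snp_pos = pd.DataFrame({"snp": snp_ids, "chrom": snp_chrom, "pos": snp_bp})

    expr = 7.0 + rng.standard_normal(n_genes)[:, None] + noise_sd * rng.standard_normal(
        (n_genes, n_samples)
    )
    truth_rows = []
    for i in range(n_true_eqtls):
        if beta != 0:
            expr[i] += beta * dosage[i]
            truth_rows.append((snp_ids[i], gene_ids[i], beta))
    truth = pd.DataFrame(truth_rows, columns=["snp", "gene", "beta"])

    samples = pd.DataFrame(
        {"group": "na", "cohort": "eqtl"}, index=pd.Index(sample_ids, name="sample")
    )
    study = ExpressionStudy(pd.DataFrame(expr, index=gene_ids, columns=sample_ids), samples)
    return dosages, study, snp_pos, gene_pos, truth


def generate_gmt(
    universe: list[str],
    n_sets: int = 10,
    set_size: int = 30,
    seed: int = 0,
    enriched_genes: list[str] | None = None,
) -> dict[str, set[str]]:
    """Random annotation sets over a universe, plus one set seeded with
    ``enriched_genes`` (if given) so a positive control exists."""
    rng = np.random.default_rng(seed)
    universe = list(universe)
    sets: dict[str, set[str]] = {}
    for i in range(n_sets):
        size = min(set_size, len(universe))
        sets[f"SET{i:03d}"] = set(rng.choice(universe, size=size, replace=False))
    if enriched_genes:
        core = list(enriched_genes)[:set_size]
        pad = min(max(0, set_size - len(core)), len(universe))
        sets["SET_planted"] = set(core) | set(rng.choice(universe, size=pad, replace=False))
    return sets


def generate_gwas_summary(
    snps: list[str],
    n_associated: int = 0,
    effect: float = 0.05,
    se: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-SNP effect/SE/p summary table with ``n_associated`` true signals.

    Null SNPs draw their effect from N(0, se^2); associated SNPs (the first
    ``n_associated`` in the list) from N(effect, se^2).  p-values are the
    two-sided normal tail of effect/se, so p = 2*Phi(-|z|) holds by
    construction.
    """
    if not snps:
        raise ValueError("snps must be nonempty")
    rng = np.random.default_rng(seed)
    effects = rng.normal(0.0, se, size=len(snps))
    effects[:n_associated] = rng.normal(effect, se, size=n_associated)
    z = effects / se
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"snp": list(snps), "effect": effects, "se": se, "p_value": p})
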