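# Methods

This note records the models, defaults and design choices behind
`smokesig`, and what the synthetic studies do and do not establish about
real data.

## Differential expression

Each gene is modelled by ordinary least squares on a design with an
intercept, a two-level contrast indicator (exposed/control,
smoker/never, severe/mild) and optional covariates; categorical
covariates are dummy-coded against their first level.  The contrast
coefficient is the log2 fold change.  Rank-deficient designs are rejected
with the offending columns named.

Variance moderation follows the standard empirical-Bayes hierarchy for
expression arrays: s²_g | σ²_g ~ σ²_g·χ²_df/df with σ²_g drawn from a
scaled inverse-chi-square prior (d₀, s₀²).  The hyperparameters are
estimated by moment-matching e_g = log s²_g − ψ(df/2) + log(df/2):
E[e] = log s₀² − ψ(d₀/2) + log(d₀/2) and
Var[e] = ψ′(df/2) + ψ′(d₀/2), with the trigamma equation inverted by
Newton iteration.  When the observed spread of log-variances does not
exceed the within-gene expectation, d₀ is infinite and every posterior
variance equals s₀².  Moderated t statistics are referred to
t(d₀ + df), with the total degrees of freedom capped at the pooled
residual df of the whole gene collection — shrinkage cannot claim more
information than was observed.  A unit test cross-checks t, p and the
hyperparameters against limma's `eBayes` on a small fixture (agreement to
0.5%; the residual difference is limma's slightly different moment
correction).

Zero residual variances (possible in degenerate fixtures) are excluded
from hyperparameter estimation but still shrunk.  BH adjustment is
delegated to statsmodels and verified against a brute-force step-up
oracle; NaN p-values are excluded and propagated.  Signatures use strict
FDR < cutoff, except that cutoff = 1.0 keeps everything; p-ties in
reports are broken by gene id so outputs are byte-stable.

The pooled mouse analysis uses exposure as the only model term (cohort is
handled by the batch-correction step, and the controls are pooled across
experiments); cohort can be added as a covariate via `DesignSpec` if a
user prefers a blocked analysis.

## Pooling, QC and batch correction

Cohorts are pooled on the intersection of their gene panels
(lexicographically ordered).  Batch correction shifts each batch's
per-gene mean to the global gene mean — exactly the additive structure
the generator plants, and the component a supervised batch-merging
method such as distance-weighted discrimination removes for additive
offsets.  Full DWD needs a second-order-cone solver and is used in the
original analyses only to merge two cohorts; mean-centering is the
deliberate approximation here, and the correction function is a single
seam where another strategy can be plugged in.  The correction never
reads group labels, is idempotent, and preserves within-batch contrasts
to machine precision; a batch fully confounded with the biological group
is warned about but still corrected.

Sample QC projects the batch-corrected pooled matrix onto PC1/PC2 of the
gene-centered data (no variance scaling) and flags samples with robust
z = |score − median|/(1.4826·MAD) above 3 on either component, falling
back to the SD when the MAD degenerates and skipping numerically
degenerate components.  The rule is disabled below 4 samples.  No
threshold for "a clear outlier" exists in the source analyses (visual
inspection is implied); robust z > 3 is a stand-in that makes the
exclusion reproducible, and its false-flag rate on Gaussian scores
(~0.5% per sample per component) is why QC-sensitive tests are seeded.
QC runs after batch correction so cohort offsets cannot masquerade as
sample outliers.

## Ortholog translation

Translation expands one-to-many mouse genes (every human ortholog
inherits the mouse direction and p) — real maps carry a few percent more
human genes than mouse genes, so expansion rather than collapsing is the
faithful choice.  Many-to-one conflicts keep the smaller p; an exact p
tie keeps the entry when directions agree and drops the human gene with
a warning when they disagree (the source analyses are silent on this
case, and no guess is made about intent — the gene stays in the
universe, since it was measured).  The signature's universe is
translated as the set image under the same map.  Genes on MT or
scaffold placements are removed from entries and universe alike;
chromosomes 1–22, X and Y are retained.

## Overlap and enrichment

Direction-aware overlap partitions shared genes into concordant-up,
concordant-down and discordant; the three classes always sum to the
overlap size (property-tested).  Coverage percentages round half away
from zero to integers, and the denominator is always an explicit
argument because published overlap narratives switch denominators
between sentences; reports print both conventions.

Fold enrichment is k·N/(|A|·|B|) with a one-sided upper hypergeometric
tail.  Direction is ignored in enrichment counts (published overlap
totals include opposite-direction genes); concordance is reported
separately.  The universe N defaults to the intersection of the two
signatures' measured-gene universes — only genes measurable in both
studies can overlap — with union or an explicit set as alternatives; the
choice is surfaced in configuration rather than hard-coded, because the
published tables never state N, and inverting the printed folds implies
different universes for different comparisons.  GMT-based gene-set
enrichment tests a query against each annotation set with the same
machinery and applies BH across sets.

## eQTL mapping and GWAS follow-up

Per cohort, each (SNP, gene) pair is a simple regression of expression
on additive dosage, vectorised over all pairs; slopes and SEs match the
closed-form simple-regression formulas exactly (tested).  Cohorts are
combined by inverse-variance fixed-effect meta-analysis; a single BH runs
across all tested pairs, cis and trans jointly, at 10% FDR.  The cis
window is 1 Mb around the TSS, boundary inclusive ("within 1 Mb" read
inclusively and documented).  Monomorphic SNPs are skipped per cohort and
dropped with a logged count when untestable everywhere.  Top-eQTL
selection takes the minimum meta p per gene, breaking exact ties by SNP
id, and deduplicates SNPs topping several genes.  The GWAS follow-up
computes BH over the submitted lookup list only — the reading consistent
with a 73-SNP lookup whose best p of 6.07e-5 yields FDR ≈ 0.0044 — and
reports missing SNPs rather than dropping them.

## Synthetic data: what it emulates and what it does not

Expression is generated directly on the log2 scale (per-gene baseline
N(7, 1), residual noise N(0, noise_sd²)), with additive per-cohort
gene-wise batch offsets N(0, batch_shift_sd²) and planted group
differences.  Defaults: 2,000 genes per cohort, 4+4 samples for mouse
cohorts (the real exposure experiments are this small), 30+30 for the
human cohort, frac_de = 0.1, planted |log2 FC| ~ N(1.5, 0.5²) (the
published signature spans roughly 0.7–4), noise_sd = 0.5 log2 units and
batch_shift_sd = 0.5.  The within-study variance magnitude is not
reported anywhere; 0.5 log2 units is a typical array residual SD and was
fixed once.  Cross-species sharing plants the same-direction effect on
the human ortholog of a chosen fraction of planted mouse genes
(default 0.5).  The ortholog generator controls multiplicity classes
exactly (one-to-one, one-to-two, many-to-one, unmapped) and assigns
chromosome labels with occasional MT/scaffold entries so the filter has
work to do.  eQTL data place gene TSSs 2 Mb apart and planted SNPs
alternately cis (0.5 Mb from the TSS) and trans (other chromosome);
truth tables are written beside every dataset and never read by analysis
code.

Not emulated: probe-level intensities and scanner artifacts, RNA-seq
counts, correlated gene-gene structure, population LD between SNPs, and
covariate confounding in the eQTL panel.  Passing tests therefore
establish the correctness of the statistical machinery and the
end-to-end calibration of the pipeline under additive batch structure
and independent genes — not robustness to correlated noise or to
non-additive batch effects in real cohorts.

## Problem sizes and numerical choices

The test suite and the acceptance script run the pipeline at reduced
sizes (500–1,700 ortholog pairs, 2–3 mouse cohorts, 15–80 SNPs,
100–200 eQTL samples, 50 repeated runs for calibration), chosen so the
whole suite completes in a few minutes on one CPU while keeping every
statistical check informative; hyperparameter recovery uses 5,000 genes
as specified for moment-matching accuracy.  All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; identical
configuration and seed give byte-identical outputs (tested).  Trigamma
inversion iterates Newton steps to a 1e-10 relative tolerance; BH ties
and p-ties in reports are broken deterministically; the enrichment fold
is NaN for empty sets rather than 0, to distinguish "no overlap
possible" from "no enrichment".

## Known limitations

Mean-centering removes only additive batch structure; PCA outlier
flagging at robust z > 3 is a convention, not an inference; the
discordant-tie rule in ortholog translation drops information in a case
real maps may never produce; and the synthetic world's independence
assumptions make its calibration results a necessary, not sufficient,
condition for real-data validity.
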