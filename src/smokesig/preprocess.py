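"""Cohort pooling, PCA-based sample QC and additive batch correction.

Cohorts profiled on different platforms measure different gene panels, so
pooling keeps only the genes common to every cohort.  Quality control
projects the pooled matrix onto its first principal components and flags
samples far from the bulk by a robust distance.  Batch correction removes
per-cohort additive offsets by gene-wise mean-centering per batch — for
additive batch structure this is exactly the direction a supervised
batch-merging method (e.g. distance-weighted discrimination) would remove,
and it never looks at the biological group labels.
"""

from __future__ import annotations

import logging
import warnings
from functools import reduce

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from smokesig.types import ExpressionStudy, PcaResult

logger = logging.getLogger(__name__)


def intersect_common_genes(studies: list[ExpressionStudy]) -> ExpressionStudy:
    """Pool cohorts on the genes common to all of them.

    The output gene list is the set intersection in lexicographic order
    (byte-stable across runs); samples are concatenated with their cohort
    labels preserved.  Raises if the intersection is empty.
    """
    if len(studies) < 2:
        raise ValueError("need at least two studies to pool")
    common = sorted(
        reduce(lambda a, b: a & b, (set(s.genes) for s in studies))
    )
    if not common:
        raise ValueError("gene lists of the studies have an empty intersection")
    values = pd.concat([s.values.loc[common] for s in studies], axis=1)
    samples = pd.concat([s.samples for s in studies], axis=0)
    if values.columns.duplicated().any():
        raise ValueError("duplicate sample ids across studies; disambiguate first")
    logger.info(
        "pooled %d studies: %d common genes, %d samples",
        len(studies), len(common), values.shape[1],
    )
    return ExpressionStudy(values, samples)


def run_pca(study: ExpressionStudy, k: int = 2) -> PcaResult:
    """Project samples onto the top-k principal components of gene-centered data.

    Genes are mean-centered but not variance-scaled.  Variance fractions
    are relative to the total gene-centered variance.
    """
    if study.n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    max_k = min(study.n_samples, study.n_genes)
    if k > max_k:
        warnings.warn(f"k={k} exceeds rank bound {max_k}; capping", stacklevel=2)
        k = max_k
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(study.values.to_numpy().T)
    scores = pd.DataFrame(
        scores, index=study.sample_ids, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return PcaResult(scores, pca.explained_variance_ratio_)


def flag_outlier_samples(pca: PcaResult, k_sd: float = 3.0) -> list[str]:
    """Flag samples whose robust z on PC1 or PC2 exceeds ``k_sd``.

    The robust z is |score - median| / (1.4826 * MAD) per component; if the
    MAD degenerates to zero the SD is used, and if both are zero nothing is
    flagged.  The rule is disabled below 4 samples, where a median-based
    distance is meaningless.
    """
    if pca.n_components < 2:
        raise ValueError("need at least two components for outlier flagging")
    if len(pca.scores) < 4:
        return []
    flagged: set[str] = set()
    for pc in ("PC1", "PC2"):
        x = pca.scores[pc].to_numpy()
        med = np.median(x)
        scale = 1.4826 * np.median(np.abs(x - med))
        if scale == 0:
            scale = np.std(x)
        # a numerically-degenerate component (all scores ~0) carries no signal
        if scale <= 1e-9 * max(1.0, np.max(np.abs(x))):
            continue
        z = np.abs(x - med) / scale
        flagged.update(pca.scores.index[z > k_sd])
    return sorted(flagged)


def correct_batch(
    study: ExpressionStudy, batch: pd.Series | None = None
) -> ExpressionStudy:
    """Shift each batch's per-gene mean to the global gene mean.

    ``batch`` defaults to the study's cohort labels.  Group labels are
    never consulted; a batch fully confounded with the biological group is
    reported with a warning but still corrected (the caller must judge
    whether the contrast survives).  The correction is idempotent.
    """
    if batch is None:
        batch = study.samples["cohort"]
    batch = batch.loc[study.sample_ids]
    if batch.isna().any():
        raise ValueError("every sample needs a batch label")
    if "group" in study.samples.columns:
        for b, members in study.samples.groupby(batch, observed=True):
            if members["group"].nunique() == 1:
                warnings.warn(
                    f"batch {b!r} is confounded with group "
                    f"({members['group'].iloc[0]!r} only); correcting anyway",
                    stacklevel=2,
                )
    values = study.values.copy()
    global_mean = values.mean(axis=1)
    for _, cols in values.T.groupby(batch, observed=True):
        ids = cols.index
        batch_mean = values[ids].mean(axis=1)
        values[ids] = values[ids].sub(batch_mean - global_mean, axis=0)
    return ExpressionStudy(values, study.samples)


def qc_report(pca: PcaResult, flagged: list[str]) -> pd.DataFrame:
    """Per-sample QC table: PC1, PC2 scores and the outlier flag."""
    report = pca.scores[["PC1", "PC2"]].copy()
    report["flagged"] = report.index.isin(flagged)
    report.index.name = "sample"
    return report
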