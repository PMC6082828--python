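"""Gene-wise linear models, empirical-Bayes moderated t, BH-FDR, meta-analysis.

Each gene is fit by ordinary least squares against a design with an
intercept, a two-level contrast (e.g. smoke-exposed vs control) and
optional covariates (age, sex, smoking status).  Gene-wise residual
variances s_g^2 are then shrunk toward a common prior s0^2 with prior
degrees of freedom d0 estimated from the whole collection of genes:

    s_tilde_g^2 = (d0 * s0^2 + df_g * s_g^2) / (d0 + df_g)

and the moderated t = beta_g / (s_tilde_g * u_g) — with u_g the unscaled
coefficient SE from the design — is referred to a t distribution on
d0 + df_g degrees of freedom.  The hyperparameters are estimated by
moment-matching log s_g^2 against the theoretical moments of a log scaled
F / inverse-chi-square variate (digamma/trigamma inversion), the standard
empirical-Bayes scheme for expression microarrays.

Benjamini-Hochberg adjustment and the inverse-variance fixed-effect
meta-analysis used to combine per-cohort estimates live here too, as does
signature derivation at an FDR cutoff.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from smokesig.types import ExpressionStudy, Signature

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DesignSpec:
    """A two-level primary contrast plus optional adjustment covariates.

    ``contrast`` names the annotation column; ``levels`` orders it as
    (numerator, reference), so the coefficient is numerator minus
    reference.  Covariate columns may be numeric or categorical
    (categoricals are dummy-coded against their first level).
    """

    contrast: str = "group"
    levels: tuple[str, str] = ("exposed", "control")
    covariates: tuple[str, ...] = ()


def build_design_matrix(samples: pd.DataFrame, design: DesignSpec) -> pd.DataFrame:
    """Intercept + contrast indicator + covariate columns, one row per sample."""
    if design.contrast not in samples.columns:
        raise ValueError(f"contrast column {design.contrast!r} missing from annotation")
    observed = set(samples[design.contrast].unique())
    if observed != set(design.levels):
        raise ValueError(
            f"contrast must have exactly levels {design.levels}, found {sorted(observed)}"
        )
    numerator, reference = design.levels
    counts = samples[design.contrast].value_counts()
    if counts.min() < 2:
        raise ValueError("each contrast level needs at least 2 samples")
    X = pd.DataFrame(
        {"intercept": 1.0, design.contrast: (samples[design.contrast] == numerator).astype(float)},
        index=samples.index,
    )
    for cov in design.covariates:
        if cov not in samples.columns:
            raise ValueError(f"covariate {cov!r} missing from annotation")
        col = samples[cov]
        if pd.api.types.is_numeric_dtype(col):
            X[cov] = col.astype(float)
        else:
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify the columns that add no rank, in order
        bad = []
        cols = X.columns.tolist()
        for j in range(1, len(cols)):
            sub = X.iloc[:, : j + 1].to_numpy()
            if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(X.iloc[:, :j].to_numpy()):
                bad.append(cols[j])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return X


def fit_gene_models(study: ExpressionStudy, design: DesignSpec) -> pd.DataFrame:
    """OLS per gene; returns gene, logFC, SE, sigma2 (residual variance), df.

    logFC is the contrast coefficient (numerator minus reference, adjusted
    for covariates); ``stdev_unscaled`` is the coefficient SE divided by
    the residual SD, needed by the moderated t.
    """
    X = build_design_matrix(study.samples, design)
    Xm = X.to_numpy()
    Y = study.values.to_numpy()
    n, p = Xm.shape
    df = n - p
    if df < 1:
        raise ValueError(f"residual df = {df} < 1; need more samples than coefficients")
    xtx_inv = np.linalg.inv(Xm.T @ Xm)
    coefs = Y @ Xm @ xtx_inv  # genes x p
    resid = Y - coefs @ Xm.T
    rss = np.einsum("ij,ij->i", resid, resid)
    sigma2 = rss / df
    j = X.columns.get_loc(design.contrast)
    unscaled = np.sqrt(xtx_inv[j, j])
    logfc = coefs[:, j]
    se = np.sqrt(np.maximum(sigma2, 0.0)) * unscaled
    return pd.DataFrame(
        {
            "gene": study.genes,
            "logFC": logfc,
            "SE": se,
            "sigma2": sigma2,
            "df": float(df),
            "stdev_unscaled": unscaled,
        }
    )


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) / x < 1e-10):
            break
    return x


def estimate_prior(s2: np.ndarray, df: np.ndarray | float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from the spread of log residual variances.

    Under the hierarchical model s_g^2 ~ s0^2 * F(df_g, d0):
    E[log s_g^2] and Var[log s_g^2] have closed forms in digamma/trigamma;
    subtracting the within-gene contribution leaves trigamma(d0/2), which
    is inverted numerically.  If the observed spread does not exceed the
    within-gene expectation, d0 is infinite and s0^2 is the (geometric
    mean based) common variance.
    """
    s2 = np.asarray(s2, dtype=float)
    if len(s2) < 10:
        raise ValueError("prior estimation needs at least 10 genes")
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = s2 > 0
    if not ok.all():
        # zero residual variances carry no log information; exclude from moments
        s2_fit, df_fit = s2[ok], df[ok]
    else:
        s2_fit, df_fit = s2, df
    e = np.log(s2_fit) - special.digamma(df_fit / 2) + np.log(df_fit / 2)
    evar = np.var(e, ddof=1) - np.mean(special.polygamma(1, df_fit / 2))
    if evar <= 0:
        d0 = np.inf
        s02 = float(np.exp(np.mean(e)))
    else:
        d0 = float(2 * _trigamma_inverse(evar))
        s02 = float(np.exp(np.mean(e) + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s02


def posterior_variances(
    s2: np.ndarray, df: np.ndarray | float, d0: float, s02: float
) -> np.ndarray:
    """Shrink gene variances toward the prior: (d0*s02 + df*s2)/(d0 + df)."""
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    if np.isinf(d0):
        return np.full_like(s2, s02)
    return (d0 * s02 + df * s2) / (d0 + df)


@dataclass
class ModerationResult:
    d0: float
    s02: float
    s2_post: np.ndarray
    t: np.ndarray | None = None
    p_value: np.ndarray | None = None
    df_total: np.ndarray | None = None


def moderate_variances(
    s2: np.ndarray,
    df: np.ndarray | float,
    coef: np.ndarray | None = None,
    stdev_unscaled: np.ndarray | float | None = None,
    prior: tuple[float, float] | None = None,
) -> ModerationResult:
    """Estimate the variance prior, shrink, and (optionally) test coefficients.

    With ``coef`` and ``stdev_unscaled`` given, moderated t statistics and
    two-sided p-values on d0 + df degrees of freedom are filled in.
    ``prior`` overrides the estimated (d0, s0^2) — useful for the limiting
    cases d0 = 0 (no shrinkage) and d0 = inf (full shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    dfb = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    if prior is not None:
        d0, s02 = prior
    else:
        d0, s02 = estimate_prior(s2, dfb)
    if d0 == 0:
        s2_post = s2.copy()
    else:
        s2_post = posterior_variances(s2, dfb, d0, s02)
    result = ModerationResult(d0=d0, s02=s02, s2_post=s2_post)
    if coef is not None:
        if stdev_unscaled is None:
            raise ValueError("stdev_unscaled required to compute moderated t")
        u = np.broadcast_to(np.asarray(stdev_unscaled, dtype=float), s2.shape)
        t = np.asarray(coef, dtype=float) / (np.sqrt(s2_post) * u)
        # total df capped at the pooled residual df of the whole collection:
        # even full shrinkage cannot claim more information than was observed
        df_total = np.minimum(dfb + d0, dfb.sum())
        p = 2 * stats.t.sf(np.abs(t), df_total)
        result.t, result.p_value, result.df_total = t, p, df_total
    return result


def adjust_bh(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    NaN p-values are excluded from the adjustment (with a warning) and
    propagated as NaN in the output.
    """
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} NaN p-values excluded from BH", stacklevel=2)
    if (arr[ok] < 0).any() or (arr[ok] > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    return out


def differential_expression(
    study: ExpressionStudy, design: DesignSpec
) -> pd.DataFrame:
    """Fit, moderate and adjust: the standard per-gene DE table.

    Columns: gene, logFC, SE, t, p_value, fdr (plus sigma2/df/s2_post for
    inspection).  Rows are ordered by (p_value, gene) for deterministic
    reports.
    """
    fit = fit_gene_models(study, design)
    mod = moderate_variances(
        fit["sigma2"].to_numpy(),
        fit["df"].to_numpy(),
        coef=fit["logFC"].to_numpy(),
        stdev_unscaled=fit["stdev_unscaled"].to_numpy(),
    )
    table = fit[["gene", "logFC", "SE", "sigma2", "df"]].copy()
    table["s2_post"] = mod.s2_post
    table["t"] = mod.t
    table["p_value"] = mod.p_value
    table["fdr"] = adjust_bh(mod.p_value)
    table = table.sort_values(["p_value", "gene"], kind="mergesort").reset_index(drop=True)
    return table[["gene", "logFC", "SE", "t", "p_value", "fdr", "sigma2", "df", "s2_post"]]


@dataclass
class MetaResult:
    """Inverse-variance fixed-effect combination of per-cohort estimates."""

    effect: np.ndarray
    se: np.ndarray
    p_value: np.ndarray
    per_cohort_effects: np.ndarray = field(repr=False, default=None)
    per_cohort_ses: np.ndarray = field(repr=False, default=None)


def meta_analyze_fixed(
    effects: np.ndarray, ses: np.ndarray
) -> MetaResult:
    """Fixed-effect meta-analysis with inverse-variance weights.

    ``effects`` and ``ses`` are (n_units, n_cohorts) arrays (or 1-D for a
    single unit).  Combined effect = sum(w*b)/sum(w) with w = 1/se^2,
    combined SE = 1/sqrt(sum(w)), p from the normal two-sided tail.  NaN
    cohort entries (unit not measured in that cohort) are skipped.
    """
    b = np.atleast_2d(np.asarray(effects, dtype=float))
    s = np.atleast_2d(np.asarray(ses, dtype=float))
    if b.shape != s.shape:
        raise ValueError("effects and ses must have the same shape")
    if np.any(s[~np.isnan(s)] <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / s**2
    valid = ~np.isnan(b) & ~np.isnan(s)
    w = np.where(valid, w, 0.0)
    bz = np.where(valid, b, 0.0)
    wsum = w.sum(axis=1)
    if np.any(wsum == 0):
        raise ValueError("some units have no cohort with a finite estimate")
    combined = (w * bz).sum(axis=1) / wsum
    se_comb = 1.0 / np.sqrt(wsum)
    z = combined / se_comb
    p = 2 * stats.norm.sf(np.abs(z))
    return MetaResult(combined, se_comb, p, b, s)


def derive_signature(
    results: pd.DataFrame,
    fdr_cutoff: float = 0.1,
    species: str = "human",
) -> Signature:
    """Threshold a DE table at FDR < cutoff (strict) into a directional signature.

    The signature's universe is the full set of tested genes.  An empty
    signature is valid but warned about.
    """
    if results.empty:
        raise ValueError("DE results table is empty")
    if not 0 < fdr_cutoff <= 1:
        raise ValueError("fdr_cutoff must lie in (0, 1]")
    # strict inequality, except that cutoff 1.0 means "keep everything"
    hits = results if fdr_cutoff >= 1 else results[results["fdr"] < fdr_cutoff]
    hits = hits[hits["logFC"] != 0]
    if hits.empty:
        warnings.warn("no genes pass the FDR cutoff; signature is empty", stacklevel=2)
    entries = pd.DataFrame(
        {
            "direction": np.sign(hits["logFC"]).astype(int).to_numpy(),
            "p_value": hits["p_value"].to_numpy(),
            "fdr": hits["fdr"].to_numpy(),
        },
        index=pd.Index(hits["gene"], name="gene"),
    )
    return Signature(entries, frozenset(results["gene"]), species)
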