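"""Small builders shared across test modules."""

import numpy as np
import pandas as pd

from smokesig.types import ExpressionStudy, Signature


def make_study(values, groups, cohorts=None, gene_ids=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n_samples)]
    if cohorts is None:
        cohorts = ["c1"] * n_samples
    samples = pd.DataFrame(
        {"group": groups, "cohort": cohorts},
        index=pd.Index(sample_ids, name="sample"),
    )
    return ExpressionStudy(
        pd.DataFrame(values, index=pd.Index(gene_ids, name="gene"), columns=sample_ids),
        samples,
    )


def make_signature(up, down, universe=None, species="human", p=None):
    sig = Signature.from_lists(up, down, universe=universe, species=species)
    if p is not None:
        sig.entries["p_value"] = p
    return sig


def bh_bruteforce(p):
    """Literal step-up definition: q(i) = min over p(j) >= p(i) of min(1, m*p(j)/rank(j))."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for i in range(m):
        candidates = [
            min(1.0, m * p[order[j]] / (j + 1)) for j in range(m) if p[order[j]] >= p[order[i]]
        ]
        q[order[i]] = min(candidates)
    return q


def hypergeom_tail_bruteforce(k, n_universe, size_a, size_b):
    """P(X >= k) by explicit summation of the hypergeometric pmf."""
    from math import comb

    total = comb(n_universe, size_b)
    upper = min(size_a, size_b)
    return sum(
        comb(size_a, x) * comb(n_universe - size_a, size_b - x) for x in range(k, upper + 1)
    ) / total
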