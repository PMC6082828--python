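"""Direction-aware signature overlap and hypergeometric fold-enrichment.

Two signatures in the same gene namespace are compared three ways:

* ``overlap_directional`` — the shared genes, split into concordant-up,
  concordant-down and discordant by the sign pair of their effects;
* ``coverage_percent`` — an overlap count as an integer percentage of a
  stated denominator (the denominator convention is always explicit,
  because published overlap narratives switch denominators mid-paragraph);
* ``enrichment_fisher`` — overlap count k of sets A and B in a universe of
  N genes, fold enrichment k*N/(|A|*|B|), and the one-sided upper
  hypergeometric tail P(X >= k), X ~ Hypergeom(N, |A|, |B|).  Direction is
  deliberately ignored here: published overlap totals include
  opposite-direction genes, and concordance is reported separately.

A generic GMT-based gene-set enrichment (each annotation set tested
against the query, BH across sets) covers ontology-style analyses.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from smokesig.types import Signature

logger = logging.getLogger(__name__)


@dataclass
class OverlapResult:
    """Shared genes of two (or three) signatures with direction classes."""

    table: pd.DataFrame  # gene, direction per signature, class
    concordant_up: int
    concordant_down: int
    discordant: int

    @property
    def n_shared(self) -> int:
        return len(self.table)

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.concordant_up, self.concordant_down, self.discordant)


def _check_namespace(*sigs: Signature) -> None:
    species = {s.species for s in sigs}
    if len(species) > 1:
        raise ValueError(f"signatures live in different namespaces: {sorted(species)}")


def _classify(directions: np.ndarray) -> str:
    if (directions == 1).all():
        return "concordant_up"
    if (directions == -1).all():
        return "concordant_down"
    return "discordant"


def overlap_directional(a: Signature, b: Signature) -> OverlapResult:
    """Shared genes of two signatures, classified by direction pair."""
    _check_namespace(a, b)
    shared = sorted(a.genes & b.genes)
    rows = []
    for g in shared:
        da, db = a.direction_of(g), b.direction_of(g)
        rows.append((g, da, db, _classify(np.array([da, db]))))
    table = pd.DataFrame(rows, columns=["gene", "direction_a", "direction_b", "class"])
    cls = table["class"].value_counts() if len(table) else pd.Series(dtype=int)
    return OverlapResult(
        table,
        int(cls.get("concordant_up", 0)),
        int(cls.get("concordant_down", 0)),
        int(cls.get("discordant", 0)),
    )


def overlap_three_way(a: Signature, b: Signature, c: Signature) -> OverlapResult:
    """Triple intersection; concordant requires the same direction in all three."""
    _check_namespace(a, b, c)
    shared = sorted(a.genes & b.genes & c.genes)
    rows = []
    for g in shared:
        ds = np.array([a.direction_of(g), b.direction_of(g), c.direction_of(g)])
        rows.append((g, *ds, _classify(ds)))
    table = pd.DataFrame(
        rows, columns=["gene", "direction_a", "direction_b", "direction_c", "class"]
    )
    cls = table["class"].value_counts() if len(table) else pd.Series(dtype=int)
    return OverlapResult(
        table,
        int(cls.get("concordant_up", 0)),
        int(cls.get("concordant_down", 0)),
        int(cls.get("discordant", 0)),
    )


def coverage_percent(overlap_count: int, denominator: int) -> int:
    """Integer percentage, rounded half away from zero (48 for 184/386)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= overlap_count <= denominator:
        raise ValueError("overlap_count must lie in [0, denominator]")
    return int(math.floor(100 * overlap_count / denominator + 0.5))


@dataclass
class EnrichmentResult:
    """Overlap of two gene sets in a universe, with fold and hypergeometric p."""

    k: int
    size_a: int
    size_b: int
    universe_n: int
    fold: float
    p_value: float


def resolve_universe(
    a: Signature, b: Signature, policy: str | int | set = "intersection"
) -> frozenset:
    """The background gene set of an enrichment test.

    ``"intersection"`` (default): genes measured in both source analyses —
    the only genes that could have appeared in both signatures.
    ``"union"``: measured in either.  An explicit set is used as given.
    """
    if isinstance(policy, (set, frozenset)):
        return frozenset(policy)
    if policy == "intersection":
        return frozenset(a.universe & b.universe)
    if policy == "union":
        return frozenset(a.universe | b.universe)
    raise ValueError(f"unknown universe policy {policy!r}")


def enrichment_fisher(
    a: Signature | set,
    b: Signature | set,
    universe: set | frozenset | None = None,
    alternative: str = "greater",
) -> EnrichmentResult:
    """Hypergeometric over-representation of the overlap of A and B in a universe.

    Entries outside the universe are dropped with a warning.  The default
    one-sided p is the upper tail P(X >= k); ``alternative="two-sided"``
    uses Fisher's exact two-sided p on the 2x2 table.
    """
    set_a = a.genes if isinstance(a, Signature) else frozenset(a)
    set_b = b.genes if isinstance(b, Signature) else frozenset(b)
    if universe is None:
        if not (isinstance(a, Signature) and isinstance(b, Signature)):
            raise ValueError("universe required unless both inputs are signatures")
        universe = resolve_universe(a, b)
    universe = frozenset(universe)
    if not universe:
        raise ValueError("universe is empty")
    for name, s in (("A", set_a), ("B", set_b)):
        stray = s - universe
        if stray:
            warnings.warn(
                f"{len(stray)} genes of set {name} outside the universe; dropped",
                stacklevel=2,
            )
    set_a &= universe
    set_b &= universe
    n = len(universe)
    k = len(set_a & set_b)
    if set_a and set_b:
        fold = k * n / (len(set_a) * len(set_b))
    else:
        fold = float("nan")
    if alternative == "greater":
        p = float(stats.hypergeom.sf(k - 1, n, len(set_a), len(set_b)))
    elif alternative == "two-sided":
        table = [
            [k, len(set_a) - k],
            [len(set_b) - k, n - len(set_a) - len(set_b) + k],
        ]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return EnrichmentResult(k, len(set_a), len(set_b), n, fold, p)


def enrichment_matrix(
    signatures: dict[str, Signature],
    universe_policy: str | int | set = "intersection",
) -> pd.DataFrame:
    """Pairwise enrichment of named signatures: tidy (a, b, k, fold, p) table.

    The diagonal is omitted (self-enrichment is not informative).  With a
    shared universe the table is symmetric in (fold, p).
    """
    if len(signatures) < 2:
        raise ValueError("need at least two signatures")
    rows = []
    names = list(signatures)
    for ia, na in enumerate(names):
        for nb in names:
            if na == nb:
                continue
            res = enrichment_fisher(signatures[na], signatures[nb], policy_universe(
                signatures[na], signatures[nb], universe_policy))
            rows.append(
                (na, nb, res.k, res.size_a, res.size_b, res.universe_n, res.fold, res.p_value)
            )
    return pd.DataFrame(
        rows,
        columns=["signature_a", "signature_b", "k", "size_a", "size_b", "universe_n", "fold", "p_value"],
    )


def policy_universe(a: Signature, b: Signature, policy) -> frozenset:
    if isinstance(policy, (set, frozenset)):
        return frozenset(policy)
    return resolve_universe(a, b, policy)


def geneset_enrichment(
    genes: set | frozenset,
    annotation: dict[str, set],
    universe: set | frozenset,
) -> pd.DataFrame:
    """Test a query gene set against every annotation set; BH across sets.

    Annotation sets with no member in the universe are skipped with a
    warning.  Returns a table (set_name, set_size, k, fold, p_value, fdr)
    sorted by p then name.
    """
    from smokesig.diffexpr import adjust_bh

    if not annotation:
        raise ValueError("annotation collection is empty")
    universe = frozenset(universe)
    query = frozenset(genes) & universe
    rows = []
    for name in sorted(annotation):
        members = frozenset(annotation[name]) & universe
        if not members:
            warnings.warn(f"annotation set {name!r} has no universe members; skipped",
                          stacklevel=2)
            continue
        res = enrichment_fisher(query, members, universe)
        rows.append((name, len(members), res.k, res.fold, res.p_value))
    out = pd.DataFrame(rows, columns=["set_name", "set_size", "k", "fold", "p_value"])
    out["fdr"] = adjust_bh(out["p_value"].to_numpy()) if len(out) else []
    return out.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)
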