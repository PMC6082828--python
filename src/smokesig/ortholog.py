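"""Mouse-to-human signature translation via an ortholog map.

One-to-many mouse genes expand (each human ortholog inherits the mouse
gene's direction and p-value — the observed expansion in real maps is a
few percent more human genes than mouse genes); many-to-one conflicts are
resolved by keeping the entry with the smaller p, and an exact p tie with
discordant directions drops the gene with a warning.  The signature's
universe is translated with the same expansion rules so that entry and
universe stay in the same gene space.  Human genes are finally restricted
to chromosomes 1-22, X and Y, dropping mitochondrial and scaffold
placements from entries and universe alike.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from smokesig.types import AUTOSOMES_XY, Signature

logger = logging.getLogger(__name__)


def validate_ortholog_map(omap: pd.DataFrame) -> pd.DataFrame:
    need = {"mouse_gene", "human_gene", "human_chromosome"}
    if not need <= set(omap.columns):
        raise ValueError(f"ortholog map needs columns {sorted(need)}")
    if omap.duplicated(["mouse_gene", "human_gene"]).any():
        raise ValueError("duplicate (mouse, human) pairs in ortholog map")
    return omap


def translate_universe(universe: frozenset, omap: pd.DataFrame) -> frozenset:
    """Image of a mouse gene set under the ortholog relation."""
    hit = omap[omap["mouse_gene"].isin(universe)]
    return frozenset(hit["human_gene"])


def translate_signature(sig: Signature, omap: pd.DataFrame) -> Signature:
    """Translate a mouse signature into human gene space.

    Unmapped mouse genes are dropped (count logged).  When several mouse
    entries map to the same human gene, the smallest p wins; on an exact
    tie, concordant directions keep one entry and discordant directions
    drop the human gene with a warning.
    """
    if sig.species != "mouse":
        raise ValueError(f"expected a mouse signature, got species={sig.species!r}")
    if omap.empty:
        raise ValueError("ortholog map is empty")
    validate_ortholog_map(omap)

    entries = sig.entries.reset_index()
    merged = entries.merge(omap, left_on="gene", right_on="mouse_gene", how="left")
    unmapped = merged["human_gene"].isna()
    n_unmapped = merged.loc[unmapped, "gene"].nunique()
    if n_unmapped:
        logger.info("%d mouse signature genes have no human ortholog; dropped", n_unmapped)
    merged = merged[~unmapped]

    rows = []
    merged = merged.assign(_rank_p=merged["p_value"].fillna(np.inf))
    for hg, grp in merged.groupby("human_gene", sort=True):
        grp = grp.sort_values(["_rank_p", "mouse_gene"], kind="mergesort")
        best_p = grp["_rank_p"].iloc[0]
        ties = grp[grp["_rank_p"] == best_p]
        if len(ties) > 1 and ties["direction"].nunique() > 1:
            warnings.warn(
                f"human gene {hg}: tied p with discordant directions; dropped",
                stacklevel=2,
            )
            continue
        top = ties.iloc[0]
        rows.append((hg, int(top["direction"]), top["p_value"], top["fdr"]))
    out = pd.DataFrame(
        rows, columns=["gene", "direction", "p_value", "fdr"]
    ).set_index("gene")
    universe = translate_universe(sig.universe, omap)
    # a dropped discordant tie stays in the universe: the gene was measured
    return Signature(out, universe, species="human")


def chromosome_lookup(omap: pd.DataFrame) -> pd.Series:
    """human_gene -> chromosome label (first label wins if a gene repeats)."""
    return omap.drop_duplicates("human_gene").set_index("human_gene")["human_chromosome"]


def filter_human_chromosomes(
    target: Signature | pd.DataFrame, omap: pd.DataFrame
) -> Signature | pd.DataFrame:
    """Keep only human genes on chromosomes 1-22, X or Y.

    Accepts a Signature (entries and universe both filtered) or a plain
    gene table with a ``gene`` column.  Genes without a chromosome label
    are dropped with a warning.
    """
    chrom = chromosome_lookup(omap)

    def keep(genes: pd.Index | pd.Series) -> np.ndarray:
        labels = pd.Series(list(genes)).map(chrom)
        missing = labels.isna()
        if missing.any():
            warnings.warn(
                f"{int(missing.sum())} genes lack a chromosome label; dropped",
                stacklevel=3,
            )
        return (labels.isin(AUTOSOMES_XY) & ~missing).to_numpy()

    if isinstance(target, Signature):
        entries = target.entries[keep(target.entries.index)]
        universe_list = sorted(target.universe)
        universe = frozenset(np.array(universe_list)[keep(pd.Index(universe_list))]) if universe_list else frozenset()
        return Signature(entries, universe, target.species)
    if "gene" not in target.columns:
        raise ValueError("gene table needs a 'gene' column")
    return target[keep(target["gene"])].reset_index(drop=True)
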