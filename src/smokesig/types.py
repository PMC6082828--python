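"""Shared in-memory containers for expression studies and gene signatures."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Human chromosome labels retained in cross-species comparisons.
AUTOSOMES_XY = frozenset([str(i) for i in range(1, 23)] + ["X", "Y"])


@dataclass
class ExpressionStudy:
    """A gene-by-sample log2 expression matrix with its sample annotation.

    Parameters
    ----------
    values
        DataFrame of log2 expression, genes on the rows, samples on the
        columns.
    samples
        DataFrame indexed by sample id.  Must carry a ``group`` column
        (the two-level condition, e.g. exposed/control) and a ``cohort``
        column; further columns are treated as covariates.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if not self.values.columns.equals(self.samples.index):
            if set(self.values.columns) != set(self.samples.index):
                raise ValueError("sample ids of matrix and annotation differ")
            self.samples = self.samples.loc[self.values.columns]
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, keep: list[str] | pd.Index) -> "ExpressionStudy":
        keep = pd.Index(keep)
        return ExpressionStudy(self.values[keep], self.samples.loc[keep])


@dataclass
class Signature:
    """A directional gene set with the universe it was derived from.

    ``entries`` is indexed by gene id with columns ``direction`` (+1/-1),
    ``p_value`` and ``fdr``; ``universe`` is the set of all genes tested in
    the source analysis.  Every entry gene must be in the universe.
    """

    entries: pd.DataFrame
    universe: frozenset = field(default_factory=frozenset)
    species: str = "human"

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        missing = {"direction", "p_value", "fdr"} - set(self.entries.columns)
        if missing:
            raise ValueError(f"signature entries lack columns: {sorted(missing)}")
        if (self.entries["direction"] == 0).any():
            raise ValueError("signature directions must be nonzero")
        if self.universe and not set(self.entries.index) <= self.universe:
            stray = set(self.entries.index) - self.universe
            raise ValueError(f"entries outside universe: {sorted(stray)[:5]}")

    @property
    def genes(self) -> frozenset:
        return frozenset(self.entries.index)

    def __len__(self) -> int:
        return len(self.entries)

    def direction_of(self, gene: str) -> int:
        return int(self.entries.at[gene, "direction"])

    @classmethod
    def from_lists(
        cls,
        up: list[str],
        down: list[str],
        universe=None,
        species: str = "human",
    ) -> "Signature":
        """Build a signature from plain up/down gene lists (p and fdr set to NaN)."""
        genes = list(up) + list(down)
        entries = pd.DataFrame(
            {
                "direction": [1] * len(up) + [-1] * len(down),
                "p_value": np.nan,
                "fdr": np.nan,
            },
            index=pd.Index(genes, name="gene"),
        )
        if universe is None:
            universe = genes
        return cls(entries, frozenset(universe), species)


@dataclass
class PcaResult:
    """Per-sample principal-component scores and component variance fractions."""

    scores: pd.DataFrame  # samples x PC1..PCk
    variance_fraction: np.ndarray

    def __post_init__(self) -> None:
        vf = np.asarray(self.variance_fraction, dtype=float)
        if np.any(np.diff(vf) > 1e-9):
            raise ValueError("variance fractions must be nonincreasing")
        if vf.sum() > 1 + 1e-9:
            raise ValueError("variance fractions must sum to at most 1")
        self.variance_fraction = vf

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]
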