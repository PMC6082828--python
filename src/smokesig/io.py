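"""Plain-text (TSV / GMT) readers and writers for every pipeline artifact.

All tabular formats are tab-separated with a header row.  Expression
matrices are written genes-by-samples with the gene id as the first
column; signatures, ortholog maps, genotype dosages, position tables and
GWAS summaries each have a fixed column set documented on the writer.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from smokesig.types import ExpressionStudy, Signature


def write_study(study: ExpressionStudy, expr_path, annot_path) -> None:
    study.values.to_csv(expr_path, sep="\t", index_label="gene")
    study.samples.to_csv(annot_path, sep="\t", index_label="sample")


def read_study(expr_path, annot_path) -> ExpressionStudy:
    values = pd.read_csv(expr_path, sep="\t", index_col="gene")
    samples = pd.read_csv(annot_path, sep="\t", index_col="sample")
    return ExpressionStudy(values, samples)


def write_signature(sig: Signature, path) -> None:
    """Columns: gene, direction (+1/-1), p_value, fdr."""
    sig.entries.to_csv(path, sep="\t", index_label="gene")
    upath = Path(path)
    universe_path = upath.with_name(upath.stem + ".universe.txt")
    universe_path.write_text("\n".join(sorted(sig.universe)) + "\n")


def read_signature(path, species: str = "human") -> Signature:
    entries = pd.read_csv(path, sep="\t", index_col="gene")
    upath = Path(path)
    universe_path = upath.with_name(upath.stem + ".universe.txt")
    if universe_path.exists():
        universe = frozenset(universe_path.read_text().split())
    else:
        universe = frozenset(entries.index)
    return Signature(entries, universe, species)


def write_de_results(table: pd.DataFrame, path) -> None:
    """Columns: gene, logFC, SE, t, p_value, fdr."""
    table.to_csv(path, sep="\t", index=False)


def read_de_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ortholog_map(omap: pd.DataFrame, path) -> None:
    """Columns: mouse_gene, human_gene, human_chromosome."""
    omap.to_csv(path, sep="\t", index=False)


def read_ortholog_map(path) -> pd.DataFrame:
    omap = pd.read_csv(path, sep="\t", dtype=str)
    need = {"mouse_gene", "human_gene", "human_chromosome"}
    if not need <= set(omap.columns):
        raise ValueError(f"ortholog map needs columns {sorted(need)}")
    return omap


def write_genotypes(dosages: pd.DataFrame, path) -> None:
    """SNP-by-sample dosage matrix, values in {0, 1, 2}."""
    dosages.to_csv(path, sep="\t", index_label="snp")


def read_genotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="snp")


def write_positions(pos: pd.DataFrame, path) -> None:
    pos.to_csv(path, sep="\t", index=False)


def read_positions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gwas(gwas: pd.DataFrame, path) -> None:
    """Columns: snp, effect, se, p_value."""
    gwas.to_csv(path, sep="\t", index=False)


def read_gwas(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index_label="gene")


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file: one gene set per line, name TAB description TAB members."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description] + sorted(members))
        for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
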