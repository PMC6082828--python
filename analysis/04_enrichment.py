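#!/usr/bin/env python
"""Hypergeometric fold-enrichment of every signature pair, plus gene sets.

Reads the human-space signatures, computes the pairwise enrichment matrix
(fold = k*N/(|A|*|B|), one-sided upper hypergeometric p, universe = genes
measured in both analyses) and a GMT-based gene-set enrichment of the
three-way overlap genes.  Writes to results/enrichment/.
"""

from pathlib import Path

import pandas as pd

from smokesig import io
from smokesig.overlap import enrichment_matrix, geneset_enrichment
from smokesig.synthetic import generate_gmt

ROOT = Path(__file__).resolve().parents[1] / "results"
IN, OUT = ROOT / "overlap", ROOT / "enrichment"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    sigs = {
        name: io.read_signature(IN / f"signature_{name}.human_space.tsv")
        for name in ("human_smoking", "mouse_short", "mouse_long")
    }

    matrix = enrichment_matrix(sigs, "intersection")
    matrix.to_csv(OUT / "enrichment_matrix.tsv", sep="\t", index=False)
    for _, r in matrix.iterrows():
        if r["signature_a"] < r["signature_b"]:
            print(f"{r['signature_a']} in {r['signature_b']}: "
                  f"fold {r['fold']:.2f} (k={r['k']}, N={r['universe_n']}, "
                  f"p={r['p_value']:.3g})")

    three = pd.read_csv(IN / "overlap_three_way.tsv", sep="\t")
    universe = sorted(sigs["human_smoking"].universe)
    gmt = generate_gmt(universe, seed=5,
                       enriched_genes=sorted(three["gene"]) if len(three) else None)
    io.write_gmt(gmt, OUT / "annotation.gmt")
    table = geneset_enrichment(set(three["gene"]), gmt, set(universe))
    table.to_csv(OUT / "geneset_enrichment.tsv", sep="\t", index=False)
    top = table.iloc[0]
    print(f"top gene set for the three-way overlap: {top['set_name']} "
          f"(fold {top['fold']:.2f}, FDR {top['fdr']:.2g})")


if __name__ == "__main__":
    main()
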