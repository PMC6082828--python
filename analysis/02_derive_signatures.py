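#!/usr/bin/env python
"""Pool the mouse cohorts, run QC and derive all three smoking signatures.

Reads results/inputs/, pools the short-term cohorts on their common genes,
corrects cohort batch offsets, excludes PCA outliers, fits gene-wise
moderated-t models and thresholds each analysis at FDR < 0.1.  Writes DE
tables, the QC report and the signatures to results/signatures/.
"""

from pathlib import Path

import pandas as pd

from smokesig import io
from smokesig.diffexpr import DesignSpec, derive_signature, differential_expression
from smokesig.preprocess import (
    correct_batch,
    flag_outlier_samples,
    intersect_common_genes,
    qc_report,
    run_pca,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
IN, OUT = ROOT / "inputs", ROOT / "signatures"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    short = [io.read_study(p, p.with_name(p.name.replace(".expr.", ".annot.")))
             for p in sorted(IN.glob("mouse_short*.expr.tsv"))]
    pooled = correct_batch(intersect_common_genes(short))
    pca = run_pca(pooled, k=2)
    flagged = flag_outlier_samples(pca, k_sd=3.0)
    qc_report(pca, flagged).to_csv(OUT / "qc_mouse_short.tsv", sep="\t")
    if flagged:
        pooled = correct_batch(
            pooled.subset_samples([s for s in pooled.sample_ids if s not in set(flagged)])
        )
    print(f"pooled {len(short)} short-term cohorts: {pooled.n_genes} common genes, "
          f"{pooled.n_samples} samples ({len(flagged)} outliers excluded)")

    mouse_design = DesignSpec("group", ("exposed", "control"))
    human_design = DesignSpec("group", ("smoker", "never"))
    runs = {
        "mouse_short": (pooled, mouse_design, "mouse"),
        "mouse_long": (io.read_study(IN / "mouse_long1.expr.tsv", IN / "mouse_long1.annot.tsv"),
                       mouse_design, "mouse"),
        "human_smoking": (io.read_study(IN / "human.expr.tsv", IN / "human.annot.tsv"),
                          human_design, "human"),
    }
    for name, (study, design, species) in runs.items():
        table = differential_expression(study, design)
        io.write_de_results(table[["gene", "logFC", "SE", "t", "p_value", "fdr"]],
                            OUT / f"de_{name}.tsv")
        sig = derive_signature(table, 0.1, species=species)
        io.write_signature(sig, OUT / f"signature_{name}.tsv")
        print(f"{name}: {len(sig)}/{study.n_genes} genes differentially "
              f"expressed at FDR < 0.1")


if __name__ == "__main__":
    main()
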