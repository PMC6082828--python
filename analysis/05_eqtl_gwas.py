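#!/usr/bin/env python
"""eQTL scan of the genotype panel and GWAS follow-up of the top eQTLs.

Regresses every gene on every SNP dosage, labels pairs cis (within 1 Mb of
the TSS) or trans, applies a joint 10% FDR, takes the most significant
eQTL per gene and looks those SNPs up in the GWAS summary table with BH
over the lookup list (5% FDR).  Also reports recovery of the planted
eQTLs.  Writes to results/eqtl/.
"""

from pathlib import Path

import pandas as pd

from smokesig import io
from smokesig.eqtl import gwas_followup, map_eqtls, select_top_per_probe

ROOT = Path(__file__).resolve().parents[1] / "results"
IN, OUT = ROOT / "inputs", ROOT / "eqtl"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records = map_eqtls(
        io.read_genotypes(IN / "genotypes.tsv"),
        io.read_study(IN / "eqtl.expr.tsv", IN / "eqtl.annot.tsv"),
        io.read_positions(IN / "snp_positions.tsv"),
        io.read_positions(IN / "gene_positions.tsv"),
        fdr_cutoff=0.1,
    )
    records.to_csv(OUT / "eqtl_records.tsv", sep="\t", index=False)
    sig = records[records["significant"]]
    n_cis = int(sig["cis"].sum())
    print(f"{len(records)} (SNP, gene) pairs tested; {len(sig)} significant at "
          f"10% FDR ({n_cis} cis, {len(sig) - n_cis} trans)")

    truth = pd.read_csv(IN / "eqtl_truth.tsv", sep="\t")
    planted = set(map(tuple, truth[["snp", "gene"]].to_numpy()))
    hits = set(map(tuple, sig[["snp", "gene"]].to_numpy()))
    print(f"planted eQTL recovery: {len(hits & planted)}/{len(planted)}")

    top = select_top_per_probe(sig)
    follow = gwas_followup(top, io.read_gwas(IN / "gwas_summary.tsv"), fdr_cutoff=0.05)
    follow.table.to_csv(OUT / "gwas_followup.tsv", sep="\t", index=False)
    flagged = follow.table[follow.table["flagged"]]
    print(f"{len(top)} top-eQTL SNPs looked up in the GWAS summary; "
          f"{len(flagged)} associated at FDR < 0.05"
          + (f" (best: {flagged['snp'].iloc[0]}, FDR {flagged['fdr'].iloc[0]:.2g})"
             if len(flagged) else ""))


if __name__ == "__main__":
    main()
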