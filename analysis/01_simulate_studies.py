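#!/usr/bin/env python
"""Generate the synthetic study collection every later step analyses.

Writes multi-cohort mouse smoke-exposure studies (short- and long-term),
a human smoking cohort, the mouse-to-human ortholog map, the eQTL
genotype/expression panel and the GWAS summary table — plus the planted
truth tables that only the evaluation steps may read — to
results/inputs/.

Usage: python analysis/01_simulate_studies.py [--seed N]
"""

import argparse
from pathlib import Path

from smokesig import io
from smokesig.pipeline import generate_world, load_config
from smokesig.synthetic import generate_gwas_summary

OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    cfg = load_config(overrides={"seed": args.seed})
    world = generate_world(cfg)
    OUT.mkdir(parents=True, exist_ok=True)

    for i, study in enumerate(world["mouse_short"], 1):
        io.write_study(study, OUT / f"mouse_short{i}.expr.tsv", OUT / f"mouse_short{i}.annot.tsv")
    for i, study in enumerate(world["mouse_long"], 1):
        io.write_study(study, OUT / f"mouse_long{i}.expr.tsv", OUT / f"mouse_long{i}.annot.tsv")
    io.write_study(world["human"], OUT / "human.expr.tsv", OUT / "human.annot.tsv")
    io.write_ortholog_map(world["omap"], OUT / "ortholog_map.tsv")
    io.write_truth(world["mouse_truth"], OUT / "mouse_truth.tsv")
    io.write_truth(world["human_truth"], OUT / "human_truth.tsv")

    dosages, expr, snp_pos, gene_pos, eqtl_truth = world["eqtl"]
    io.write_genotypes(dosages, OUT / "genotypes.tsv")
    io.write_study(expr, OUT / "eqtl.expr.tsv", OUT / "eqtl.annot.tsv")
    io.write_positions(snp_pos, OUT / "snp_positions.tsv")
    io.write_positions(gene_pos, OUT / "gene_positions.tsv")
    eqtl_truth.to_csv(OUT / "eqtl_truth.tsv", sep="\t", index=False)
    gwas = generate_gwas_summary(list(dosages.index), seed=cfg["seed"] + 99,
                                 **cfg["synthetic"]["gwas"])
    io.write_gwas(gwas, OUT / "gwas_summary.tsv")

    n_mouse = world["mouse_truth"].shape[0]
    n_planted = int((world["mouse_truth"]["logfc"] != 0).sum())
    n_shared = int(world["mouse_truth"]["shared"].sum())
    print(f"simulated {len(world['mouse_short'])} short-term + "
          f"{len(world['mouse_long'])} long-term mouse cohorts and 1 human cohort")
    print(f"{n_mouse} mouse genes, {n_planted} planted DE, "
          f"{n_shared} with a shared human-ortholog effect")
    print(f"inputs written to {OUT}")


if __name__ == "__main__":
    main()
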