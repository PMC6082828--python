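#!/usr/bin/env python
"""Translate the mouse signatures into human gene space and measure overlap.

Mouse signatures are expanded through the ortholog map (one-to-many mouse
genes emit one entry per human ortholog), restricted to chromosomes
1-22/X/Y, and intersected with the human smoking signature: pairwise and
three-way overlaps with concordant/discordant direction classes and
coverage percentages under both denominator conventions.  Writes to
results/overlap/.
"""

from pathlib import Path

import pandas as pd

from smokesig import io
from smokesig.ortholog import filter_human_chromosomes, translate_signature
from smokesig.overlap import coverage_percent, overlap_directional, overlap_three_way

ROOT = Path(__file__).resolve().parents[1] / "results"
IN_SIG, IN, OUT = ROOT / "signatures", ROOT / "inputs", ROOT / "overlap"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    omap = io.read_ortholog_map(IN / "ortholog_map.tsv")

    sigs = {}
    for name, species in [("mouse_short", "mouse"), ("mouse_long", "mouse"),
                          ("human_smoking", "human")]:
        sig = io.read_signature(IN_SIG / f"signature_{name}.tsv", species=species)
        if species == "mouse":
            sig = translate_signature(sig, omap)
        sig = filter_human_chromosomes(sig, omap)
        sigs[name] = sig
        io.write_signature(sig, OUT / f"signature_{name}.human_space.tsv")
        print(f"{name}: {len(sig)} human-space entries "
              f"(universe {len(sig.universe)})")

    rows = []
    for na, nb in [("human_smoking", "mouse_short"), ("human_smoking", "mouse_long"),
                   ("mouse_short", "mouse_long")]:
        ov = overlap_directional(sigs[na], sigs[nb])
        up, down, disc = ov.counts
        rows.append({
            "signature_a": na, "signature_b": nb, "shared": ov.n_shared,
            "concordant_up": up, "concordant_down": down, "discordant": disc,
            "pct_of_a": coverage_percent(ov.n_shared, len(sigs[na])),
            "pct_of_b": coverage_percent(ov.n_shared, len(sigs[nb])),
        })
        ov.table.to_csv(OUT / f"overlap_{na}_vs_{nb}.tsv", sep="\t", index=False)
        print(f"{na} vs {nb}: {ov.n_shared} shared "
              f"({up} up / {down} down in both, {disc} discordant) — "
              f"{rows[-1]['pct_of_a']}% of {na}, {rows[-1]['pct_of_b']}% of {nb}")
    pd.DataFrame(rows).to_csv(OUT / "overlap_pairwise.tsv", sep="\t", index=False)

    three = overlap_three_way(sigs["human_smoking"], sigs["mouse_short"], sigs["mouse_long"])
    three.table.to_csv(OUT / "overlap_three_way.tsv", sep="\t", index=False)
    up, down, disc = three.counts
    print(f"three-way: {three.n_shared} shared ({up} up / {down} down everywhere, "
          f"{disc} discordant)")


if __name__ == "__main__":
    main()
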