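#!/usr/bin/env python
"""Pathway scores (mean LFC / sd LFC) with top/bottom-decile calls.

Scores every 20-80-gene set per timepoint, ranks them, and calls the top
and bottom 10% up/down. Writes scored tables and pathway x timepoint
heatmap matrices under results/pathway_scores/, then reports where the two
planted sets landed — the transient inflammatory set should be "up" at its
6 h peak only, the persistent contractile set "down" throughout.
"""

from pathlib import Path

from vasctx.diffexpr import read_de_table
from vasctx.geneset_io import filter_by_size, read_gmt
from vasctx.pathway_score import build_heatmap_matrix, score_catalog, write_heatmap, write_scores

ROOT = Path(__file__).resolve().parent.parent / "results"
TIMEPOINTS = ("1h", "6h", "24h")


def main() -> None:
    catalog = read_gmt(ROOT / "simdata" / "sets.gmt")
    out = ROOT / "pathway_scores"
    out.mkdir(parents=True, exist_ok=True)

    scored_by_tp = []
    for tp in TIMEPOINTS:
        de = read_de_table(ROOT / "de" / f"de_{tp}.tsv")
        usable = filter_by_size(catalog, 20, 80, universe=list(de.index))
        scored = score_catalog(de, usable, fraction=0.10)
        write_scores(scored, out / f"scores_{tp}.tsv")
        scored_by_tp.append((tp, scored))

    write_heatmap(build_heatmap_matrix(scored_by_tp, "score"), out / "heatmap_score.tsv")
    write_heatmap(
        build_heatmap_matrix(scored_by_tp, "mean_lfc"), out / "heatmap_mean_lfc.tsv"
    )

    for name in ("INFLAMMATORY_RESPONSE", "VSMC_CONTRACTION"):
        cells = []
        for tp, scored in scored_by_tp:
            row = scored[scored["pathway_name"] == name].iloc[0]
            cells.append(f"{tp}: score {row['score']:+.2f} rank {row['rank']} -> {row['call']}")
        print(f"{name:>22} | " + " | ".join(cells))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
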