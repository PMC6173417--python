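#!/usr/bin/env python
"""Preranked enrichment on the signed -log10(p) gene ranking.

Builds the ranking per timepoint (sign from the fold-change direction),
writes RNK files, runs the weighted-KS permutation test over all sets,
and keeps sets with FDR <= 0.05 at any timepoint for the display table
(rows at all timepoints, the time-course panel convention). Outputs under
results/enrichment/.
"""

from pathlib import Path

import numpy as np

from vasctx.diffexpr import read_de_table
from vasctx.geneset_io import filter_by_size, read_gmt
from vasctx.ranked_enrichment import (
    filter_significant,
    gsea_preranked,
    rank_metric,
    write_rnk,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
TIMEPOINTS = ("1h", "6h", "24h")
SEED = 20240917


def main() -> None:
    catalog = read_gmt(ROOT / "simdata" / "sets.gmt")
    out = ROOT / "enrichment"
    out.mkdir(parents=True, exist_ok=True)

    seeds = np.random.SeedSequence(SEED).generate_state(len(TIMEPOINTS)) % (2**31)
    by_tp = []
    for tp, seed in zip(TIMEPOINTS, seeds):
        de = read_de_table(ROOT / "de" / f"de_{tp}.tsv")
        ranking = rank_metric(de)
        write_rnk(ranking, out / f"ranking_{tp}.rnk")
        usable = filter_by_size(catalog, 20, 80, universe=list(de.index))
        res = gsea_preranked(ranking, usable, n_perm=1000, seed=int(seed))
        res.to_csv(out / f"gsea_{tp}.tsv", sep="\t", index=False)
        by_tp.append((tp, res))
        top = res.sort_values("fdr_q").head(2)
        shown = "; ".join(
            f"{r.set_name} (NES {r.nes:+.2f}, q {r.fdr_q:.3f})" for r in top.itertuples()
        )
        print(f"{tp:>4}: lowest-q sets -> {shown}")

    filtered = filter_significant(by_tp, q_max=0.05)
    filtered.to_csv(out / "gsea_filtered.tsv", sep="\t", index=False)
    kept = sorted(set(filtered["set_name"]))
    print(f"sets with FDR <= 0.05 at any timepoint: {kept}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
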