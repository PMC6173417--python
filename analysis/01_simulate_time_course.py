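#!/usr/bin/env python
"""Simulate a vascular-injury RNA-seq time course with known ground truth.

The synthetic design mirrors the injury biology the pipeline targets: a
baseline condition (uninjured vessel) and 1 h / 6 h / 24 h post-injury
timepoints, with two planted gene-set signals among otherwise-null sets —

* INFLAMMATORY_RESPONSE: transient, +2 log2FC peaking at 6 h only
  (the acute inflammatory burst that resolves);
* VSMC_CONTRACTION: persistent, -1 log2FC at every timepoint
  (sustained loss of contractile/differentiation gene expression).

Writes counts, sample annotations, gene sets (GMT), and the truth tables
under results/simdata/.
"""

from pathlib import Path

from vasctx.diffexpr import CountMatrix  # noqa: F401  (type of `counts`)
from vasctx.geneset_io import write_gmt
from vasctx.simulate import PlantedSignal, SimConfig, simulate_counts

OUT = Path(__file__).resolve().parent.parent / "results" / "simdata"
SEED = 20240917

CONFIG = SimConfig(
    n_genes=4000,
    timepoints=("1h", "6h", "24h"),
    n_replicates=6,
    dispersion=0.1,
    planted=(
        PlantedSignal("INFLAMMATORY_RESPONSE", "transient", 2.0, peak="6h"),
        PlantedSignal("VSMC_CONTRACTION", "persistent", -1.0),
    ),
    n_sets=100,
    set_size_range=(20, 80),
    seed=SEED,
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts, catalog, truth = simulate_counts(CONFIG)
    counts.to_tsv(OUT / "counts.tsv", OUT / "samples.tsv")
    write_gmt(catalog, OUT / "sets.gmt")
    truth.to_tsv(OUT / "truth_lfc.tsv")
    truth.label_tsv(OUT / "set_labels.tsv")
    print(f"simulated {counts.counts.shape[0]} genes x {counts.counts.shape[1]} samples")
    print(f"catalog: {len(catalog)} sets (2 planted, {len(catalog) - 2} null)")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
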