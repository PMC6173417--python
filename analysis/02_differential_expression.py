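#!/usr/bin/env python
"""Differential expression of each post-injury timepoint versus baseline.

Median-of-ratios normalization followed by the NB Wald test; one DE table
per timepoint under results/de/. Prints how many genes pass adj_p < 0.05
per contrast — the transient signal should make 6 h the busiest timepoint.
"""

from pathlib import Path

from vasctx.diffexpr import CountMatrix, estimate_size_factors, test_two_group, write_de_table

ROOT = Path(__file__).resolve().parent.parent / "results"
TIMEPOINTS = ("1h", "6h", "24h")


def main() -> None:
    counts = CountMatrix.from_tsv(ROOT / "simdata" / "counts.tsv",
                                  ROOT / "simdata" / "samples.tsv")
    sf = estimate_size_factors(counts)
    out = ROOT / "de"
    out.mkdir(parents=True, exist_ok=True)
    print("size factors:", ", ".join(f"{v:.3f}" for v in sf))
    for tp in TIMEPOINTS:
        de = test_two_group(counts, sf, "baseline", tp)
        write_de_table(de, out / f"de_{tp}.tsv")
        n_sig = int((de["adj_p"] < 0.05).sum())
        print(f"{tp:>4}: {n_sig} genes at adj_p < 0.05")


if __name__ == "__main__":
    main()
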