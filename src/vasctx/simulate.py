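"""Synthetic RNA-seq time-course data with known ground truth.

Emulates the structure of a vascular-injury time course: a baseline
condition (uninjured vessel) plus post-injury timepoints, negative-binomial
counts per gene and sample, and planted gene-set signals of two temporal
shapes observed after vessel surgery — a transient response that is present
at a single peak timepoint, and a persistent response sustained at every
timepoint. Gene sets are coherent: every gene of a planted set is shifted
by the same log2 fold change (optionally jittered). All remaining sets are
null.

Also provides a qPCR CT-table generator for the 2^-ddCt module.

Randomness: one global seed; every component draws from a named
sub-stream spawned from it, so adding a component never perturbs another's
draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .diffexpr import CountMatrix
from .geneset_io import GeneSet, GeneSetCatalog

__all__ = [
    "PlantedSignal",
    "SimConfig",
    "TruthRecord",
    "simulate_counts",
    "simulate_ct_table",
]

_SUBSTREAMS = ("means", "membership", "libsize", "counts", "jitter")


@dataclass(frozen=True)
class PlantedSignal:
    """A gene set carrying a true signal.

    profile "persistent": log2 fold change ``delta`` at every non-baseline
    timepoint. profile "transient": ``delta`` only at ``peak`` (zero at all
    other timepoints).
    """

    set_name: str
    profile: str  # "persistent" | "transient"
    delta: float
    peak: str | None = None

    def __post_init__(self) -> None:
        if self.profile not in ("persistent", "transient"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.profile == "transient" and self.peak is None:
            raise ValueError("transient signal needs a peak timepoint")
        if not np.isfinite(self.delta):
            raise ValueError("delta must be finite")


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    NB parameterization: variance = mu + dispersion * mu^2. Per-gene
    baseline means are log-normal (meanlog 4, sdlog 1.5 by default) to span
    low- to high-count genes; per-sample library-size multipliers are
    uniform on ``libsize_range`` so normalization is exercised.
    """

    n_genes: int = 2000
    timepoints: tuple[str, ...] = ("1h", "6h", "24h")
    baseline_label: str = "baseline"
    n_replicates: int = 6
    baseline_meanlog: float = 4.0
    baseline_sdlog: float = 1.5
    dispersion: float = 0.1
    planted: tuple[PlantedSignal, ...] = ()
    n_sets: int = 100
    set_size_range: tuple[int, int] = (20, 80)
    libsize_range: tuple[float, float] = (0.7, 1.3)
    delta_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        lo, hi = self.set_size_range
        if not (2 <= lo <= hi <= self.n_genes):
            raise ValueError(
                f"set_size_range {self.set_size_range} infeasible for "
                f"{self.n_genes} genes"
            )
        for sig in self.planted:
            if sig.profile == "transient" and sig.peak not in self.timepoints:
                raise ValueError(f"peak {sig.peak!r} not among timepoints")

    @property
    def conditions(self) -> tuple[str, ...]:
        return (self.baseline_label, *self.timepoints)


@dataclass
class TruthRecord:
    """Ground truth of a simulation.

    ``lfc``: genes x timepoints DataFrame of true log2 fold changes versus
    baseline; ``set_labels``: set name -> "null" | "transient" | "persistent".
    Genes outside planted sets have LFC 0 everywhere.
    """

    lfc: pd.DataFrame
    set_labels: dict[str, str]

    def to_tsv(self, path: str | Path) -> None:
        df = self.lfc.copy()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")

    def label_tsv(self, path: str | Path) -> None:
        pd.Series(self.set_labels, name="label").rename_axis("set_name").to_csv(
            path, sep="\t"
        )


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_SUBSTREAMS, children)}


def _draw_counts(
    rng: np.random.Generator, mean: np.ndarray, alpha: float
) -> np.ndarray:
    """NB draws with variance = mean + alpha * mean^2 (Poisson when alpha=0)."""
    if alpha == 0:
        return rng.poisson(mean)
    # gamma-Poisson mixture: shape 1/alpha, scale alpha*mean
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mean)
    return rng.poisson(lam)


def simulate_counts(
    config: SimConfig,
) -> tuple[CountMatrix, GeneSetCatalog, TruthRecord]:
    """Simulate a count matrix, a gene-set catalog, and its ground truth.

    Planted sets occupy disjoint gene blocks; null sets are drawn from the
    remaining genes. Deterministic given ``config.seed``.
    """
    rngs = _rngs(config.seed)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    mu = np.exp(
        rngs["means"].normal(
            config.baseline_meanlog, config.baseline_sdlog, size=config.n_genes
        )
    )

    # --- set membership ---------------------------------------------------
    mem_rng = rngs["membership"]
    lo, hi = config.set_size_range
    sizes = mem_rng.integers(lo, hi + 1, size=config.n_sets)
    n_planted = len(config.planted)
    if n_planted > config.n_sets:
        raise ValueError("more planted signals than sets")
    planted_total = int(sizes[:n_planted].sum())
    if planted_total > config.n_genes:
        raise ValueError("planted sets need more genes than simulated")

    perm = mem_rng.permutation(config.n_genes)
    gene_arr = np.array(genes)
    sets: list[GeneSet] = []
    set_labels: dict[str, str] = {}
    truth_lfc = pd.DataFrame(
        0.0, index=genes, columns=list(config.timepoints)
    )

    offset = 0
    for sig, size in zip(config.planted, sizes):
        members = gene_arr[perm[offset : offset + size]]
        offset += size
        sets.append(
            GeneSet(sig.set_name, f"planted {sig.profile}", tuple(members), "synthetic")
        )
        set_labels[sig.set_name] = sig.profile
        if config.delta_jitter_sd > 0:
            deltas = sig.delta + rngs["jitter"].normal(
                0.0, config.delta_jitter_sd, size=size
            )
        else:
            deltas = np.full(size, sig.delta)
        for tp in config.timepoints:
            if sig.profile == "persistent" or tp == sig.peak:
                truth_lfc.loc[members, tp] = deltas

    null_pool = perm[offset:]
    for i in range(n_planted, config.n_sets):
        size = int(sizes[i])
        if size > len(null_pool):
            raise ValueError("set_size_range infeasible: null gene pool exhausted")
        members = gene_arr[mem_rng.choice(null_pool, size=size, replace=False)]
        name = f"NULL_SET_{i:03d}"
        sets.append(GeneSet(name, "null set", tuple(members), "synthetic"))
        set_labels[name] = "null"

    # --- counts -----------------------------------------------------------
    conditions = config.conditions
    n_samples = len(conditions) * config.n_replicates
    libsize = rngs["libsize"].uniform(*config.libsize_range, size=n_samples)

    lfc_by_cond = {config.baseline_label: np.zeros(config.n_genes)}
    for tp in config.timepoints:
        lfc_by_cond[tp] = truth_lfc[tp].to_numpy()

    cols, cond_map = [], {}
    count_cols = []
    crng = rngs["counts"]
    j = 0
    for cond in conditions:
        gene_mean = mu * 2.0 ** lfc_by_cond[cond]
        for r in range(config.n_replicates):
            sid = f"{cond}_r{r + 1}"
            cols.append(sid)
            cond_map[sid] = cond
            count_cols.append(_draw_counts(crng, libsize[j] * gene_mean,
                                           config.dispersion))
            j += 1

    counts = pd.DataFrame(
        np.column_stack(count_cols), index=genes, columns=cols
    )
    return (
        CountMatrix(counts, cond_map),
        GeneSetCatalog(tuple(sets)),
        TruthRecord(truth_lfc, set_labels),
    )


def simulate_ct_table(
    n_samples: int,
    true_fold_change: float,
    ct_noise_sd: float,
    seed: int,
    target_gene: str = "Acta2",
    reference_gene: str = "B2m",
    calibrator_group: str = "calibrator",
    treated_group: str = "treated",
    base_target_ct: float = 26.0,
    base_reference_ct: float = 19.0,
) -> pd.DataFrame:
    """Simulate a qPCR CT table for the 2^-ddCt fold-change module.

    Treated-group target CTs sit ``-log2(true_fold_change)`` cycles from the
    calibrator baseline plus Gaussian noise; reference-gene CTs share the
    same structure in both groups. Returns rows of (sample_id, group, gene,
    ct, reference_ct).
    """
    if true_fold_change <= 0:
        raise ValueError("true_fold_change must be > 0")
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    if n_samples < 2:
        raise ValueError("need >= 2 samples per group")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for group, shift in (
        (calibrator_group, 0.0),
        (treated_group, -np.log2(true_fold_change)),
    ):
        for i in range(n_samples):
            rows.append(
                {
                    "sample_id": f"{group}_{i + 1}",
                    "group": group,
                    "gene": target_gene,
                    "ct": base_target_ct + shift + rng.normal(0.0, ct_noise_sd),
                    "reference_ct": base_reference_ct + rng.normal(0.0, ct_noise_sd),
                }
            )
    df = pd.DataFrame(rows)
    df["reference_gene"] = reference_gene
    return df
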