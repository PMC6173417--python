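"""Per-pathway activity scores from differential-expression results.

The score of a gene set is the mean log2 fold change of its genes divided
by the standard deviation of those fold changes (a signal-to-spread ratio:
large when a set moves coherently in one direction). Pathways are ranked by
score from highest to lowest, and the top and bottom deciles of the ranked
list are called significantly up- and down-regulated respectively.

Scores use raw fold changes regardless of per-gene significance; sets with
fewer than two measured genes, or with identical fold changes (zero sd),
cannot be scored and are flagged instead of receiving infinities.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geneset_io import GeneSet, GeneSetCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "compute_score",
    "score_catalog",
    "rank_and_call",
    "build_heatmap_matrix",
]

SCORE_COLUMNS = [
    "pathway_name",
    "n_genes_used",
    "n_genes_dropped",
    "mean_lfc",
    "sd_lfc",
    "score",
    "rank",
    "call",
]


def compute_score(
    de: pd.DataFrame, gene_set: GeneSet, sd_mode: str = "sample"
) -> dict:
    """Score one gene set against a DE table.

    Uses the log2 fold changes of the set's genes present in the DE table;
    absent genes are ignored and counted in ``n_genes_dropped``. ``sd_mode``
    "sample" (n-1 denominator, default) or "population" (n). Returns a dict
    with mean_lfc, sd_lfc, score, n_genes_used, n_genes_dropped and a
    ``flag`` that is None for a finite score, otherwise "too_few_genes" or
    "zero_sd".
    """
    if sd_mode not in ("sample", "population"):
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    present = [g for g in gene_set.genes if g in de.index]
    n_used = len(present)
    n_dropped = len(gene_set.genes) - n_used
    out = {
        "pathway_name": gene_set.name,
        "n_genes_used": n_used,
        "n_genes_dropped": n_dropped,
        "mean_lfc": math.nan,
        "sd_lfc": math.nan,
        "score": math.nan,
        "flag": None,
    }
    if n_used < 2:
        out["flag"] = "too_few_genes"
        logger.info("pathway %s skipped: %d usable gene(s)", gene_set.name, n_used)
        return out
    lfc = de.loc[present, "log2_fold_change"].to_numpy(dtype=float)
    ddof = 1 if sd_mode == "sample" else 0
    mean = float(lfc.mean())
    sd = float(lfc.std(ddof=ddof))
    out["mean_lfc"] = mean
    out["sd_lfc"] = sd
    if sd == 0.0:
        out["flag"] = "zero_sd"
        logger.info("pathway %s flagged: identical fold changes (sd=0)", gene_set.name)
        return out
    out["score"] = mean / sd
    return out


def score_catalog(
    de: pd.DataFrame,
    catalog: GeneSetCatalog,
    fraction: float = 0.10,
    sd_mode: str = "sample",
) -> pd.DataFrame:
    """Score every set of a catalog, then rank and decile-call.

    Flagged sets (too few genes, zero sd) are excluded from ranking; they
    are returned with call "flagged" and no rank. See :func:`rank_and_call`.
    """
    rows = [compute_score(de, s, sd_mode=sd_mode) for s in catalog]
    df = pd.DataFrame(rows)
    finite = df[df["flag"].isna()].drop(columns="flag")
    flagged = df[df["flag"].notna()].copy()
    ranked = rank_and_call(finite, fraction=fraction)
    if len(flagged):
        flagged["rank"] = pd.NA
        flagged["call"] = "flagged"
        flagged = flagged.rename(columns={"flag": "note"})
        ranked = pd.concat([ranked, flagged.drop(columns="note")], ignore_index=True)
    return ranked


def rank_and_call(scores: pd.DataFrame, fraction: float = 0.10) -> pd.DataFrame:
    """Sort by score (highest first) and call the extreme deciles.

    The top k = floor(fraction * N) rows are called "up", the bottom k
    "down", the rest "none". Ties at any boundary are broken by pathway
    name (lexicographic) for determinism. All rows must carry finite
    scores; 0 < fraction < 0.5.
    """
    if not (0 < fraction < 0.5):
        raise ValueError("fraction must be in (0, 0.5)")
    if len(scores) == 0:
        out = scores.copy()
        out["rank"] = pd.Series(dtype=int)
        out["call"] = pd.Series(dtype=str)
        return out
    if not np.isfinite(scores["score"].to_numpy(dtype=float)).all():
        raise ValueError("rank_and_call requires finite scores")
    df = scores.sort_values(
        ["score", "pathway_name"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    n = len(df)
    k = int(math.floor(fraction * n))
    if k == 0:
        logger.warning("decile size floor(%.3g * %d) = 0; all calls 'none'", fraction, n)
    df["rank"] = np.arange(1, n + 1)
    calls = np.array(["none"] * n, dtype=object)
    calls[:k] = "up"
    if k:
        calls[-k:] = "down"
    df["call"] = calls
    return df


def build_heatmap_matrix(
    scored_per_timepoint: Mapping[str, pd.DataFrame] | Sequence[tuple[str, pd.DataFrame]],
    value: str = "score",
) -> pd.DataFrame:
    """Pathways x timepoints matrix of scores or mean fold changes.

    Rows are the union of pathway names across timepoints (order of first
    appearance), columns the timepoints in supplied order; cells missing a
    pathway at a timepoint are NaN. ``value`` is "score" or "mean_lfc".
    """
    if value not in ("score", "mean_lfc"):
        raise ValueError(f"unknown value column {value!r}")
    items = (
        list(scored_per_timepoint.items())
        if isinstance(scored_per_timepoint, Mapping)
        else list(scored_per_timepoint)
    )
    if not items:
        raise ValueError("need at least one timepoint")
    labels = [tp for tp, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate timepoint labels: {labels}")
    pathways: list[str] = []
    for _, df in items:
        for name in df["pathway_name"]:
            if name not in pathways:
                pathways.append(name)
    mat = pd.DataFrame(np.nan, index=pathways, columns=labels)
    for tp, df in items:
        mat.loc[df["pathway_name"].to_numpy(), tp] = df[value].to_numpy()
    mat.index.name = "pathway"
    return mat


def write_scores(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_heatmap(mat: pd.DataFrame, path: str | Path) -> None:
    mat.to_csv(path, sep="\t", na_rep="NA")
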