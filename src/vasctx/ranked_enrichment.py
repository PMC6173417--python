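"""Preranked gene-set enrichment from scratch.

Genes are ranked by a signed significance metric, sign(LFC) * -log10(p),
so strongly up-regulated genes sit at the top of the list and strongly
down-regulated ones at the bottom. For each gene set a weighted
Kolmogorov-Smirnov running sum walks the ranking: hits add
|metric|^w / sum_hits |metric|^w, misses subtract 1/(N - N_hits); the
enrichment score (ES) is the signed maximal deviation from zero. A null
distribution comes from random same-size gene draws from the ranking
(the only permutation scheme available for preranked input); the
normalized ES (NES) divides ES by the mean absolute null ES of matching
sign, and the FDR q-value follows the canonical pooled-NES-null procedure
(a BH alternative on nominal p is available behind a flag).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexpr import adjust_bh
from .geneset_io import GeneSet, GeneSetCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "rank_metric",
    "enrichment_score",
    "gsea_preranked",
    "filter_significant",
    "read_rnk",
    "write_rnk",
]

RESULT_COLUMNS = ["set_name", "n_genes_used", "es", "nes", "nominal_p", "fdr_q"]


def rank_metric(de: pd.DataFrame, p_floor: float = 1e-300) -> pd.DataFrame:
    """Signed -log10(p) ranking metric from a DE table.

    metric_g = sign(LFC_g) * -log10(max(p_g, p_floor)); an LFC of zero
    gives metric 0. Returns columns (gene_id, metric) sorted descending by
    metric, ties broken by gene id (lexicographic). Genes with missing p or
    LFC are excluded and logged.
    """
    if len(de) == 0:
        raise ValueError("DE table is empty")
    if not (0 < p_floor < 1):
        raise ValueError("p_floor must be in (0, 1)")
    usable = de[["log2_fold_change", "p_value"]].notna().all(axis=1)
    if (~usable).any():
        logger.info("rank_metric: excluded %d gene(s) with missing values",
                    int((~usable).sum()))
    sub = de.loc[usable]
    p = np.maximum(sub["p_value"].to_numpy(dtype=float), p_floor)
    lfc = sub["log2_fold_change"].to_numpy(dtype=float)
    metric = np.sign(lfc) * -np.log10(p)
    out = pd.DataFrame({"gene_id": sub.index.to_numpy(), "metric": metric})
    return out.sort_values(
        ["metric", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def _hit_weights(abs_metric_pow: np.ndarray) -> tuple[np.ndarray, float]:
    total = abs_metric_pow.sum()
    if total == 0:
        # all hit metrics zero: fall back to equal hit increments
        return np.full_like(abs_metric_pow, 1.0 / len(abs_metric_pow)), 1.0
    return abs_metric_pow, total


def enrichment_score(
    ranking: pd.DataFrame, gene_set: GeneSet, weight_exponent: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS running-sum enrichment score of one set.

    Returns (es, running_sum) where running_sum has one entry per ranking
    position. Requires at least one hit and at least one miss.
    """
    genes = ranking["gene_id"].to_numpy()
    metric = ranking["metric"].to_numpy(dtype=float)
    n = len(genes)
    hit = np.isin(genes, np.asarray(gene_set.genes))
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError(f"set {gene_set.name!r} has no genes in the ranking")
    if n_hit == n:
        raise ValueError(f"set {gene_set.name!r} covers the whole ranking")
    w, total = _hit_weights(np.abs(metric[hit]) ** weight_exponent)
    steps = np.full(n, -1.0 / (n - n_hit))
    steps[hit] = w / total
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def _es_walk(positions: np.ndarray, abs_metric_pow: np.ndarray, n: int) -> float:
    """ES of one set by the full running-sum walk (same arithmetic as
    :func:`enrichment_score`)."""
    k = len(positions)
    w, total = _hit_weights(abs_metric_pow[positions])
    steps = np.full(n, -1.0 / (n - k))
    steps[positions] = w / total
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def _es_from_positions(
    positions: np.ndarray, abs_metric_pow: np.ndarray, n: int
) -> np.ndarray:
    """ES for many same-size sets given their sorted hit positions.

    ``positions`` is (m, k), each row the sorted 0-based ranking positions
    of one set's hits. The running sum is piecewise linear between hits, so
    its extrema occur just before or just after a hit; both candidates are
    evaluated per hit and scanned in walk order so ties resolve exactly as
    in the full walk.
    """
    m, k = positions.shape
    w = abs_metric_pow[positions].astype(float)
    totals = w.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    if zero.any():
        w[zero] = 1.0
        totals = w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1) / totals
    miss_step = 1.0 / (n - k)
    idx = np.arange(k)
    misses_before = (positions - idx) * miss_step
    after = cum - misses_before  # value at each hit, after adding its weight
    before = after - w / totals  # value just before each hit
    cand = np.empty((m, 2 * k))
    cand[:, 0::2] = before
    cand[:, 1::2] = after
    return cand[np.arange(m), np.argmax(np.abs(cand), axis=1)]


def gsea_preranked(
    ranking: pd.DataFrame,
    catalog: GeneSetCatalog,
    n_perm: int = 1000,
    weight_exponent: float = 1.0,
    seed: int = 0,
    fdr_method: str = "pooled",
) -> pd.DataFrame:
    """Run preranked enrichment for every set of a catalog.

    Per set: observed ES; a null of ``n_perm`` random same-size draws from
    the ranking; NES = ES / mean(|null ES of matching sign|); nominal p =
    fraction of same-sign null ES at least as extreme, with a +1/(n+1)
    continuity correction; FDR over the pooled signed null NES
    (``fdr_method="pooled"``, canonical) or BH on the nominal p
    (``fdr_method="bh"``). Sets without hits are skipped and logged.
    Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    if fdr_method not in ("pooled", "bh"):
        raise ValueError(f"unknown fdr_method {fdr_method!r}")

    genes = ranking["gene_id"].to_numpy()
    metric = ranking["metric"].to_numpy(dtype=float)
    n = len(genes)
    absw = np.abs(metric) ** weight_exponent
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    rows = []
    null_nes_pos: list[np.ndarray] = []
    null_nes_neg: list[np.ndarray] = []
    for s in catalog:
        pos = np.array(sorted(gene_pos[g] for g in s.genes if g in gene_pos))
        k = len(pos)
        if k == 0:
            logger.info("gsea: set %s skipped (no genes in ranking)", s.name)
            continue
        if k >= n:
            logger.info("gsea: set %s skipped (covers whole ranking)", s.name)
            continue
        # observed ES via the full walk so it matches enrichment_score bitwise
        # (the vectorized candidate path can flip sign on exact |ES| ties)
        es = _es_walk(pos, absw, n)

        perm_pos = np.sort(
            rng.random((n_perm, n)).argpartition(k - 1, axis=1)[:, :k], axis=1
        )
        null = _es_from_positions(perm_pos, absw, n)
        pos_null = null[null >= 0]
        neg_null = null[null < 0]

        if es >= 0:
            same = pos_null
            denom = pos_null.mean() if len(pos_null) else np.nan
        else:
            same = np.abs(neg_null)
            denom = np.abs(neg_null).mean() if len(neg_null) else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        n_same = len(same)
        nominal_p = (np.sum(same >= abs(es)) + 1.0) / (n_same + 1.0)

        mean_pos = pos_null.mean() if len(pos_null) else np.nan
        mean_neg = np.abs(neg_null).mean() if len(neg_null) else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            null_nes_pos.append(pos_null / mean_pos if len(pos_null) else pos_null)
            null_nes_neg.append(neg_null / mean_neg if len(neg_null) else neg_null)

        rows.append(
            {
                "set_name": s.name,
                "n_genes_used": k,
                "es": es,
                "nes": nes,
                "nominal_p": float(min(nominal_p, 1.0)),
            }
        )

    res = pd.DataFrame(rows)
    if len(res) == 0:
        res["fdr_q"] = pd.Series(dtype=float)
        return res

    if fdr_method == "bh":
        res["fdr_q"] = adjust_bh(res["nominal_p"].to_numpy())
        return res

    pooled = np.concatenate(null_nes_pos + null_nes_neg) if rows else np.array([])
    pooled = pooled[np.isfinite(pooled)]
    obs = res["nes"].to_numpy(dtype=float)
    q = np.full(len(res), np.nan)
    n_null_pos = np.sum(pooled >= 0)
    n_null_neg = np.sum(pooled < 0)
    n_obs_pos = np.sum(obs >= 0)
    n_obs_neg = np.sum(obs < 0)
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            q[i] = 1.0
            continue
        if nes >= 0:
            null_frac = (
                np.sum(pooled >= nes) / n_null_pos if n_null_pos else 0.0
            )
            obs_frac = np.sum(obs >= nes) / n_obs_pos if n_obs_pos else 1.0
        else:
            null_frac = (
                np.sum(pooled <= nes) / n_null_neg if n_null_neg else 0.0
            )
            obs_frac = np.sum(obs <= nes) / n_obs_neg if n_obs_neg else 1.0
        q[i] = min(null_frac / obs_frac if obs_frac > 0 else 0.0, 1.0)
    res["fdr_q"] = q
    return res


def filter_significant(
    results: pd.DataFrame | Mapping[str, pd.DataFrame] | Sequence[tuple[str, pd.DataFrame]],
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Keep sets significant (fdr_q <= q_max) at any timepoint.

    Given per-timepoint result tables, a set significant at ANY timepoint is
    retained with its rows at ALL timepoints (the display convention for
    time-course enrichment panels); the output gains a ``timepoint`` column.
    A single table is treated as one timepoint without the extra column.
    """
    if isinstance(results, pd.DataFrame):
        return results[results["fdr_q"] <= q_max].reset_index(drop=True)
    items = (
        list(results.items()) if isinstance(results, Mapping) else list(results)
    )
    keep: set[str] = set()
    for _, df in items:
        keep.update(df.loc[df["fdr_q"] <= q_max, "set_name"])
    out = []
    for tp, df in items:
        sub = df[df["set_name"].isin(keep)].copy()
        sub.insert(0, "timepoint", tp)
        out.append(sub)
    if not out:
        return pd.DataFrame(columns=["timepoint", *RESULT_COLUMNS])
    return pd.concat(out, ignore_index=True)


def write_rnk(ranking: pd.DataFrame, path: str | Path) -> None:
    """Write a 2-column RNK file (gene, metric), no header."""
    ranking[["gene_id", "metric"]].to_csv(path, sep="\t", header=False, index=False)


def read_rnk(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "metric"])
    return df.sort_values(
        ["metric", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
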