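"""End-to-end pipeline: counts -> DE per timepoint -> pathway scores ->
decile calls -> preranked enrichment -> display tables and heatmap matrices.

A run is driven by a :class:`PipelineConfig`, loadable from a YAML file.
Inputs are either external files (counts + annotations + GMT, optional
ortholog map and CT table) or a self-contained simulation block. Every
artifact is plain TSV/GMT/RNK with "." decimals and Unix newlines, and a
manifest captures parameters, seeds, package/library versions and input
digests, so a rerun from the same config and seed reproduces every
artifact byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ddct import delta_delta_ct, read_ct_table, write_fold_changes
from .diffexpr import CountMatrix, estimate_size_factors, test_two_group, write_de_table
from .geneset_io import (
    GeneSetCatalog,
    OrthologMap,
    filter_by_size,
    map_orthologs,
    read_gmt,
    select_by_term,
    write_gmt,
)
from .pathway_score import build_heatmap_matrix, score_catalog, write_heatmap, write_scores
from .ranked_enrichment import (
    filter_significant,
    gsea_preranked,
    rank_metric,
    write_rnk,
)
from .simulate import PlantedSignal, SimConfig, simulate_counts

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything a run needs; see the module docstring.

    Exactly one of (``counts_path`` + ``annotations_path``) or ``simulate``
    must provide the counts. ``contrasts`` lists the treated condition
    labels, each tested against ``reference``.
    """

    seed: int = 0
    reference: str = "baseline"
    contrasts: tuple[str, ...] = ("1h", "6h", "24h")
    counts_path: str | None = None
    annotations_path: str | None = None
    gmt_path: str | None = None
    ortholog_map_path: str | None = None
    ortholog_map_header: bool = False
    geneset_term: str | None = None
    simulate: SimConfig | None = None
    ct_table_path: str | None = None
    ddct_calibrator: str | None = None
    # pathway-score parameters
    min_size: int = 20
    max_size: int = 80
    fraction: float = 0.10
    sd_mode: str = "sample"
    intersect_universe: bool = True
    # enrichment parameters
    weight_exponent: float = 1.0
    n_perm: int = 1000
    q_max: float = 0.05
    p_floor: float = 1e-300

    def validate(self) -> None:
        if self.simulate is None:
            for label, p in (
                ("counts", self.counts_path),
                ("annotations", self.annotations_path),
            ):
                if p is None:
                    raise PipelineError(
                        f"config: no simulation block and no {label} path"
                    )
                if not Path(p).exists():
                    raise PipelineError(f"config: {label} path not found: {p}")
            if self.gmt_path is None:
                raise PipelineError("config: no simulation block and no GMT path")
        for p in (self.gmt_path, self.ortholog_map_path, self.ct_table_path):
            if p is not None and not Path(p).exists():
                raise PipelineError(f"config: path not found: {p}")
        if self.ct_table_path is not None and self.ddct_calibrator is None:
            raise PipelineError("config: CT table given without a calibrator group")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from a YAML file."""
    raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
    sim = raw.pop("simulate", None)
    if sim is not None:
        planted = tuple(
            PlantedSignal(**p) for p in sim.pop("planted", [])
        )
        for key in ("timepoints",):
            if key in sim:
                sim[key] = tuple(sim[key])
        if "set_size_range" in sim:
            sim["set_size_range"] = tuple(sim["set_size_range"])
        sim = SimConfig(planted=planted, **sim)
    if "contrasts" in raw:
        raw["contrasts"] = tuple(raw["contrasts"])
    return PipelineConfig(simulate=sim, **raw)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""

    class _Ctx:
        def __init__(self) -> None:
            self.t0 = 0.0

        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s finished in %.2fs", name, dt)
                return False
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return _Ctx()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute the full pipeline; returns the manifest dict.

    Writes, per contrast: DE table, scored pathways with decile calls, RNK
    ranking, enrichment results; plus the any-timepoint FDR-filtered
    display table, score/mean-LFC heatmap matrices, optional ddCt tables,
    and ``manifest.json``.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "parameters": _config_dict(config),
        "inputs": {},
        "artifacts": [],
        "complete": False,
    }

    def emit(name: str) -> Path:
        manifest["artifacts"].append(name)
        return outdir / name

    try:
        # --- counts + catalog ------------------------------------------------
        if config.simulate is not None:
            with _stage("simulate"):
                counts, catalog, truth = simulate_counts(config.simulate)
                counts.to_tsv(emit("counts.tsv"), emit("samples.tsv"))
                write_gmt(catalog, emit("sets.gmt"))
                truth.to_tsv(emit("truth_lfc.tsv"))
                truth.label_tsv(emit("set_labels.tsv"))
        else:
            with _stage("load_inputs"):
                counts = CountMatrix.from_tsv(
                    config.counts_path, config.annotations_path
                )
                catalog = read_gmt(config.gmt_path)
                for key, p in (
                    ("counts", config.counts_path),
                    ("annotations", config.annotations_path),
                    ("gmt", config.gmt_path),
                ):
                    manifest["inputs"][key] = _sha256(p)

        with _stage("prepare_genesets"):
            if config.geneset_term:
                catalog = select_by_term(catalog, config.geneset_term)
            if config.ortholog_map_path:
                omap = OrthologMap.read_tsv(
                    config.ortholog_map_path, header=config.ortholog_map_header
                )
                catalog = map_orthologs(catalog, omap)
                manifest["inputs"]["ortholog_map"] = _sha256(config.ortholog_map_path)
            universe = (
                list(counts.gene_ids) if config.intersect_universe else None
            )
            catalog = filter_by_size(
                catalog, config.min_size, config.max_size, universe=universe
            )
            if len(catalog) == 0:
                raise ValueError("no gene set survived filtering")

        # --- per-contrast stages --------------------------------------------
        with _stage("size_factors"):
            size_factors = estimate_size_factors(counts)

        gsea_seeds = (
            np.random.SeedSequence(config.seed).generate_state(len(config.contrasts))
            % (2**31)
        )
        scored_by_tp: list[tuple[str, pd.DataFrame]] = []
        gsea_by_tp: list[tuple[str, pd.DataFrame]] = []
        for i, tp in enumerate(config.contrasts):
            with _stage(f"de[{tp}]"):
                de = test_two_group(counts, size_factors, config.reference, tp)
                write_de_table(de, emit(f"de_{tp}.tsv"))
            with _stage(f"score[{tp}]"):
                scored = score_catalog(
                    de, catalog, fraction=config.fraction, sd_mode=config.sd_mode
                )
                write_scores(scored, emit(f"scores_{tp}.tsv"))
                scored_by_tp.append((tp, scored))
            with _stage(f"gsea[{tp}]"):
                ranking = rank_metric(de, p_floor=config.p_floor)
                write_rnk(ranking, emit(f"ranking_{tp}.rnk"))
                gsea = gsea_preranked(
                    ranking,
                    catalog,
                    n_perm=config.n_perm,
                    weight_exponent=config.weight_exponent,
                    seed=int(gsea_seeds[i]),
                )
                gsea.to_csv(emit(f"gsea_{tp}.tsv"), sep="\t", index=False)
                gsea_by_tp.append((tp, gsea))

        with _stage("display_tables"):
            filt = filter_significant(gsea_by_tp, q_max=config.q_max)
            filt.to_csv(emit("gsea_filtered.tsv"), sep="\t", index=False)
            write_heatmap(
                build_heatmap_matrix(scored_by_tp, value="score"),
                emit("heatmap_score.tsv"),
            )
            write_heatmap(
                build_heatmap_matrix(scored_by_tp, value="mean_lfc"),
                emit("heatmap_mean_lfc.tsv"),
            )

        if config.ct_table_path is not None:
            with _stage("ddct"):
                ct = read_ct_table(config.ct_table_path)
                manifest["inputs"]["ct_table"] = _sha256(config.ct_table_path)
                per_sample, per_group = delta_delta_ct(ct, config.ddct_calibrator)
                write_fold_changes(per_sample, per_group, outdir / "ddct")
                manifest["artifacts"] += ["ddct_per_sample.tsv", "ddct_per_group.tsv"]

        manifest["complete"] = True
    finally:
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return manifest


def _config_dict(config: PipelineConfig) -> dict[str, Any]:
    d = asdict(config)
    if config.simulate is not None:
        d["simulate"] = asdict(config.simulate)
        d["simulate"]["planted"] = [asdict(p) for p in config.simulate.planted]
    return d
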