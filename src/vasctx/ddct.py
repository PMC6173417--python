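"""Relative qPCR quantification by the 2^-ddCt method.

For each sample, dCt = target CT - reference-gene CT (the housekeeping
assay, e.g. B2m); ddCt = dCt - mean dCt of the calibrator group (e.g.
normal, uninjured vessels); fold change = 2^-ddCt. Amplification
efficiency is fixed at 2 (perfect doubling per cycle); efficiency-corrected
quantification is out of scope. Group summaries are geometric means with
log-scale dispersion, since fold changes are multiplicative.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["delta_delta_ct", "read_ct_table", "write_fold_changes"]

CT_COLUMNS = ["sample_id", "group", "gene", "ct", "reference_ct"]


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a CT table CSV with columns sample_id, group, gene, ct, reference_ct."""
    df = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CT table missing column(s): {missing}")
    return df


def delta_delta_ct(
    table: pd.DataFrame, calibrator_group: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample and per-group fold changes versus a calibrator group.

    Returns ``(per_sample, per_group)``. Per sample: delta_ct,
    delta_delta_ct (against the calibrator group's mean delta_ct, per
    gene), fold_change = 2^-ddCt. Per group and gene: geometric-mean fold
    change with the standard deviation of log2 fold changes. Samples with a
    missing reference CT are dropped with a log message; an absent or empty
    calibrator group is an error.
    """
    df = table.copy()
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CT table missing column(s): {missing}")
    bad = df["ct"].isna() | df["reference_ct"].isna()
    if bad.any():
        logger.info(
            "delta_delta_ct: dropped %d sample row(s) with missing CT values: %s",
            int(bad.sum()), ", ".join(df.loc[bad, "sample_id"].astype(str)),
        )
        df = df[~bad]
    if not (df["group"] == calibrator_group).any():
        raise ValueError(f"calibrator group {calibrator_group!r} absent or empty")

    df["delta_ct"] = df["ct"] - df["reference_ct"]
    out = []
    for gene, sub in df.groupby("gene", sort=False):
        cal = sub.loc[sub["group"] == calibrator_group, "delta_ct"]
        if len(cal) == 0:
            raise ValueError(
                f"calibrator group {calibrator_group!r} has no samples for gene {gene!r}"
            )
        sub = sub.copy()
        sub["delta_delta_ct"] = sub["delta_ct"] - cal.mean()
        sub["fold_change"] = 2.0 ** (-sub["delta_delta_ct"])
        out.append(sub)
    per_sample = pd.concat(out, ignore_index=True)

    log2fc = np.log2(per_sample["fold_change"])
    per_sample = per_sample.assign(_log2fc=log2fc)
    grouped = per_sample.groupby(["gene", "group"], sort=False)["_log2fc"]
    per_group = grouped.agg(["mean", "std", "count"]).reset_index()
    per_group["geomean_fold_change"] = 2.0 ** per_group["mean"]
    per_group = per_group.rename(
        columns={"mean": "mean_log2_fc", "std": "sd_log2_fc", "count": "n_samples"}
    )
    per_sample = per_sample.drop(columns="_log2fc")
    return per_sample, per_group


def write_fold_changes(
    per_sample: pd.DataFrame, per_group: pd.DataFrame, prefix: str | Path
) -> None:
    per_sample.to_csv(str(prefix) + "_per_sample.tsv", sep="\t", index=False)
    per_group.to_csv(str(prefix) + "_per_group.tsv", sep="\t", index=False)
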