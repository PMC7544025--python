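"""Relative expression from RT-qPCR Ct values (delta-Ct method).

Technical replicates are averaged per biological sample, each sample's
target Ct is normalized against the mean Ct of the reference (housekeeping)
genes, and relative expression is 2^(-dCt) -- i.e. amplification efficiency
is taken as a perfect doubling per cycle unless overridden.  Averaging the
reference genes' Cts is equivalent to normalizing against the geometric
mean of their expression levels.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

CT_COLUMNS = ["sample", "species", "tissue", "gene", "rep", "ct"]
TISSUES = {"leaf", "bark"}

#: Technical-replicate scatter above this many cycles flags a sample.
TECH_SD_OUTLIER = 0.5


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV Ct table with columns sample, species, tissue, gene, rep, ct."""
    df = pd.read_csv(path, sep="\t")
    return validate_ct_table(df)


def validate_ct_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    df = df[CT_COLUMNS].copy()
    df["ct"] = df["ct"].astype(float)
    if ((df["ct"] <= 0) | (df["ct"] >= 45)).any():
        raise ValueError("Ct values must lie in (0, 45) cycles")
    bad_tissue = set(df["tissue"]) - TISSUES
    if bad_tissue:
        raise ValueError(f"unknown tissues: {sorted(bad_tissue)}")
    return df


def aggregate_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and sd of technical replicates per (sample, gene).

    A single replicate yields sd 0 with ``single_replicate`` flagged; a
    technical sd above 0.5 cycles sets ``outlier_flag``.
    """
    table = validate_ct_table(table)
    grouped = table.groupby(["sample", "species", "tissue", "gene"], sort=True)
    agg = grouped["ct"].agg(mean_ct="mean", sd_ct="std", n_reps="count").reset_index()
    agg["single_replicate"] = agg["n_reps"] == 1
    agg["sd_ct"] = agg["sd_ct"].fillna(0.0)
    agg["outlier_flag"] = agg["sd_ct"] > TECH_SD_OUTLIER
    return agg


def delta_ct(
    sample_means: pd.DataFrame,
    target_gene: str,
    reference_genes: Sequence[str],
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Per-(species, tissue) relative expression of one target gene.

    For each biological sample: dCt = Ct_target - mean(Ct of references);
    rel_expr = efficiency^(-dCt).  Rows aggregate biological samples with
    the mean and sd of both dCt and rel_expr.
    """
    if not reference_genes:
        raise ValueError("at least one reference gene is required")
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    per_sample = []
    for (sample, species, tissue), sub in sample_means.groupby(
        ["sample", "species", "tissue"], sort=True
    ):
        genes = dict(zip(sub["gene"], sub["mean_ct"]))
        if target_gene not in genes:
            raise ValueError(f"sample {sample!r}: target gene {target_gene!r} not measured")
        missing = [g for g in reference_genes if g not in genes]
        if missing:
            raise ValueError(f"sample {sample!r}: missing reference genes {missing}")
        ref_ct = float(np.mean([genes[g] for g in reference_genes]))
        dct = genes[target_gene] - ref_ct
        per_sample.append({
            "sample": sample, "species": species, "tissue": tissue,
            "gene": target_gene, "delta_ct": dct,
            "rel_expr": efficiency ** (-dct),
        })
    per_sample = pd.DataFrame(per_sample)
    rows = []
    for (species, tissue), sub in per_sample.groupby(["species", "tissue"], sort=True):
        rows.append({
            "species": species, "tissue": tissue, "gene": target_gene,
            "n_bio": len(sub),
            "mean_delta_ct": sub["delta_ct"].mean(),
            "sd_delta_ct": sub["delta_ct"].std(ddof=1) if len(sub) > 1 else 0.0,
            "rel_expr": sub["rel_expr"].mean(),
            "sd_rel_expr": sub["rel_expr"].std(ddof=1) if len(sub) > 1 else 0.0,
        })
    return pd.DataFrame(rows)


def relative_expression(
    table: pd.DataFrame,
    target_gene: str,
    reference_genes: Sequence[str],
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Convenience wrapper: aggregate technical replicates, then delta-Ct."""
    return delta_ct(aggregate_replicates(table), target_gene, reference_genes, efficiency)
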