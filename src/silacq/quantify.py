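"""Peptide-evidence aggregation into per-protein SILAC ratios.

Evidence tables carry one row per observed peptide with per-channel
intensities (light/medium/heavy) and a replicate id.  Quantification
proceeds: length filter -> per-row M/L and H/L intensity ratios ->
per-protein, per-replicate aggregate (median by default) -> replicate
intersection and averaging.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "EVIDENCE_COLUMNS",
    "filter_evidence",
    "peptide_ratios",
    "aggregate_protein",
    "aggregate_evidence",
    "merge_replicates",
]

EVIDENCE_COLUMNS = [
    "sequence",
    "protein",
    "charge",
    "intensity_l",
    "intensity_m",
    "intensity_h",
    "replicate",
]


def filter_evidence(evidence: pd.DataFrame, min_length: int = 6) -> pd.DataFrame:
    """Drop peptides shorter than ``min_length`` residues; order preserved."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    keep = evidence["sequence"].str.len() >= min_length
    return evidence.loc[keep].copy()


def peptide_ratios(evidence: pd.DataFrame) -> pd.DataFrame:
    """Append per-row ``ml`` and ``hl`` intensity-ratio columns.

    A ratio is defined only when both channel intensities are present and
    strictly positive; otherwise NaN propagates.
    """
    out = evidence.copy()
    light = out["intensity_l"].astype(float)
    for col, chan in (("ml", "intensity_m"), ("hl", "intensity_h")):
        num = out[chan].astype(float)
        ratio = num / light
        ratio[(light <= 0) | (num <= 0)] = np.nan
        out[col] = ratio
    return out


def _aggregate(values: pd.Series, method: str) -> float:
    vals = values.dropna()
    if vals.empty:
        return np.nan
    return float(vals.median() if method == "median" else vals.mean())


def aggregate_protein(
    rows: pd.DataFrame,
    method: Literal["median", "mean"] = "median",
    min_ratio_count: int = 1,
) -> dict:
    """Aggregate one protein's peptide rows (single replicate) to ratios.

    Returns ``{"ml_ratio", "hl_ratio", "n_peptides"}``; a channel ratio is
    NaN when fewer than ``min_ratio_count`` peptide ratios are defined.
    """
    if rows.empty:
        raise ValueError("rows must be non-empty")
    if rows["protein"].nunique() > 1 or rows["replicate"].nunique() > 1:
        raise ValueError("rows must belong to one protein and one replicate")
    if not {"ml", "hl"} <= set(rows.columns):
        rows = peptide_ratios(rows)
    out = {"n_peptides": int(len(rows))}
    for ch in ("ml", "hl"):
        n_def = int(rows[ch].notna().sum())
        out[f"{ch}_ratio"] = (
            _aggregate(rows[ch], method) if n_def >= min_ratio_count else np.nan
        )
    return out


def aggregate_evidence(
    evidence: pd.DataFrame,
    method: Literal["median", "mean"] = "median",
    min_ratio_count: int = 1,
) -> pd.DataFrame:
    """Vectorized per-(protein, replicate) aggregation of an evidence table.

    Returns one row per protein x replicate with ``ml_ratio``, ``hl_ratio``
    and ``n_peptides``.
    """
    ev = evidence if {"ml", "hl"} <= set(evidence.columns) else peptide_ratios(evidence)
    grp = ev.groupby(["protein", "replicate"], sort=True)
    agg_fn = "median" if method == "median" else "mean"
    out = grp.agg(
        ml_ratio=("ml", agg_fn),
        hl_ratio=("hl", agg_fn),
        n_peptides=("sequence", "size"),
    ).reset_index()
    if min_ratio_count > 1:
        counts = grp.agg(n_ml=("ml", "count"), n_hl=("hl", "count")).reset_index()
        out.loc[counts["n_ml"] < min_ratio_count, "ml_ratio"] = np.nan
        out.loc[counts["n_hl"] < min_ratio_count, "hl_ratio"] = np.nan
    return out


def merge_replicates(
    per_replicate: pd.DataFrame,
    required_replicates: int = 2,
    average: Literal["ratio", "log"] = "ratio",
) -> pd.DataFrame:
    """Intersect replicates and average per-protein ratios.

    A channel average is reported only for proteins whose ratio is defined
    in at least ``required_replicates`` replicates; proteins with neither
    channel average are dropped.  ``average="ratio"`` takes the arithmetic
    mean of ratios (matching printed "M/L average" columns);
    ``average="log"`` averages on the log2 scale (geometric mean).
    """
    if required_replicates < 1:
        raise ValueError("required_replicates must be >= 1")
    grp = per_replicate.groupby("protein", sort=True)

    def _avg(vals: pd.Series) -> float:
        v = vals.dropna()
        if len(v) < required_replicates:
            return np.nan
        if average == "log":
            return float(2.0 ** np.log2(v.astype(float)).mean())
        return float(v.mean())

    out = grp.agg(
        ml_average=("ml_ratio", _avg),
        hl_average=("hl_ratio", _avg),
        n_replicates=("replicate", "nunique"),
        n_peptides_total=("n_peptides", "sum"),
    ).reset_index()
    keep = out["ml_average"].notna() | out["hl_average"].notna()
    return out.loc[keep].reset_index(drop=True)
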