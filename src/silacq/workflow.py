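"""End-to-end quantification pipeline and classification scoring.

Ties the stages together in the published order: length filter ->
peptide ratios -> per-replicate protein aggregation -> replicate
intersection/averaging -> per-replicate z-scores -> replicate z-averaging
-> confidence tiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import quantify, ratio_stats

__all__ = ["RunConfig", "run_pipeline", "evaluate_classification"]


@dataclass
class RunConfig:
    """Knobs of the quantification/classification pipeline."""

    min_peptide_length: int = 6
    required_replicates: int = 2
    aggregation: str = "median"          # peptide -> protein
    min_ratio_count: int = 1
    replicate_average: str = "ratio"     # "ratio" | "log"
    normalization: str = "per-channel"   # "per-channel" | "paper-compat"
    confidence_levels: tuple[float, ...] = (95.0, 99.0, 99.9)
    clustering_metric: str = "euclidean"
    clustering_linkage: str = "average"
    enrichment_min_count: int = 2
    ease_threshold: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_peptide_length < 1:
            raise ValueError("min_peptide_length must be >= 1")
        if self.required_replicates < 1:
            raise ValueError("required_replicates must be >= 1")
        if self.aggregation not in ("median", "mean"):
            raise ValueError("aggregation must be 'median' or 'mean'")
        if self.normalization not in ("per-channel", "paper-compat"):
            raise ValueError("unknown normalization mode")
        if not 0 < self.ease_threshold <= 1:
            raise ValueError("ease_threshold must be in (0, 1]")


def run_pipeline(evidence: pd.DataFrame, config: RunConfig | None = None) -> dict:
    """Run evidence -> ratios -> z-scores -> tiers.

    Returns a dict with ``evidence`` (filtered), ``per_replicate``,
    ``proteins`` (merged averages), ``records`` (classified z-score table)
    and ``params`` (normalization parameters per data set).
    """
    cfg = config or RunConfig()
    ev = quantify.filter_evidence(evidence, cfg.min_peptide_length)
    ev = quantify.peptide_ratios(ev)
    per_rep = quantify.aggregate_evidence(
        ev, method=cfg.aggregation, min_ratio_count=cfg.min_ratio_count
    )
    proteins = quantify.merge_replicates(
        per_rep,
        required_replicates=cfg.required_replicates,
        average=cfg.replicate_average,
    )
    # z-scores are computed on the replicate-intersected population only,
    # per data set, then averaged across replicates per protein
    kept = per_rep[per_rep["protein"].isin(proteins["protein"])]
    zrec, params = ratio_stats.zscore_table(kept, mode=cfg.normalization)
    records = proteins.merge(zrec, on="protein", how="left")
    for ch in ("ml", "hl"):
        records[f"log2_{ch}"] = np.log2(records[f"{ch}_average"].astype(float))
    records = ratio_stats.classify_table(records, cfg.confidence_levels)
    return {
        "evidence": ev,
        "per_replicate": per_rep,
        "proteins": proteins,
        "records": records,
        "params": params,
    }


def evaluate_classification(
    records: pd.DataFrame, truth: pd.DataFrame, level: float = 95.0
) -> dict[str, float]:
    """Sensitivity/specificity of tier calls against a ground-truth manifest.

    A (protein, channel) entry counts as a true positive when the channel
    reaches ``level`` with the planted direction.  Proteins lost upstream
    (not quantified) count as misses.
    """
    merged = truth.merge(records, on="protein", how="left")
    out: dict[str, float] = {}
    tp = fn = tn = fp = 0
    for ch in ("ml", "hl"):
        reg = merged[f"regulated_{ch}"].to_numpy()
        tier = merged[f"tier_{ch}"].fillna(0).to_numpy()
        direction = merged[f"direction_{ch}"].fillna("none").to_numpy()
        called = (tier >= level) & (direction != "none")
        sign = np.where(direction == "up", 1, np.where(direction == "down", -1, 0))
        tp += int(((reg != 0) & called & (sign == reg)).sum())
        fn += int(((reg != 0) & ~(called & (sign == reg))).sum())
        fp += int(((reg == 0) & called).sum())
        tn += int(((reg == 0) & ~called).sum())
    out["sensitivity"] = tp / (tp + fn) if tp + fn else float("nan")
    out["specificity"] = tn / (tn + fp) if tn + fp else float("nan")
    out["tp"], out["fn"], out["fp"], out["tn"] = tp, fn, fp, tn
    return out
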