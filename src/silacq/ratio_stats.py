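"""z-score standardization and confidence-tier calling of SILAC ratios.

The differential-regulation statistic: per data set (channel, replicate),
log2 ratios are standardized against the population mean and sample SD,

    z = (log2 r - mean) / sd,

and a protein is called regulated when |z| reaches the two-sided normal
critical value of a confidence level (95% -> 1.960 sigma, 99% -> 2.576,
99.9% -> 3.291).  Replicate z-scores are averaged before tier assignment;
ratio averages are reported alongside.  Includes the 2^-ddCt helper used
to corroborate calls by qPCR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NormalizationParams",
    "DdctMeasurement",
    "CONFIDENCE_LEVELS",
    "log2_ratio",
    "fit_params",
    "zscore",
    "confidence_to_threshold",
    "average_z",
    "classify",
    "classify_table",
    "zscore_table",
    "fold_change",
    "count_regulated",
    "ddct_fold",
]

CONFIDENCE_LEVELS = (95.0, 99.0, 99.9)


class DegeneratePopulationError(ValueError):
    """Population SD is zero: z-scores are undefined."""


class InsufficientDataError(ValueError):
    """Too few values to estimate mean and SD."""


@dataclass(frozen=True)
class NormalizationParams:
    """Mean and sample SD of a log2-ratio population."""

    mean_log2: float
    sd_log2: float
    channel: str = "global"

    def __post_init__(self) -> None:
        if self.sd_log2 <= 0:
            raise DegeneratePopulationError("sd_log2 must be > 0")


@dataclass(frozen=True)
class DdctMeasurement:
    """Ct quadruple for relative qPCR quantification."""

    ct_target_treated: float
    ct_ref_treated: float
    ct_target_control: float
    ct_ref_control: float


def log2_ratio(r: float) -> float:
    if r <= 0 or not math.isfinite(r):
        raise ValueError(f"ratio must be positive and finite, got {r}")
    return math.log2(r)


def fit_params(
    log2_values: Sequence[float] | np.ndarray, channel: str = "global"
) -> NormalizationParams:
    """Arithmetic mean and sample SD (n-1 denominator) of log2 ratios."""
    vals = np.asarray(log2_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise InsufficientDataError("need at least 2 finite log2 values")
    sd = float(vals.std(ddof=1))
    if sd == 0:
        raise DegeneratePopulationError("constant population, SD is 0")
    return NormalizationParams(float(vals.mean()), sd, channel)


def zscore(log2_value: float, params: NormalizationParams) -> float:
    return (log2_value - params.mean_log2) / params.sd_log2


def confidence_to_threshold(level: float) -> float:
    """Two-sided standard-normal critical value of a confidence level (%)."""
    if not 0 < level < 100:
        raise ValueError("confidence level must be in (0, 100)")
    return float(stats.norm.ppf(1 - (1 - level / 100) / 2))


def average_z(z_per_replicate: Sequence[float]) -> float:
    vals = [v for v in z_per_replicate if np.isfinite(v)]
    if not vals:
        raise ValueError("no finite z-scores to average")
    return float(np.mean(vals))


def classify(
    z: float, levels: Sequence[float] = CONFIDENCE_LEVELS
) -> tuple[float, str]:
    """Highest confidence tier reached by ``z`` and its direction.

    Returns ``(level, direction)`` where level is 0 (none) or one of the
    configured levels; comparison is inclusive (|z| >= threshold).
    """
    if not np.isfinite(z):
        return 0.0, "none"
    tier, direction = 0.0, "none"
    for lv in sorted(levels):
        if abs(z) >= confidence_to_threshold(lv):
            tier = lv
            direction = "up" if z > 0 else "down"
    return tier, direction


def fold_change(r: float) -> float:
    """Direction-free magnitude of a ratio: max(r, 1/r) >= 1."""
    if r <= 0 or not math.isfinite(r):
        raise ValueError(f"ratio must be positive and finite, got {r}")
    return max(r, 1.0 / r)


def zscore_table(
    per_replicate: pd.DataFrame,
    mode: Literal["per-channel", "paper-compat"] = "per-channel",
    shared_params: NormalizationParams | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Standardize per-replicate protein ratios and average z across replicates.

    ``per_replicate`` carries columns ``protein, replicate, ml_ratio,
    hl_ratio``.  In ``per-channel`` mode each (channel, replicate) data set
    is standardized against its own mean/SD; in ``paper-compat`` mode a
    single parameter set (``shared_params``, or fit on the pooled M/L
    log2 ratios) standardizes both channels.  Returns one row per protein
    with ``z_ml``/``z_hl`` (replicate-averaged) plus the fitted params per
    data set.
    """
    df = per_replicate.copy()
    for ch in ("ml", "hl"):
        df[f"log2_{ch}"] = np.log2(df[f"{ch}_ratio"].astype(float))

    params: dict[tuple[str, object], NormalizationParams] = {}
    if mode == "paper-compat":
        shared = shared_params or fit_params(
            df["log2_ml"].dropna().to_numpy(), channel="M/L"
        )
        for ch in ("ml", "hl"):
            df[f"z_{ch}"] = (df[f"log2_{ch}"] - shared.mean_log2) / shared.sd_log2
            params[(ch, "shared")] = shared
    elif mode == "per-channel":
        df["z_ml"] = np.nan
        df["z_hl"] = np.nan
        for rep, sub in df.groupby("replicate"):
            for ch in ("ml", "hl"):
                vals = sub[f"log2_{ch}"].dropna()
                if len(vals) < 2:
                    continue
                p = fit_params(vals.to_numpy(), channel="M/L" if ch == "ml" else "H/L")
                params[(ch, rep)] = p
                df.loc[sub.index, f"z_{ch}"] = (
                    sub[f"log2_{ch}"] - p.mean_log2
                ) / p.sd_log2
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")

    agg = df.groupby("protein", sort=True).agg(
        z_ml=("z_ml", "mean"), z_hl=("z_hl", "mean")
    )
    return agg.reset_index(), params


def classify_table(
    records: pd.DataFrame,
    levels: Sequence[float] = CONFIDENCE_LEVELS,
) -> pd.DataFrame:
    """Attach tier/direction per channel and the both-channels flag.

    ``records`` needs ``z_ml``/``z_hl`` columns; a missing channel yields
    tier 0 ("none") for that channel.  The both-channels flag is set when
    both channels reach a tier in the same direction; ``tier_both`` is the
    highest level reached jointly.
    """
    out = records.copy()
    for ch in ("ml", "hl"):
        tiers, dirs = [], []
        for z in out[f"z_{ch}"].to_numpy(dtype=float):
            t, d = classify(z, levels)
            tiers.append(t)
            dirs.append(d)
        out[f"tier_{ch}"] = tiers
        out[f"direction_{ch}"] = dirs
    same = (out["direction_ml"] == out["direction_hl"]) & (out["direction_ml"] != "none")
    out["tier_both"] = np.where(same, np.minimum(out["tier_ml"], out["tier_hl"]), 0.0)
    out["direction_both"] = np.where(same, out["direction_ml"], "none")
    for ch in ("ml", "hl"):
        col = f"{ch}_average"
        if col in out.columns:
            r = out[col].astype(float)
            out[f"fold_{ch}"] = np.where(r > 0, np.maximum(r, 1.0 / r), np.nan)
    return out


def count_regulated(
    records: pd.DataFrame, level: float = 95.0
) -> dict[str, int]:
    """Up/down counts per channel and for the shared-direction set."""
    counts: dict[str, int] = {}
    for ch in ("ml", "hl", "both"):
        tier = records.get(f"tier_{ch}")
        direction = records.get(f"direction_{ch}")
        if tier is None:
            counts[f"{ch}_up"] = counts[f"{ch}_down"] = 0
            continue
        reached = tier >= level
        counts[f"{ch}_up"] = int((reached & (direction == "up")).sum())
        counts[f"{ch}_down"] = int((reached & (direction == "down")).sum())
    return counts


def ddct_fold(m: DdctMeasurement) -> float:
    """Relative expression by the 2^-ddCt method."""
    ddct = (m.ct_target_treated - m.ct_ref_treated) - (
        m.ct_target_control - m.ct_ref_control
    )
    return float(2.0 ** (-ddct))
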