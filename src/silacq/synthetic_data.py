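"""Synthetic three-channel peptide evidence, spectra, and annotations.

No raw data accompany the study this package models, so every stage is
exercised on simulated inputs with the statistical structure the analysis
assumes: per-protein true log2 M/L and H/L ratios drawn from a Gaussian
background with a small regulated fraction carrying large effects,
peptide-level multiplicative noise on log-normal base intensities, two
replicates with a small protein-level shift, and channel-wise missingness.
Ground-truth manifests accompany each table so recovery can be scored.

One global seed feeds a :class:`numpy.random.SeedSequence` hierarchy, so
each sub-stream (ratios, peptides, intensities, missingness, ...) can be
regenerated independently and outputs are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .silac_labels import (
    LIGHT,
    MEDIUM,
    HEAVY,
    PRO_CONVERSION_DELTA,
    PeakList,
    PeptideSpec,
    TripletMatch,
    peptide_mz,
    channel_mass_shift,
)

__all__ = [
    "SimConfig",
    "simulate_evidence",
    "simulate_peaklist",
    "simulate_annotations",
    "simulate_replicate_presence",
]

# Channel patterns for regulated proteins: which comparisons carry the
# effect and with what relative sign.  Mirrors a mixture of NMIBC-specific,
# metastasis-specific and shared regulation.
_PATTERNS = ("ml_only", "hl_only", "both_same")


class ConfigError(ValueError):
    """Invalid simulation configuration; message lists offending fields."""


@dataclass
class SimConfig:
    """Study-scale defaults for the peptide-evidence generator.

    ``background_log2`` reflects a ratio population centred slightly below
    0 with most proteins within +/-1; regulated effects start at ~5-fold
    (|log2| >= 2.3), the magnitude at which calls clear the 95% tier of a
    population of this spread.
    """

    n_proteins: int = 2000
    fraction_regulated: float = 0.06
    effect_log2_range: tuple[float, float] = (2.3, 5.3)
    background_log2_mean: float = -0.07
    background_log2_sd: float = 0.8
    peptide_noise_sd_log2: float = 0.3
    peptides_per_protein_mean: float = 4.0  # 1 + Poisson(mean)
    base_intensity_median: float = 1e6
    base_intensity_gsd: float = 4.0
    n_replicates: int = 2
    replicate_shift_sd: float = 0.05
    missing_rate: float = 0.05
    incorporation: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.n_proteins < 1:
            bad.append("n_proteins")
        for f in ("fraction_regulated", "missing_rate", "incorporation"):
            if not 0 <= getattr(self, f) <= 1:
                bad.append(f)
        for f in (
            "background_log2_sd",
            "peptide_noise_sd_log2",
            "replicate_shift_sd",
            "peptides_per_protein_mean",
        ):
            if getattr(self, f) < 0:
                bad.append(f)
        if self.effect_log2_range[0] > self.effect_log2_range[1] or self.effect_log2_range[0] < 0:
            bad.append("effect_log2_range")
        if self.base_intensity_median <= 0 or self.base_intensity_gsd < 1:
            bad.append("base_intensity")
        if self.n_replicates < 1:
            bad.append("n_replicates")
        if bad:
            raise ConfigError(f"invalid config fields: {', '.join(bad)}")


_AA_POOL = np.array(list("ACDEFGHILMNPQSTVWY"))  # internal residues


def _random_peptides(
    rng: np.random.Generator, n: int, never_short: np.ndarray | None = None
) -> list[str]:
    """Tryptic-like sequences ending in K/R; ~2% below the 6-mer filter.

    Positions flagged in ``never_short`` always pass the length filter so
    every protein keeps at least one quantifiable peptide.
    """
    lengths = rng.integers(7, 21, size=n)
    short = rng.random(n) < 0.02
    if never_short is not None:
        short &= ~never_short
    lengths[short] = rng.integers(4, 6, size=int(short.sum()))
    seqs = []
    for L in lengths:
        body = "".join(rng.choice(_AA_POOL, size=L - 1))
        seqs.append(body + ("K" if rng.random() < 0.5 else "R"))
    return seqs


def simulate_evidence(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a peptide-evidence table and its ground-truth manifest.

    Returns ``(evidence, truth)``: evidence in the canonical TSV dialect
    (sequence, protein, charge, intensity_l/m/h, replicate) and truth with
    one row per protein (true log2 ratios, regulated direction per channel).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    r_truth, r_pep, r_int, r_miss = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]

    n = config.n_proteins
    proteins = np.array([f"P{i:05d}" for i in range(n)])

    true_ml = r_truth.normal(config.background_log2_mean, config.background_log2_sd, n)
    true_hl = r_truth.normal(config.background_log2_mean, config.background_log2_sd, n)
    reg_ml = np.zeros(n, dtype=int)
    reg_hl = np.zeros(n, dtype=int)

    n_reg = round(config.fraction_regulated * n)
    reg_idx = r_truth.choice(n, size=n_reg, replace=False)
    lo, hi = config.effect_log2_range
    for i in reg_idx:
        pattern = _PATTERNS[r_truth.integers(len(_PATTERNS))]
        sign = 1 if r_truth.random() < 0.5 else -1
        effect = sign * r_truth.uniform(lo, hi)
        if pattern in ("ml_only", "both_same"):
            true_ml[i] = effect
            reg_ml[i] = sign
        if pattern in ("hl_only", "both_same"):
            true_hl[i] = effect
            reg_hl[i] = sign

    truth = pd.DataFrame(
        {
            "protein": proteins,
            "true_log2_ml": true_ml,
            "true_log2_hl": true_hl,
            "regulated_ml": reg_ml,
            "regulated_hl": reg_hl,
        }
    )

    n_pep = 1 + r_pep.poisson(config.peptides_per_protein_mean, n)
    prot_col = np.repeat(proteins, n_pep)
    ml_col = np.repeat(true_ml, n_pep)
    hl_col = np.repeat(true_hl, n_pep)
    total = int(n_pep.sum())
    first = np.zeros(total, dtype=bool)
    first[np.concatenate([[0], np.cumsum(n_pep)[:-1]])] = True
    seqs = _random_peptides(r_pep, total, never_short=first)
    charges = r_pep.integers(2, 4, size=total)

    frames = []
    for rep in range(1, config.n_replicates + 1):
        shift_ml = np.repeat(
            r_truth.normal(0, config.replicate_shift_sd, n), n_pep
        ) if config.replicate_shift_sd > 0 else 0.0
        shift_hl = np.repeat(
            r_truth.normal(0, config.replicate_shift_sd, n), n_pep
        ) if config.replicate_shift_sd > 0 else 0.0
        base = config.base_intensity_median * np.exp(
            r_int.normal(0, np.log(config.base_intensity_gsd), total)
        )
        noise = config.peptide_noise_sd_log2
        eps_m = r_int.normal(0, noise, total) if noise > 0 else 0.0
        eps_h = r_int.normal(0, noise, total) if noise > 0 else 0.0
        df = pd.DataFrame(
            {
                "sequence": seqs,
                "protein": prot_col,
                "charge": charges,
                "intensity_l": base,
                "intensity_m": base * 2.0 ** (ml_col + shift_ml + eps_m),
                "intensity_h": base * 2.0 ** (hl_col + shift_hl + eps_h),
                "replicate": f"rep{rep}",
            }
        )
        frames.append(df)
    evidence = pd.concat(frames, ignore_index=True)

    if config.missing_rate > 0:
        for col in ("intensity_l", "intensity_m", "intensity_h"):
            drop = r_miss.random(len(evidence)) < config.missing_rate
            evidence.loc[drop, col] = np.nan
        all_missing = evidence[["intensity_l", "intensity_m", "intensity_h"]].isna().all(axis=1)
        evidence = evidence.loc[~all_missing].reset_index(drop=True)

    return evidence, truth


def simulate_peaklist(
    spec: PeptideSpec,
    incorporation: float = 1.0,
    conversion_fraction: float = 0.0,
    n_noise_peaks: int = 0,
    seed: int = 0,
    main_intensity: float = 1e5,
    mz_range: tuple[float, float] = (300.0, 1800.0),
) -> tuple[PeakList, list[TripletMatch]]:
    """Plant an L/M/H triplet (plus optional artifacts) for one peptide.

    The medium and heavy peaks sit at the exact label spacings for the
    peptide's charge.  The light peak is scaled by ``1 - incorporation``
    (absent at full incorporation).  ``conversion_fraction`` > 0 adds
    Arg→Pro satellites next to the medium and heavy peaks when the peptide
    contains proline.  Uniform noise peaks are added last.  Returns the
    peak list and the planted-triplet manifest.
    """
    rng = np.random.default_rng(seed)
    z = spec.charge
    mz_l = peptide_mz(spec, LIGHT)
    mz_m = mz_l + channel_mass_shift(spec, MEDIUM) / z
    mz_h = mz_l + channel_mass_shift(spec, HEAVY) / z

    light_int = main_intensity * (1.0 - incorporation)
    pairs = [(mz_m, main_intensity), (mz_h, main_intensity)]
    if light_int > 0:
        pairs.append((mz_l, light_int))
    if conversion_fraction > 0 and spec.n_pro > 0:
        for chan, base_mz in (("medium", mz_m), ("heavy", mz_h)):
            pairs.append(
                (base_mz + PRO_CONVERSION_DELTA[chan] / z,
                 main_intensity * conversion_fraction)
            )
    for _ in range(n_noise_peaks):
        while True:
            mz = rng.uniform(*mz_range)
            if all(abs(mz - p[0]) > 1.5 for p in pairs):
                break
        pairs.append((mz, rng.uniform(0.01, 0.5) * main_intensity))

    truth = [
        TripletMatch(
            light_mz=mz_l, medium_mz=mz_m, heavy_mz=mz_h,
            light_int=max(light_int, 0.0),
            medium_int=main_intensity, heavy_int=main_intensity,
            charge=z,
        )
    ]
    return PeakList.from_pairs(pairs), truth


def simulate_annotations(
    truth: pd.DataFrame,
    n_terms: int = 50,
    planted_terms: int = 2,
    enrichment_strength: float = 8.0,
    term_size_mean: float = 30.0,
    seed: int = 0,
) -> tuple["AnnotationTable", list[str]]:
    """Assign proteins to flat annotation terms, enriching some for the
    regulated set.

    Background terms sample proteins uniformly; each planted term samples
    regulated proteins at ``enrichment_strength`` times the uniform rate.
    Returns the annotation table and the planted term ids.
    """
    from .enrichment import AnnotationTable

    if planted_terms > n_terms:
        raise ValueError("planted_terms must be <= n_terms")
    rng = np.random.default_rng(seed)
    proteins = truth["protein"].to_numpy()
    regulated = truth.loc[
        (truth["regulated_ml"] != 0) | (truth["regulated_hl"] != 0), "protein"
    ].to_numpy()
    n = len(proteins)

    terms: dict[str, set[str]] = {}
    planted: list[str] = []
    for t in range(n_terms):
        size = max(2, int(rng.poisson(term_size_mean)))
        term_id = f"T{t:04d}"
        if t < planted_terms and len(regulated):
            w = np.ones(n)
            w[np.isin(proteins, regulated)] = enrichment_strength
            members = rng.choice(proteins, size=min(size, n), replace=False,
                                 p=w / w.sum())
            planted.append(term_id)
        else:
            members = rng.choice(proteins, size=min(size, n), replace=False)
        terms[term_id] = set(members)
    return AnnotationTable(terms), planted


def simulate_replicate_presence(
    n_total: int = 3721, n_both: int = 1766, seed: int = 0
) -> pd.DataFrame:
    """Minimal evidence where exactly ``n_both`` proteins appear in both
    replicates and the rest in one, for replicate-intersection accounting.
    """
    if not 0 <= n_both <= n_total:
        raise ValueError("need 0 <= n_both <= n_total")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_total):
        prot = f"P{i:05d}"
        reps = ["rep1", "rep2"] if i < n_both else [
            "rep1" if rng.random() < 0.5 else "rep2"
        ]
        for rep in reps:
            base = rng.uniform(1e5, 1e7)
            rows.append(
                {
                    "sequence": "ELVISLIVEK",
                    "protein": prot,
                    "charge": 2,
                    "intensity_l": base,
                    "intensity_m": base * rng.uniform(0.2, 5.0),
                    "intensity_h": base * rng.uniform(0.2, 5.0),
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows)
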