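"""Isotope-label mass arithmetic for the three-plex SILAC K/R scheme.

The scheme pairs unlabeled lysine/arginine ("light", K0R0) with
:sup:`2`\\ H₄-Lys + :sup:`13`\\ C₆-Arg ("medium", K4R6) and
:sup:`13`\\ C₆ :sup:`15`\\ N₂-Lys + :sup:`13`\\ C₆ :sup:`15`\\ N₄-Arg
("heavy", K8R10).  Every tryptic peptide carries at most a handful of
labelable residues, so the three channel forms of a peptide appear as a
triplet of peaks with exactly predictable m/z spacings.  This module
computes those spacings, detects planted/observed triplets in centroided
peak lists, and runs the two standard labeling QC checks: incorporation
efficiency and arginine-to-proline conversion satellites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mass as _pmass

__all__ = [
    "IsotopeLabel",
    "PeptideSpec",
    "PeakList",
    "TripletMatch",
    "LIGHT",
    "MEDIUM",
    "HEAVY",
    "LABEL_SCHEME",
    "PRO_CONVERSION_DELTA",
    "PROTON_MASS",
    "channel_mass_shift",
    "peptide_mz",
    "expected_mz_spacing",
    "detect_triplets",
    "incorporation_efficiency",
    "check_arg_pro_conversion",
]

# Monoisotopic isotope mass differences (Da).
_C13 = 1.0033548378  # 13C - 12C
_N15 = 0.9970348934  # 15N - 14N
_H2 = 1.0062767458   # 2H - 1H

PROTON_MASS = 1.0072765
WATER_MASS = 18.0105646

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


class InvalidSequenceError(ValueError):
    """Sequence contains characters outside the 20 standard amino acids."""


class UndefinedEfficiencyError(ValueError):
    """Incorporation efficiency is undefined when all intensities vanish."""


@dataclass(frozen=True)
class IsotopeLabel:
    """One SILAC channel: mass shift added per Lys and per Arg residue."""

    channel: str
    lys_delta: float
    arg_delta: float

    def __post_init__(self) -> None:
        if self.channel not in ("light", "medium", "heavy"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.lys_delta < 0 or self.arg_delta < 0:
            raise ValueError("label mass deltas must be >= 0")


# K4 = 4 x (2H-1H); K8 = 6 x (13C-12C) + 2 x (15N-14N);
# R6 = 6 x (13C-12C); R10 = 6 x (13C-12C) + 4 x (15N-14N).
LIGHT = IsotopeLabel("light", 0.0, 0.0)
MEDIUM = IsotopeLabel("medium", 4 * _H2, 6 * _C13)
HEAVY = IsotopeLabel("heavy", 6 * _C13 + 2 * _N15, 6 * _C13 + 4 * _N15)

LABEL_SCHEME: dict[str, IsotopeLabel] = {
    "light": LIGHT,
    "medium": MEDIUM,
    "heavy": HEAVY,
}

# Labeled Arg metabolically converted to Pro leaves 13C5 (medium) or
# 13C5 15N1 (heavy) in the proline; satellites appear at these shifts
# per converted Pro residue.
PRO_CONVERSION_DELTA: dict[str, float] = {
    "medium": 5 * _C13,
    "heavy": 5 * _C13 + _N15,
}


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide sequence plus charge; labelable-residue counts derived."""

    sequence: str
    charge: int = 1

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID_AA
        if bad or not self.sequence:
            raise InvalidSequenceError(
                f"invalid residues {sorted(bad)!r} in sequence {self.sequence!r}"
            )
        if self.charge < 1:
            raise ValueError("charge must be >= 1")

    @property
    def n_lys(self) -> int:
        return self.sequence.count("K")

    @property
    def n_arg(self) -> int:
        return self.sequence.count("R")

    @property
    def n_pro(self) -> int:
        return self.sequence.count("P")

    def neutral_mass(self) -> float:
        """Unlabeled monoisotopic neutral mass (standard residue table)."""
        return _pmass.fast_mass(self.sequence)


@dataclass
class PeakList:
    """A centroided spectrum: m/z strictly increasing, intensities >= 0."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")

    def __len__(self) -> int:
        return int(self.mz.size)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[float, float]]) -> "PeakList":
        pairs = sorted(pairs)
        if not pairs:
            return cls(np.empty(0), np.empty(0))
        mz, inten = zip(*pairs)
        return cls(np.array(mz), np.array(inten))


@dataclass(frozen=True)
class TripletMatch:
    """A light/medium/heavy peak triplet at the expected label spacings."""

    light_mz: float
    medium_mz: float
    heavy_mz: float
    light_int: float
    medium_int: float
    heavy_int: float
    charge: int
    mass_error_ppm: tuple[float, float] = (0.0, 0.0)  # (medium, heavy) vs expected


def channel_mass_shift(spec: PeptideSpec, label: IsotopeLabel) -> float:
    """Total label mass shift of ``spec`` in ``label``'s channel (Da).

    The shift is additive over labelable residues:
    ``n_lys * lys_delta + n_arg * arg_delta``; exactly 0 for light.
    """
    return spec.n_lys * label.lys_delta + spec.n_arg * label.arg_delta


def peptide_mz(spec: PeptideSpec, label: IsotopeLabel = LIGHT) -> float:
    """m/z of the labeled peptide: (M + shift + z*proton) / z."""
    m = spec.neutral_mass() + channel_mass_shift(spec, label)
    return (m + spec.charge * PROTON_MASS) / spec.charge


def expected_mz_spacing(
    spec: PeptideSpec, channel_pair: tuple[IsotopeLabel, IsotopeLabel]
) -> float:
    """m/z spacing (Th) between the two channel forms of ``spec``.

    Returns ``(shift(heavier) - shift(lighter)) / charge``; 0 for an
    identical pair.
    """
    a, b = channel_pair
    sa, sb = channel_mass_shift(spec, a), channel_mass_shift(spec, b)
    return abs(sb - sa) / spec.charge


def _nearest_within(
    mz: np.ndarray, target: float, tol_ppm: float
) -> tuple[int, float] | None:
    """Index and ppm error of the peak nearest ``target`` within tolerance."""
    if mz.size == 0:
        return None
    i = int(np.searchsorted(mz, target))
    best = None
    for j in (i - 1, i):
        if 0 <= j < mz.size:
            err = abs(mz[j] - target) / target * 1e6
            if err <= tol_ppm and (best is None or err < best[1]):
                best = (j, err)
    return best


def detect_triplets(
    peaks: PeakList, spec: PeptideSpec, tolerance_ppm: float = 10.0
) -> list[TripletMatch]:
    """Find L/M/H triplets in ``peaks`` at the spacings expected for ``spec``.

    Every peak is tried as a light candidate; medium and heavy partners
    must lie within ``tolerance_ppm`` of the expected spacing.  Overlapping
    candidates are resolved greedily by smallest combined ppm error, each
    peak used at most once.  Results are sorted by light m/z.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be > 0")
    if len(peaks) == 0:
        return []
    d_m = expected_mz_spacing(spec, (LIGHT, MEDIUM))
    d_h = expected_mz_spacing(spec, (LIGHT, HEAVY))
    if d_m == 0 or d_h == 0:
        return []  # no labelable residues: channels are degenerate

    mz, inten = peaks.mz, peaks.intensity
    candidates = []
    for i in range(mz.size):
        hit_m = _nearest_within(mz, mz[i] + d_m, tolerance_ppm)
        hit_h = _nearest_within(mz, mz[i] + d_h, tolerance_ppm)
        if hit_m is None or hit_h is None:
            continue
        (jm, em), (jh, eh) = hit_m, hit_h
        if len({i, jm, jh}) < 3:
            continue
        candidates.append((em + eh, i, jm, jh, em, eh))

    candidates.sort(key=lambda c: (c[0], c[1]))
    used: set[int] = set()
    out: list[TripletMatch] = []
    for _, i, jm, jh, em, eh in candidates:
        if used & {i, jm, jh}:
            continue
        used.update({i, jm, jh})
        out.append(
            TripletMatch(
                light_mz=float(mz[i]),
                medium_mz=float(mz[jm]),
                heavy_mz=float(mz[jh]),
                light_int=float(inten[i]),
                medium_int=float(inten[jm]),
                heavy_int=float(inten[jh]),
                charge=spec.charge,
                mass_error_ppm=(em, eh),
            )
        )
    out.sort(key=lambda t: t.light_mz)
    return out


def incorporation_efficiency(light_int: float, labeled_int: float) -> float:
    """Fraction of signal carrying the label: labeled / (light + labeled)."""
    if light_int < 0 or labeled_int < 0:
        raise ValueError("intensities must be >= 0")
    total = light_int + labeled_int
    if total == 0:
        raise UndefinedEfficiencyError("both intensities are zero")
    return labeled_int / total


def check_arg_pro_conversion(
    peaks: PeakList,
    spec: PeptideSpec,
    channel: str,
    tolerance_ppm: float = 10.0,
    satellite_threshold: float = 0.05,
    main_mz: float | None = None,
) -> tuple[bool, float]:
    """Flag Arg→Pro conversion satellites next to the channel's main peak.

    Satellites are searched at ``+k * pro_delta(channel) / charge`` for
    ``k = 1..n_pro`` relative to the main channel peak (the most intense
    peak unless ``main_mz`` is given).  Returns ``(flag, fraction)`` where
    ``fraction`` is the largest satellite intensity relative to the main
    peak and the flag is set when it exceeds ``satellite_threshold``.
    A peptide without proline is vacuously clean.
    """
    if channel not in ("medium", "heavy"):
        raise ValueError("conversion satellites arise in medium/heavy channels only")
    if spec.n_pro == 0 or len(peaks) == 0:
        return False, 0.0
    delta = PRO_CONVERSION_DELTA[channel] / spec.charge
    if main_mz is None:
        i_main = int(np.argmax(peaks.intensity))
    else:
        hit = _nearest_within(peaks.mz, main_mz, tolerance_ppm)
        if hit is None:
            return False, 0.0
        i_main = hit[0]
    main_int = peaks.intensity[i_main]
    if main_int == 0:
        return False, 0.0
    frac = 0.0
    for k in range(1, spec.n_pro + 1):
        hit = _nearest_within(peaks.mz, peaks.mz[i_main] + k * delta, tolerance_ppm)
        if hit is not None and hit[0] != i_main:
            frac = max(frac, float(peaks.intensity[hit[0]] / main_int))
    return frac > satellite_threshold, frac
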