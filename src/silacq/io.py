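"""Readers and writers for the package's tab-separated dialects and peak lists.

Canonical evidence dialect: UTF-8, header ``sequence, protein, charge,
intensity_l, intensity_m, intensity_h, replicate``; empty string = missing.
MaxQuant-style headers are accepted through a column mapping.  All writers
emit UTF-8, LF line endings and a fixed column order so outputs hash
stably.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .quantify import EVIDENCE_COLUMNS
from .silac_labels import PeakList

logger = logging.getLogger("silacq")

__all__ = [
    "MAXQUANT_MAPPING",
    "SchemaError",
    "read_evidence",
    "write_evidence",
    "write_records",
    "read_annotations",
    "read_peaklist",
    "write_peaklist",
    "load_run_config",
]

MAXQUANT_MAPPING = {
    "Sequence": "sequence",
    "Proteins": "protein",
    "Charge": "charge",
    "Intensity L": "intensity_l",
    "Intensity M": "intensity_m",
    "Intensity H": "intensity_h",
    "Experiment": "replicate",
}


class SchemaError(ValueError):
    """Required columns are missing from an input table."""


def read_evidence(
    path: str | Path,
    mapping: dict[str, str] | None = None,
    on_bad_rows: str = "skip",
) -> pd.DataFrame:
    """Read a peptide-evidence TSV into the canonical column set.

    ``mapping`` renames foreign headers (e.g. :data:`MAXQUANT_MAPPING`).
    Rows with non-numeric intensities are skipped with a logged warning
    (``on_bad_rows="skip"``) or raise (``"abort"``).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if mapping:
        df = df.rename(columns=mapping)
    missing = [c for c in EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {', '.join(missing)}")
    df = df[EVIDENCE_COLUMNS].copy()

    bad_lines: list[int] = []
    for col in ("intensity_l", "intensity_m", "intensity_h"):
        raw = df[col].replace("", np.nan)
        num = pd.to_numeric(raw, errors="coerce")
        bad = raw.notna() & num.isna()
        bad_lines.extend((df.index[bad] + 2).tolist())  # +2: header + 1-based
        df[col] = num
    df["charge"] = pd.to_numeric(df["charge"], errors="coerce").astype("Int64")

    if bad_lines:
        msg = f"{len(set(bad_lines))} malformed rows at lines {sorted(set(bad_lines))[:10]}"
        if on_bad_rows == "abort":
            raise ValueError(msg)
        logger.warning("%s: %s (skipped)", path, msg)
        drop = df.index[np.isin(df.index + 2, bad_lines)]
        df = df.drop(index=drop)
    return df.reset_index(drop=True)


def _write_tsv(df: pd.DataFrame, path: str | Path, float_format=None) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n",
              float_format=float_format, encoding="utf-8")


def write_evidence(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(df[EVIDENCE_COLUMNS], path)


def write_records(
    df: pd.DataFrame, path: str | Path, table_compat: bool = False
) -> None:
    """Write result records; ``table_compat`` formats floats to 2 d.p."""
    _write_tsv(df, path, float_format="%.2f" if table_compat else None)


def load_run_config(path: str | Path | None, **overrides):
    """Build a :class:`~silacq.workflow.RunConfig` from a TOML file.

    Keys in a ``[pipeline]`` table (or at top level) map directly onto
    RunConfig fields; keyword overrides (e.g. CLI flags) win over the
    file.  ``path=None`` returns a default config with overrides applied.
    """
    import tomllib

    from .workflow import RunConfig

    values: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        values.update(data.get("pipeline", data))
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(values) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {', '.join(sorted(unknown))}")
    if "confidence_levels" in values:
        values["confidence_levels"] = tuple(values["confidence_levels"])
    return RunConfig(**values)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read an annotation TSV (accession, term_id[, term_label, namespace])."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if "accession" not in cols or "term_id" not in cols:
        if len(cols) >= 2 and not {"accession", "term_id"} & set(cols):
            # headerless two/four-column minimal form
            df = pd.read_csv(
                path, sep="\t", dtype=str, header=None, keep_default_na=False
            )
            names = ["accession", "term_id", "term_label", "namespace"]
            df.columns = names[: df.shape[1]]
        else:
            raise SchemaError("annotation table needs accession and term_id columns")
    return df


def read_peaklist(path: str | Path, fmt: str = "auto") -> PeakList:
    """Read a centroided peak list from two-column text or MGF."""
    path = Path(path)
    if fmt == "auto":
        fmt = "mgf" if path.suffix.lower() == ".mgf" else "text"
    if fmt == "mgf":
        with _mgf.MGF(str(path)) as reader:
            spectrum = next(iter(reader))
        return PeakList(spectrum["m/z array"], spectrum["intensity array"])
    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        return PeakList(np.empty(0), np.empty(0))
    order = np.argsort(data[:, 0])
    return PeakList(data[order, 0], data[order, 1])


def write_peaklist(
    peaks: PeakList,
    path: str | Path,
    fmt: str = "auto",
    pepmass: float | None = None,
    charge: int | None = None,
    title: str = "spectrum",
) -> None:
    """Write a peak list as two-column text or an MGF block."""
    path = Path(path)
    if fmt == "auto":
        fmt = "mgf" if path.suffix.lower() == ".mgf" else "text"
    if fmt == "mgf":
        params: dict = {"title": title}
        if pepmass is not None:
            params["pepmass"] = pepmass
        if charge is not None:
            params["charge"] = charge
        spectra = [
            {
                "params": params,
                "m/z array": peaks.mz,
                "intensity array": peaks.intensity,
            }
        ]
        _mgf.write(spectra, str(path), file_mode="w")
    else:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for mz, inten in zip(peaks.mz, peaks.intensity):
                fh.write(f"{float(mz)!r} {float(inten)!r}\n")
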