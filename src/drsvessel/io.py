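"""Spectral CSV readers/writers with validation and provenance metadata.

CSV is the sole spectral interchange format (RFC-4180, dot decimal).  Files
written by this package carry provenance as leading ``#``-comment lines
(config hash, seed, tool version); readers skip them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .adding_doubling import MeasuredPair

__all__ = [
    "SpectrumTable",
    "SpectrumFormatError",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "config_hash",
]

try:
    _VERSION = version("drsvessel")
except PackageNotFoundError:  # pragma: no cover - editable-install edge
    _VERSION = "unknown"

_FRACTION_COLUMNS = {"m_r", "m_t", "r", "t", "r_diffuse", "r_specular", "reflectance", "transmittance"}


class SpectrumFormatError(ValueError):
    """A spectral table violates the format contract."""


@dataclass
class SpectrumTable:
    """Validated spectral table plus provenance metadata."""

    data: pd.DataFrame
    metadata: dict

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return self.data["wavelength_nm"].to_numpy()

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def measured_pairs(self) -> list[MeasuredPair]:
        if "m_r" not in self.data or "m_t" not in self.data:
            raise SpectrumFormatError(
                f"need columns M_R and M_T, found {list(self.data.columns)}"
            )
        return [
            MeasuredPair(float(r), float(t), float(w))
            for w, r, t in zip(
                self.data["wavelength_nm"], self.data["m_r"], self.data["m_t"]
            )
        ]


def config_hash(cfg: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(cfg, sort_keys=True, separators=(",", ":")).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def read_spectrum_csv(path) -> SpectrumTable:
    """Read and validate a spectral CSV.

    Requirements: UTF-8, a header row, a wavelength column (``wavelength_nm``,
    case-insensitive), strictly increasing unique wavelengths, and R/T-like
    columns parseable as finite numbers in [0, 1].  Violations raise
    :class:`SpectrumFormatError` naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise SpectrumFormatError(f"no such file: {path}")
    metadata: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            body_start += 1
            if "=" in line:
                key, _, val = line.lstrip("# ").rstrip("\n").partition("=")
                metadata[key.strip()] = val.strip()
        else:
            break
    if body_start >= len(lines):
        raise SpectrumFormatError(f"{path}: no header row found")
    try:
        df = pd.read_csv(path, skiprows=body_start)
    except Exception as exc:
        raise SpectrumFormatError(f"{path}: cannot parse CSV: {exc}") from exc
    df.columns = [c.strip().lower() for c in df.columns]
    if "wavelength_nm" not in df.columns:
        raise SpectrumFormatError(
            f"{path}: missing wavelength_nm column (found {list(df.columns)})"
        )
    wl = df["wavelength_nm"]
    if wl.isna().any() or not np.isfinite(wl.to_numpy(dtype=float)).all():
        row = int(wl.index[wl.isna() | ~np.isfinite(wl.astype(float))][0]) + 2 + body_start
        raise SpectrumFormatError(f"{path}: non-finite wavelength at line {row}")
    dup = wl.duplicated()
    if dup.any():
        row = int(wl.index[dup][0]) + 2 + body_start
        raise SpectrumFormatError(
            f"{path}: duplicate wavelength {wl[dup].iloc[0]} at line {row}"
        )
    if not wl.is_monotonic_increasing:
        raise SpectrumFormatError(f"{path}: wavelengths must be strictly increasing")
    for col in df.columns:
        if col == "wavelength_nm":
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals)
        if bad.any():
            row = int(df.index[bad][0]) + 2 + body_start
            raise SpectrumFormatError(
                f"{path}: non-numeric value in column {col!r} at line {row}"
            )
        if col in _FRACTION_COLUMNS:
            out = (vals < 0) | (vals > 1)
            if out.any():
                row = int(df.index[out][0]) + 2 + body_start
                raise SpectrumFormatError(
                    f"{path}: column {col!r} value {vals[out].iloc[0]} outside "
                    f"[0, 1] at line {row}"
                )
        df[col] = vals
    return SpectrumTable(df, metadata)


def write_spectrum_csv(path, wavelengths_nm, columns: dict, config=None, seed=None) -> None:
    """Write a spectral CSV with provenance comment lines."""
    df = pd.DataFrame({"wavelength_nm": np.asarray(wavelengths_nm, dtype=float)})
    for name, vals in columns.items():
        df[name] = np.asarray(vals, dtype=float)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# tool_version = {_VERSION}\n")
        if config is not None:
            fh.write(f"# config_hash = {config_hash(config)}\n")
        if seed is not None:
            fh.write(f"# seed = {seed}\n")
        df.to_csv(fh, index=False, lineterminator="\n")
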