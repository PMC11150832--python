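"""Readers, writers and run configuration.

MGF peak lists are read through pyteomics (PEPMASS, RTINSECONDS, CHARGE and
TITLE honored); writing is done with a fixed deterministic layout — peaks
sorted by m/z, four decimal places — so repeated runs of the same
simulation are byte-identical.  Tables are plain delimited text with a
mandatory header row, handled by pandas.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml
from pyteomics import mgf as _pyteomics_mgf

from .annotate import Peak, Spectrum
from .quantify import DEFAULT_ADDUCT_POLICY

__all__ = ["RunConfig", "read_mgf", "write_mgf", "read_table", "write_table"]

logger = logging.getLogger("ethercdl")


@dataclass
class RunConfig:
    """Pipeline settings; defaults are the anchored values (3 ppm MS¹,
    5 ppm MS², saturated C14–C17 chains)."""

    ms1_tol_ppm: float = 3.0
    ms2_tol_ppm: float = 5.0
    chain_lengths: list = field(default_factory=lambda: [14, 15, 16, 17])
    head_groups: list = field(default_factory=lambda: [
        "PE", "PG", "CDL", "MLCL", "DLCL", "LPE", "LPG"])
    unsaturations: list = field(default_factory=lambda: [0])
    adduct_policy: dict = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_ADDUCT_POLICY.items()}
    )
    quant_policy: str = "sum"
    scenario: str = "mix"
    mix_weights: list = field(default_factory=lambda: [0.5, 0.5])
    seed: int = 0
    output_dir: str = "."

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file into :class:`Spectrum` objects.

    A block without PEPMASS yields a spectrum with ``precursor_mz=None``
    (unusable for MS² annotation, flagged by a warning).  An empty file
    yields an empty list with a warning; malformed blocks raise with the
    offending entry identified.
    """
    path = Path(path)
    spectra: list[Spectrum] = []
    try:
        with _pyteomics_mgf.MGF(str(path), convert_arrays=1) as reader:
            for i, entry in enumerate(reader):
                params = entry.get("params", {})
                pep = params.get("pepmass")
                precursor = float(pep[0]) if pep and pep[0] else None
                rt = params.get("rtinseconds")
                peaks = tuple(
                    Peak(float(mz), float(inten))
                    for mz, inten in zip(
                        entry["m/z array"], entry["intensity array"]
                    )
                )
                if precursor is None:
                    logger.warning(
                        "MGF block %d (%s) has no PEPMASS; unusable for MS2 "
                        "annotation", i, params.get("title", "untitled"),
                    )
                spectra.append(Spectrum(
                    peaks=peaks,
                    precursor_mz=precursor,
                    retention_time=float(rt) / 60.0 if rt is not None else None,
                    level=2,
                    title=str(params.get("title", f"spectrum_{i}")),
                ))
    except (ValueError, KeyError) as exc:
        raise ValueError(
            f"malformed MGF block in {path} (after {len(spectra)} valid "
            f"spectra): {exc}"
        ) from exc
    if not spectra:
        logger.warning("no BEGIN IONS blocks found in %s", path)
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra with a fixed deterministic format (m/z to 4 decimals)."""
    path = Path(path)
    lines: list[str] = []
    for i, sp in enumerate(spectra):
        lines.append("BEGIN IONS")
        lines.append(f"TITLE={sp.title or f'spectrum_{i}'}")
        if sp.precursor_mz is not None:
            lines.append(f"PEPMASS={sp.precursor_mz:.4f}")
        if sp.retention_time is not None:
            lines.append(f"RTINSECONDS={sp.retention_time * 60.0:.2f}")
        lines.append("CHARGE=1+")
        for p in sp.peaks:
            lines.append(f"{p.mz:.4f} {p.intensity:.4f}")
        lines.append("END IONS")
        lines.append("")
    path.write_text("\n".join(lines))


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a comma- or tab-separated table (header row mandatory)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.columns.str.match(r"^Unnamed").any() or df.columns.str.match(r"^\d+$").all():
        raise ValueError(f"{path}: table must carry a header row")
    return df


def write_table(df: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> None:
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df.to_csv(path, sep=sep, index=False, float_format=float_format)
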