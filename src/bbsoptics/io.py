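"""CSV / JSON dialects shared by the CLI and the analysis drivers.

Formats are deliberately minimal plain-text tables:

* spectrum:  ``wavelength_nm,value``
* titration: ``protein_nM,time_h,fluorescence`` (long format; ``time_h``
  may be omitted for single equilibrium scans)
* melt:      ``temp_C,A390,A376`` or ``temp_C,ratio``
* slab R/T:  ``wavelength_nm,R,T``
"""

from __future__ import annotations

import dataclasses
import enum
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .adding_doubling import RTMeasurement
from .binding import TitrationSeries
from .spectra import Spectrum, SpectrumKind
from .unfolding import MeltCurve

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_titration_csv",
    "read_melt_csv",
    "read_rt_csv",
    "to_jsonable",
    "write_json",
]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_spectrum_csv(path, kind: SpectrumKind | str, label: str = "") -> Spectrum:
    df = pd.read_csv(path)
    _require_columns(df, ["wavelength_nm", "value"], path)
    df = df.sort_values("wavelength_nm")
    return Spectrum(
        df["wavelength_nm"].to_numpy(float),
        df["value"].to_numpy(float),
        SpectrumKind(kind),
        label,
    )


def write_spectrum_csv(path, spectrum: Spectrum) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "value": spectrum.values}
    ).to_csv(path, index=False)


def read_titration_csv(path, ligand_total_nM: float) -> TitrationSeries:
    """Long-format titration table -> TitrationSeries (molar units)."""
    df = pd.read_csv(path)
    _require_columns(df, ["protein_nM", "fluorescence"], path)
    if "time_h" in df.columns and df["time_h"].nunique() > 1:
        pivot = df.pivot_table(
            index="protein_nM", columns="time_h", values="fluorescence"
        ).sort_index()
        return TitrationSeries(
            pivot.index.to_numpy(float) * 1e-9,
            ligand_total_nM * 1e-9,
            pivot.to_numpy(float),
            timepoints=pivot.columns.to_numpy(float),
        )
    df = df.sort_values("protein_nM")
    return TitrationSeries(
        df["protein_nM"].to_numpy(float) * 1e-9,
        ligand_total_nM * 1e-9,
        df["fluorescence"].to_numpy(float),
    )


def read_melt_csv(path) -> MeltCurve:
    df = pd.read_csv(path)
    if "ratio" in df.columns:
        _require_columns(df, ["temp_C", "ratio"], path)
        ratio = df["ratio"].to_numpy(float)
    else:
        _require_columns(df, ["temp_C", "A390", "A376"], path)
        a376 = df["A376"].to_numpy(float)
        if np.any(a376 <= 0):
            raise ValueError(f"{path}: A376 must be > 0 to form the ratio")
        ratio = df["A390"].to_numpy(float) / a376
    df = df.assign(_ratio=ratio).sort_values("temp_C")
    return MeltCurve(df["temp_C"].to_numpy(float), df["_ratio"].to_numpy(float))


def read_rt_csv(path) -> list[RTMeasurement]:
    df = pd.read_csv(path)
    _require_columns(df, ["wavelength_nm", "R", "T"], path)
    return [
        RTMeasurement(float(r), float(t), float(w))
        for w, r, t in df[["wavelength_nm", "R", "T"]].itertuples(index=False)
    ]


def to_jsonable(obj: Any) -> Any:
    """Recursively convert results (dataclasses, enums, arrays) to JSON."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: to_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_json(path, payload: Any) -> None:
    Path(path).write_text(
        json.dumps(to_jsonable(payload), indent=2, sort_keys=True) + "\n"
    )
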