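"""On-disk containers for cubes, spectra and pipeline configuration.

A cube container is a directory holding:

* ``axis.csv`` — single-column CSV of wavenumbers (cm^-1);
* ``data.npy`` (portable binary) or ``data_long.csv`` (long form
  ``row,col,channel,intensity``) — the intensity array;
* ``metadata.json`` — pixel size, surface row, shape and provenance.

Component spectra travel as a wide CSV whose first column is
``wavenumber_cm-1`` and remaining columns are named components.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .mcr import FINGERPRINT_RANGE
from .phantom import DEFAULT_SECTIONS, TISSUE_MODELS
from .quantify import WATER_BAND
from .spectral import HyperspectralCube, WavenumberAxis

__all__ = [
    "read_cube",
    "write_cube",
    "read_spectra_csv",
    "write_spectra_csv",
    "PipelineConfig",
]

_AXIS_FILE = "axis.csv"
_META_FILE = "metadata.json"
_NPY_FILE = "data.npy"
_LONG_FILE = "data_long.csv"


def write_cube(cube: HyperspectralCube, path: str | Path,
               fmt: Literal["npy", "csv"] = "npy",
               provenance: dict | None = None) -> Path:
    """Write a cube container directory; returns its path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savetxt(path / _AXIS_FILE, cube.axis.values, fmt="%.10g",
               header="wavenumber_cm-1", comments="")
    meta = {
        "pixel_size_um": cube.pixel_size_um,
        "surface_row": cube.surface_row,
        "shape": list(cube.data.shape),
        "format": fmt,
        "provenance": provenance or {},
    }
    (path / _META_FILE).write_text(json.dumps(meta, indent=2, sort_keys=True))
    if fmt == "npy":
        np.save(path / _NPY_FILE, cube.data)
    elif fmt == "csv":
        rows, cols, chans = cube.data.shape
        r, c, ch = np.meshgrid(np.arange(rows), np.arange(cols),
                               np.arange(chans), indexing="ij")
        df = pd.DataFrame({
            "row": r.ravel(), "col": c.ravel(), "channel": ch.ravel(),
            "intensity": cube.data.ravel(),
        })
        df.to_csv(path / _LONG_FILE, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown cube format {fmt!r}")
    return path


def read_cube(path: str | Path) -> HyperspectralCube:
    """Read a cube container written by :func:`write_cube`."""
    path = Path(path)
    meta = json.loads((path / _META_FILE).read_text())
    for key in ("pixel_size_um", "surface_row", "shape", "format"):
        if key not in meta:
            raise ValueError(f"metadata is missing required field {key!r}")
    axis_vals = np.loadtxt(path / _AXIS_FILE, skiprows=1, ndmin=1)
    if axis_vals.size >= 2 and np.any(np.diff(axis_vals) <= 0):
        raise ValueError("axis.csv violates monotonicity: wavenumbers must "
                         "be strictly increasing")
    axis = WavenumberAxis(axis_vals)
    shape = tuple(meta["shape"])
    if shape[2] != len(axis):
        raise ValueError(
            f"metadata field 'shape' ({shape}) disagrees with axis length "
            f"{len(axis)}"
        )
    if meta["format"] == "npy":
        data = np.load(path / _NPY_FILE)
        if data.shape != shape:
            raise ValueError(
                f"metadata field 'shape' ({shape}) disagrees with stored "
                f"array {data.shape}"
            )
    else:
        df = pd.read_csv(path / _LONG_FILE)
        expected = shape[0] * shape[1] * shape[2]
        if len(df) != expected:
            present = set(zip(df["row"], df["col"]))
            for r in range(shape[0]):
                for c in range(shape[1]):
                    if (r, c) not in present:
                        raise ValueError(f"long-form CSV is missing pixel ({r}, {c})")
            raise ValueError(
                f"long-form CSV has {len(df)} entries, expected {expected}"
            )
        data = np.zeros(shape)
        data[df["row"], df["col"], df["channel"]] = df["intensity"]
    return HyperspectralCube(axis, data, meta["pixel_size_um"], meta["surface_row"])


def write_spectra_csv(spectra, path: str | Path) -> Path:
    """Write ComponentSpectra as a wide CSV (wavenumber + one column each)."""
    path = Path(path)
    df = pd.DataFrame({"wavenumber_cm-1": spectra.axis.values})
    for name, row in zip(spectra.names, spectra.spectra):
        df[name] = row
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_spectra_csv(path: str | Path):
    """Read a wide spectral CSV into ComponentSpectra."""
    from .mcr import ComponentSpectra

    path = Path(path)
    header = path.read_text().splitlines()[0].split(",")
    names = header[1:]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate component names in {path.name}: {dupes}")
    try:
        df = pd.read_csv(path, dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric value in {path.name}: {exc}") from exc
    axis = WavenumberAxis(df.iloc[:, 0].to_numpy())
    spectra = df.iloc[:, 1:].to_numpy().T
    return ComponentSpectra(spectra, tuple(names), axis)


class PipelineConfig(BaseModel):
    """Validated configuration of one full pipeline run.

    Unknown keys are rejected; the JSON schema is available through
    ``PipelineConfig.model_json_schema()``.
    """

    model_config = ConfigDict(extra="forbid")

    tissue_model: Literal["native", "engineered", "digested"] = "native"
    # phantom geometry and physics (None -> reduced defaults per model)
    n_rows: int | None = Field(None, ge=1)
    n_cols: int | None = Field(None, ge=1)
    pixel_size_um: float | None = Field(None, gt=0)
    axis_lo: float = Field(350.0, gt=0)
    axis_hi: float = 3600.0
    axis_step: float = Field(5.0, gt=0)
    baseline_amplitude: float = Field(20.0, ge=0)
    noise_frac: float = Field(0.02, ge=0)
    noise_floor: float = Field(0.0, ge=0)
    lateral_cv: float | None = Field(None, ge=0)  # None -> tissue-model default
    include_cells: bool = False
    # preprocessing
    baseline_method: Literal["rolling_shape", "asymmetric_ls"] = "rolling_shape"
    baseline_window_points: int = Field(1000, ge=3)
    # unmixing
    fit_lo: float = FINGERPRINT_RANGE[0]
    fit_hi: float = FINGERPRINT_RANGE[1]
    k: int = Field(4, ge=1)
    init: Literal["reference", "purest_pixel", "seeded_random"] = "reference"
    merge_threshold: float = Field(0.9, gt=0, le=1)
    max_iter: int = Field(200, ge=1)
    tol: float = Field(1e-6, gt=0)
    # quantification
    water_band_lo: float = WATER_BAND[0]
    water_band_hi: float = WATER_BAND[1]
    # assay emulation
    n_sections: int | None = Field(None, ge=2)
    assay_noise_cv: float = Field(0.08, ge=0)
    # randomness
    seed: int = 0

    @model_validator(mode="after")
    def _check_ranges(self) -> "PipelineConfig":
        if self.axis_lo >= self.axis_hi:
            raise ValueError("axis_lo must be below axis_hi")
        if self.fit_lo >= self.fit_hi:
            raise ValueError("fit_lo must be below fit_hi")
        if self.water_band_lo >= self.water_band_hi:
            raise ValueError("water_band_lo must be below water_band_hi")
        return self

    def sections(self) -> int:
        return self.n_sections or DEFAULT_SECTIONS[self.tissue_model]

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate_json(Path(path).read_text())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))
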