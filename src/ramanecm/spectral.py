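"""Shared domain types and elementary spectral-axis operations.

Conventions used throughout the package:

* a hyperspectral cube is ``(depth rows, lateral columns, wavenumber
  channels)``; row 0 is the tissue surface and the depth of row ``r`` is
  ``(r + 0.5) * pixel_size_um / 1000`` mm (pixel centres);
* wavenumber intervals are closed (spectra are sampled points), pixel
  index ranges are half-open (pixel blocks tile without overlap).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "WavenumberAxis",
    "Spectrum",
    "HyperspectralCube",
    "ROI",
    "crop_range",
    "band_integral",
    "roi_to_pixels",
]


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing Raman-shift axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("axis needs at least one wavenumber point")
        if not np.all(np.isfinite(values)):
            raise ValueError("axis contains non-finite wavenumbers")
        if np.any(values <= 0):
            raise ValueError("wavenumbers must be positive")
        if np.any(np.diff(values) <= 0):
            raise ValueError("axis must be strictly increasing")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def spacing(self) -> float:
        """Mean channel spacing in cm^-1 (axes may be non-uniform)."""
        if len(self) < 2:
            raise ValueError("spacing undefined for a single-channel axis")
        return float(np.mean(np.diff(self.values)))

    def slice_for(self, lo: float, hi: float) -> slice:
        """Channel slice for the closed wavenumber interval [lo, hi]."""
        if lo >= hi:
            raise ValueError(f"invalid band: lo={lo} must be < hi={hi}")
        mask = (self.values >= lo) & (self.values <= hi)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(
                f"band [{lo}, {hi}] cm^-1 contains no channels of axis "
                f"[{self.values[0]}, {self.values[-1]}]"
            )
        return slice(int(idx[0]), int(idx[-1]) + 1)


@dataclass(frozen=True)
class Spectrum:
    """A single Raman spectrum: one row of the pixel matrix D."""

    axis: WavenumberAxis
    intensities: np.ndarray

    def __post_init__(self) -> None:
        intens = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", intens)
        if intens.shape != (len(self.axis),):
            raise ValueError(
                f"intensities shape {intens.shape} does not match axis "
                f"length {len(self.axis)}"
            )
        if not np.all(np.isfinite(intens)):
            raise ValueError("intensities contain NaN/Inf")


@dataclass(frozen=True)
class HyperspectralCube:
    """Depth x lateral x wavenumber intensity cube.

    ``data[r, c, :]`` is the spectrum of the pixel in depth row ``r``
    (row 0 at the tissue surface) and lateral column ``c``. Flattening
    rows-then-columns yields the pixel matrix D.
    """

    axis: WavenumberAxis
    data: np.ndarray
    pixel_size_um: float = 10.0
    surface_row: int = 0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 3:
            raise ValueError("cube data must be 3-D (rows, cols, channels)")
        if data.shape[2] != len(self.axis):
            raise ValueError(
                f"cube has {data.shape[2]} channels but axis has "
                f"{len(self.axis)}"
            )
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.data.shape[0] * self.data.shape[1]

    def depths_mm(self) -> np.ndarray:
        """Pixel-centre depth of every row, in mm from the surface."""
        rows = np.arange(self.n_rows) - self.surface_row
        return (rows + 0.5) * self.pixel_size_um / 1000.0

    def to_matrix(self) -> np.ndarray:
        """Pixel matrix D (n_pixels x n_channels), rows-then-columns."""
        return self.data.reshape(self.n_pixels, len(self.axis))

    def pixel(self, row: int, col: int) -> Spectrum:
        return Spectrum(self.axis, self.data[row, col])

    def with_data(self, data: np.ndarray, axis: WavenumberAxis | None = None):
        return replace(self, data=data, axis=axis if axis is not None else self.axis)


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest in micrometres from the cube origin."""

    top_um: float
    left_um: float
    height_um: float
    width_um: float

    def __post_init__(self) -> None:
        if self.height_um <= 0 or self.width_um <= 0:
            raise ValueError("ROI height and width must be positive")
        if self.top_um < 0 or self.left_um < 0:
            raise ValueError("ROI origin must be non-negative")


def crop_range(cube: HyperspectralCube, lo: float, hi: float) -> HyperspectralCube:
    """Restrict a cube to channels with wavenumber in the closed [lo, hi]."""
    sl = cube.axis.slice_for(lo, hi)
    return cube.with_data(cube.data[:, :, sl], WavenumberAxis(cube.axis.values[sl]))


def band_integral(spectrum: Spectrum, lo: float, hi: float) -> float:
    """Trapezoidal integral of intensity over the band [lo, hi] (a.u. * cm^-1)."""
    sl = spectrum.axis.slice_for(lo, hi)
    if sl.stop - sl.start < 2:
        raise ValueError(f"band [{lo}, {hi}] covers fewer than two channels")
    return float(
        np.trapezoid(spectrum.intensities[sl], spectrum.axis.values[sl])
    )


def roi_to_pixels(roi: ROI, cube: HyperspectralCube) -> tuple[slice, slice]:
    """Convert a micrometre ROI to half-open pixel index ranges.

    Returns ``(rows, cols)`` slices with ``r0 = floor(top / px)`` and
    ``r1 = r0 + round(height / px)`` (same laterally), so a 250x250 um
    ROI at 10 um resolution is exactly a 25 x 25 pixel block.
    """
    px = cube.pixel_size_um
    r0 = int(np.floor(roi.top_um / px))
    c0 = int(np.floor(roi.left_um / px))
    r1 = r0 + int(round(roi.height_um / px))
    c1 = c0 + int(round(roi.width_um / px))
    if r1 <= r0 or c1 <= c0:
        raise ValueError("ROI maps to an empty pixel block")
    if r1 > cube.n_rows or c1 > cube.n_cols:
        raise ValueError(
            f"ROI pixel block [{r0}:{r1}, {c0}:{c1}] exceeds cube shape "
            f"({cube.n_rows}, {cube.n_cols})"
        )
    return slice(r0, r1), slice(c0, c1)
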