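"""Quantitative outputs: depth profiles, normalization, water mapping
and localized heterogeneity.

Depth profiles laterally average each concentration map and are
expressed against pixel-centre depth from the tissue surface. Three
normalization schemes mirror how sectioned-assay comparisons are
anchored: to the peak-region value at a stated depth (constituents that
increase with depth), to the topmost/surface value (constituents that
decrease), or to the profile mean (uniform constituents). Absolute
% wet weight profiles are obtained by rescaling a relative profile so
its depth average matches the bulk assay mean.

Water is quantified univariately in the high-wavenumber region: the
fingerprint range carries almost no water signal, so the broad OH
stretching band near 3400 cm^-1 (integrated over 3100-3600 cm^-1 by
default) maps tissue hydration per pixel.

Localized heterogeneity is the coefficient of variation of pixel
concentrations within a region of interest (250 x 250 um in the source
protocol), reported in percent (100 * sd / mean, sample sd).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .mcr import ConcentrationMaps
from .preprocess import BaselineParams, subtract_baseline
from .spectral import ROI, HyperspectralCube, crop_range, roi_to_pixels

__all__ = [
    "DepthProfile",
    "HeterogeneityScore",
    "WATER_BAND",
    "lateral_average",
    "normalize_profile",
    "to_absolute",
    "water_map_hw",
    "relative_decrease",
    "local_cov",
]

logger = logging.getLogger(__name__)

#: default OH-stretch integration band (cm^-1)
WATER_BAND = (3100.0, 3600.0)


@dataclass(frozen=True)
class DepthProfile:
    """Laterally averaged concentration vs depth from the surface."""

    depths_mm: np.ndarray
    values: np.ndarray
    sd: np.ndarray | None = None
    constituent: str = ""
    normalization: dict | None = None  # {scheme, anchor_depth_mm, anchor_value}

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths_mm, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "depths_mm", depths)
        object.__setattr__(self, "values", values)
        if depths.shape != values.shape or depths.ndim != 1:
            raise ValueError("depths and values must be 1-D of equal length")
        if depths.size and np.any(np.diff(depths) <= 0):
            raise ValueError("depths must be strictly increasing")
        if self.sd is not None:
            sd = np.asarray(self.sd, dtype=float)
            object.__setattr__(self, "sd", sd)
            if sd.shape != values.shape:
                raise ValueError("sd must match values in length")

    def interpolate(self, depths_mm: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(depths_mm, dtype=float),
                         self.depths_mm, self.values)


@dataclass(frozen=True)
class HeterogeneityScore:
    roi: ROI
    constituent: str
    cov: float  # percent: 100 * sd / mean

    def __post_init__(self) -> None:
        if self.cov < 0:
            raise ValueError("coefficient of variation cannot be negative")


def lateral_average(concentration_map: np.ndarray, pixel_size_um: float,
                    constituent: str = "") -> DepthProfile:
    """Average a depth x lateral map across the lateral dimension.

    Returns per-row means with the per-row standard deviation across
    columns in ``sd``; depths at pixel centres.
    """
    m = np.asarray(concentration_map, dtype=float)
    if m.ndim != 2 or m.size == 0:
        raise ValueError("expected a non-empty 2-D concentration map")
    depths = (np.arange(m.shape[0]) + 0.5) * pixel_size_um / 1000.0
    sd = m.std(axis=1, ddof=1) if m.shape[1] > 1 else np.zeros(m.shape[0])
    return DepthProfile(depths, m.mean(axis=1), sd, constituent)


def _nearest_index(depths: np.ndarray, target: float) -> int:
    return int(np.argmin(np.abs(depths - target)))


def normalize_profile(profile: DepthProfile, scheme: str,
                      anchor_depth_mm: float | None = None) -> DepthProfile:
    """Divide a profile by its anchor value.

    ``peak_anchor``: value at the profile point nearest the given anchor
    depth (the depth of peak concentration); ``surface_anchor``: topmost
    point, or the point nearest the given depth; ``mean_anchor``: the
    profile mean (for uniform constituents).
    """
    if scheme not in ("peak_anchor", "surface_anchor", "mean_anchor"):
        raise ValueError(f"unknown normalization scheme {scheme!r}")
    if scheme == "mean_anchor":
        anchor_value = float(profile.values.mean())
        anchor_depth = float(profile.depths_mm[0])
    else:
        if scheme == "peak_anchor":
            if anchor_depth_mm is None:
                raise ValueError("peak_anchor requires anchor_depth_mm")
            idx = _nearest_index(profile.depths_mm, anchor_depth_mm)
        else:
            idx = 0 if anchor_depth_mm is None else _nearest_index(
                profile.depths_mm, anchor_depth_mm)
        anchor_value = float(profile.values[idx])
        anchor_depth = float(profile.depths_mm[idx])
    if anchor_value <= 0:
        raise ValueError(f"anchor value {anchor_value} is not positive")
    return replace(
        profile,
        values=profile.values / anchor_value,
        sd=None if profile.sd is None else profile.sd / anchor_value,
        normalization={
            "scheme": scheme,
            "anchor_depth_mm": anchor_depth,
            "anchor_value": anchor_value,
        },
    )


def to_absolute(profile: DepthProfile, mean_concentration: float,
                mode: str = "match_mean") -> DepthProfile:
    """Convert a relative profile to % wet weight.

    ``match_mean`` (default) rescales so the depth-averaged output
    equals the bulk assay mean; ``direct`` multiplies the profile by the
    mean as-is.
    """
    if mean_concentration <= 0:
        raise ValueError("mean_concentration must be positive")
    if mode not in ("match_mean", "direct"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "direct":
        factor = mean_concentration
    else:
        profile_mean = float(profile.values.mean())
        if profile_mean <= 0:
            raise ValueError("profile mean is not positive")
        factor = mean_concentration / profile_mean
    return replace(
        profile,
        values=profile.values * factor,
        sd=None if profile.sd is None else profile.sd * factor,
        normalization={"scheme": "absolute_percent_ww",
                       "anchor_depth_mm": None,
                       "anchor_value": factor},
    )


def water_map_hw(
    cube: HyperspectralCube,
    band: tuple[float, float] = WATER_BAND,
    baseline: BaselineParams | None = None,
    single_channel: float | None = None,
) -> ConcentrationMaps:
    """Univariate high-wavenumber water map.

    Integrates the OH stretching band per pixel (trapezoid over the
    closed band) after optional baseline subtraction; pass
    ``single_channel`` to map the intensity at one wavenumber instead.
    Negative values (noise on near-zero pixels) are clipped to zero.
    """
    if baseline is not None:
        cube = subtract_baseline(cube, baseline)
    if single_channel is not None:
        idx = _nearest_index(cube.axis.values, single_channel)
        values = cube.data[:, :, idx]
    else:
        sub = crop_range(cube, band[0], band[1])
        if len(sub.axis) < 2:
            raise ValueError(f"band {band} covers fewer than two channels")
        values = np.trapezoid(sub.data, sub.axis.values, axis=2)
    n_neg = int(np.sum(values < 0))
    if n_neg:
        warnings.warn(f"clipped {n_neg} negative water-band integrals to zero",
                      stacklevel=2)
        values = np.maximum(values, 0.0)
    return ConcentrationMaps(values[None, ...], ("water",), cube.pixel_size_um)


def relative_decrease(profile: DepthProfile, depth_top_mm: float,
                      depth_deep_mm: float, window_mm: float = 0.1) -> float:
    """Percent decrease of a profile between two depths.

    Each depth's value is the mean over a +/- *window_mm* neighbourhood
    (unbiased for locally linear profiles, robust to single-row noise);
    set ``window_mm=0`` for plain interpolation.
    """
    def value_at(d: float) -> float:
        if window_mm <= 0:
            return float(profile.interpolate(np.array([d]))[0])
        mask = (profile.depths_mm >= d - window_mm) & \
               (profile.depths_mm <= d + window_mm)
        if not mask.any():
            return float(profile.interpolate(np.array([d]))[0])
        return float(profile.values[mask].mean())

    v_top = value_at(depth_top_mm)
    v_deep = value_at(depth_deep_mm)
    if v_top <= 0:
        raise ValueError("profile value at the top anchor is not positive")
    return 100.0 * (v_top - v_deep) / v_top


def local_cov(concentration_map: np.ndarray, roi: ROI,
              pixel_size_um: float, constituent: str = "") -> HeterogeneityScore:
    """Coefficient of variation (%) of pixel concentrations in an ROI."""
    m = np.asarray(concentration_map, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D concentration map")
    # reuse the ROI->pixel convention by wrapping the map in a fake cube shape
    px = pixel_size_um
    r0 = int(np.floor(roi.top_um / px))
    c0 = int(np.floor(roi.left_um / px))
    r1 = r0 + int(round(roi.height_um / px))
    c1 = c0 + int(round(roi.width_um / px))
    if r1 > m.shape[0] or c1 > m.shape[1] or r1 <= r0 or c1 <= c0:
        raise ValueError("ROI outside the concentration map")
    block = m[r0:r1, c0:c1]
    if block.size < 2:
        raise ValueError("ROI must contain at least two pixels")
    mean = float(block.mean())
    if mean <= 0:
        raise ValueError("ROI mean concentration is not positive")
    cov = 100.0 * float(block.std(ddof=1)) / mean
    return HeterogeneityScore(roi, constituent, cov)
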