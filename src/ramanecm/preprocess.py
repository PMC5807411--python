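"""Per-pixel autofluorescence baseline estimation and subtraction.

Two interchangeable estimators of the smooth fluorescence background
under the Raman peaks:

``rolling_shape``
    an iterative morphological lower envelope — grey opening (rolling
    minimum then maximum) over a wide window followed by Gaussian
    smoothing. The default window of 1000 data points refers to a
    spectrometer-native export of ~1 point per cm^-1 over 0-3600 cm^-1,
    i.e. a 1000 cm^-1 spectral window; it is converted to points on the
    actual axis through its mean channel spacing.
``asymmetric_ls``
    asymmetric least squares (Whittaker smoother with asymmetric
    weights), the standard chemometric alternative.

Residual negatives after subtraction are deliberately kept: the
non-negativity constraints of the unmixing apply to concentrations and
pure spectra, not to the corrected data, and clipping would bias
low-signal pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solveh_banded
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.signal import savgol_filter

from .spectral import HyperspectralCube, Spectrum

__all__ = ["BaselineParams", "estimate_baseline", "subtract_baseline"]

# channel spacing (cm^-1 per point) of the native full-range export that
# the default window width is expressed in
_NATIVE_SPACING_CM = 3600.0 / 3600.0


@dataclass(frozen=True)
class BaselineParams:
    method: str = "rolling_shape"  # rolling_shape | asymmetric_ls
    window_points: int = 1000
    smoothness: float = 1e5  # asymmetric_ls lambda
    asymmetry: float = 0.01  # asymmetric_ls p
    n_iter: int = 10

    def __post_init__(self) -> None:
        if self.method not in ("rolling_shape", "asymmetric_ls"):
            raise ValueError(f"unknown baseline method {self.method!r}")
        if self.window_points < 3:
            raise ValueError("window_points must be >= 3")
        if self.smoothness <= 0 or not (0 < self.asymmetry < 1) or self.n_iter < 1:
            raise ValueError("invalid asymmetric_ls parameters")

    def window_channels(self, axis_values: np.ndarray) -> int:
        """Window width in channels of the given axis (odd, >= 3)."""
        spacing = float(np.mean(np.diff(axis_values)))
        w = int(round(self.window_points * _NATIVE_SPACING_CM / spacing))
        w = max(w, 3)
        return w if w % 2 == 1 else w + 1


def _robust_edge_line(segment: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row line through the lower envelope of an edge segment.

    Fits intercept and slope to the points at or below the segment's
    30th percentile, so a Raman band sitting on the edge does not drag
    the extrapolation upward. Returns (intercept, slope) against the
    in-segment channel index.
    """
    L = segment.shape[-1]
    x = np.arange(L, dtype=float)
    q = np.quantile(segment, 0.3, axis=-1, keepdims=True)
    mask = segment <= q + 1e-12
    n = mask.sum(axis=-1)
    sx = (x * mask).sum(axis=-1)
    sy = (segment * mask).sum(axis=-1)
    sxx = (x**2 * mask).sum(axis=-1)
    sxy = (x * segment * mask).sum(axis=-1)
    denom = n * sxx - sx**2
    safe = denom > 1e-12
    slope = np.where(safe, (n * sxy - sx * sy) / np.where(safe, denom, 1.0), 0.0)
    intercept = (sy - slope * sx) / np.maximum(n, 1)
    return intercept, slope


def _pad_linear(stack: np.ndarray, h: int) -> np.ndarray:
    """Extend spectra on both ends by extrapolating the robust lower
    trend of the edge region, so morphology neither creates flat
    shoulders on a sloped background nor follows a band that is
    truncated by the end of the axis."""
    n = stack.shape[-1]
    k = max(4, min(h, n // 4))
    # left segment: channels [0, k); extrapolate to x = -h .. -1
    b_l, m_l = _robust_edge_line(stack[..., :k])
    steps = np.arange(-h, 0, dtype=float)
    left = b_l[..., None] + m_l[..., None] * steps
    # right segment: channels [n-k, n); extrapolate to x = k .. k+h-1
    b_r, m_r = _robust_edge_line(stack[..., -k:])
    steps_r = np.arange(k, k + h, dtype=float)
    right = b_r[..., None] + m_r[..., None] * steps_r
    return np.concatenate([left, stack, right], axis=-1)


def _envelope_pass(stack: np.ndarray, window: int) -> np.ndarray:
    """One smoothed grey-opening pass over each row of a 2-D stack."""
    h = window // 2
    padded = _pad_linear(stack, h)
    opened = maximum_filter1d(
        minimum_filter1d(padded, size=window, axis=-1, mode="nearest"),
        size=window, axis=-1, mode="nearest",
    )
    # quadratic-preserving smoothing: a plain Gaussian would inflate a
    # convex fluorescence decay by ~(sigma/tau)^2/2, which is material
    # where the Raman signal is much weaker than the background
    wl = min(window, opened.shape[-1])
    wl = wl if wl % 2 == 1 else wl - 1
    smooth = savgol_filter(opened, window_length=wl, polyorder=2, mode="nearest")
    return smooth[..., h: h + stack.shape[-1]]


def _rolling_shape_stack(stack: np.ndarray, window: int,
                         n_passes: int = 3) -> np.ndarray:
    """Iterative morphological lower envelope.

    A single opening over-estimates the background wherever a sloped
    baseline never reaches a signal-free channel at the window edge
    (dense peak regions); re-opening the residual picks that error up,
    so a few refinement passes converge onto the true envelope.
    """
    base = _envelope_pass(stack, window)
    for _ in range(n_passes - 1):
        base = base + _envelope_pass(stack - base, window)
    return base


def _asls_single(y: np.ndarray, lam: float, p: float, n_iter: int) -> np.ndarray:
    n = y.size
    # banded representation (upper form) of I*w + lam * D2'D2
    d2_diag = np.full(n, 6.0 * lam)
    d2_diag[[0, -1]] = lam
    d2_diag[[1, -2]] = 5.0 * lam
    off1 = np.full(n, -4.0 * lam)
    off1[[1, -1]] = -2.0 * lam
    off2 = np.full(n, lam)
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        ab = np.zeros((3, n))
        ab[0] = off2
        ab[1] = off1
        ab[2] = d2_diag + w
        z = solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def _estimate_stack(stack: np.ndarray, axis_values: np.ndarray,
                    params: BaselineParams) -> np.ndarray:
    n = stack.shape[-1]
    if params.method == "rolling_shape":
        window = params.window_channels(axis_values)
        if window > n:
            raise ValueError(
                f"baseline window of {window} channels exceeds spectrum "
                f"length {n}"
            )
        return _rolling_shape_stack(stack, window)
    flat = stack.reshape(-1, n)
    out = np.empty_like(flat)
    for i, y in enumerate(flat):
        out[i] = _asls_single(y, params.smoothness, params.asymmetry, params.n_iter)
    return out.reshape(stack.shape)


def estimate_baseline(spectrum: Spectrum, params: BaselineParams | None = None) -> Spectrum:
    """Smooth lower-envelope estimate of one spectrum's background."""
    params = params or BaselineParams()
    base = _estimate_stack(spectrum.intensities[None, :], spectrum.axis.values, params)[0]
    return Spectrum(spectrum.axis, base)


def subtract_baseline(cube: HyperspectralCube,
                      params: BaselineParams | None = None) -> HyperspectralCube:
    """Estimate and subtract the per-pixel background of a whole cube."""
    params = params or BaselineParams()
    flat = cube.to_matrix()
    base = _estimate_stack(flat, cube.axis.values, params)
    return cube.with_data((flat - base).reshape(cube.data.shape))
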