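import numpy as np
import pytest

from ramanecm.phantom import (PhantomParams, default_components, make_phantom,
                              separated_fields)
from ramanecm.spectral import HyperspectralCube, Spectrum, WavenumberAxis


@pytest.fixture
def uniform_axis():
    """350-3600 cm^-1 at 5 cm^-1 spacing (reduced acquisition axis)."""
    return WavenumberAxis(np.arange(350.0, 3601.0, 5.0))


@pytest.fixture
def toy_axis():
    return WavenumberAxis(np.array([1000.0, 1010.0, 1020.0, 1030.0, 1040.0]))


@pytest.fixture
def triangle_spectrum(toy_axis):
    return Spectrum(toy_axis, np.array([0.0, 1.0, 2.0, 1.0, 0.0]))


def recovery_phantom(seed=0, noiseless=True, n_rows=60, n_cols=20,
                     names=("GAG", "collagen", "cell")):
    """Separated-field phantom with fingerprint-active components.

    Noiseless variant restricts the axis to the fingerprint range with
    500 channels; the realistic variant keeps the full axis so baseline
    subtraction is exercised.
    """
    comps = [c for c in default_components(include_cells=True) if c.name in names]
    if noiseless:
        params = PhantomParams(
            n_rows=n_rows, n_cols=n_cols, pixel_size_um=3500.0 / n_rows,
            axis_lo=800.0, axis_hi=1800.0, axis_step=1000.0 / 499,
            baseline_amplitude=0.0, baseline_poly_scale=0.0,
            noise_frac=0.0, noise_floor=0.0,
        )
    else:
        params = PhantomParams(
            n_rows=n_rows, n_cols=n_cols, pixel_size_um=3500.0 / n_rows,
            axis_lo=350.0, axis_hi=3600.0, axis_step=5.0, noise_frac=0.02,
        )
    fields = separated_fields(n_rows, n_cols, names=names, seed=seed)
    return make_phantom("native", params, seed=seed, components=comps,
                        fields=fields)


@pytest.fixture(scope="session")
def noiseless_recovery():
    return recovery_phantom(seed=42, noiseless=True)


@pytest.fixture
def tiny_cube():
    """4x3 pixel cube on a 6-channel fingerprint axis, nonnegative rank 2."""
    axis = WavenumberAxis(np.linspace(900.0, 1400.0, 6))
    rng = np.random.default_rng(3)
    c = rng.random((12, 2))
    s = rng.random((2, 6))
    data = (c @ s).reshape(4, 3, 6)
    return HyperspectralCube(axis, data, pixel_size_um=10.0)
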