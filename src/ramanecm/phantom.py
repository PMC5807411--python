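"""Synthetic hyperspectral phantoms of cartilage tissue models.

Generates Raman image cubes with known ground truth for three tissue
models used to exercise the whole pipeline:

``native``
    articular cartilage: GAG and collagen increase with depth from the
    articular surface, water decreases (12.5% relative decrease between
    0.1 mm and 2.5 mm by default);
``engineered``
    cultured constructs: GAG and collagen decrease with depth from the
    media-exposed surface;
``digested``
    trypsin-treated deep-zone explants: GAG increases from the treated
    surface, collagen is uniform.

Each pixel spectrum is a non-negative mixture of Gaussian-peak component
spectra plus a smooth autofluorescence-like baseline and Gaussian noise
with an intensity-proportional term. Default concentration fields are
expressed in % wet weight, anchored to the ranges reported for immature
bovine cartilage (e.g. native GAG rising from ~3 to ~11 %ww over
3.5 mm); they are generator parameters, not assertions about any given
specimen. Sectioned biochemical assays are emulated by slab-averaging
the ground-truth fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral import HyperspectralCube, Spectrum, WavenumberAxis

__all__ = [
    "PeakSpec",
    "ComponentModel",
    "ProfileModel",
    "PhantomParams",
    "GroundTruth",
    "SectionedAssay",
    "render_component_spectrum",
    "make_profile",
    "make_phantom",
    "sample_assay",
    "default_components",
    "default_profiles",
    "TISSUE_MODELS",
    "DEFAULT_SECTIONS",
]

TISSUE_MODELS = ("native", "engineered", "digested")

#: sections cut for the biochemical assay: eight for native cartilage,
#: four for engineered constructs and digested cartilage
DEFAULT_SECTIONS = {"native": 8, "engineered": 4, "digested": 4}

#: default per-pixel multiplicative field heterogeneity per tissue
#: model, anchored to observed localized CoV: native cartilage is very
#: homogeneous, engineered constructs markedly less so
_MODEL_LATERAL_CV = {"native": 0.05, "engineered": 0.15, "digested": 0.05}


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian Raman band: centre and sigma in cm^-1, amplitude in a.u."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("peak width must be positive")
        if self.amplitude < 0:
            raise ValueError("peak amplitude must be non-negative")


@dataclass(frozen=True)
class ComponentModel:
    """A pure molecular constituent as a sum of Gaussian bands."""

    name: str
    peaks: tuple[PeakSpec, ...]

    def __post_init__(self) -> None:
        if len(self.peaks) == 0:
            raise ValueError(f"component {self.name!r} has no peaks")
        object.__setattr__(self, "peaks", tuple(self.peaks))


@dataclass(frozen=True)
class ProfileModel:
    """Depth dependence of one constituent's concentration.

    ``value_at_surface`` / ``value_at_depth`` are the values at the first
    and last pixel-centre depths; ``shape`` interpolates between them.
    """

    constituent: str
    shape: str  # linear | sigmoid | constant
    value_at_surface: float
    value_at_depth: float
    tissue_depth_mm: float
    sigmoid_steepness: float = 8.0

    def __post_init__(self) -> None:
        if self.shape not in ("linear", "sigmoid", "constant"):
            raise ValueError(f"unknown profile shape {self.shape!r}")
        if self.value_at_surface < 0 or self.value_at_depth < 0:
            raise ValueError("profile values must be non-negative")
        if self.shape == "constant" and self.value_at_surface != self.value_at_depth:
            raise ValueError("constant profile requires equal endpoint values")
        if self.tissue_depth_mm <= 0:
            raise ValueError("tissue depth must be positive")


@dataclass(frozen=True)
class SectionedAssay:
    """Emulated biochemical assay of transverse tissue sections (% wet weight)."""

    section_mid_depths_mm: np.ndarray
    concentrations: dict[str, np.ndarray]
    n_sections: int

    def __post_init__(self) -> None:
        mids = np.asarray(self.section_mid_depths_mm, dtype=float)
        object.__setattr__(self, "section_mid_depths_mm", mids)
        if mids.size != self.n_sections or np.any(np.diff(mids) <= 0):
            raise ValueError("section mid-depths must be strictly increasing, one per section")
        for name, vals in self.concentrations.items():
            vals = np.asarray(vals, dtype=float)
            if vals.size != self.n_sections:
                raise ValueError(f"{name}: {vals.size} values for {self.n_sections} sections")
            if np.any(vals < 0):
                raise ValueError(f"{name}: negative assay concentration")
            self.concentrations[name] = vals


@dataclass
class GroundTruth:
    """Everything needed to score a recovery against the generator."""

    components: list[ComponentModel]
    spectra: np.ndarray  # k x n_channels, rendered on the cube axis
    component_names: list[str]
    concentration_fields: dict[str, np.ndarray]  # name -> rows x cols
    baseline: np.ndarray  # rows x cols x channels
    noise: np.ndarray  # rows x cols x channels
    axis: WavenumberAxis
    pixel_size_um: float
    tissue_model: str
    seed: int
    params: "PhantomParams"

    def field_matrix(self) -> np.ndarray:
        """Ground-truth C (n_pixels x k), pixel order matching cube.to_matrix()."""
        cols = [self.concentration_fields[n].reshape(-1) for n in self.component_names]
        return np.stack(cols, axis=1)

    def depth_profile(self, name: str) -> np.ndarray:
        """Laterally averaged ground-truth concentration vs depth row."""
        return self.concentration_fields[name].mean(axis=1)

    def depths_mm(self) -> np.ndarray:
        n_rows = next(iter(self.concentration_fields.values())).shape[0]
        return (np.arange(n_rows) + 0.5) * self.pixel_size_um / 1000.0


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, optics and noise configuration of a phantom."""

    n_rows: int = 70
    n_cols: int = 20
    pixel_size_um: float = 50.0
    axis_lo: float = 350.0
    axis_hi: float = 3600.0
    axis_step: float = 5.0
    baseline_amplitude: float = 20.0
    baseline_tau_cm: float = 1200.0
    baseline_poly_scale: float = 5.0
    noise_floor: float = 0.0
    noise_frac: float = 0.02
    lateral_cv: float = 0.05
    include_cells: bool = False

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("phantom needs at least one row and one column")
        if self.pixel_size_um <= 0 or self.axis_step <= 0:
            raise ValueError("pixel size and axis step must be positive")
        if self.axis_lo >= self.axis_hi:
            raise ValueError("axis_lo must be below axis_hi")
        if min(self.baseline_amplitude, self.baseline_poly_scale,
               self.noise_floor, self.noise_frac, self.lateral_cv) < 0:
            raise ValueError("amplitudes, noise levels and CVs must be non-negative")

    def make_axis(self) -> WavenumberAxis:
        values = np.arange(self.axis_lo, self.axis_hi + 0.5 * self.axis_step, self.axis_step)
        return WavenumberAxis(values)

    @property
    def tissue_depth_mm(self) -> float:
        return self.n_rows * self.pixel_size_um / 1000.0

    @classmethod
    def full_size(cls, tissue_model: str = "native", **overrides) -> "PhantomParams":
        """Full acquisition geometry: ~3500 x 1000 um at ~10 um resolution."""
        depth = {"native": 3.5, "engineered": 3.2, "digested": 2.5}[tissue_model]
        defaults = dict(n_rows=int(depth * 100), n_cols=100, pixel_size_um=10.0,
                        axis_lo=320.0, axis_hi=3600.0, axis_step=4.0,
                        lateral_cv=_MODEL_LATERAL_CV[tissue_model])
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def reduced(cls, tissue_model: str = "native", **overrides) -> "PhantomParams":
        """Reduced geometry for tests: same tissue depth, coarser pixels."""
        n_rows = {"native": 70, "engineered": 64, "digested": 50}[tissue_model]
        defaults = dict(n_rows=n_rows, n_cols=20, pixel_size_um=50.0,
                        lateral_cv=_MODEL_LATERAL_CV[tissue_model])
        defaults.update(overrides)
        return cls(**defaults)


# Band assignments follow the usual cartilage Raman markers: 1061 cm^-1
# S=O stretch for sulfated GAGs; 836/875 proline and hydroxyproline,
# 1245 amide III, 1450 CH2 deformation, 1672 amide I and the 2940 CH
# stretch for collagen; 1004 phenylalanine for the cellular residual;
# the broad OH stretch near 3400 cm^-1 (plus the weak 1640 bending
# band) for water. Amplitudes are per % wet weight and fold in the
# constituents' very different effective Raman cross-sections: collagen
# scatters far more strongly per unit mass than GAG, and water's
# fingerprint signal is inherently weak — which is why collagen
# dominates the explained variance of fingerprint unmixing in tissue
# even where its mass fraction is small.
_PEAK_TABLES: dict[str, tuple[tuple[float, float, float], ...]] = {
    "GAG": ((1061.0, 12.0, 1.0), (1158.0, 12.0, 0.25), (1380.0, 15.0, 0.35)),
    "collagen": (
        (836.0, 10.0, 1.8),
        (875.0, 10.0, 2.0),
        (1245.0, 14.0, 3.2),
        (1450.0, 14.0, 4.0),
        (1672.0, 16.0, 3.6),
        (2940.0, 30.0, 4.8),
    ),
    "water": ((1640.0, 40.0, 0.06), (3400.0, 110.0, 1.0)),
    "cell": ((1004.0, 6.0, 1.0), (1450.0, 14.0, 0.30), (2930.0, 25.0, 0.50)),
}


def default_components(include_cells: bool = False) -> list[ComponentModel]:
    names = ["GAG", "collagen", "water"] + (["cell"] if include_cells else [])
    return [
        ComponentModel(n, tuple(PeakSpec(*p) for p in _PEAK_TABLES[n])) for n in names
    ]


def _native_water_endpoint(d0: float, dn: float,
                           anchor_top: float = 0.1, anchor_deep: float = 2.5,
                           rel_decrease: float = 0.125) -> float:
    """Endpoint of a linear water profile (surface value 1) whose relative
    decrease from *anchor_top* to *anchor_deep* equals *rel_decrease*.

    The slope is fixed by the anchors alone, so phantoms shallower than
    the deep anchor still carry the same per-mm gradient.
    """
    slope = rel_decrease / ((anchor_deep - anchor_top) + rel_decrease * (anchor_top - d0))
    return max(1.0 - slope * (dn - d0), 0.0)


def default_profiles(tissue_model: str, params: PhantomParams) -> dict[str, ProfileModel]:
    """Per-constituent depth profiles for one tissue model.

    Endpoint values in % wet weight extrapolate the assayed ranges
    (native GAG 3.3->10.3 %ww between 0.2 and 3.2 mm, collagen
    4.1->8.2 %ww; engineered GAG 7.3->2.8 %ww between 0.4 and 2.6 mm,
    collagen 0.9->0.2; digested GAG 1.7->6.7 %ww between 0.34 and
    2.7 mm, collagen uniform at 9.7 %ww) linearly to the phantom's
    surface and bottom. Native water is scaled to ~80 %ww hydration at
    the surface with the default 12.5% relative decrease to 2.5 mm.
    """
    if tissue_model not in TISSUE_MODELS:
        raise ValueError(f"unknown tissue model {tissue_model!r}")
    depth = params.tissue_depth_mm
    px_mm = params.pixel_size_um / 1000.0
    d0 = 0.5 * px_mm
    dn = (params.n_rows - 0.5) * px_mm

    def endpoints(v_a: float, d_a: float, v_b: float, d_b: float) -> tuple[float, float]:
        slope = (v_b - v_a) / (d_b - d_a)
        return (max(v_a + slope * (d0 - d_a), 0.0),
                max(v_a + slope * (dn - d_a), 0.0))

    def linear(name, v_a, d_a, v_b, d_b) -> ProfileModel:
        vs, vd = endpoints(v_a, d_a, v_b, d_b)
        return ProfileModel(name, "linear", vs, vd, depth)

    def sigmoid(name, v_a, d_a, v_b, d_b) -> ProfileModel:
        # GAG fronts (matrix deposition, enzymatic extraction) are
        # diffusion-shaped rather than linear; the distinct curvature
        # relative to collagen also keeps the constituents spectrally
        # and spatially resolvable
        vs, vd = endpoints(v_a, d_a, v_b, d_b)
        return ProfileModel(name, "sigmoid", vs, vd, depth)

    if tissue_model == "native":
        water_vd = 80.0 * _native_water_endpoint(d0, dn)
        profiles = {
            "GAG": sigmoid("GAG", 3.3, 0.2, 10.3, 3.2),
            "collagen": linear("collagen", 4.1, 0.2, 8.2, 3.2),
            "water": ProfileModel("water", "linear", 80.0, water_vd, depth),
        }
    elif tissue_model == "engineered":
        profiles = {
            "GAG": sigmoid("GAG", 7.3, 0.4, 2.8, 2.6),
            "collagen": linear("collagen", 0.9, 0.4, 0.2, 2.6),
            "water": ProfileModel("water", "constant", 80.0, 80.0, depth),
        }
    else:  # digested
        profiles = {
            "GAG": sigmoid("GAG", 1.7, 0.34, 6.7, 2.7),
            "collagen": ProfileModel("collagen", "constant", 9.7, 9.7, depth),
            "water": ProfileModel("water", "constant", 82.0, 82.0, depth),
        }
    if params.include_cells:
        profiles["cell"] = ProfileModel("cell", "constant", 2.0, 2.0, depth)
    return profiles


def separated_fields(
    n_rows: int,
    n_cols: int,
    names: tuple[str, ...] = ("GAG", "collagen", "water"),
    seed: int = 0,
    floor: float = 0.05,
    amplitude: float = 10.0,
    lateral_cv: float = 0.15,
) -> dict[str, np.ndarray]:
    """Spatially separated concentration fields for recovery testing.

    Each component concentrates in its own depth band (Gaussian bump on
    a small floor) with multiplicative lateral variation, so every
    component dominates some pixels. Graded tissue-model profiles are
    deliberately collinear across constituents (all near-linear in
    depth), which leaves the bilinear factorization rotationally
    ambiguous; parameter-recovery studies therefore use these separated
    fields, which make the factorization essentially unique.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    d = (np.arange(n_rows) + 0.5) / n_rows
    centers = np.linspace(0.15, 0.85, len(names))
    sigma = 0.4 / len(names)
    fields = {}
    for c, n in zip(centers, names):
        prof = floor + amplitude * np.exp(-0.5 * ((d - c) / sigma) ** 2)
        f = np.repeat(prof[:, None], n_cols, axis=1)
        if lateral_cv > 0:
            f = f * np.maximum(1.0 + lateral_cv * rng.standard_normal(f.shape), 0.0)
        fields[n] = f
    return fields


def render_component_spectrum(model: ComponentModel, axis: WavenumberAxis) -> Spectrum:
    """Evaluate the sum of a component's Gaussian bands on the axis."""
    nu = axis.values
    intens = np.zeros_like(nu)
    for p in model.peaks:
        intens += p.amplitude * np.exp(-0.5 * ((nu - p.center) / p.width) ** 2)
    return Spectrum(axis, intens)


def make_profile(model: ProfileModel, n_rows: int, pixel_size_um: float) -> np.ndarray:
    """Sample a depth profile at the n_rows pixel-centre depths.

    For the linear and sigmoid shapes the first and last samples equal
    ``value_at_surface`` and ``value_at_depth`` exactly.
    """
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    if n_rows == 1:
        return np.array([model.value_at_surface])
    t = np.linspace(0.0, 1.0, n_rows)
    if model.shape == "constant":
        return np.full(n_rows, model.value_at_surface)
    if model.shape == "linear":
        return model.value_at_surface + (model.value_at_depth - model.value_at_surface) * t
    # sigmoid: logistic rescaled to hit the endpoints exactly
    k = model.sigmoid_steepness
    raw = 1.0 / (1.0 + np.exp(-k * (t - 0.5)))
    raw = (raw - raw[0]) / (raw[-1] - raw[0])
    return model.value_at_surface + (model.value_at_depth - model.value_at_surface) * raw


def _baseline_cube(params: PhantomParams, axis: WavenumberAxis,
                   rng: np.random.Generator) -> np.ndarray:
    """Smooth per-pixel autofluorescence stand-in: broad exponential decay
    plus a low-order polynomial, amplitudes randomized per pixel."""
    shape = (params.n_rows, params.n_cols)
    if params.baseline_amplitude == 0 and params.baseline_poly_scale == 0:
        return np.zeros(shape + (len(axis),))
    nu = axis.values
    u = (nu - nu[0]) / (nu[-1] - nu[0])
    decay = np.exp(-(nu - nu[0]) / params.baseline_tau_cm)
    amp = params.baseline_amplitude * (0.75 + 0.5 * rng.random(shape))
    c0 = params.baseline_poly_scale * (0.75 + 0.5 * rng.random(shape))
    c1 = params.baseline_poly_scale * (rng.random(shape) - 0.5)
    c2 = params.baseline_poly_scale * (rng.random(shape) - 0.5)
    base = (
        amp[..., None] * decay
        + c0[..., None]
        + c1[..., None] * u
        + c2[..., None] * u**2
    )
    return np.maximum(base, 0.0)


def make_phantom(
    tissue_model: str,
    params: PhantomParams | None = None,
    seed: int = 0,
    components: list[ComponentModel] | None = None,
    profiles: dict[str, ProfileModel] | None = None,
    fields: dict[str, np.ndarray] | None = None,
) -> tuple[HyperspectralCube, GroundTruth]:
    """Generate one tissue-model phantom and its ground truth.

    The emitted cube is ``sum_k c_k(x) s_k(nu) + baseline(x, nu) +
    noise(x, nu)``; re-running with identical parameters and seed
    reproduces it bit for bit. The master seed is split into independent
    substreams for fields, baseline and noise, so changing e.g. the
    noise level does not shift the concentration fields.
    """
    if tissue_model not in TISSUE_MODELS:
        raise ValueError(f"unknown tissue model {tissue_model!r}")
    if params is None:
        params = PhantomParams.reduced(tissue_model)
    axis = params.make_axis()
    if components is None:
        components = default_components(params.include_cells)
    if profiles is None:
        profiles = default_profiles(tissue_model, params)
    names = [c.name for c in components]

    ss_fields, ss_base, ss_noise = np.random.SeedSequence(seed).spawn(3)
    rng_fields = np.random.default_rng(ss_fields)

    spectra = np.stack(
        [render_component_spectrum(c, axis).intensities for c in components]
    )
    if fields is not None:
        missing = [n for n in names if n not in fields]
        if missing:
            raise ValueError(f"no concentration field for component(s) {missing}")
        shape = (params.n_rows, params.n_cols)
        fields = {n: np.asarray(fields[n], dtype=float) for n in names}
        for n, f in fields.items():
            if f.shape != shape:
                raise ValueError(
                    f"field {n!r} has shape {f.shape}, expected {shape}")
            if np.any(f < 0):
                raise ValueError(f"field {n!r} has negative concentrations")
    else:
        missing = [n for n in names if n not in profiles]
        if missing:
            raise ValueError(f"no depth profile for component(s) {missing}")
        fields = {}
        for name in names:
            profile = make_profile(profiles[name], params.n_rows, params.pixel_size_um)
            f = np.repeat(profile[:, None], params.n_cols, axis=1)
            if params.lateral_cv > 0:
                f = f * np.maximum(
                    1.0 + params.lateral_cv * rng_fields.standard_normal(f.shape), 0.0
                )
            else:
                # keep substream consumption identical either way
                rng_fields.standard_normal(f.shape)
            fields[name] = f

    c_matrix = np.stack([fields[n].reshape(-1) for n in names], axis=1)
    clean = (c_matrix @ spectra).reshape(params.n_rows, params.n_cols, len(axis))

    baseline = _baseline_cube(params, axis, np.random.default_rng(ss_base))
    rng_noise = np.random.default_rng(ss_noise)
    if params.noise_floor > 0 or params.noise_frac > 0:
        sigma = params.noise_floor + params.noise_frac * np.abs(clean)
        noise = sigma * rng_noise.standard_normal(clean.shape)
    else:
        noise = np.zeros_like(clean)

    cube = HyperspectralCube(axis, clean + baseline + noise, params.pixel_size_um)
    truth = GroundTruth(
        components=list(components),
        spectra=spectra,
        component_names=names,
        concentration_fields=fields,
        baseline=baseline,
        noise=noise,
        axis=axis,
        pixel_size_um=params.pixel_size_um,
        tissue_model=tissue_model,
        seed=seed,
        params=params,
    )
    return cube, truth


def sample_assay(
    truth: GroundTruth,
    n_sections: int | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
    constituents: tuple[str, ...] = ("GAG", "collagen"),
    conversion: dict[str, float] | None = None,
) -> SectionedAssay:
    """Emulate transverse sectioning plus biochemical assaying.

    The tissue depth is cut into *n_sections* equal slabs; each section's
    value is the mean of the ground-truth field over the slab, scaled by
    a constituent-specific conversion to % wet weight (identity by
    default: the fields already carry %ww units) and perturbed by
    multiplicative Gaussian noise of coefficient of variation *noise_cv*.
    """
    if n_sections is None:
        n_sections = DEFAULT_SECTIONS[truth.tissue_model]
    if n_sections < 2:
        raise ValueError("need at least two sections")
    n_rows = next(iter(truth.concentration_fields.values())).shape[0]
    if n_sections > n_rows:
        raise ValueError(f"{n_sections} sections exceed {n_rows} depth rows")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    conversion = conversion or {}
    depth_mm = n_rows * truth.pixel_size_um / 1000.0
    edges = np.round(np.linspace(0, n_rows, n_sections + 1)).astype(int)
    mids = (edges[:-1] + edges[1:]) / 2.0 * truth.pixel_size_um / 1000.0
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    concentrations: dict[str, np.ndarray] = {}
    for name in constituents:
        if name not in truth.concentration_fields:
            raise KeyError(f"no ground-truth field for {name!r}")
        fld = truth.concentration_fields[name]
        vals = np.array(
            [fld[edges[i]: edges[i + 1]].mean() for i in range(n_sections)]
        ) * conversion.get(name, 1.0)
        if noise_cv > 0:
            vals = vals * np.maximum(
                1.0 + noise_cv * rng.standard_normal(n_sections), 0.0
            )
        else:
            rng.standard_normal(n_sections)
        concentrations[name] = vals
    assert mids[-1] <= depth_mm
    return SectionedAssay(mids, concentrations, n_sections)
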