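"""End-to-end pipeline: phantom -> preprocess -> unmix -> quantify -> validate.

Runs the complete workflow on one tissue-model phantom (or a cube
loaded from disk), mirroring how the imaging study proceeds: baseline
subtraction, MCR-ALS on the fingerprint range, merging of degenerate
components, identification against reference spectra, lateral
averaging into normalized depth profiles, high-wavenumber water
mapping, localized coefficient-of-variation scoring, and statistical
validation against (emulated) sectioned biochemical assays.

Every product is written to an output directory as inspectable CSV and
JSON; runs are fully deterministic given the config and its seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import PipelineConfig, write_spectra_csv
from .mcr import (ComponentSpectra, ConcentrationMaps, MCROptions, MCRResult,
                  fit_mcr, match_references, merge_degenerate)
from .phantom import (GroundTruth, PhantomParams, SectionedAssay, make_phantom,
                      sample_assay)
from .preprocess import BaselineParams, subtract_baseline
from .quantify import (DepthProfile, lateral_average, local_cov,
                       normalize_profile, relative_decrease, water_map_hw)
from .spectral import ROI, HyperspectralCube, crop_range
from .validate import ValidationReport, validate_constituent

__all__ = ["run_pipeline", "PipelineResult", "NORMALIZATION", "gradient_direction"]

logger = logging.getLogger(__name__)

#: per-tissue-model normalization scheme and anchor depth (mm) for each
#: constituent: increasing constituents anchor at their peak depth,
#: decreasing ones at the topmost section, uniform ones at the mean
NORMALIZATION: dict[str, dict[str, tuple[str, float | None]]] = {
    "native": {
        "GAG": ("peak_anchor", 1.4),
        "collagen": ("peak_anchor", 1.4),
        "water": ("surface_anchor", 0.1),
    },
    "engineered": {
        "GAG": ("surface_anchor", 0.4),
        "collagen": ("surface_anchor", 0.4),
        "water": ("surface_anchor", 0.4),
    },
    "digested": {
        "GAG": ("peak_anchor", 2.5),
        "collagen": ("mean_anchor", None),
        "water": ("mean_anchor", None),
    },
}

#: heterogeneity ROI placements (name -> depth of ROI top, um)
_ROI_DEPTHS: dict[str, dict[str, float]] = {
    "native": {"deep": 2600.0},
    "engineered": {"peripheral": 100.0, "central": 2000.0},
    "digested": {"deep": 1500.0},
}
_ROI_SIZE_UM = 250.0


@dataclass
class PipelineResult:
    config: PipelineConfig
    cube: HyperspectralCube
    truth: GroundTruth
    mcr: MCRResult
    reference_r2: dict[str, float]
    maps: ConcentrationMaps
    profiles: dict[str, DepthProfile]
    water_decrease_pct: float | None
    assay: SectionedAssay
    validation: dict[str, ValidationReport]
    heterogeneity: pd.DataFrame
    gradients: dict[str, str]
    outdir: Path | None


def gradient_direction(depths_mm: np.ndarray, values: np.ndarray,
                       alpha: float = 0.05,
                       min_relative_change: float = 0.1) -> tuple[str, float]:
    """Classify a depth profile as increasing, decreasing or uniform.

    A direction is assigned only when the fitted linear trend is both
    statistically significant (slope p < *alpha*) and material: the
    fitted change across the profiled depth must exceed
    *min_relative_change* of the profile mean. Constituents whose
    profile varies less than that are reported uniform — a depth
    gradient smaller than assay repeatability is not a gradient.
    """
    res = stats.linregress(depths_mm, values)
    span = depths_mm[-1] - depths_mm[0]
    mean = np.mean(values)
    relative_change = abs(res.slope) * span / abs(mean) if mean != 0 else np.inf
    if res.pvalue >= alpha or relative_change < min_relative_change:
        return "uniform", float(res.pvalue)
    return ("increasing" if res.slope > 0 else "decreasing"), float(res.pvalue)


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s: %.2f s", name, dt)
                return False
            logger.error("stage %s failed after %.2f s: %s", name, dt, exc)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    return _Timer()


def _phantom_params(config: PipelineConfig) -> PhantomParams:
    defaults = PhantomParams.reduced(config.tissue_model)
    return PhantomParams(
        n_rows=config.n_rows or defaults.n_rows,
        n_cols=config.n_cols or defaults.n_cols,
        pixel_size_um=config.pixel_size_um or defaults.pixel_size_um,
        axis_lo=config.axis_lo,
        axis_hi=config.axis_hi,
        axis_step=config.axis_step,
        baseline_amplitude=config.baseline_amplitude,
        noise_frac=config.noise_frac,
        noise_floor=config.noise_floor,
        lateral_cv=(defaults.lateral_cv if config.lateral_cv is None
                    else config.lateral_cv),
        include_cells=config.include_cells,
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None,
                 cube: HyperspectralCube | None = None,
                 truth: GroundTruth | None = None) -> PipelineResult:
    """Execute the full workflow; optionally persist results to *outdir*.

    A phantom of ``config.tissue_model`` is generated unless an
    existing *cube* (with ground truth for validation) is supplied.
    """
    model = config.tissue_model
    with _stage("phantom"):
        if cube is None:
            params = _phantom_params(config)
            cube, truth = make_phantom(model, params, seed=config.seed)
        if truth is None:
            raise ValueError("an externally supplied cube needs ground truth "
                             "for validation")
        logger.info("cube shape %s, pixel %.3g um", cube.data.shape,
                    cube.pixel_size_um)

    with _stage("preprocess"):
        bl = BaselineParams(method=config.baseline_method,
                            window_points=config.baseline_window_points)
        corrected = subtract_baseline(cube, bl)

    with _stage("water_map"):
        water_maps = water_map_hw(
            corrected, band=(config.water_band_lo, config.water_band_hi))

    with _stage("fit_mcr"):
        fingerprint = crop_range(corrected, config.fit_lo, config.fit_hi)
        sl = truth.axis.slice_for(config.fit_lo, config.fit_hi)
        refs = ComponentSpectra(
            np.maximum(truth.spectra[:, sl], 0.0), tuple(truth.component_names),
            fingerprint.axis,
        )
        # reference spectra of the pure biochemicals initialize the ALS
        # by default: with one constituent dominating every pixel, a
        # data-driven start resolves mixtures of the dominant species
        init_spectra = refs.spectra if config.init == "reference" else None
        opts = MCROptions(max_iter=config.max_iter, tol=config.tol,
                          fit_range=None, seed=config.seed,
                          init=("purest_pixel" if config.init == "reference"
                                else config.init),
                          init_spectra=init_spectra)
        result = fit_mcr(fingerprint, k=config.k, opts=opts)
        logger.info("explained variance %.2f%% after %d iterations",
                    result.explained_variance_total, result.n_iterations)

    with _stage("merge_and_match"):
        result = merge_degenerate(result, config.merge_threshold)
        match = match_references(result.S, refs)
        maps = ConcentrationMaps(result.C.maps, match.spectra.names,
                                 result.C.pixel_size_um)

    with _stage("quantify"):
        profiles: dict[str, DepthProfile] = {}
        schemes = NORMALIZATION[model]
        for name in ("GAG", "collagen"):
            if name not in maps.names:
                continue
            prof = lateral_average(maps.get(name), cube.pixel_size_um, name)
            scheme, anchor = schemes[name]
            profiles[name] = normalize_profile(prof, scheme, anchor)
        water_prof = lateral_average(water_maps.get("water"),
                                     cube.pixel_size_um, "water")
        scheme, anchor = schemes["water"]
        profiles["water"] = normalize_profile(water_prof, scheme, anchor)
        water_decrease = None
        if profiles["water"].depths_mm[-1] >= 2.5:
            water_decrease = relative_decrease(profiles["water"], 0.1, 2.5)

        rois: list[dict] = []
        width_um = cube.n_cols * cube.pixel_size_um
        depth_um = cube.n_rows * cube.pixel_size_um
        for region, top_um in _ROI_DEPTHS[model].items():
            if top_um + _ROI_SIZE_UM > depth_um or _ROI_SIZE_UM > width_um:
                logger.info("skipping ROI %s: outside cube extent", region)
                continue
            roi = ROI(top_um, (width_um - _ROI_SIZE_UM) / 2.0,
                      _ROI_SIZE_UM, _ROI_SIZE_UM)
            for name in ("GAG", "collagen"):
                if name in maps.names:
                    score = local_cov(maps.get(name), roi, cube.pixel_size_um, name)
                    rois.append({"tissue": model, "region": region,
                                 "constituent": name,
                                 "cov_percent": score.cov})
        heterogeneity = pd.DataFrame(
            rois, columns=["tissue", "region", "constituent", "cov_percent"])

    with _stage("validate"):
        constituents = ("GAG", "collagen", "water") if model == "native" \
            else ("GAG", "collagen")
        assay = sample_assay(truth, config.sections(),
                             noise_cv=config.assay_noise_cv, seed=config.seed,
                             constituents=constituents)
        validation: dict[str, ValidationReport] = {}
        gradients: dict[str, str] = {}
        for name in constituents:
            if name not in profiles:
                continue
            scheme, anchor = schemes[name]
            # water is always validated from the high-wavenumber
            # univariate map: its fingerprint signal is too weak
            raw_prof = (lateral_average(water_maps.get("water"),
                                        cube.pixel_size_um, "water")
                        if name == "water" else
                        lateral_average(maps.get(name), cube.pixel_size_um, name))
            validation[name] = validate_constituent(
                raw_prof, assay, name, scheme=scheme, anchor_depth_mm=anchor)
        for name, prof in profiles.items():
            direction, _p = gradient_direction(prof.depths_mm, prof.values)
            gradients[name] = direction

    res = PipelineResult(
        config=config, cube=cube, truth=truth, mcr=result,
        reference_r2=match.r_squared, maps=maps, profiles=profiles,
        water_decrease_pct=water_decrease, assay=assay, validation=validation,
        heterogeneity=heterogeneity, gradients=gradients,
        outdir=Path(outdir) if outdir is not None else None,
    )
    if outdir is not None:
        with _stage("write_outputs"):
            _write_outputs(res)
    return res


def _write_outputs(res: PipelineResult) -> None:
    out = res.outdir
    out.mkdir(parents=True, exist_ok=True)
    res.config.to_json(out / "config.json")
    write_spectra_csv(res.mcr.S, out / "spectra_resolved.csv")

    rows = []
    for name, prof in res.profiles.items():
        norm = prof.normalization or {}
        for i in range(prof.depths_mm.size):
            rows.append({
                "constituent": name,
                "depth_mm": prof.depths_mm[i],
                "value": prof.values[i],
                "sd": prof.sd[i] if prof.sd is not None else np.nan,
                "scheme": norm.get("scheme", ""),
                "anchor_depth_mm": norm.get("anchor_depth_mm", np.nan),
            })
    pd.DataFrame(rows).to_csv(out / "profiles.csv", index=False,
                              float_format="%.12g")

    pd.DataFrame([v.to_row() for v in res.validation.values()]).to_csv(
        out / "validation.csv", index=False, float_format="%.12g")
    res.heterogeneity.to_csv(out / "heterogeneity.csv", index=False,
                             float_format="%.12g")
    for name in res.maps.names:
        np.savetxt(out / f"map_{name}.csv", res.maps.get(name),
                   delimiter=",", fmt="%.12g")

    report = {
        "tissue_model": res.config.tissue_model,
        "seed": res.config.seed,
        "explained_variance_total_percent": float(res.mcr.explained_variance_total),
        "explained_variance_per_component_percent":
            [float(x) for x in res.mcr.explained_variance_per_component],
        "n_iterations": res.mcr.n_iterations,
        "converged": bool(res.mcr.converged),
        "k_after_merge": res.mcr.S.k,
        "reference_r2": res.reference_r2,
        "gradients": res.gradients,
        "water_decrease_percent_0p1_to_2p5_mm": res.water_decrease_pct,
        "validation": {k: v.to_row() for k, v in res.validation.items()},
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
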