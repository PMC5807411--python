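#!/usr/bin/env python
"""Parameter-recovery study of the MCR-ALS unmixing.

Two regimes on phantoms with spatially separated components (each
constituent dominating its own depth band, which makes the bilinear
factorization essentially unique):

1. noiseless fingerprint-range cubes — the factorization should be
   recovered nearly exactly;
2. realistic cubes with autofluorescence baseline and 2% noise, pushed
   through baseline subtraction before fitting — laterally averaged
   profiles should still track the ground truth closely.

Writes results/recovery_metrics.csv.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

import ramanecm as rm
from ramanecm.mcr import ComponentSpectra, ConcentrationMaps, MCROptions
from ramanecm.phantom import PhantomParams, default_components, make_phantom, \
    separated_fields
from ramanecm.quantify import lateral_average, normalize_profile
from ramanecm.validate import r_squared, rmsep

OUT = Path(__file__).resolve().parent.parent / "results"
NAMES = ("GAG", "collagen", "cell")


def phantom(seed, noiseless):
    comps = [c for c in default_components(include_cells=True)
             if c.name in NAMES]
    kw = (dict(axis_lo=800.0, axis_hi=1800.0, axis_step=1000.0 / 499,
               baseline_amplitude=0.0, baseline_poly_scale=0.0, noise_frac=0.0)
          if noiseless else
          dict(axis_lo=350.0, axis_hi=3600.0, axis_step=5.0, noise_frac=0.02))
    params = PhantomParams(n_rows=60, n_cols=20, pixel_size_um=3500.0 / 60, **kw)
    fields = separated_fields(60, 20, names=NAMES, seed=seed)
    return make_phantom("native", params, seed=seed, components=comps,
                        fields=fields)


def main() -> None:
    warnings.filterwarnings("ignore")
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []

    cube, truth = phantom(42, noiseless=True)
    res = rm.fit_mcr(cube, k=3, opts=MCROptions(max_iter=500, fit_range=None))
    refs = ComponentSpectra(truth.spectra, tuple(truth.component_names),
                            truth.axis)
    match = rm.match_references(res.S, refs)
    maps = ConcentrationMaps(res.C.maps, match.spectra.names,
                             res.C.pixel_size_um)
    print(f"noiseless fit: explained variance "
          f"{res.explained_variance_total:.3f}% in {res.n_iterations} iterations")
    for name in NAMES:
        field_r = np.corrcoef(maps.get(name).ravel(),
                              truth.concentration_fields[name].ravel())[0, 1]
        print(f"  {name}: spectral r2 {match.r_squared[name]:.4f}, "
              f"field r {field_r:.4f}")
        rows.append({"regime": "noiseless", "constituent": name,
                     "spectral_r2": match.r_squared[name],
                     "field_r": field_r, "profile_r2": np.nan,
                     "profile_rmsep_pct": np.nan})

    print("\nrealistic regime (baseline + 2% noise, 10 seeds):")
    metrics = {n: {"r2": [], "err": []} for n in ("GAG", "collagen")}
    for seed in range(10):
        cube, truth = phantom(seed, noiseless=False)
        corrected = rm.subtract_baseline(cube)
        res = rm.fit_mcr(corrected, k=3, opts=MCROptions())
        match = rm.match_references(res.S, refs)
        maps = ConcentrationMaps(res.C.maps, match.spectra.names,
                                 res.C.pixel_size_um)
        for name in metrics:
            prof = normalize_profile(
                lateral_average(maps.get(name), cube.pixel_size_um),
                "mean_anchor")
            ref_prof = truth.depth_profile(name)
            ref_prof = ref_prof / ref_prof.mean()
            metrics[name]["r2"].append(r_squared(prof.values, ref_prof))
            metrics[name]["err"].append(rmsep(prof.values, ref_prof))
    for name, m in metrics.items():
        print(f"  {name}: median profile R2 {np.median(m['r2']):.4f}, "
              f"median RMSEP {np.median(m['err']):.2f}%")
        rows.append({"regime": "realistic_median_of_10", "constituent": name,
                     "spectral_r2": np.nan, "field_r": np.nan,
                     "profile_r2": np.median(m["r2"]),
                     "profile_rmsep_pct": np.median(m["err"])})
    pd.DataFrame(rows).to_csv(OUT / "recovery_metrics.csv", index=False,
                              float_format="%.6g")
    print(f"\nwrote {OUT / 'recovery_metrics.csv'}")


if __name__ == "__main__":
    main()
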