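#!/usr/bin/env python
"""High-wavenumber water profiling and localized heterogeneity.

Maps tissue water per pixel by integrating the OH stretching band
(3100-3600 cm^-1) after baseline subtraction, extracts the
surface-anchored depth profile of native cartilage, and scores
localized heterogeneity (CoV of pixel concentrations in 250 x 250 um
regions) for native and engineered tissues. Writes
results/water_profile.csv and results/heterogeneity_summary.csv.
"""

import warnings
from pathlib import Path

import pandas as pd

import ramanecm as rm
from ramanecm.io import PipelineConfig
from ramanecm.phantom import PhantomParams, make_phantom
from ramanecm.pipeline import run_pipeline
from ramanecm.quantify import (lateral_average, normalize_profile,
                               relative_decrease)

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    warnings.filterwarnings("ignore")
    OUT.mkdir(parents=True, exist_ok=True)

    params = PhantomParams.reduced("native", n_cols=40)
    cube, _ = make_phantom("native", params, seed=SEED)
    corrected = rm.subtract_baseline(cube)
    maps = rm.water_map_hw(corrected)
    prof = normalize_profile(
        lateral_average(maps.get("water"), cube.pixel_size_um, "water"),
        "surface_anchor", 0.1)
    decrease = relative_decrease(prof, 0.1, 2.5)
    print(f"native water: relative decrease {decrease:.2f}% "
          f"from 0.1 mm to 2.5 mm (generator truth: 12.5%)")
    pd.DataFrame({"depth_mm": prof.depths_mm,
                  "relative_water": prof.values,
                  "sd": prof.sd}).to_csv(OUT / "water_profile.csv",
                                         index=False, float_format="%.6g")

    rows = []
    for model in ("native", "engineered"):
        res = run_pipeline(PipelineConfig(tissue_model=model, seed=SEED))
        for row in res.heterogeneity.itertuples():
            print(f"{model} {row.region} {row.constituent}: "
                  f"CoV {row.cov_percent:.1f}%")
            rows.append({"tissue": model, "region": row.region,
                         "constituent": row.constituent,
                         "cov_percent": row.cov_percent})
    pd.DataFrame(rows).to_csv(OUT / "heterogeneity_summary.csv", index=False,
                              float_format="%.6g")
    print(f"\nwrote {OUT / 'water_profile.csv'} and "
          f"{OUT / 'heterogeneity_summary.csv'}")


if __name__ == "__main__":
    main()
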