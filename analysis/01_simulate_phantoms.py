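#!/usr/bin/env python
"""Generate the three cartilage tissue phantoms and their emulated
sectioned biochemical assays.

Writes the ground-truth depth profiles and assay tables under
results/phantoms/. These are the study conditions every later stage is
scored against: native cartilage (GAG and collagen rising from the
articular surface, water falling), engineered constructs (GAG and
collagen falling from the media-exposed surface) and trypsin-digested
explants (GAG rising from the treated surface over uniform collagen).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ramanecm.phantom import (DEFAULT_SECTIONS, PhantomParams, make_phantom,
                              sample_assay)

OUT = Path(__file__).resolve().parent.parent / "results" / "phantoms"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    profile_rows, assay_rows = [], []
    for model in ("native", "engineered", "digested"):
        params = PhantomParams.reduced(model)
        cube, truth = make_phantom(model, params, seed=SEED)
        print(f"{model}: cube {cube.data.shape}, pixel {cube.pixel_size_um} um, "
              f"depth {params.tissue_depth_mm} mm, lateral CV {params.lateral_cv}")
        depths = truth.depths_mm()
        for name in truth.component_names:
            prof = truth.depth_profile(name)
            for d, v in zip(depths, prof):
                profile_rows.append({"tissue": model, "constituent": name,
                                     "depth_mm": d, "pct_wet_weight": v})
            print(f"  {name}: {prof[0]:.2f} -> {prof[-1]:.2f} %ww "
                  f"(surface -> {depths[-1]:.2f} mm)")
        constituents = (("GAG", "collagen", "water") if model == "native"
                        else ("GAG", "collagen"))
        assay = sample_assay(truth, noise_cv=0.08, seed=SEED,
                             constituents=constituents)
        for name, vals in assay.concentrations.items():
            for d, v in zip(assay.section_mid_depths_mm, vals):
                assay_rows.append({"tissue": model, "constituent": name,
                                   "section_mid_depth_mm": d,
                                   "pct_wet_weight": v})
        print(f"  assay: {DEFAULT_SECTIONS[model]} sections, 8% CV noise")
    pd.DataFrame(profile_rows).to_csv(OUT / "ground_truth_profiles.csv",
                                      index=False, float_format="%.6g")
    pd.DataFrame(assay_rows).to_csv(OUT / "sectioned_assays.csv",
                                    index=False, float_format="%.6g")
    print(f"\nwrote {OUT / 'ground_truth_profiles.csv'}")
    print(f"wrote {OUT / 'sectioned_assays.csv'}")


if __name__ == "__main__":
    main()
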