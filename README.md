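# ramanecm

Spectral unmixing and depth profiling of cartilage extracellular
matrix (ECM) from Raman hyperspectral images, with a synthetic phantom
framework for validating every stage against known ground truth.

## The problem

Articular cartilage owes its mechanics to the spatial organization of
three constituents: glycosaminoglycans (GAG), collagen and water. In
native tissue GAG and collagen concentrations rise with depth from the
articular surface while water falls; engineered constructs show the
opposite gradients from their media-exposed surface; trypsin digestion
strips GAG from the treated surface while leaving collagen uniform.
Confocal Raman microspectroscopy can image these gradients label-free
on hydrated tissue, but the per-pixel spectra are mixtures riding on a
large autofluorescence background, so turning an image cube into
constituent concentration maps requires chemometric unmixing — and that
unmixing needs validation.

## The model

Each pixel spectrum (fingerprint range, 800–1800 cm⁻¹) is modelled as a
non-negative bilinear mixture

```
D = C S + E,    C ≥ 0,  S ≥ 0
```

where `D` (pixels × channels) holds the baseline-corrected spectra,
`S` (k × channels) the pure component spectra, `C` (pixels × k) their
relative concentrations and `E` the residuals. `ramanecm` solves this
by multivariate curve resolution with alternating least squares
(MCR-ALS): exact non-negative least squares alternately on `C`
(pixel-wise) and `S` (channel-wise), rows of `S` held at unit norm, the
residual norm provably non-increasing. Degenerate components (spectral
Pearson r ≥ 0.9) are summed into one; resolved spectra are identified
against reference spectra of the pure biochemicals by optimal
assignment. Water, whose fingerprint signal is weak, is mapped
univariately from the OH stretching band (3100–3600 cm⁻¹). Maps are
laterally averaged into depth profiles, normalized to anchor depths
matching the sectioned-assay protocol, and compared with (emulated)
biochemical assays via R², RMSEP (% of mean) and two-way ANOVA
(technique × depth, type-II sums of squares, α = 0.05). Localized
heterogeneity is the coefficient of variation of pixel concentrations
in a 250 × 250 µm region, in percent.

Because the real tissue data cannot be bundled, the `phantom` module
generates hyperspectral cubes of the three tissue models with known
component spectra, concentration fields (% wet weight, anchored to
measured cartilage ranges), smooth per-pixel fluorescence baselines and
shot-like noise — so recovery can be scored exactly.

## Worked example

```python
from ramanecm.io import PipelineConfig
from ramanecm.pipeline import run_pipeline

result = run_pipeline(PipelineConfig(tissue_model="native", seed=1),
                      outdir="results/native")
print(f"explained variance {result.mcr.explained_variance_total:.2f}%")
print(result.gradients)
print(f"water decrease 0.1->2.5 mm: {result.water_decrease_pct:.1f}%")
```

prints

```
explained variance 99.96%
{'GAG': 'increasing', 'collagen': 'increasing', 'water': 'decreasing'}
water decrease 0.1->2.5 mm: 13.1%
```

i.e. the unmixing explains 99.96% of the variance of the fingerprint
data, the recovered depth gradients match the native-cartilage ground
truth (GAG and collagen rising with depth, water falling), and the
high-wavenumber water profile recovers the 12.5% relative decrease
built into the phantom to within the noise. The output directory holds
the resolved spectra, per-constituent maps and profiles, the
validation table (R²/RMSEP/ANOVA per constituent) and heterogeneity
scores, all as CSV/JSON.

The numbered scripts under `analysis/` run the full study: phantom
generation (`01`), parameter recovery in noiseless and realistic
regimes (`02`), the three tissue-model pipelines (`03`), and water plus
heterogeneity quantification (`04`). Each writes its tables under
`results/`. A `ramanecm` command-line interface wraps the same stages
(`ramanecm run --tissue-model native out/`).

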