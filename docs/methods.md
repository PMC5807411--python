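# Methods

This note records the models, defaults and numerical choices behind
`ramanecm`, and what the synthetic phantoms do and do not establish.

## Forward model and phantom generator

A phantom cube is built as

```
data[r, c, :] = Σ_k  c_k(r, c) · s_k(ν)  +  baseline(r, c, ν)  +  noise
```

* **Component spectra** `s_k` are sums of Gaussian bands at the
  standard cartilage Raman assignments (GAG 1061 cm⁻¹ S=O plus minor
  1158/1380 bands; collagen 836, 875, 1245, 1450, 1672 and 2940 cm⁻¹;
  water: broad OH stretch at 3400 cm⁻¹, σ = 110 cm⁻¹, plus the weak
  1640 cm⁻¹ bending band; an optional cellular component dominated by
  phenylalanine 1004 cm⁻¹). Band amplitudes are per % wet weight and
  fold in effective Raman cross-sections: collagen is set ~4× stronger
  per unit mass than GAG, and water's fingerprint amplitude is tiny
  (0.06). This reproduces the situation in real tissue, where collagen
  dominates the explained variance of fingerprint unmixing even when
  its mass fraction is modest, and water is essentially invisible in
  the fingerprint. Gaussian (not Voigt) lineshapes: linewidth physics
  is irrelevant to recovery testing.
* **Concentration fields** `c_k` are in % wet weight. Tissue-model
  defaults extrapolate measured ranges linearly to the phantom's
  surface and bottom: native GAG 3.3→10.3 %ww between 0.2 and 3.2 mm
  and collagen 4.1→8.2; engineered GAG 7.3→2.8 %ww (0.4–2.6 mm) and
  collagen 0.9→0.2; digested GAG 1.7→6.7 %ww with collagen uniform at
  9.7 %ww. GAG profiles are sigmoid in depth (matrix deposition and
  enzymatic extraction are diffusion-front shaped), collagen linear,
  water linear. The native water profile is scaled to ~80 %ww at the
  surface with its slope solved so the relative decrease from 0.1 mm
  to 2.5 mm is exactly 12.5%. Per-pixel multiplicative lateral
  heterogeneity (CV 5% native/digested, 15% engineered — anchored to
  the observed localized CoV ranges) is applied by default.
* **Identifiability.** All-linear, laterally constant profiles make
  the columns of `C` collinear (rank 2), and a non-negative bilinear
  factorization of such data is rotationally ambiguous no matter how
  good the fit — the noiseless reconstruction can be perfect while the
  factors are mixed. The curvature contrast (sigmoid GAG vs linear
  collagen), the lateral heterogeneity and the cross-section contrast
  together restore enough scatter for the tissue pipelines; the
  dedicated parameter-recovery studies instead use
  `phantom.separated_fields`, which gives every component its own
  depth band (Gaussian bump, amplitude 10 on a 0.05 floor, lateral CV
  15%) so that each component dominates some pixels and the
  factorization is essentially unique.
* **Baseline** per pixel: a broad exponential decay (τ = 1200 cm⁻¹)
  plus a low-order polynomial, amplitudes randomized per pixel around
  an amplitude of 20 (same order as the strongest Raman bands) —
  emulating tissue autofluorescence without modelling photophysics.
* **Noise**: additive Gaussian with σ = floor + 0.02·|signal|
  (shot-noise-like at CCD count levels; 2% is the default study
  condition).
* **Seeding**: one master seed is split into independent substreams
  (fields, baseline, noise, assay), so changing one noise source never
  shifts another; identical parameters and seed reproduce a cube
  bit-for-bit.
* **Sectioned assays** cut the depth into equal slabs (8 for native, 4
  for engineered/digested), take exact slab means of the true fields,
  and perturb multiplicatively with CV 8% — a realistic biochemical
  repeatability, which also keeps correlations well-defined for
  uniform constituents.

What the phantoms do **not** emulate: chondrocyte morphology, confocal
point-spread functions, depth-dependent laser attenuation, collagen
orientation effects (the cause of real degenerate components), and
instrument wavelength error. Passing recovery tests therefore shows
the algorithmic chain is correct and well-conditioned under the stated
conditions, not that any particular instrument will achieve the same
numbers on tissue.

## Baseline estimation

The default `rolling_shape` estimator is an iterative morphological
lower envelope: grey opening (rolling minimum then maximum) over a
wide window, Savitzky–Golay smoothing (order 2) of the opened signal,
and three refinement passes that re-open the residual. Two details
matter numerically:

* plain Gaussian smoothing inflates a convex fluorescence decay by
  ≈ (σ/τ)²/2 — material when the Raman signal is an order of magnitude
  weaker than the background — hence the quadratic-preserving smoother;
* a single opening overestimates the background in dense-peak regions
  where a sloped baseline never meets a signal-free channel at the
  window edge; the residual passes remove this.

The window defaults to 1000 data points of a spectrometer-native
full-range export (~1 cm⁻¹/point over 0–3600 cm⁻¹), i.e. a 1000 cm⁻¹
spectral window, converted to channels of the actual axis via its mean
spacing. Edges are padded by extrapolating a robust lower-quantile
trend so a band sitting at the end of the axis does not drag the pad
upward. An asymmetric-least-squares (Whittaker, λ = 1e5, p = 0.01)
alternative is provided. Residual negatives are kept — non-negativity
belongs to the unmixing factors, not the corrected data.

Known limitation: the OH stretching band is truncated by the 3600 cm⁻¹
end of the axis, so near the edge every local window sees elevated
intensity and part of the band tail is indistinguishable from
background. The captured fraction scales with the band amplitude, so
high-wavenumber water maps remain proportional to water content and
anchored profiles are unaffected; absolute band areas are biased low.

## MCR-ALS

* Non-negativity is enforced on both factors by exact active-set NNLS
  (Lawson–Hanson), with a vectorized fast path: the unconstrained
  least-squares solution is accepted wherever it is already
  non-negative (where it is feasible it is the NNLS optimum), and only
  violating columns fall back to the active-set solver.
* Rows of `S` are renormalized to unit Euclidean norm after each `S`
  update, concentrations rescaled accordingly — fixing the bilinear
  scale ambiguity so concentrations are comparable across components.
* Initialization: `purest_pixel` (deterministic; most intense pixel,
  then greedily the pixel with the largest orthogonal residual to the
  span of those chosen) or `seeded_random`; optionally explicit
  initial spectra. The pipeline initializes from the reference spectra
  of the expected pure biochemicals — the standard chemometric choice
  when references exist, and necessary here because one dominant
  constituent (collagen) otherwise lets ALS settle on blended
  components. The unsupervised purest-pixel path is exercised by the
  separated-field recovery studies.
* Convergence: relative change of the residual Frobenius norm < 1e-6
  or 200 iterations (both configurable); an absolute floor declares
  convergence when the relative residual falls below 1e-7 (exact
  factorization). After the loop one final `C` refresh makes the
  returned `C` exactly the per-pixel NNLS solution against the
  returned `S`. Each half-step is an exact constrained minimizer, so
  the recorded residual history is non-increasing.
* Explained variance: 100·(1 − ‖D−CS‖²_F/‖D‖²_F); per-component
  shares ‖c_k s_k‖²_F/‖D‖²_F are reported separately and need not sum
  to the total (cross terms).
* `merge_degenerate` groups components by pairwise spectral Pearson
  r ≥ 0.9 (transitive closure), sums their maps and takes the
  total-concentration-weighted mean spectrum, renormalized. For exact
  duplicates this leaves the reconstruction unchanged to rounding.
* `match_references` maximizes total Pearson r over one-to-one
  assignments (Hungarian algorithm); surplus components are labelled
  `residual`. References on another axis are linearly resampled.

## Quantification conventions

* Depth of row `r` is `(r + 0.5) · pixel_size / 1000` mm from the
  surface (pixel centres); wavenumber crops are closed intervals,
  pixel ROIs half-open index ranges.
* Normalization schemes mirror the sectioned-assay protocol:
  `peak_anchor` (value at the stated anchor depth, used for
  constituents that increase with depth), `surface_anchor` (topmost
  section), `mean_anchor` (profile mean, for uniform constituents).
  In validation the anchor depth is first resolved to the nearest
  assay section mid-depth so both series are anchored at the same
  physical position.
* `to_absolute` rescales a relative profile so its depth average
  equals the bulk assay mean (% wet weight); a `direct` multiplication
  mode exists because the alternative reading of the protocol is
  defensible.
* Water: trapezoidal band integral over 3100–3600 cm⁻¹ per pixel
  (single-channel mode at ~3400 cm⁻¹ available); negative integrals on
  near-zero pixels are clipped to zero with a warning. Gradient
  magnitudes between two depths are measured on ±0.1 mm windows of the
  laterally averaged profile — unbiased for locally linear profiles
  and robust to single-row noise.
* CoV is 100·sd/mean with sample (n−1) sd, over the ROI pixel block;
  reported in percent.
* Gradient classification fits a line to the dense profile and calls
  a direction only when the slope is significant (p < 0.05) *and* the
  fitted change across the depth exceeds 10% of the profile mean;
  otherwise the profile is uniform. The effect-size condition keeps
  the label stable where a test of exact zero slope would fire on
  noise.

## Validation statistics

R² is the squared Pearson correlation (matching the "correlation
coefficient" usage); RMSEP is 100·√mean((pred−obs)²)/mean(obs). The
two-way ANOVA uses statsmodels OLS with type-II sums of squares,
factors technique (Raman vs assay) and depth section; the interaction
is included only when replicates exist (with one observation per cell
it is the residual). All-equal responses return zero sums of squares
and p = 1. Agreement between techniques appears as a non-significant
technique effect at α = 0.05; note that under exact agreement the
technique p-value is uniform, so a 5% false-flag rate is intrinsic to
that check.

## Problem sizes and defaults

Full acquisition geometry is ~3500 × 1000 µm at 10 µm pixels
(350 × 100); the package default is a reduced geometry with identical
tissue depth at 50 µm pixels (70 × 20 native) and a 350–3600 cm⁻¹ axis
at 5 cm⁻¹ spacing, which keeps a complete pipeline run to a couple of
seconds while preserving every physical scale (anchor depths, ROI
sizes, section counts). Recovery studies use 60 × 20 px cubes with 500
fingerprint channels. The pipeline default is k = 4 with merge
threshold 0.9, fingerprint fit range 800–1800 cm⁻¹, water band
3100–3600 cm⁻¹.

## Known limitations

Rotational ambiguity is handled by study design and reference
initialization, not analyzed (no MCR-BANDS); equality constraints from
known spectra are not implemented. Collagen-orientation splitting is
only emulated abstractly (via duplicated components in tests). The
absolute scale of concentrations is arbitrary until anchored to an
assay mean. Water quantification near the axis edge inherits the
truncation bias described above.
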