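# Methods

`wheatspad` is a tested re-implementation of a UAV-multispectral workflow
for predicting winter-wheat SPAD (relative chlorophyll) at the booting
stage. Because the original field imagery and SPAD measurements are not
public, the package ships a synthetic-data generator that reproduces the
experiment's *structure* — the 72-plot split-plot design, the five-band
sensor, the ground-sampling-distance (GSD) ladder, the SPAD sampling
protocol — together with a known, monotone SPAD→reflectance forward model,
so that every downstream stage (resampling, feature extraction, selection,
regression, evaluation) is exercised end to end against ground truth.

## Synthetic scenes

**Design.** Experiment 1: 4 nitrogen rates (0/150/240/330 kg/ha, main
plots) × 4 varieties (YM22/YM25/YM39/NM26, subplots) × 3 replicates = 48
plots. Experiment 2: 2 varieties × 4 fertilizer application methods
(M1–M4) × 3 replicates = 24 plots at 240 kg/ha. Plots are 3 m × 4 m
(12 m²) with 25 cm row spacing, laid on a 12-column grid with 0.5 m alleys;
the seed randomizes which grid position each plot occupies, never the
factorial structure.

**True SPAD.** Additive treatment model
`spad = μ0 + variety offset + method offset + f(N) + N(0, σ_plot)`,
truncated to the 0–99.9 meter range. Defaults: μ0 = 44 SPAD, variety
offsets −1…+2, method offsets 0…0.8, f linear spanning 10 SPAD units over
0–330 kg/ha, σ_plot = 1. These were chosen once so the plot-mean SPAD
(≈ 49) and between-plot SD (≈ 3–4) sit where a booting-stage nitrogen
trial's measured values plausibly sit (a mean near 49 and SD near 3.2 are
what the reported relative errors of such trials imply). Truncation, not
resampling, handles values pushed outside physical ranges: simpler and
directly testable.

**Measured SPAD.** The field protocol is simulated literally: 5 sampling
points × 10 flag leaves × 3 reads per leaf. Per leaf
`value = spad + N(0, leaf_sd)` (default 1.5 SPAD); each read adds
`N(0, meter_sd)` (default 0.5 SPAD, bounded above by the SPAD-502Plus
±1.0-unit accuracy); the plot's measurement is the mean over the 50
per-leaf read means. With leaf_sd = 2 the SD of (measured − true) is
2/√50 ≈ 0.283, which the tests verify against the standard-error formula.

**Reflectance forward model.** Vegetation reflectance per band is
`ρ_b(SPAD) = a_b·exp(−SPAD/k_b) + c_b` — monotone, bounded, and cheap.
Red/green/blue decrease with SPAD (chlorophyll absorption); the red edge
decreases gently; NIR uses a negative `a_b` with a dominant plateau
`c_b = 0.62`, so it mildly increases. Soil is a fixed bright spectrum
(0.10/0.16/0.22/0.26/0.30 for B/G/R/RE/NIR), brighter in red than
vegetation. Within a plot, pixels are vegetation when their position
within the 25 cm row period falls below the plot's canopy cover, itself
linear in nitrogen rate (0.60 + 0.0009·N, clipped to [0, 1]) — this
couples soil exposure to treatment, reproducing the soil-background
confound of sparse canopies. Per-band Gaussian pixel noise (SD 0.01
reflectance) is added and the result clipped to [0, 1].

This generator is *not* a radiative-transfer model: no BRDF, no
illumination variation, no leaf-angle or multiple-scattering effects, no
within-plot SPAD gradients. Passing tests therefore demonstrate that the
pipeline machinery recovers a recoverable signal and preserves the stated
structural invariants — not that the specific accuracy figures transfer to
real canopies.

## Altitude simulation

GSD scales linearly with altitude at fixed optics: 1.06 cm/px at 20 m
gives 2.12 at 40 m and 3.18 at 60 m (the package reports 2-decimal
half-up roundings; internally full precision is kept). Higher altitudes
are emulated by nearest-neighbor resampling only — no blur, vignetting or
BRDF change — matching the resolution-only degradation of the original
workflow. The resampler maps each output pixel center into source
coordinates and copies the nearest source pixel, with halfway ties broken
toward the smaller index (a frozen, documented convention); output band
value sets are therefore always subsets of the input's, and the plot mask
is resampled with the identical index map.

## Features

**Vegetation indices (22).** The five plot-mean band reflectances plus 17
derived indices, with constants L = 0.16 (OSAVI) and a = 0.12 (WDRVI).
Two formulas intentionally follow the source workflow rather than common
convention: EVI = 2.5(NIR−R)/(1+NIR−2.4R) without a blue term, and
OSAVI = (NIR−R)/(NIR−R+L); NDREI here is (RE−G)/(RE+G). Indices are
computed from plot-mean reflectance (mean-then-index); per-pixel-then-mean
is available as an option. Zero denominators yield NaN plus a per-index
error record, never an exception; downstream matrices drop non-finite
columns with a logged warning.

**GLCM texture (40).** Eight Haralick metrics (mean, variance,
homogeneity, contrast, dissimilarity, entropy, angular second moment,
correlation) per band. Bands are min–max quantized to 64 gray levels over
the full raster (64 matches the common remote-sensing default; the
workflow being emulated does not state it). For every pixel whose 7×7
window lies entirely inside the plot mask — windows straddling plot
boundaries would mix neighboring treatments — the co-occurrence matrix of
the 25 ordered pairs at displacement (+2 columns, +2 rows) is summarized,
and the plot feature is the mean over windows. Non-symmetric counting is
frozen (the symmetric variant is a flag). Conventions: natural-log entropy
with 0·ln 0 = 0; correlation := 1 for zero-variance windows, preventing
NaN propagation from constant texture. The implementation never builds
per-window matrices: moment metrics are integral-image block sums of
per-pair images, and entropy/ASM come from run lengths of each window's
sorted pair codes; tests verify exact (1e-10) agreement with a brute-force
double loop.

**Wavelet features (20).** One 2-D analysis level of the biorthogonal 1.3
wavelet (6-tap analysis low-pass, symmetric boundary extension, via
PyWavelets) yields LL/LH/HL/HH sub-images per band. The scalar per
(band, sub-band) is the mean coefficient over the plot footprint mapped to
the sub-band grid by nearest neighbor (mean |coefficient| optional for
detail bands) — consistent with how the other feature families aggregate
per plot. The analysis low-pass has DC gain √2 per axis, so a constant
band of value c gives LL ≡ 2c and zero detail; perfect reconstruction
through the synthesis pair holds to 1e-8 on random rasters.

## Selection and models

**RFE-CV.** Features are ranked by recursive elimination (step 1) using
random-forest impurity importance inside a standardize→forest pipeline;
the learning curve scores every retained size 1..p by mean 5-fold CV R².
The retained size is the curve argmax with ties toward the smallest n
(a one-standard-error rule is available). The forest uses 100 trees by
default: at 72 plots the impurity ranking is stable at this size, and it
keeps a full study grid tractable on a single core; the size is a
parameter for users who want larger ensembles.

**Regressors.** Ridge (penalty 1e-3…1e3), random forest (100–500 trees ×
depth ∅/5/10), RBF-SVR (C 0.1–100, γ = scale-heuristic ×0.1/1/10,
ε 0.01–0.5), and a one-hidden-layer MLP (8/16/32 units, logistic or ReLU,
2000-iteration cap, seeded init) — the latter grids are declared stand-ins,
since the emulated workflow names the model families but not their search
spaces. All are fitted by exhaustive grid search scored by 5-fold CV R²
and refitted on the full training set. Standardization lives inside the CV
pipeline (train-fold statistics only); the forest takes raw features.
The 8:2 train/test split rounds the test size half-up (72 → 58/14) —
documented because 72·0.2 = 14.4 is ambiguous.

**Metrics.** RMSE = √(Σ(ŷ−y)²/n); RRMSE = RMSE/ȳ; RPD = SD/RMSE with SD
the (n−1)-denominator sample SD of the *measured* values on the evaluated
partition (the chemometric convention; residual-SD is a flag). Two R²
forms are kept: the conventional 1 − SSE/SST (headline) and the
explained-variance ratio Σ(ŷ−ȳ)²/Σ(y−ȳ)² that some reports print — they
differ whenever predictions are biased or shrunk, so neither is silently
"corrected" into the other.

## Studies and reproducibility

The altitude study extracts VIs at each of 20/40/60/80/100/120 m
(resampling the one rendered base scene, not re-rendering); the
variable-set study compares the 7 sets (VIs, TIs, DWT and their unions)
at 20 m. Both use a single shared 8:2 split per study (per-cell
resplitting is a flag), re-run selection per cell on training plots only,
and record seed, config hash and the selected feature list in every output
row. A failing cell is logged and skipped, not fatal. All randomness
derives from one master seed through a seed sequence, so rerunning a study
reproduces its CSV byte for byte.

**Problem sizes.** VIs-only runs use the full 1.06 cm/px baseline (plot
means are cheap at any resolution). Texture extraction is the one heavy
stage (≈ 7 million windows per band at 1.06 cm/px); the shipped tests and
the acceptance script therefore exercise the variable-set study at a 4
cm/px working resolution (≈ 6 × 10³ windows per plot-band, ~5 s for all
72 plots), which preserves every structural property being checked. Full
resolution remains a parameter change.

## Known limitations

- The forward model is a stand-in; absolute accuracy figures obtained on
  synthetic scenes say nothing about field accuracy, and the reported
  per-altitude/per-set orderings of the original field study are not
  asserted (only the weak expectation that pooling all three families is
  not substantially worse than the weakest single family).
- Resampling emulates resolution loss only; real altitude changes also
  alter optics and atmospheric path.
- The GLCM displacement convention ("direction (2,2)" read as +2 columns,
  +2 rows, non-symmetric) and the nearest-neighbor tie rule are frozen
  choices where the emulated workflow is silent; both are isolated behind
  configuration.
- Scene rasters carry no geographic referencing (plain multiband TIFF +
  JSON sidecar with GSD/altitude/band order); plot geometry lives in scene
  coordinates (meters).
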