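# wheatspad

Predicting winter-wheat canopy SPAD (relative chlorophyll) from UAV
multispectral imagery, as a tested, fully synthetic-reproducible pipeline.

The scientific question: can SPAD at the booting stage — the growth stage
where prediction is notoriously hardest — be predicted as well from
high-altitude UAV imagery (coarse ground sampling distance, GSD) as from
the usual 20 m flights, and which predictor families carry the signal?
The workflow compares six flight altitudes (20–120 m, GSD 1.06–6.35
cm/px, simulated by nearest-neighbor resampling), seven predictor-variable
sets — 22 vegetation indices (VIs), 40 GLCM texture indices (TIs,
7×7 window, (2,2) displacement), 20 discrete-wavelet features (bior 1.3,
LL/LH/HL/HH per band), and their unions — and four regressors (ridge,
random forest, SVR, BP neural network), each grid-searched and evaluated
on a held-out 20% of plots with

    R² = 1 − Σ(ŷᵢ−yᵢ)²/Σ(yᵢ−ȳ)²,   RMSE = √(Σ(ŷᵢ−yᵢ)²/n),
    RRMSE = RMSE/ȳ,                 RPD = SD(y)/RMSE.

Because the original field data are not public, the package includes a
first-class synthetic-data module: a 72-plot split-plot nitrogen ×
variety trial, a monotone SPAD→reflectance forward model with a
soil/vegetation row-stripe mixture, and a simulation of the five-point /
50-flag-leaf SPAD-meter protocol. Every stage is tested against
independent oracles (brute-force GLCM, wavelet perfect reconstruction,
exhaustive nearest-neighbor index maps, closed-form regression fits).
See `docs/methods.md` for the model details and limitations.

## Worked example

```python
import wheatspad as ws

cfg = ws.ExperimentConfig(seed=1)
design, spad, scene = ws.generate_dataset(cfg)   # 72 plots @ 1.06 cm/px
print(len(design), scene.gsd_cm)                 # 72 1.06

print(ws.gsd_for_altitude(40, rounded=True))     # 2.12  (cm/px at 40 m)
print(ws.gsd_for_altitude(60, rounded=True))     # 3.18

rec = ws.compute_metrics([40, 42, 44], [41, 42, 43])
print(round(rec.rmse, 4), round(rec.rpd, 4), rec.r2)
# 0.8165 2.4495 0.75

result = ws.vis_pipeline_run(seed=1)   # 20 m, VIs set, ridge + SVR
print(round(result["best"], 3), round(result["best_rpd"], 2))
# 0.99 10.43
```

The last two numbers are the held-out test R² and RPD of the better of
ridge/SVR on the VIs set at 20 m: on these synthetic scenes the SPAD
signal is strong by construction (plot reflectance is a clean monotone
function of SPAD plus mild noise), so R² near 0.99 says the pipeline
recovers a recoverable signal — a machinery check, not a field-accuracy
claim. A label-permuted control run of the identical pipeline lands near
R² ≈ 0 (−0.02 at this seed).

Command-line equivalents (see `wheatspad --help`): `synth`, `resample`,
`features`, `select`, `train`, `evaluate`, `run-altitude-study`,
`run-variable-study`.

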