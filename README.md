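# rotospec

Electrorotation (EROT) spectroscopy of single cells: forward dielectric
shell models, spectrum fitting, model selection, rotation tracking from
video, and cohort-level comparison of dielectric phenotypes.

## The problem

A cell suspended in a rotating AC electric field acquires an induced dipole
that lags the field, producing a frequency-dependent torque. At steady
state against Stokes drag the angular velocity is

    u(f) = - (ε_m / 2η) · Im K_CM(f) · E_rms²

where ε_m is the absolute permittivity of the medium, η its viscosity, and
K_CM the Clausius–Mossotti factor

    K_CM = (ε_p* − ε_m*) / (ε_p* + 2 ε_m*),   ε* = ε ε₀ − j σ/ω.

The cell's effective complex permittivity ε_p* comes from concentric
smeared-shell models: a **single-shell** cell (conductive cytoplasm wrapped
in a thin, poorly conducting membrane) or a **double-shell** cell (adding a
nucleoplasm core inside a nuclear envelope). Fitting the measured rotation
spectrum u(f) over 3 kHz – 10 MHz recovers the identifiable electrical
phenotype of each cell:

* specific membrane capacitance  C̄_mb = ε_mb ε₀ / t  (F/m²),
* specific membrane conductance  Ḡ_mb = σ_mb / t  (S/cm²),
* cytoplasm conductivity  σ_cp  (S/m).

These phenotypes shift systematically with cell state — for example with
increasing malignancy in staged ovarian-cancer cell panels — so the
pipeline supports cohort-level statistical comparison (one-way ANOVA gate,
pairwise Welch t-tests, kernel-density summaries).

The package is aimed at experimentalists running quadrupole EROT chambers
and at method developers who need a tested forward model, two independent
fitting routes, and a fully synthetic test bed.

## What is inside

| Module | Contents |
| --- | --- |
| `rotospec.shell_models` | complex permittivities, K_CM, single/double-shell recursions, torque and velocity |
| `rotospec.fitting` | bounded Levenberg–Marquardt and parallel-tempered ensemble-MCMC estimators (scikit-learn API), SSR / AIC / reduced χ², AIC model selection, pooled cohort fits |
| `rotospec.sampling` | replica-exchange layer over `emcee` ensembles |
| `rotospec.tracking` | video pipeline: temporal-median background subtraction, Otsu segmentation, moment ellipse fit, 180°-ambiguity unwrapping, mean angular velocity |
| `rotospec.synthetic` | cohort and rotating-ellipse video generators with ground truth |
| `rotospec.cohort_stats` | derived parameters, ANOVA → t-test comparison, KDE summaries |
| `rotospec.io`, `rotospec.config`, `rotospec.pipeline`, `rotospec.cli` | CSV/TIFF/JSON formats, TOML config, end-to-end driver, `rotospec` CLI |

## Worked example

Fit a noisy synthetic spectrum of a late-stage-like cell (membrane
ε_mb = 30, σ_mb = 52 µS/m, t = 4 nm; cytoplasm ε_cp = 45, σ_cp = 1 S/m;
R = 6 µm) and derive its phenotype:

```python
import numpy as np
from rotospec import (DielectricMaterial, SingleShellCell, FieldConfig,
                      RotationSpectrum, DEFAULT_MEDIUM, predict_spectrum,
                      fit_lm, derive_params)

cell = SingleShellCell(radius=6e-6, membrane_thickness=4e-9,
                       membrane=DielectricMaterial(30.0, 52e-6),
                       cytoplasm=DielectricMaterial(45.0, 1.0))
field = FieldConfig.log_spaced(3e3, 10e6, 20)          # E_rms = 14 kV/m
spectrum = predict_spectrum(cell, DEFAULT_MEDIUM, field)

rng = np.random.default_rng(0)                          # 5% peak noise
noisy = spectrum.velocities + rng.normal(0, 0.05 * spectrum.peak_speed, 20)
observed = RotationSpectrum("demo", "MOSE-L", 6e-6,
                            spectrum.frequencies, noisy)

result = fit_lm(observed, seed=1)
derived = derive_params(result)
print(f"SSR      : {result.ssr:.2f} (rad/s)^2 over {result.n_points} points")
print(f"C_mb     : {derived.c_mb:.4f} F/m^2")
print(f"G_mb     : {derived.g_mb_S_per_cm2:.2f} S/cm^2")
print(f"sigma_cp : {derived.sigma_cp:.2f} S/m")
```

prints

```
SSR      : 4.32 (rad/s)^2 over 20 points
C_mb     : 0.0634 F/m^2
G_mb     : 1.31 S/cm^2
sigma_cp : 0.98 S/m
```

The generating values are C̄_mb = 0.0664 F/m², Ḡ_mb = 1.30 S/cm²,
σ_cp = 1.0 S/m: at 5% measurement noise the identifiable derived
parameters come back within a few percent. (Only the ratios C̄_mb and
Ḡ_mb are identifiable — ε_mb and t individually are not.)

The same analysis runs from the shell:

```bash
rotospec simulate --seed 1 --out-dir data/
rotospec fit data/spectra.csv --model both --method lm --out-dir fits/
rotospec run --config examples/demo_config.toml     # full pipeline
```

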