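# Methods

This note documents the models, numerical choices and limitations of
`rotospec`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Forward model

**Electrorotation velocity.** The time-averaged torque on a polarizable
sphere in a rotating field is `⟨T_E⟩ = −4π ε_m R³ Im(K_CM) E_rms²` in the
dipole limit; balancing against rotational Stokes drag `⟨T_D⟩ = 8π η R³ u`
gives `u = −(ε_m / 2η) Im(K_CM) E_rms²`. Two conventions matter:

* `ε_m` is the **absolute** medium permittivity (`80 ε₀` for the default
  aqueous buffer). With the relative value the expression would not have
  units of 1/s. At the reference constants (ε_m,rel = 80, η = 0.89 mPa·s,
  E_rms = 14 kV/m) the prefactor is 78.0 rad/s per unit |Im K_CM|.
* Positive `u` is co-field rotation, i.e. `Im(K_CM) < 0`. All interfaces
  accept frequency in Hz; `ω = 2πf` is internal.

**Shell models.** A shelled sphere is replaced inside-out by equivalent
homogeneous spheres (Maxwell–Wagner mixing). The single-shell form

    ε_p* = ε_mb* (v0 + 2X)/(v0 − X),  X = (ε_cp* − ε_mb*)/(ε_cp* + 2ε_mb*),
    v0 = (R/(R−t))³

is algebraically identical to the volume-fraction form used at each level
of the double-shell recursion (the test suite cross-checks both forms to
12 significant digits). The double-shell recursion mixes nucleoplasm into
the nuclear envelope (fraction v3), the effective nucleus into cytoplasm
(v2), and the interior into the membrane (v1). The middle level carries
the prefactor ε_nb*/ε_cp* — the (effective nucleus)/(cytoplasm)
permittivity ratio — which is the unique choice under which a nucleus made
of cytoplasm material drops out exactly and the double-shell model reduces
to the single-shell model (verified to ≤1e−10 relative over 10³ random
parameter draws). Higher-order multipole corrections, traveling-wave
effects and frequency-dependent layer properties are out of scope.

## Parameter space and identifiability

Free parameters and bounds (SI):

| name | bounds | scale | meaning |
| --- | --- | --- | --- |
| ε_mb | [1, 30] | linear | membrane relative permittivity |
| σ_mb | [1e−12, 1e−3] S/m | log10 | membrane conductivity |
| ε_cp | [45, 125] | linear | cytoplasm relative permittivity |
| σ_cp | [0.01, 2.0] S/m | linear | cytoplasm conductivity |
| t | [4, 40] nm | linear | membrane thickness |
| ε_nb | [1, 100] | linear | nuclear-envelope permittivity |
| σ_nb | [1e−5, 1e−1] S/m | log10 | nuclear-envelope conductivity |
| ε_np | [45, 125] | linear | nucleoplasm permittivity |
| σ_np | [0.01, 2.0] S/m | linear | nucleoplasm conductivity |
| t_n | [20, 80] nm | linear | nuclear-envelope thickness |

The first five are the standard physiological ranges for mammalian cells;
the nuclear-layer bounds are the package's own choices from standard
dielectric-spectroscopy values (the nuclear envelope is porous, hence far
more conductive than the plasma membrane; its two lipid bilayers make
t_n ≈ 40 nm typical). Conductivities spanning many decades are optimized
and sampled in log10; a linear-uniform treatment of a nine-decade range
would make physiological values (~1e−5 S/m) an unreachable sliver of the
space.

The cell radius is measured per cell and never fitted. The nucleus radius
is tied to the cell: `R_n = nucleus_ratio · (R − t)` with per-cohort
ratios (defaults 0.67 / 0.59 / 0.68 for the three bundled cohorts).

**Identifiability.** For t ≪ R a rotation spectrum constrains only the
ratios C̄_mb = ε_mb ε₀/t and Ḡ_mb = σ_mb/t, not ε_mb and t individually
(the membrane enters almost exclusively through its per-area admittance).
All recovery tests and reports therefore assert C̄_mb, Ḡ_mb and σ_cp,
never raw membrane parameters. ε_cp is weakly identified below ~10 MHz.

## Levenberg–Marquardt fitting

The objective is the unweighted SSR between observed and predicted
velocities. LM itself is unconstrained, so each free coordinate is mapped
onto its (possibly log10) range with a logistic transform; the optimizer
works on the whole real line while every iterate stays inside bounds.

Start policy: the range midpoint (or a caller-supplied start), plus the
best `n_restarts = 4` candidates of a seeded 64-point Latin-hypercube
screen evaluated in a single vectorized forward call. The screen costs
about one LM iteration and removes a failure mode in which all plain
restarts die on logistic-saturation plateaus (without it roughly 40% of
noisy fits stalled far above the noise floor; with it, 0 of 42 in the
bundled study and median derived-parameter errors of ~3% at 5% noise).
The lowest-SSR polish wins; ties go to the earliest start. Tolerances are
xtol = ftol = gtol = 1e−14, which is what lets a noise-free synthetic
spectrum be reproduced to SSR < 1e−12 · (peak velocity)² even when the
generating values sit on the boundary of the box.

## Ensemble MCMC

The sampler is the affine-invariant stretch move (via `emcee`) with a
replica-exchange layer implemented in `rotospec.sampling`: one ensemble
per temperature on a geometric ladder `T_l = ratio^l` (default ratio 2),
per-walker configuration swaps between adjacent rungs after every joint
step, standard acceptance `exp((β_i − β_j)(logL_j − logL_i))`. Only the
cold chain is recorded. Defaults: 20 walkers, 5 temperatures, 10 000
steps, no burn-in discarded (the tempered ensemble forgets its uniform
initialization quickly, and the point estimate is a maximum, not an
average). The walker count is raised automatically to 2×(dimension) when
a model needs it (the stretch move requires it; the 11-dimensional
double-shell posterior runs with 22 walkers).

Likelihood: Gaussian iid residuals with the noise SD as a nuisance
parameter, log-uniform over [1e−6, 10] × max|u|. Priors: independent
uniform on each sampling-scale coordinate (so log-uniform for the two
wide conductivities). A `prior_only` switch replaces the likelihood by a
constant for calibration runs; the marginal means then reproduce the box
midpoints.

The point estimate is the maximum-posterior sample — comparable to an LM
local optimum, and on noise-free data the two routes agree on C̄_mb to
better than 2% at a reduced budget (20 walkers, 3 temperatures, 2000
steps). Full posterior samples are returned for uncertainty reporting.

## Fit quality and model selection

* `SSR` — unweighted, in (rad/s)².
* `reduced χ² = SSR / (σ_noise² (n − k))`, with σ_noise² taken from the
  residual variance of the best fit unless the true value is supplied.
  With the true noise variance its long-run mean is ~1 on
  correctly-specified synthetic data.
* `AIC = 2k − n·log SSR` (natural log; the base is configurable). Note
  the sign: this published form *decreases* with growing SSR, which is
  the opposite of the standard Gaussian-residual criterion
  `2k + n·ln SSR`. For nested fits optimized so that SSR_double ≤
  SSR_single the two forms select identically — the 2Δk parameter
  penalty decides — and `rotospec.fitting.aic` keeps the published form
  for comparability. To guarantee that nesting numerically,
  `fit_both_models` warm-starts the double-shell fit from an embedding of
  the single-shell optimum (nucleoplasm ← cytoplasm values, envelope thin
  and maximally conductive). On single-shell-generated data this selects
  the single-shell model essentially always, with a relative probability
  for the double-shell model below exp(−5) ≈ 0.7%.
* Ties select the fewer-parameter model and are flagged.

Both per-cell and pooled (one parameter set per cohort, per-cell radii,
concatenated residuals) fitting modes are provided.

## Rotation tracking

Pipeline: per-pixel temporal-median background subtraction → Otsu
threshold of |residual| → largest connected component (rejected if
< 25 px or solidity < 0.8, which discards percolating noise speckle) →
image-moment ellipse → orientation in [0°, 180°) → per-step ambiguity
resolution (minimum-|Δ| representative of Δ mod 180°) → centered moving
average (default window 5, odd) → mean velocity from the unwrapped trace.

Constraints and guards:

* Orientation is 180°-periodic, so apparent rates ≥ 90°/frame alias
  irrecoverably; the video generator refuses them and the tracker raises
  once increments reach an 85°/frame guard rather than report an alias.
* Near-circular fits (axis ratio < 1.05) carry no orientation; such
  frames are bridged by linear interpolation of the unwrapped angle.
* A motionless scene defeats temporal-median subtraction (residual ≈ 0);
  the tracker then falls back to segmenting the raw frames, so a static
  object correctly yields zero velocity.
* The temporal median is only an unbiased background estimate once the
  cell sweeps a full half-turn; slow rotations need proportionally longer
  sequences (the 15 s protocol at 30 fps covers 2°/frame comfortably).

The synthetic fixture rotates an anti-aliased ellipse rigidly about the
frame centre with its centroid offset 14 px along the minor axis,
mimicking the slightly eccentric rotation of a trapped cell; this offset
is also what keeps every pixel background-dominated in the median. Round
trips at SNR 5 recover 2–60°/frame within 0.1%, crossing the 180° wrap.

## Synthetic cohorts

`generate_cohort` draws per-cell shell parameters from truncated normal
distributions clipped to the fitting bounds, evaluates the forward model
on 20 log-spaced frequencies over 3 kHz – 10 MHz, and adds Gaussian noise
with SD = 5% of that cell's peak speed (all defaults configurable). The
three bundled cohort presets (14, 15 and 13 cells) encode published
per-cell phenotype statistics — σ_cp 0.78/1.01/1.31 S/m, Ḡ_mb
0.71/1.37/1.62 S/cm², C̄_mb 0.051/0.063/0.065 F/m² (means, with matching
SDs) — mapped to primitive parameters at fixed t = 4 nm, which loses
nothing because only the derived ratios are identifiable. Radii
(8.0/6.5/6.3 µm means) and ε_cp centers (68/80/91) are package choices
consistent with the staged-malignancy phenotype.

What the generator does *not* emulate: Brownian wobble, levitation-height
and field inhomogeneity (E_rms is constant per run), cell-to-cell optical
texture, membrane dispersion. Passing tests demonstrate correctness of
the analysis chain under the stated noise model, not robustness to every
artifact of real recordings.

**A statistical caveat the test suite surfaces deliberately:** with the
bundled cohort statistics, the specific-capacitance ordering between the
two most malignant cohorts is not resolvable at n ≈ 13–15. Their means
differ by 0.002 F/m² while the most aggressive cohort's SD is 0.056 F/m²,
and the physical bound C̄_mb ≤ 30 ε₀ / 4 nm ≈ 0.066 F/m² truncates that
cohort's realized mean below the other's. The replicate-study ordering
check therefore reports ~90% ordering success for σ_cp, ~80–85% for
Ḡ_mb, and ~0% for C̄_mb; the corresponding acceptance test is expected
to fail for C̄_mb and is intentionally left failing, because it reflects
a real power limit of the study design, not a defect of the estimator.

## Cohort statistics

One-way ANOVA per derived parameter gates (α = 0.05) all pairwise
unpaired t-tests; Welch's form is the default because cohort variances
differ several-fold. No multiple-testing correction is applied by default
(matching the reporting scheme this pipeline mirrors); Holm–Bonferroni is
available. Significance tiers: * p<0.01, ** p<0.001, *** p<0.0001. Under
the null the pairwise test's type-I rate calibrates to 5% ± 2%, and at a
3-SD mean separation with n = 15 per group the ANOVA gate's power exceeds
95%. KDE summaries use a Gaussian kernel with Scott's bandwidth.

## Reproducibility

Every stochastic component takes an explicit seed: generators,
Latin-hypercube screens, samplers, swap decisions. The pipeline driver
writes a manifest with the package version, the seed and a hash of the
scientific configuration (output paths excluded); reruns are
byte-identical. Problem sizes in the test suite and acceptance script —
50-cell recovery cohorts, 100-spectrum selection runs, 50 replicate
studies at n = 14/15/13, the reduced MCMC budget of 20 walkers × 3
temperatures × 2000 steps — are the package's chosen desk-scale study
conditions; all thresholds were fixed with the study design, not tuned to
outcomes.
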