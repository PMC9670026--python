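# Methods

## Binding model

Each IgG species binds the immobilised Protein A surface with reaction-limited
pseudo-first-order 1:1 Langmuir kinetics. During association at molar analyte
concentration C,

    dR/dt = k_on · C · (R_max − R) − k_off · R
    R(t)  = R_eq (1 − e^{−(k_on C + k_off) t}),   R_eq = R_max C / (C + K_D)

and during dissociation R(t) = R₀ e^{−k_off t}, with K_D = k_off / k_on.
Avidity is not modelled mechanistically: an aggregate is one analyte species
with its own *effective* rate constants, and the multivalent interaction is
visible only as its smaller effective k_off (and hence K_D) at mildly acidic
pH. Mass-transport limitation, bivalent rebinding and two-state
conformational models are out of scope.

Assumptions worth stating explicitly:

* concentrations are molar; mass concentrations (mg/mL) are converted by the
  species molar mass, and an aggregate (dimer by default, 3.0×10⁵ g/mol vs
  1.5×10⁵ for the monomer) counts as **one** analyte — at equal mass a dimer
  solution has half the particle molarity, which changes how its k_on is to
  be read;
* the analyte concentration at the surface is constant during association
  (flow-cell excess) and exactly zero during dissociation;
* the baseline is zero and the surface starts empty (regeneration between
  injections is assumed perfect and not simulated).

### Shipped rate constants

`aggsense.presets` ships published per-pH Langmuir-fit rate constants for
human IgG1 monomers and aggregates on Protein A chips (pH 7.4, 4.0, 3.8,
3.5). K_D is always recomputed as k_off/k_on; a separate table of the
printed, 2-significant-figure K_D values is retained only for cross-checks.
At pH 7.4 both species bind essentially irreversibly on the 300 s timescale
(k_off = 2.9×10⁻⁵ s⁻¹); at pH 3.8–4.0 the aggregate k_off is ~4× lower than
the monomer's, the contrast the entire quantification strategy exploits.

## Injection protocol and landmarks

Default timing: baseline 0–10 s, association 10–110 s, dissociation
110–300 s, sampled at 1 Hz. The two scalar landmarks used throughout are the
response at the protocol end ("r_300") and the smoothed derivative at
dissociation start + 2 s ("d_112" under the default timing); both generalise
to protocols with other timings. The real instrument's injection plumbing
(sample-loop volume, dispersion) is deliberately not modelled; timing is a
parameter, not an inference.

## Synthetic data

`synthetic.generate_design` produces three canned designs with ground truth:

| design | layout | purpose |
|---|---|---|
| `fig3_levels` | 9 aggregate levels 1–98 % at 0.45 mg/mL | level trends |
| `fig4_grid` | the 9 levels × totals {0.1125, 0.25, 0.45} mg/mL = 27 train + 7 controls | calibration |
| `fig5_lowrange` | 13 levels 1–20 % × 5 totals = 65 traces, 51 train / 14 validation | network regression |

The 1 % floor is kept even for "monomer" samples because purified monomer
fractions retain about that much aggregate. Intermediate levels of the grids
are package defaults (the source experiments print only the endpoints). The
seven controls sit at aggregate concentrations 3.4–100 µg/mL, inside the
calibration's usable range, with one deliberately below the detection limit.
The validation split of `fig5_lowrange` is a seeded stratified hold-out over
aggregate level. All per-sample noise seeds derive from one design seed via
`SeedSequence`, so a design is byte-reproducible from a single integer.

Noise model (defaults): additive white Gaussian noise σ = 2 pm; a −10 pm
bulk refractive-index jump confined to the association window; optional
linear drift (0 pm/s by default). Real sensorgrams additionally contain
drift, regeneration artefacts, chip-to-chip R_max variation and correlated
noise, none of which are emulated — passing tests therefore demonstrate
correctness of the *analysis* under the stated model, not instrument-grade
robustness.

### Mixtures: independent vs competitive binding

The default mixture model is **independent**: each species binds its own
sites and the noiseless mixture trace is exactly the pointwise sum of the
single-species traces. This keeps the generative model linear in the species
and makes ground-truth decomposition trivial, but it has a known consequence:
at 0.45 mg/mL the concentrations are far above the per-species K_D, so both
species saturate independently and a 50/50 mixture can reach nearly twice
the single-species R_max. Real chips have one shared capacity. Therefore,
under the independent default, (i) the endpoint r_300 is *not* strictly
monotone in aggregate fraction above ~60 % aggregate, (ii) the pH 7.4
endpoint spread across levels is large rather than small, and (iii) the
varying monomer tail across totals limits the cross-total endpoint
calibration (see below).

`simulate_mixture(..., interaction="competitive")` provides the
shared-capacity alternative, solving the linear system
dR_i/dt = k_on,i C_i (R_max − Σ_j R_j) − k_off,i R_i in closed form by
eigendecomposition. It caps the total response at R_max, reproduces the
qualitative single-chip observations (near-identical saturating responses of
monomers and aggregates at pH 7.4; strictly monotone r_300 and d_112 across
all nine levels at pH 3.8, with early-dissociation derivatives running from
≈ −8.8 pm/s at 1 % aggregate toward 0 at 98 %), and reduces to the additive
model in the dilute limit. It is intentionally *not* the design default:
the canned designs and their documented statistics are defined on the
independent model, whose additivity is part of the package contract.

### The monomer tail and the endpoint calibration

With the shipped pH 3.8 monomer k_off of 1.0×10⁻² s⁻¹, a monomer still
retains e^{−1.9} ≈ 15 % of its end-of-association response after the 190 s
dissociation. Across the `fig4_grid` totals this residual varies between
roughly 0 and 135 pm at fixed aggregate concentration, so r_300 is not a
function of aggregate concentration alone. Consequences, measured on
noiseless data: the one-site endpoint calibration reaches R² ≈ 0.97 (not
≳ 0.995 as on the real instrument, where low-aggregate samples decayed to
near zero), and the synthetic detection limit works out to ≈ 75 µg/mL rather
than ≈ 9 µg/mL. The calibration curve therefore includes a fitted baseline
offset R0 (set `fit_offset=False` for the pure two-parameter one-site form),
and control-sample prediction through the linear branch still reaches
R² ≥ 0.95. This is a faithful property of the declared generative model, not
a defect of the calibration code; the competitive option narrows but does not
remove the total-concentration dependence (there, monomer crowding modulates
how much aggregate binds).

## Kinetic fitting

`LangmuirKineticsFitter` minimises the joint SSR over association and
dissociation at a known molar concentration, optimising (log k_on, log k_off,
R_max) with `scipy.optimize.least_squares` from a log-spaced multistart grid
(k_on 10³–10⁶ M⁻¹s⁻¹ × k_off 10⁻⁵–10⁻¹ s⁻¹, 4×4 by default; ties broken
toward the lowest k_off). Rates are bounded positive via the log
parameterisation; R_max is bounded by 5× the observed maximum. The first 3 s
of the association window are masked by default because of the bulk-jump
artefact. R² is 1 − SSR/SST with SST about the mean over the fitted windows.
Flat traces return `converged=False` rather than raising. On noiseless
self-simulations all eight shipped parameter sets are recovered to ≲10⁻¹⁰
relative error; at σ = 2 pm the median error over seeds stays below ~6 %
(worst case: k_off at pH 7.4, where only 5.5 pm of decay constrains it
against 2 pm noise).

## Features

* `response_at` — linear interpolation, exact on grid points.
* `derivative_trace` — Savitzky–Golay first derivative, polynomial order 2,
  default window 11 points at 1 Hz (edges by the filter's polynomial
  extension). The window must stay inside a phase for quantitative slope
  reading; the d_112 landmark intentionally tolerates the phase-boundary
  blur because only its ordering across samples is used.
* `fit_exponentials` — offset + amplitude·e^{−rate·t} per phase, time
  re-zeroed at the window start. For each candidate rate on a log-spaced
  grid (10⁻⁴–10⁻¹ s⁻¹, 7 points) the linear pair is solved exactly, and the
  best candidate seeds a full nonlinear refinement. Amplitudes below
  10⁻⁶ pm mark the fit degenerate and pin the rate to 0. For a pure 1:1
  dissociation this family is exact (offset ≈ 0, rate = k_off, amplitude =
  response at dissociation start); for two-species mixtures the fitted rate
  is an effective value strictly between the two k_off values and decreases
  monotonically with aggregate fraction.

## Calibration

One-site curve R = R0 + R_cap·C/(C + K_half) over all training points; a
straight line over the sub-saturating points (r_300 ≤ 550 pm by default) is
inverted for prediction. LOD = 3.3σ/S and LOQ = 10σ/S use the residual sd
(n−2 denominator) and slope of a linear fit restricted to the 9–21 µg/mL
window when it holds ≥3 points, else of the main line; the identities hold
exactly by construction, so LOQ/LOD = 10/3.3 always. Predictions below the
LOD are flagged "below detection", between LOD and LOQ "detected, below
quantification"; responses above the exclusion threshold are refused as out
of the linear range.

## PCA discrimination

Feature matrix: raw responses sampled every 1 s over 190–300 s (111 columns)
concatenated with smoothed derivatives over 110–122 s (13 columns); grids
are endpoint-inclusive. Default preprocessing is mean-centring without
unit-variance scaling — both column families are on comparable pm-scale
ranges, and scaling is exposed as an option. Signs are fixed per component
(largest-magnitude loading positive) so scores are reproducible. On the
default conditions (0.45 mg/mL, pH 3.8, σ = 2 pm) PC1 separates 5 % from
1–2 % aggregate samples by sign in 20/20 seeded replicates.

## Network regression

The predictor maps exponential-fit parameters — (d, f, g) in
`dissociation_only` mode, (a, b, c, d, f, g) in `both_phases` — to
(monomer, aggregate) concentrations through a seven-layer network: four
linear layers alternating with three SELU activations, hidden width 16
(input → 16 → 16 → 16 → 2). Inputs are z-scored; targets are
log-transformed and z-scored on the training split, making predictions
strictly positive after inversion. Training is full-batch Adam
(lr 0.01, 2000 epochs, MSE on the transformed targets), LeCun-normal
initialisation, deterministic per seed. The network is hand-written NumPy
(forward, backprop, Adam) — it is small enough that CPU training takes
under a second, and the explicit implementation keeps the layer sequence an
inspectable contract rather than a framework configuration.

Evaluation reports the squared Pearson correlation of predicted vs expected
values per output and the mean absolute percent error; a k-fold
cross-validation utility reports per-fold statistics. On the synthetic
`fig5_lowrange` design both feature modes reach validation R² ≈ 0.99 and
~1–3 % monomer error: the synthetic exponential features are far cleaner
than instrument data, so the two modes are statistically tied for monomers
(their ordering varies with the training seed), while `both_phases` is
consistently slightly *worse* for aggregates — the one qualitative contrast
with real data that does reproduce.

## Numerical and degenerate-input conventions

* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng` / `SeedSequence`; derived seeds are reduced
  mod 2³¹.
* `least_squares` tolerances are 10⁻¹⁴ so noiseless self-fits are limited
  by conditioning, not stopping rules.
* Zero-concentration species, flat traces and zero-variance feature
  matrices are explicit degenerate cases: simulators return exact zeros,
  fitters flag non-convergence, PCA raises.
* Trace CSVs are written at 6 significant figures; read-back errors name
  the first offending line.

## Known limitations

* The generator is a model of the assay, not the instrument: no drift by
  default, no regeneration artefacts, no mass-transport limitation, no
  injection-plug dispersion. Absolute detection limits computed on
  synthetic data are therefore not transferable to hardware.
* The independent-mixture default cannot reproduce capacity-limited
  observations (see above); the competitive option cannot reproduce the
  observed near-total independence of r_300 from total IgG concentration.
  No reaction-limited 1:1 model with the shipped constants reproduces both
  simultaneously — a useful reminder that the effective constants summarise,
  rather than generate, the real sensor physics.
* Single-trace kinetic fitting at a single concentration cannot separate
  R_max from concentration errors; k_off at pH 7.4 is constrained by only a
  few pm of decay and is the least precise fitted quantity.
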