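# aggsense

Avidity-based detection and quantification of IgG aggregates from label-free
biosensor sensorgrams.

## The problem

Aggregation of therapeutic monoclonal antibodies is a critical quality
attribute: aggregates alter pharmacokinetics and raise immunogenicity, yet the
standard assays (SEC, SV-AUC) are slow and unsuited to at-line bioprocess
monitoring. On a Protein A-functionalised LSPR sensor chip, IgG aggregates
(predominantly dimers) can engage several immobilised ligands at once. At
mildly acidic pH (3.8–4.0) this avidity shows up as a markedly slower
effective dissociation rate — roughly four-fold lower k_off, five-fold lower
apparent K_D than monomeric IgG — so the late-dissociation signal of a
sensorgram reports on the aggregate content of a sample within minutes.

`aggsense` implements that analysis end to end for anyone working with
sensorgram-shaped data (time in s, response in pm of LSPR peak shift):

* **kinetics** — closed-form 1:1 Langmuir forward models per species,
  R(t) = R_max·C/(C+K_D)·(1 − e^−(k_on·C + k_off)·t) during association and
  R(t) = R₀·e^−k_off·t during dissociation, with a packaged table of
  published per-pH rate constants for IgG1 monomers and aggregates;
* **synthetic designs** — noisy mixture sensorgrams emulating the
  characterisation experiments (nine aggregate levels 1–98 %, a 27+7-sample
  calibration grid over three total concentrations, a 65-trace low-aggregate
  set), so every stage is testable without instrument data;
* **kinetic fitting** — joint association+dissociation least squares
  returning k_on, k_off, K_D, R² and monomer/aggregate avidity ratios;
* **features** — endpoint response (r_300), Savitzky–Golay derivatives, the
  early-dissociation derivative landmark, and the exponential reductions
  a + b·e^−ct / d + f·e^−gt whose triples compress each phase to three
  numbers;
* **calibration** — one-site endpoint calibration with linear-range
  inversion and LOD = 3.3σ/S, LOQ = 10σ/S;
* **PCA** — score/loading discrimination of low (1–5 %) aggregate levels
  from late-dissociation responses and early-dissociation derivatives;
* **neural network** — a seven-layer linear/SELU regressor (NumPy, Adam) on
  the exponential-fit parameters that predicts monomer and aggregate
  concentrations simultaneously, trained on log-transformed targets.

Estimators follow scikit-learn conventions (`fit`/`predict`/`transform`,
`get_params`, trailing-underscore fitted attributes) and compose with sklearn
pipelines; module-level functions wrap them for one-shot use.

## Worked example

```python
from aggsense import (InjectionProtocol, NoiseModel, simulate_mixture,
                      fit_langmuir, summary_features, avidity_ratios)
from aggsense.presets import default_species

species = default_species()

# simulate pure-monomer and pure-aggregate injections at pH 3.8, 0.45 mg/mL
mono = simulate_mixture(
    InjectionProtocol(ph=3.8, concentrations={"monomer": 0.45}),
    species, NoiseModel(sigma=2.0, bulk_jump=-10.0, seed=1))
agg = simulate_mixture(
    InjectionProtocol(ph=3.8, concentrations={"aggregate": 0.45}),
    species, NoiseModel(sigma=2.0, bulk_jump=-10.0, seed=2))

# fit the 1:1 model at the known molarities (monomer 150 kDa, dimer 300 kDa)
fit_m = fit_langmuir(mono, known_conc=0.45 / 1.5e5)
fit_a = fit_langmuir(agg, known_conc=0.45 / 3.0e5)
rep = avidity_ratios(fit_m, fit_a)

# endpoint features of a 5 % aggregate mixture
mix = simulate_mixture(
    InjectionProtocol(ph=3.8, concentrations={"monomer": 0.4275,
                                              "aggregate": 0.0225}),
    species, NoiseModel(sigma=2.0, seed=3))
fs = summary_features(mix)
```

Output of the above (2 pm noise):

```
monomer:   k_on = 2.93e+04 /M/s  k_off = 9.91e-03 /s  K_D = 3.38e-07 M  (R2 = 0.9999)
aggregate: k_on = 3.50e+04 /M/s  k_off = 2.36e-03 /s  K_D = 6.74e-08 M  (R2 = 0.9995)
avidity ratios (monomer/aggregate): k_off = 4.2, K_D = 5.0
5% mixture: r_300 = 268 pm, d_112 = -5.89 pm/s, effective dissociation rate g = 9.27e-03 /s
```

The fitted rates recover the generating constants (k_on 3.0×10⁴, k_off
1.0×10⁻² for monomers; 3.6×10⁴, 2.4×10⁻³ for aggregates) to a few percent
under noise, and the avidity ratios show aggregates dissociating ~4× slower
and binding ~5× tighter — the contrast the whole quantification strategy
rests on. For the mixture, `r_300` (response at the end of dissociation) and
the effective decay rate `g` sit between the pure-species values and move
monotonically with aggregate content.

A CLI mirrors the stages (`aggsense simulate | fit-kinetics |
extract-features | calibrate | predict-agg | pca | train | predict |
evaluate | run`); `aggsense run --out rundir` executes a whole design from a
YAML config.

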