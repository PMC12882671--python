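# sonoflux

Multiscale analysis of sonochemical energy coupling in accelerated pu-erh
tea fermentation: acoustic dosimetry, catechin transformation kinetics,
flavoromics and microbial-ecology statistics, cross-omics coupling models,
and acoustic propagation in solid-state piles.

## The problem

Ultrasonic cavitation can compress years of natural pu-erh tea aging into
minutes: collapsing microbubbles create transient hotspots (~5000 K,
hundreds of atm) that hydrolyze ester-type catechins, liberate taste-active
amino acids and sugars, and reshape the fermenting microbial community.
Quantifying that energy-structure-function chain requires a stack of
models that are usually scattered across separate tools:

- **Acoustic dosimetry** (`sonoflux.acoustic`): linear dose-responses of
  temperature, KI-dosimetry iodine yield, hydroxyl radicals and viscosity
  against power density P/V; the calorimetric energy-conversion
  coefficient η = m·c_p·(dT/dt)₀/P_input; a composite cavitation index
  CI = ½(z(iodine) + z(•OH)); and the empirical mass-transfer surface
  k_m = k₀ + α(P/V) + β(P/V)² − γη.
- **Catechin kinetics** (`sonoflux.kinetics`): the closed-form sequential
  network EGCG →(k₁) EGC →(k₂) GA, nonlinear refitting of (k₁, k₂), the
  conversion ratio (EGC+GA)/EGCG = e^{k₁t} − 1, quadratic power scaling
  k ∝ P², Eyring barrier shifts ΔΔG = −RT·ln(k₁/k₂) and Arrhenius
  activation energies.
- **Flavoromics statistics** (`sonoflux.flavor`): Pareto/z-score scaling,
  Welch-t differential abundance with BH-FDR and fold-change gates, PCA,
  relative odor-activity values, umami/sweet taste ratios, Spearman
  co-occurrence networks and hypergeometric pathway enrichment.
- **Community ecology** (`sonoflux.ecology`): rarefaction, Chao1/Shannon,
  Bray-Curtis, PCoA, Mantel and Procrustes concordance tests, and a
  Kruskal-Wallis + LDA effect-size screen for indicator taxa.
- **Coupling models** (`sonoflux.coupling`): NIPALS PLS regression with
  7-fold cross-validated Q², VIP scores and permutation validation, and
  redundancy analysis (RDA) with variance partitioning.
- **Acoustic propagation** (`sonoflux.propagation`): power-law attenuation
  α(f) = α_ref(f/f_ref)ⁿ, 90 % penetration depths d₉₀ = ln 10/α(f),
  multilayer interface transmission T = 4Z₁Z₂/(Z₁+Z₂)² and biofilm
  impedance modulation.

A synthetic-data module (`sonoflux.synthetic`) generates every input with
the statistical structure the analysis assumes — the 6-tea × 4-power
design grid, kinetic trajectories, paired microbiome-metabolome tables
sharing a tunable latent gradient, and quality tables — so the whole
pipeline is testable without instrument or sequencing data.  Small
deterministic fixtures (catechin, amino-acid and calorimetry tables) ship
with the package (`sonoflux.datasets`).

The fit-shaped models follow scikit-learn conventions
(`fit`/`predict`, `get_params`, fitted attributes with trailing
underscores) and compose with sklearn pipelines and model selection.

## Worked example

```python
import numpy as np
from sonoflux.kinetics import (KineticParams, simulate_sequential,
                               fit_rate_constants, barrier_shift,
                               K1_APPARENT, CONTROL_RATE)

traj = simulate_sequential(KineticParams(k1=0.031, k2=0.028), np.arange(31.0))
print(traj.iloc[30].round(4).to_dict())
# {'t_min': 30.0, 'EGCG': 0.3946, 'EGC': 0.384, 'GA': 0.2215}

fit = fit_rate_constants(traj, start=(0.01, 0.01))
print(round(fit.params.k1, 5), round(fit.params.k2, 5))
# 0.031 0.028

print(round(barrier_shift(K1_APPARENT, CONTROL_RATE), 1))
# -25.0
```

After 30 minutes of sonication roughly 39 % of the EGCG pool remains, 38 %
sits in the EGC intermediate and 22 % has reached gallic acid; refitting
the trajectory recovers the apparent rate constants exactly, and the
treated/control rate ratio corresponds to a 25 kJ/mol reduction of the
ester-hydrolysis barrier.

The full pipeline runs from one command:

```bash
sonoflux run --seed 1 --out results/
```

which writes `results/report.json` with every recomputed model quantity,
plus per-stage artifacts.  Individual operations are exposed as
subcommands (`sonoflux dosimetry`, `sonoflux kinetics fit|simulate`,
`sonoflux flavor diff|network|roav`, `sonoflux ecology
alpha|beta|mantel|lefse`, `sonoflux couple plsr|rda`, `sonoflux propagate
depth|layers`).

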