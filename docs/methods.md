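# Methods

This note documents the models implemented in `sonoflux`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions taken where the design was open.

## Acoustic field and dosimetry

The sonicated suspension is characterized by four dosimetry endpoints that
respond linearly to acoustic power density P/V over the working range
0.3–0.8 W mL⁻¹.  The calibrated endpoint means (with measurement SDs) are

| endpoint | 0.3 W mL⁻¹ | 0.8 W mL⁻¹ | SD |
|---|---|---|---|
| temperature (°C) | 24.8 | 36.9 | 0.85 |
| •OH (µM) | 40.8 | 96.1 | 4.25 |
| iodine yield (µmol L⁻¹) | 1.7 | 7.2 | 0.35 |
| viscosity (mPa s) | 1.15 | 1.00 | 0.02 |
| η (–) | 0.61 | 0.77 | 0.02 |

Each SD is the mean of the two endpoint SDs (the responses are close to
homoscedastic over this range).  Intermediate powers carry no separately
calibrated means; linear interpolation of the endpoints is used, justified
by the high linearity of the fitted responses (R² 0.92–0.97).

**Energy-conversion coefficient.**  η = m·c_p·(dT/dt)₀ / P_input, with the
initial slope estimated by least squares over the first 30 s of the
calorimetry trace.  The 30 s window is a pulse-averaged default (the
5 s on/5 s off duty cycle makes shorter windows noisy); it is a parameter
of `energy_conversion_coefficient`.  A nonpositive slope is flagged, not
raised — a flat trace legitimately encodes η = 0.

**Cavitation index.**  CI condenses the two chemical dosimeters into
CI = ½(z(iodine) + z(•OH)), standardized against a caller-supplied
calibration population.  The z-score-average definition was adopted
because CI is specified only as "derived from iodine yield and •OH
concentration"; any affine-equivariant combination would order conditions
identically, and the average of standardized scores is the simplest member
of that family.  CI is exactly collinear with power on noiseless designs.

**Mass-transfer surface.**  k_m = k₀ + α(P/V) + β(P/V)² − γη, fitted by
OLS on the design {1, P/V, (P/V)², η} with γ reported as the negated η
coefficient.  k_m is treated as already normalized to the no-ultrasound
control, so k₀ is a free intercept near 1.  One identifiability caveat
matters: if η is an *exact* linear function of power the design is rank-3
and the four coefficients are not separable.  Real calorimetry varies
sample-to-sample; the synthetic generator reproduces this with small fixed
zero-sum per-tea η intercepts (≤5 % of the η span), which makes the design
full rank.  The estimator detects rank deficiency and names the collinear
columns instead of returning a pseudo-inverse solution silently.

## Catechin transformation kinetics

The transformation of galloylated catechins is modelled as a first-order
sequential network EGCG →(k₁) EGC →(k₂) GA with closed form

    A = A₀e^{−k₁t},  B = A₀ k₁/(k₂−k₁)(e^{−k₁t} − e^{−k₂t}),  C = A₀ − A − B,

and the degenerate limit B = A₀k₁t·e^{−k₁t} when |k₁−k₂| < 10⁻⁹k₁ (the
removable singularity of the closed form).  No reverse reactions are
included — none are quantified, and the monotone rise of the conversion
ratio is inconsistent with appreciable back-reaction on the observed
time scale.  Apparent constants under the reference condition are
k₁ = 0.031 min⁻¹ and k₂ = 0.028 min⁻¹, taken to refer to the standard
power density 0.4 W mL⁻¹ (the reference power for the k ∝ P² scaling law).

The conversion ratio (EGC+GA)/EGCG from a pure-EGCG pool equals
e^{k₁t} − 1 independently of k₂ (algebraic identity: (B+C)/A = (A₀−A)/A).
Stage-wise effective doses D = k₁t are packaged so that e^D − 1 reproduces
the stage ratios 0.98 → 7.6 (PT-C) with 5.2 at PT-A; the per-sample dose
is free precisely so the non-monotone final stage is representable.

Rate refitting is joint nonlinear least squares of all three series in
log-rate parametrization (Levenberg–Marquardt), with A₀ fixed at the mean
observed total (mass is conserved by the model).  Flat, information-free
trajectories raise an error carrying the last iterate rather than
returning boundary garbage.

Thermodynamic arithmetic uses ΔΔG = −RT·ln(k_treated/k_control) at
T = 298.15 K (extraction runs at 25 ± 1 °C).  The packaged control rate
1.2895 × 10⁻⁶ min⁻¹ is the untreated ester-hydrolysis rate implied by a
−25 kJ mol⁻¹ barrier reduction relative to k₁.  Caffeine is carried as an
inert tracer at 3.2 × 10⁴ µg g⁻¹; π–π complexation energetics are out of
scope.

## Flavoromics statistics

Differential abundance uses Welch t-tests on log₂(x+ε) with
ε = half the smallest nonzero table entry (the table is the natural scale
reference; the pseudo-count shrinks extreme fold changes slightly, which
the tests account for), Benjamini–Hochberg q-values and the significance
gate |log₂FC| ≥ 1 AND q < 0.05.  Co-occurrence networks threshold pairwise
Spearman correlations; both Bonferroni (the conservative default for
network edges) and BH are exposed because different analyses in this
domain use either.  The reported clustering coefficient is the global
transitivity 3·triangles/triples, not mean local clustering.  ROAV is the
standard max-normalized odor-activity definition
ROAVᵢ = 100·(Cᵢ/OTᵢ)/max(C/OT); the shipped threshold table is synthetic
demonstration data, clearly labelled non-physiological.  The umami/sweet
ratio sums linear-scale abundances of the umami class (Glu, Asp) over the
sweet class (Ala, Thr, Ser, Gly); log-scale tables are exponentiated
first.

## Community ecology

Rarefaction draws without replacement (multivariate hypergeometric), so
expected rarefied proportions equal the originals and total depth is
preserved exactly.  Chao1 uses the bias-corrected form
S_obs + F₁(F₁−1)/(2(F₂+1)); Shannon uses natural log.  Bray–Curtis is a
semi-metric — the triangle inequality is deliberately not asserted
anywhere.  PCoA Gower-centres −½D², eigendecomposes, and drops negative
eigenvalues from the variance fractions (Lingoes/Cailliez corrections are
not implemented; the negative spectrum is reported so the caller can see
its magnitude).  The Mantel test permutes the second matrix jointly by
rows and columns with a one-sided (greater) alternative and the
add-one permutation p-value.  Procrustes follows the standard
unit-sum-of-squares normalization with m² = 1 − (Σσ)².

The indicator-taxon screen is a deliberately reduced LDA effect-size
procedure: a Kruskal–Wallis screen with BH correction, then for surviving
taxa the log₁₀ absolute class-mean gap between the two extreme groups on a
per-sample relative scale of 10⁶, thresholded at score ≥ 3.  Subclass
bootstrapping and per-subject tests of the full published algorithm are
not implemented; scores are on the conventional log₁₀ scale so thresholds
transfer.

## Coupling models

PLS is single-response NIPALS (PLS1): w ∝ Xᵀy, t = Xw, p = Xᵀt/tᵀt,
q = yᵀt/tᵀt, deflating both blocks; multi-block integration reduces to
concatenated-block PLS1.  X is autoscaled by default.  Q² = 1 − PRESS/TSS
under cross-validation with folds formed as contiguous blocks of a seeded
shuffle (the fold construction is otherwise unspecified; seeding makes it
reproducible).  The permutation p-value shuffles the response and counts
permuted fits with R²Y at least the observed value; R²Y is the permuted
statistic.  VIPⱼ = √(p·Σₐw²ⱼₐSSYₐ/ΣₐSSYₐ); the mean squared VIP is exactly
1.  RMSEE = √(SSres/(n−a−1)) is reported alongside.

RDA regresses each centred response column on the centred predictors;
the constrained fraction is SS(fitted)/SS(total) and the axes are the
principal components of the fitted values, so the axis fractions sum to
the constrained fraction by construction.  Significance row-permutes the
predictor block.

## Acoustic propagation in piles

Full poroelastic (Biot–Stoll) treatment requires frame moduli,
permeability and tortuosity values that are not available; the module
replaces it with a phenomenological power law α(f) = α_ref(f/f_ref)ⁿ —
the central simplification of this module.  Calibration uses two
(frequency, d₉₀) anchors: 0.15 m at 80 kHz and 0.80 m at 40 kHz, read as
equalities from the bounds "about 15 cm above 80 kHz" and "exceeding
80 cm at 20–40 kHz"; anchoring the low-frequency depth at 40 kHz is the
conservative choice that makes the 20 kHz prediction (4.27 m) strictly
exceed 0.80 m.  d₉₀·α(f) = ln 10 identically.  Interfaces use the
normal-incidence intensity transmission 4Z₁Z₂/(Z₁+Z₂)², single-pass
(internal re-reflections ignored).  The biofilm law
Z_eff = Z(1 + κ·ρ_EPS) is a minimal monotone model: only the direction of
the EPS-density effect is known, so the simplest one-parameter law with
the right sign and a clean ρ → 0 limit was chosen.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure* the analysis
assumes: linear dose-responses with Gaussian measurement noise (truncated
at zero), exact sequential kinetics plus truncated noise, a
one-dimensional latent fermentation gradient shared by paired
microbiome-metabolome tables, and a quality table whose sensory score is
an exact linear combination of its predictors before noise.  Fixed
zero-sum per-tea intercepts (<5 % of each response span) make tea facets
distinguishable while leaving population means at the calibrated values.

They do **not** emulate: compositional overdispersion or zero inflation
of real sequencing counts, batch effects, nonlinear saturation of
dose-responses outside 0.3–0.8 W mL⁻¹, or genuine microbial dynamics
beyond the latent gradient.  Passing tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
real-data pathologies.

**Latent-gradient coupling.**  Taxon log-abundances are
baseline + loading·g + N(0, 0.3), exponentiated and closed to
compositions; metabolite intensities are baseline + ψ·loading·g +
(1−ψ)·noise on a truncated linear scale.  The linear metabolite scale is
deliberate: exponentiated intensities produce heavy-tailed Euclidean
distances whose shape mismatch with bounded Bray–Curtis caps the
attainable Mantel correlation well below the observed cross-omics value.
ψ = 0 decouples the blocks (mean Mantel r ≈ 0) and the expected r is
monotone in ψ.  The packaged constant ψ* = 0.45 was fixed by a pre-build
bisection scan (`scripts/calibrate_psi.py`, 50 seeds per evaluation at
the reference geometry of 24 samples × 40 taxa × 60 metabolites) so the
mean Mantel correlation equals 0.87.

**Quality table.**  Trait endpoints (0.3 → 0.8 W mL⁻¹): TP 14.0 → 23.5 %,
CP 6.0 → 8.8 %, WE 32.0 → 55.0 %, TS 19.0 → 27.0 %.  The TP low endpoint
is a representative raw-tea polyphenol content (only the high end is
calibrated).  The sensory score is 7.0 + 1.2 × a fixed weighted mean of
the z-scored predictors (weights Power 1.0, CI 0.6, TP 0.5, CP 0.3,
WE 0.8, TS 0.4), which keeps the noiseless score on the 9-point hedonic
scale; noise has SD = noise_frac × the noiseless score range.

## Problem sizes and reproducibility

Stochastic summaries use 20 replicate seeds (PLSR bounds, Mantel
coupling), 50–100 seeds for Monte-Carlo bias and null-calibration checks,
999 Mantel permutations and 200 response permutations for PLSR — sizes at
which the reported means are stable to well within the stated tolerances.
Every random stream derives from an explicit seed; identical seeds and
parameters give bit-identical outputs, and the pipeline derives per-stage
child seeds by stable hashing of stage names so module streams are
decoupled.

## Known limitations

- Field results that depend on the original instrument or sequencing data
  (e.g. indicator-taxon scores of named species, real-community RDA
  fractions, compound counts) cannot be reproduced from synthetic inputs
  and are treated as demo illustrations only.
- The LDA effect-size screen is a reduced procedure (see above).
- UniFrac (needs a phylogeny), NMDS and CCA are not implemented; PCoA and
  RDA are the supported ordinations.
- The propagation module is phenomenological; it should not be read as a
  poroelastic wave model.
- An internal inconsistency in the source taste-composition summaries
  (umami proportion vs umami/sweet ratio) is resolved by treating the
  ratios as the binding constraints and the proportions as qualitative.
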