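# Methods

`pmtox` implements an integrated safety-evaluation pipeline for herbal
batches of *Polygonum multiflorum* (PM) type: chemical-profile
classification, hepatotoxicity-marker selection, dose–response tiering,
two-drug interaction analysis and chromaticity–toxicity correlation. This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic data generator does and does not emulate.

## Compound tables and qualification

Batches are rows of a 26-compound concentration matrix (mg per g dry
weight), each compound labelled anthraquinone, stilbene glycoside, flavonoid
or phenol. The pharmacopoeial qualification rule requires the dominant
stilbene glycoside THSG at ≥ 1.0% w/w; concentrations arrive in mg/g, so the
threshold is 10 mg/g (mg/g = 10 × percent). "Not less than" is read
inclusively: exactly 10 mg/g qualifies. Missing cells are rejected with a
row/column diagnostic rather than imputed — a quantification table should be
complete, and silent imputation would bias every downstream multivariate
step. The mg/g ↔ percent conversion assumes a dry-weight basis; no moisture
correction is applied.

## Chemometrics

**Scaling.** Default is unit-variance autoscaling (center, divide by the
column SD, ddof = 1), with Pareto and no-scaling options. Constant columns
are centered, scaled by 1 and flagged.

**PCA** is a plain SVD of the scaled matrix: scores `U·S`, loadings `V`,
explained fraction `s_k² / Σ s_i²`.

**Cross-validated Q² for PCA** uses Wold element-wise deletion: matrix
cells are assigned to 7 folds by a seeded permutation; each fold is held out
in turn and predicted from a rank-k model refit on the remaining cells via
EM-style imputation (fill held-out cells with the current rank-k
reconstruction, iterate to 1e-9); `Q²_k = 1 − PRESS_k / SS`. Commercial
chemometrics suites use proprietary deletion patterns, so Q² values agree
with them in behavior (near 1 for low-rank structure, ≤ 0 for noise) but not
in the third decimal.

**HCA** delegates to `scipy.cluster.hierarchy` (exact Lance–Williams
updates) with ward/average/complete linkage and euclidean/correlation
distances; labels come from cutting the tree at k clusters. Merge-distance
tie-breaking follows scipy's deterministic ordering.

**OPLS-DA** is the single-response orthogonal-projections decomposition:
classes are encoded y ∈ {−1, +1} (boundary at 0) and centered; for each of
`n_orthogonal` rounds the weight `w ∝ X'y` is computed, the loading of the
y-predictive score is split into its y-orthogonal part, and that orthogonal
component is deflated from X; a single predictive component is then
extracted from the filtered matrix. Reported diagnostics are R²X (predictive
plus orthogonal), R²Y, and Q² from venetian-blind row cross-validation
(every 7th row held out; test rows are orthogonal-filtered with the training
loadings before prediction). The default of one orthogonal component suits
two-class tables of this size; the count is selectable.

**VIP** is computed from the predictive component only:
`VIP_j = √p · |w_j|` with ‖w‖ = 1, so mean(VIP²) = 1 and Σ VIP² = p exactly
— one VIP per compound, matching how marker tables are reported.

**Permutation validation** refits the model under 200 random permutations of
the class vector, recording R²Y and Q² per permutation and the |Pearson r|
between original and permuted labels. The Q² intercept is the value at
r = 0 of a least-squares line through the permuted points plus the original
model at r = 1. A model is valid when every permuted Q² is below the
original and the intercept is negative.

## Marker selection

Per-compound univariate tests default to Welch two-sample t (Satterthwaite
df, two-sided); a one-sample mode against a reference mean is available.
p-values are adjusted by Benjamini–Hochberg step-up (via statsmodels); a
compound is a differential toxicity marker when VIP > 1 (strict) and
q < 0.05 (strict). One-way ANOVA with Tukey-HSD-adjusted pairwise p-values
covers origin-effect comparisons; Duncan's multiple range test (studentized
range at the stepwise protection level) is provided as an option for IC50
group comparisons.

BH controls the false-discovery *rate*, so at m = 26 compounds roughly 5–7%
of all-null datasets still contain some q < 0.05, and at two-group sample
sizes near 40 any null compound extreme enough to pass the q filter also
passes VIP > 1. A single comparison therefore flags exactly the true
markers in only ~88% of simulated datasets, no matter the noise level. The
study-faithful remedy, implemented as `markers.common_markers`, keeps only
compounds flagged in *both* the safe-vs-high and safe-vs-medium
comparisons; chance flags are nearly independent across comparisons, and
exact recovery rises to ~99%.

## Dose–response

Viability is `(dosing − blank)/(control − blank)` (invariant to common gain
and offset; values slightly above 1 are kept, not clipped). The curve is a
four-parameter logistic on log-dose,
`v(d) = floor + (ceiling − floor)/(1 + (d/IC50)^h)`, fit by least squares
with a deterministic multi-start (7 log-spaced IC50 starts × 3 slope
starts). By default the asymptotes are fixed at 0 and 1 because a typical
dosed range does not pin both plateaus; a free 4PL fit with bounded
asymptotes is available. Replicates are averaged per dose, weighted
1/variance when replicate variance is available. Responses spanning < 0.05
viability are declared non-convergent (no identifiable midpoint) without
raising; IC50 outside the dosed range is flagged extrapolated. Toxicity
tiers: IC50 > 450 µg/mL low, < 390 high, 390–450 inclusive medium.

## Combination analysis (One-belt, One-line)

Both drugs carry increasing percent-inhibition Hill curves. For a dose pair
(d_T, d_E) the equivalent-dose conversion maps the partner's dose onto the
target drug's axis through the iso-effect relation
`equiv_T(d_E) = curve_T⁻¹(curve_E(d_E))`, giving two additive predictions:
`f_T = curve_T(d_T + equiv_T(d_E))` and `g_E = curve_E(d_E + equiv_E(d_T))`.
The pointwise interval between f and g is the additive belt; the observed
combination curve is the line. Dose-based combination indices are
`CI_d1 = Y_obs/f_T` and `CI_d2 = Y_obs/g_E`; both above 1 is synergistic,
both below 1 antagonistic, anything else additive. CI values within 1e-9 of
1 are treated as exactly 1 (so the analytically additive case lands in the
additive class rather than being decided by the last floating-point bit). A
literal "strict" variant of the published rule text is provided, but the
row-pattern rule above is the default because it is the one consistent with
the published table. Curve inversion is analytic for Hill curves; effects
at or above a curve's ceiling convert to an infinite equivalent dose and the
prediction saturates at the ceiling with a flag. CI values are reported at
4 decimals with half-up rounding; judgments always use the unrounded values.

Self-consistency: a drug combined with itself at any split d = d1 + d2
yields f = g = curve(d1 + d2) and CI ≡ 1 — the classical Loewe sham test,
enforced to 1e-6 in the acceptance suite over random curves and splits.

## Chromaticity

Each batch contributes 4 anatomical regions × 2 surfaces × 5 sites = 40
readings of (R, G, B, L*, a*, b*). Batch descriptors are means over the raw
readings; the overall color parameter `E*ab = √(L*² + a*² + b*²)` and the
normalized channels `r/(r+g+b)` etc. are derived from the batch means
(aggregate-then-normalize, fixed and documented — the two orders coincide
only for constant-sum records). Note E*ab depends on squares only, so it
conflates red and green casts of equal magnitude; this is a property of the
descriptor itself and is kept as such. Color clustering autoscales
(norm_r, norm_g, norm_b, L*, a*, b*, E*ab) and reuses the HCA engine.
The toxicity link is univariate OLS of IC50 on each normalized channel with
a two-sided slope p-value. Image crops are converted to CIELAB under sRGB,
D65, 2° observer (the common image-editor working space; the acquisition
profile is otherwise unknowable).

## Synthetic data generator

The generator defines the study conditions: 61 batches in four latent
groups of 5/17/21/18; group A is the sub-limit group (mean THSG 7 mg/g, the
rest ≥ 10). Group mean profiles give THSG ≈ 12.5 / 45 / 25 mg/g and EG ≈
0.3 / 3 / 1.5 mg/g in the safe/high/medium-toxicity groups, with
class-level multipliers making each group's overall composition distinct
(the real batch groups separate cleanly in both HCA and PCA).
Concentrations are drawn log-normal with the group mean as the exact
expectation and CV 0.2 (positive, right-skewed; zero CV reproduces the
means exactly). Viability plates use Hill curves with group IC50s 540/480/
370/420 µg/mL (slope 2.5), additive Gaussian viability noise (sd 0.05)
truncated at 0, four replicates per dose, and fixed blank/control
absorbances. Combination rays draw observed effects from the exact Loewe
surface (Brent root of `d1/D1(Y) + d2/D2(Y) = 1`, resolved to relative
precision so that very small effects remain exact); a potency-shift factor
multiplies one drug's effective dose to inject synergy (> 1) or antagonism
(< 1). Chromaticity readings are Gaussian around group-by-region means
chosen so normalized B rises and normalized R falls with IC50 (white safer,
yellow-brown more toxic). All randomness flows from one root seed through
per-stream `SeedSequence` spawns, so each data kind regenerates
independently and bit-identically.

What the generator does **not** emulate: instrument drift, retention-time
or mass-spectral structure, inter-compound correlation beyond the group
means, plate edge effects, image glare/white-balance, or origin-linked
composition differences (origins are assigned round-robin and carry no
signal, consistent with the finding that geography does not drive the
grouping). Passing tests therefore demonstrate correctness of the
statistical machinery under the assumed data-generating process, not
performance on real chromatograms or images.

## Problem sizes and determinism

Test and acceptance runs use the study-scale sizes throughout: 61 × 26
tables, 200 permutations, 100-replicate recovery studies, 50-replicate
marker recovery, 10-dose plates with 4 replicates. Every stochastic step
takes an explicit seed; the pipeline manifest records the configuration and
SHA-256 of each artifact, and a fixed seed reproduces every artifact
byte-for-byte.

## Known limitations

- Q² values match commercial software only qualitatively (deletion pattern
  and fold assignment differ).
- The OPLS-DA implementation is two-class only; multi-group questions are
  handled as pairs of comparisons, as in the underlying study design.
- Published group-level statistics obtained from the original 61 real
  batches (PCA percentages, OPLS-DA R²/Q², per-compound VIP/p tables, batch
  IC50s) depend on unpublished raw data; the package reproduces the rules
  and decision logic, and its property suites verify behavior on synthetic
  data instead.
- The chromaticity model treats sites as independent Gaussian draws; real
  anatomical regions have correlated texture.
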