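# Methods

This note documents the statistical model, the synthetic-cohort generator,
the numerical choices, and the known limitations of `hmotriad`.

## The analysis model

The scientific question is how human milk oligosaccharide (HMO)
concentrations, infant gut *Bifidobacterium*/*Bacteroides* relative
abundances, and their interactions associate with infant cognition measured
by the Mullen Scales of Early Learning (MSEL). Data are longitudinal:
mother-infant dyads contribute one to four visits, each with a milk HMO
profile (2′-FL, 3-FL, 3′-SL, 6′-SL, LNT, LNnT, LNFP-I, A-tetra; mg/L), a
stool metagenomic relative-abundance profile, and six MSEL scores (an early
learning composite and five T-scored subdomains).

For each outcome the fixed-effects model is

    score = β₀ + β₁′·covariates + β₂′·HMO + β₃′·MB + γ′·(HMO × MB) + b_i + ε,

with covariates infant sex, delivery mode, maternal education, site and HMO
batch year (treatment coding; references female / cesarean / below-graduate
/ site B / batch 2018), standardized HMO and abundance predictors, all
pairwise HMO × species products, a subject random intercept
b_i ~ N(0, σ_b²), and ε ~ N(0, σ²). Three variants are fitted:
unstratified; A-tetra+ stratified, where HMO and interaction columns are
zero-masked on visits whose milk A-tetra is at or below the 4.4 mg/L limit
of detection and an I(A-tetra−) indicator column absorbs the stratum mean
shift; and the mirror-image A-tetra− model. Zero-masking rather than row
dropping keeps the microbiota main effects estimated from all infants.

Inference is two-step. Step one selects variables with an overlapping group
LASSO whose groups encode the interaction hierarchy: one singleton group per
HMO main effect, one per species main effect, and one triple
{HMO_j, MB_k, HMO_j × MB_k} per product. In the latent-overlap formulation
each group receives private copies of its columns, so an interaction can
only enter through a group that also carries both parents — any selected
support is hierarchical by construction. The penalty weight of a group is
√(group size). The penalty level is chosen by 10-fold cross-validation with
folds partitioning subjects (all visits of an infant share a fold; row-level
folds would leak repeated measures), and the whole CV is repeated with fresh
fold randomizations (default 200). Groups selected in at least half the
repetitions form the final model; if no interaction group is stable, the
model falls back to all eight HMO and all retained species main effects.
Frequencies are always reported so other cutoffs can be applied.

Step two refits the selected terms, plus the always-included adjusting
covariates, with a random-intercept linear mixed model estimated by REML.
The covariance of a subject's visits is σ²(I + θJ) with θ = σ_b²/σ², which
inverts in closed form per subject; the restricted likelihood is profiled
over β (GLS) and σ², leaving a scalar criterion in θ minimized on [0, 10³]
(tolerance 1e-10; the boundary θ=0 is allowed). Wald t statistics use
df = n_obs − p_fixed; this is the simplest df convention (no Satterthwaite
correction), which leaves effect sizes untouched and is recorded in the
output provenance. P-values are reported unadjusted at the 0.05 level; a
Benjamini–Hochberg option exists but defaults off to match the two-step
reporting convention the pipeline mirrors.

## Preparation steps

* **Double-MAD outlier handling** (per species, across all samples): with
  median m, left MAD = median(|x−m|) over x ≤ m and right MAD over x ≥ m
  (ties at the median count on both sides, keeping both sides non-empty),
  score(x) = |x−m| divided by its side MAD, zero at the median, +∞ when the
  side MAD is zero. No 1.4826 consistency constant is applied: the
  asymmetric method works on raw MAD ratios. Default threshold 3.0; default
  policy `set_missing` (flagged abundances become missing and their rows are
  excluded at design construction); `winsorize` and `keep` are available.
* **Species filter**: a species is retained iff its relative abundance
  summed over all samples strictly exceeds 1.0 (configurable).
* **Standardization** to mean 0, sample SD 1 over all included samples, not
  within stratum — the stratified models share microbiota terms across
  strata, so a single scale keeps effect sizes comparable; stratified models
  then zero-mask the standardized values.
* **Age residualization** (default on): standardized predictors are replaced
  by their OLS residuals on [1, age]; MSEL T-scores are already age-normed
  and are left untouched.
* **A-tetra status**: positive iff milk A-tetra > 4.4 mg/L (strict).
  Secretor classification offers both printed rules: 2′-FL/3-FL > 6.5827
  (ratio rule) and 2′-FL < 15 mg/L as non-secretor (threshold rule).

A consequence worth knowing: on sparse, heavy-tailed compositional
abundances the double-MAD score at threshold 3 flags a substantial part of
the upper tail (the side MAD of a near-zero-median species is tiny), so with
the `set_missing` policy a noticeable fraction of rows is excluded and
borderline species can drop below the retention sum. On the default
synthetic cohort about three of the twelve focal species survive both
steps. This mirrors a genuine tension in the method as stated (the source
analysis likewise lists a species whose printed mean abundance implies a
sum below its own retention threshold); both the threshold and the policy
are configurable rather than silently adjusted.

## The synthetic cohort generator

The generator emulates the cohort structure the analysis assumes, with
known ground truth for recovery testing:

* 105 subjects by default; a subject is a singleton with probability 60/105,
  otherwise draws 2–4 visits with weights (0.60, 0.35, 0.05), giving ≈170
  visits in expectation; visit ages are sorted uniforms on 2.9–12 months.
* Covariate marginals: 38% male, 79% vaginal delivery, 61% graduate-level
  maternal education, 50% site A, batch years 2018/2019/2020 with weights
  (0.3, 0.4, 0.3).
* A-tetra+ mothers are Bernoulli(36/105) draws at the mother level (no
  secretor-gene × blood-group mechanism — simpler and sufficient for
  stratification tests); their milk A-tetra is 4.4 mg/L + a lognormal draw,
  so detectability never flips within a mother; A-tetra− milk has exactly 0.
* Each HMO is lognormal around an age-linear log mean. Trend signs follow
  the reported age trends (3-FL, 3′-SL, A-tetra rising; the others falling);
  baselines are calibrated so cohort means land near reported values, e.g.
  3-FL ≈ 1551 mg/L in the A-tetra− group with a log-offset giving ≈ 1243 in
  the A-tetra+ group, and 6′-SL falling from ≈ 77 mg/L at 3–4 months to
  ≈ 57 at 4–8 months.
* The microbiota is Dirichlet over 12 focal species plus a remainder bucket.
  Weights are reported mean abundances × total concentration 1.3 — the
  small total reproduces sparse, high-dispersion compositions (SD ≈ 0.32
  for *Bif. longum* at mean 0.38). Log-weights drift linearly with age
  (centred at 8 months so marginal means stay calibrated): *Bif. longum*
  and *Bif. breve* fall, *Bif. catenulatum* and *B. vulgatus* rise.
* MSEL scores follow the fixed-effects model above on the standardized
  scale, with per-outcome intercepts near reported cohort means, default
  batch-year effects (−3, −5 T-score units for 2019/2020), σ_b = 5 (a free
  choice — within-subject MSEL correlation is not reported anywhere we can
  calibrate to) and σ = 7 (11 for the composite, matching total SDs ≈ 8.8 /
  12.5). All HMO/microbiota coefficients are zero by default; tests plant
  effects explicitly. The composite is generated as its own outcome by
  default (mirroring an analysis that treats each score as an outcome); an
  optional mode derives it as twice the mean of the four non-gross-motor
  subdomains.

What the generator does **not** emulate: sequencing and quantification
noise, compositional correlation beyond the Dirichlet (no true ecological
interactions), informative missingness, calendar confounding between batch
year and age, or outlier-contaminated abundances. Passing recovery tests
therefore demonstrates that the selection and mixed-model machinery recovers
effects expressed in the generator's own terms, not that the pipeline is
robust to every artefact of real metagenomic data.

## Numerical choices

* **Solver**: monotone accelerated proximal gradient (FISTA with a
  monotone safeguard and momentum restarts) on the latent-expanded design,
  with backtracking line search initialized at 1/L from a power-iteration
  estimate. Iterations run on the Gram form (X̃ᵀX̃, X̃ᵀy), which makes the
  per-iteration cost two m × m matvecs and yields the KKT correlation
  vector for free. Convergence requires Karush–Kuhn–Tucker residuals
  ≤ 1e-6 (relative objective stalls alone do not count); on a stall short
  of optimality the smooth restricted problem on the current active set is
  polished by L-BFGS and the full KKT system is re-checked. Groups with
  norms below 1e-11 of the largest are zeroed on return. Non-convergence
  warns and is flagged, never silent.
* **Cross-validation fits** are effort-capped (no polish, KKT tolerance
  1e-3, ≤ 2000 iterations, warm starts along the descending penalty path):
  their precision only affects held-out prediction error. The full-data fit
  at the chosen penalty runs at full precision.
* **Penalty grid**: 100 log-spaced values from λ_max (closed form from the
  residual of the unpenalized-only fit) down to 1e-3·λ_max by default;
  recovery experiments use shorter grids (25–30 points to 0.02·λ_max),
  chosen as problem sizes for the simulation studies.
* **REML**: bounded scalar minimization (`xatol` 1e-10) of the profiled
  criterion; θ̂ = 0 is accepted when it matches or beats the interior
  candidate. Per-subject closed-form inverses avoid any dense n × n solve.
* **Ties and degenerate inputs**: the species filter is strictly greater
  than; A-tetra at exactly the LOD is negative; constant series refuse to
  standardize; all-singleton subjects warn and reduce to OLS; an empty
  stratum raises.

## Design choices that were genuinely open

* Aggregating the repeated CV runs: the repetition count stabilizes the
  randomness of fold assignment, but how repetitions combine into one model
  is unspecified in the method the pipeline mirrors. We report per-group
  selection frequencies and use frequency ≥ 0.5 as the final set — a
  stability-selection convention — with the fallback applied afterwards.
* Fold assignment by subject rather than by row (prevents leakage of
  repeated measures).
* Interactions are products of standardized mains and are not
  re-standardized, keeping the hierarchy algebraically coherent; recorded in
  output metadata.
* The selection stage uses plain squared loss, ignoring within-subject
  correlation; the mixed model handles dependence afterwards (two-step
  design).
* Whether outlier scoring is per species or per sample is unspecified in
  the source; per species is used.

## Known limitations

* Wald df = n − p is anti-conservative for small subject counts relative to
  Satterthwaite-type corrections; effect sizes are unaffected.
* The latent overlapping group LASSO's selected support is hierarchical by
  construction, but collapsed coefficients of parents can be near zero when
  a main enters only through its triple.
* The stability-frequency ranking cannot distinguish a planted interaction
  from strongly correlated companion products (those sharing a parent) when
  signals are strong, and has little power when the planted standardized
  effect is below roughly a quarter of the residual SD at this design size;
  see the recovery studies run by `scripts/acceptance.py`.
* Welch tests on per-visit summaries treat visits as independent, as the
  descriptive tables they reproduce do.
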