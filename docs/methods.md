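# Methods

## Study design being modelled

Response to PD-1/PD-L1 blockade is observed at the cancer-type level: a
literature objective response rate (ORR, a fraction in [0, 1]) per tumor
type. Molecular data are per-sample: 450K-array DNA-methylation β values
(fraction methylated per CpG probe) and MAF-format somatic mutation
calls. The analysis therefore collapses each cancer type to a per-probe
mean β over its tumor samples and treats the n ≈ 18 cancer types as the
regression rows. Everything downstream inherits the two central caveats
of that design: the profiled samples are not the patients whose responses
were pooled, and n is tiny relative to the ~480k probes screened.

## CpG screen

Per probe, Spearman rank correlation between the cancer-type mean β
vector and the ORR vector. A probe passes at |ρ| ≥ 0.7 **and** p ≤ 0.001.
Choices:

- **p-values.** Exact two-sided permutation enumeration for n ≤ 9 (all n!
  orderings; ties handled by average ranks); the usual t approximation on
  n − 2 degrees of freedom for larger n. At n = 18 the t approximation is
  standard practice; the exact mode exists because desk-scale fixtures are
  often smaller, where the approximation is visibly off (at n = 6 it gives
  0.208 where the exact answer is 0.242 on a representative input).
- **No multiplicity correction** in the pass rule — with ~480k probes and
  18 rows a Bonferroni bound is hopeless, and the raw double threshold is
  the operative definition. A Benjamini–Hochberg q-value column is
  emitted for information only.
- **Missingness.** A probe missing in *all* samples of any cancer type is
  dropped from every profile (exclusion, not imputation); partially
  missing probes use the mean of available samples.
- Probes missing from any matrix of the per-cancer set are dropped by the
  intersection rule before averaging.

Enrichment of known immuno-oncology targets uses a one-sided two-sample
Kolmogorov–Smirnov test on |ρ| (gold-annotated probes vs the rest,
alternative: gold stochastically larger), delegated to
`scipy.stats.ks_2samp` and cross-checked in the test suite against R's
`ks.test` to < 1e-9. The gold gene list is a user input; the package
ships none (tests plant their own).

## Lasso ORR model

`y = α + Σⱼ βⱼ xⱼ` with Σ|βⱼ| constrained; fit via scikit-learn's
coordinate descent. Numerical choices:

- Predictors are standardised to unit variance internally; reported
  coefficients are back-transformed to the raw β scale so they are
  comparable to the shipped published equation.
- λ is chosen on a 100-point grid by **minimum** cross-validated MSE (not
  the 1-SE rule), with 10 folds by default. Fold assignment is derived
  from the seed after sorting rows by cancer code, so refitting with
  permuted row order yields bit-identical models. With fewer rows than
  folds the CV degrades gracefully to leave-one-out (logged). With 18
  rows and 10 folds, eight folds hold out 2 types and two hold out 1.
- Fixed-λ fits use a tight tolerance (1e-12) so they agree with a
  coordinate-descent oracle to ~1e-6 on the β scale.
- λ = ∞ is accepted and returns the intercept-only model (mean ORR).
- Coefficients below 1e-10 in magnitude are dropped from the stored
  support.

Generalisation is assessed by leave-one-cancer-type-out CV. By default
the CpG screen is **re-run inside every fold** (the held-out type never
influences probe selection); a `rescreen=False` mode reuses one global
screen, which is cheaper but optimistically biased. Folds where the
screen selects nothing fall back to the training-mean ORR and are
flagged.

Predictions are returned unclipped with an out-of-range flag rather than
truncated to [0, 1]: error metrics and ROC ranking need the raw values,
and clipping is a presentation decision left to the caller.

The shipped published model stores the eight printed probes. One printed
coefficient (cg04144714) is typographically illegible in the source
equation; it is stored as `null`, resolved to 0.0 at load time with a
warning, and overridable — deliberately not guessed.

## TMB

Per patient, TMB = (missense mutation count) / 38 Mb. The counted class
set defaults to `Missense_Mutation` only — the formula's operative
definition — although broader definitions (e.g. + indels) are one config
option away. Samples present in the MAF with no qualifying mutation count
as TMB 0; samples absent from the MAF are unknown, never 0. The
cancer-type summary is the cohort median. The comparison model is
`ORR = a·ln(X) + b` on the cohort median X (natural log; shipped
constants a = 0.0768, b = 0.1313), refittable by ordinary least squares
on ≥ 3 types with positive medians. Zero medians raise rather than being
silently shifted; the error message points at a pseudocount policy as the
caller's decision.

## Synergy index

Rothman's S from a logistic regression with both binary exposures and
their product: S = (OR₁₁ − 1)/((OR₁₀ − 1) + (OR₀₁ − 1)), where
OR₁₀ = exp(β_a), OR₀₁ = exp(β_b), OR₁₁ = exp(β_a + β_b + β_ab). S = 1
means the joint excess odds are exactly additive. Choices:

- The per-sample binary **outcome is a required input**: response is only
  observed per cancer type, so any per-patient label is a modelling
  surrogate. A helper (`labels_from_cancer_orr`) propagates the
  type-level responder label (ORR ≥ 0.2) to samples, but only when
  explicitly called.
- Exposures (probe β, TMB) are dichotomised at their cohort median, ties
  to the low group; the split is configurable, the median being the
  minimal-assumption default.
- The fit collapses the data to the 2×2×2 frequency table and uses a
  binomial GLM with frequency weights — identical estimates, much
  faster for per-probe screens.
- Degenerate geometry is surfaced, not patched: perfect or
  quasi-separation raises with advice; a denominator crossing zero (both
  single-exposure ORs ≈ 1) sets an `undefined` flag, since S is a ratio
  of two near-zero quantities there and its sign is meaningless. For the
  same reason, the "null" statement that *is* stable when neither
  exposure has an effect is a multiplicative interaction ratio
  OR₁₁/(OR₁₀·OR₀₁) ≈ 1, and that is what the null test asserts.

Individual-level CpG–TMB association is per-probe Spearman between
sample β and sample TMB with Benjamini–Hochberg q-values across the
probe set.

## Module entropy

Modules are (i) radius-1 ego networks in a score-filtered PPI graph
(seed gene + direct neighbors; score ≥ 400 inclusive, self-loops
dropped), (ii) pathway gene sets, (iii) ligand-receptor pairs (union of
both genes' probes). Member probes are resolved through the annotation;
modules resolving to zero probes are dropped.

The score is `H = −Σᵢ βᵢ·ln βᵢ` over member-probe β values with
0·ln 0 := 0. Each term is ≥ 0 on [0, 1], zero exactly at β ∈ {0, 1} and
maximal (1/e) at β = 1/e, so H measures distance from fully
methylated/unmethylated states. Choices:

- H is **not normalised** by module size (the defining formula has no
  normaliser); a per-probe mean is available behind `normalize=True` for
  cross-size comparison.
- βᵢ are the **cancer-type mean** β values — the association is across
  cancer types, so the module score must be one scalar per type,
  consistent with the screen's aggregation. Sample-level pooling is a
  plausible alternative reading; this is an interpretation, flagged here.
- Association with ORR reuses the screen's Spearman machinery
  (significance at p ≤ 0.05, reported per module kind; the math is
  identical for all kinds). Modules with constant entropy across types
  have no defined rank correlation; they are flagged `degenerate` and
  never reported significant.

## Evaluation

MAE, RMSE and Spearman ρ on (true, predicted) ORR pairs; ROC/AUC after
labelling types as responders at true ORR ≥ 0.2 (**inclusive**, so a
type at exactly 0.2 is a responder; the cutoff and strictness are
parameters). AUC is computed by the rank-sum (Mann–Whitney) formula with
ties counting ½, which equals the probability a random responder
outscores a random non-responder; ROC points sweep every distinct score
threshold. A single-curve AUC is reported; no fold-averaging is applied.
Model comparison declares the per-cancer winner by smaller |predicted −
true|, exact ties reported as ties.

## Synthetic data generator

`SyntheticConfig` defaults define the emulated conditions: 18 cancer
types; 60 samples/type (desk-scale stand-in for TCGA cohorts of
hundreds); 1 000 probes of which 30 informative; effect size 0.9; noise
sd 0.02 on cancer-type means; balanced bimodal mix; TMB link strength
0.8; ORR uniform on (0, 0.4), spanning the observed pan-cancer range
(0–0.387).

- **β values**: two-component Beta mixture, Beta(2, 10) and Beta(10, 2)
  (modes ≈ 0.1 / 0.9), mixture weight set per probe × cancer type so the
  sample mean is centred on the target mean. This reproduces the
  characteristic bimodality of CpG signals without claiming TCGA realism.
- **Informative probes**: target mean = 0.63 + sign · effect ·
  1.25 · (ORR − midrange), noise added, clipped to [0.02, 0.98]. The
  0.63 centre keeps informative means above 1/e, where the entropy term
  is monotone in β, so sign-coherent planted modules carry a monotone
  entropy signal; with mixed signs, module entropy cancels — which is
  why planted modules are built from the majority-sign genes only (the
  `coherent_informative_genes` truth field).
- **Mutations**: per-sample missense counts log-normal (σ = 0.6) around
  a baseline of 76 (≈ 2/Mb), log-mean shifted by `tmb_link_strength` per
  standardised ORR unit; Silent records are added so zero-missense
  samples stay in the MAF census.
- **Modules**: random scored edges (3 per gene, scores 150–999), random
  gene sets and ligand-receptor pairs, plus one planted module of each
  kind on the coherent informative genes.
- **Determinism**: one integer seed; all generators are spawned from a
  `SeedSequence`, so equal seeds give bit-identical outputs.

What passing on this generator does **not** show: robustness to batch
and purity effects, probe cross-reactivity, realistic inter-probe
correlation (probes are independent given the type mean), methylation–
expression coupling, or per-patient response heterogeneity — none of
which the generator models.

## Problem sizes used in the shipped checks

Test and acceptance runs use deliberately small instances chosen as the
package's own desk-scale defaults: screens on 120–300 probes across 18
types, 8–60 samples/type; 20–50 seed replicates for recovery rates; 100
replicates for planted-module detection; 200 replicates for the screen's
type-I calibration and the synergy null interval; 25 seeds for the
leave-one-type-out smoke check (median held-out ρ ≥ 0.6 at effect 0.9,
noise 0.03). The two published-model anchors (intercept 0.793 at zero β;
0.1313 at median TMB 1) are exact analytic identities of the shipped
fixtures and involve no simulation.

## Known limitations

- The cancer-type-level design cannot support per-patient response
  claims; the synergy outcome label is an explicit surrogate.
- With 18 rows, Lasso support is unstable under resampling; the
  published 8-probe support should be read as one minimum-MSE solution,
  not a unique signature.
- The illegible cg04144714 coefficient makes cohort predictions through
  the published model approximate whenever that probe's β is far from 0.
- Exact Spearman enumeration is factorial in n and is capped at n ≤ 9 by
  design.
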