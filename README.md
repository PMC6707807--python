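# methorr

Predicting objective response rates (ORRs) to PD-1/PD-L1 checkpoint
blockade from DNA-methylation profiles.

Only a minority of patients respond to PD-1/PD-L1 inhibition, and the
established biomarkers (PD-L1 expression, microsatellite instability,
tumor mutational burden) are imperfect. Because response is observed per
*cancer type* (the literature ORR) while molecular profiles are observed
per *tumor sample*, this package works at the cancer-type level: each
cancer type is summarised by the mean 450K-array β value per CpG probe
across its tumor samples, and those summaries are related to the type's
literature ORR. `methorr` is aimed at computational biologists who want
to run, probe, or extend this kind of pan-cancer surrogate-biomarker
analysis with fully synthetic, fully reproducible inputs.

## What it computes

Given per-cancer β matrices (probes × samples), a cancer-type ORR table,
MAF-format somatic mutation tables and functional-module definitions, the
pipeline:

1. **Screens CpGs** — Spearman rank correlation between per-type mean β
   and ORR; a probe passes at |ρ| ≥ 0.7 and P ≤ 0.001 (exact permutation
   p-values for n ≤ 9, the t approximation above). A one-sided
   Kolmogorov–Smirnov test asks whether probes annotated to known
   immuno-oncology target genes carry larger |ρ|, and passing CpGs are
   counted per gene.
2. **Fits the Lasso ORR model** — `y = α + Σ βⱼ xⱼ` with an L1 constraint,
   λ chosen by 10-fold cross-validation at minimum MSE; validated by
   leave-one-cancer-type-out cross-validation with in-fold re-screening.
   The published 8-CpG model (intercept 0.793) ships as a fixture.
3. **Computes TMB** — per patient, missense mutations / 38 Mb; per type,
   the cohort median; and the log-linear comparison model
   `ORR = a·ln(X) + b` (published constants a = 0.0768, b = 0.1313),
   refittable by OLS.
4. **Quantifies CpG × TMB synergy** — Rothman's synergy index
   `S = (OR₁₁ − 1)/((OR₁₀ − 1) + (OR₀₁ − 1))` from a logistic model with
   an interaction term (S = 1 ⇔ additive joint effect), plus per-probe
   Spearman association between sample-level β and TMB with
   Benjamini–Hochberg q-values.
5. **Scores functional modules** — PPI ego-networks (STRING-style scored
   edges, score ≥ 400), pathway gene sets (GMT) and ligand-receptor pairs
   are scored per cancer type by `H = −Σ βᵢ·ln βᵢ` over member probes
   (0·ln 0 := 0) and rank-correlated with ORR.
6. **Evaluates models** — MAE, RMSE, Spearman ρ, Mann–Whitney AUC at the
   0.2 responder cutoff, and per-cancer winner comparison.

A seeded synthetic-data generator (`methorr.synthetic`) produces cohorts
with the structure the analysis assumes — bimodal β, a planted monotone
β/ORR link, ORR-linked mutation counts and planted functional modules —
so every stage runs and is validated without any download.

## Worked example

```python
import pandas as pd
import methorr as m

cfg = m.SyntheticConfig(seed=42, n_probes=300, n_informative_probes=15,
                        noise_sd=0.03)
cohorts  = m.simulate_cohorts(cfg)
profiles = m.aggregate_to_cancer_profiles(cohorts.matrices)

screen = m.spearman_screen(profiles, cohorts.orr)
print(int(screen["passes"].sum()))          # 15  (all planted probes, no false hits)

result = m.loocv(profiles, cohorts.orr, seed=42)
print(round(result.rho, 3))                 # 0.959  held-out Spearman rho

report = m.evaluate(cohorts.orr, result.pairs["predicted"])
print(round(report.mae, 4), round(report.rmse, 4), round(report.auc, 3))
# 0.0128 0.0147 1.0

summary = m.compute_tmb(cohorts.mutations)
print(round(summary.median_tmb, 3))         # 2.105  mutations/Mb
```

The screen finds exactly the 15 planted probes among 300; leaving one
cancer type out at a time, re-screening and refitting the Lasso predicts
the held-out type's ORR with rank agreement 0.96 and a mean absolute
error of ~0.013 ORR units; labelling types as responders at ORR ≥ 0.2,
the predictions separate the classes perfectly (AUC 1.0) at these
generator settings. The shipped published models evaluate as printed:

```python
model = m.load_published_model(quiet=True)
m.predict_orr(model, {p: 0.0 for p in model.support}).value        # 0.793
m.predict_orr_from_tmb(m.PUBLISHED_TMB_ORR_MODEL, 1.0).value       # 0.1313
```

The same workflow is available from the shell (`methorr simulate`,
`methorr screen`, `methorr fit`, `methorr predict`, `methorr tmb`,
`methorr synergy`, `methorr modules`, `methorr evaluate`; see
`methorr --help`).

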