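# Methods

## The problem and the procedure

The package implements a discrimination analysis for case-control CSF
metabolomics: given relative metabolite concentrations from two platforms
(an LC electrochemical array, "ECA", and GC time-of-flight MS, "GC-TOF"), a
three-analyte protein panel (Aβ1-42, total tau, phospho-tau) and per-sample
clinical metadata, how well do different combinations of these data types
discriminate Alzheimer's disease (AD) cases from cognitively normal
controls, and is that discrimination better than chance?

The procedure has four stages.

1. **Preprocessing.** GC-TOF features are kept only if detected in at least
   50% of the samples of at least one diagnostic group, then each sample is
   normalized to its summed intensity over the identified (known)
   metabolites. ECA features are expressed as percent of a pooled central
   CSF reference (pool = 100%). All metabolite values are natural-log
   transformed; residual missing values are imputed with half the feature's
   minimum observed value so that the regression stage sees complete rows.
   Protein analytes are log-transformed the same way — the transform is
   monotone, so it changes coefficients but not ranks or AUCs, and it keeps
   the likelihood well behaved for skewed positive concentrations.

2. **Confound screening.** Drug classes associated with diagnosis (Fisher's
   exact test, p < 0.05) define the drug screens: every metabolite is tested
   against each such drug's use flag by a two-group Kruskal-Wallis test, and
   against the ApoE risk grouping (E3/E4 and E4/E4 genotypes high risk).
   Any metabolite with any screening p < 0.05 is removed before model
   building. This is deliberately conservative: AD treatment is nearly
   exclusive to cases, so a drug-response metabolite is indistinguishable
   from a disease marker at the single-cohort level. Protein analytes are
   never screened. The union of removals is counted once per feature.

3. **Model building.** Forward stepwise logistic regression scored by BIC
   (−2L + k·ln n, k counting the intercept): starting from the
   intercept-only model, each step fits every single-feature addition and
   accepts the lowest-BIC candidate if it is strictly lower than the current
   BIC. The search is nested inside stratified 5-fold cross-validation:
   each fold's stepwise model is built on the 4/5 training portion only and
   scored by training AUC and held-out testing AUC. The final variable set
   is chosen by *cross-validation consistency* — variables selected in a
   majority (≥3 of 5) of folds, falling back to the maximal-count variables
   if none reach the majority. The final model is refit on all samples for
   coefficient reporting, but the reported discrimination is always the
   mean testing AUC, never the refit's apparent AUC. Screening stays
   outside the CV loop, mirroring the sequential design (screen once, then
   cross-validate the model building); the associated optimism is absorbed
   by the permutation test below, which repeats both stages.

4. **Evaluation.** AUC is the midrank Mann-Whitney statistic (identical to
   the trapezoidal area under the empirical ROC). Sensitivity and
   specificity are computed on pooled out-of-fold predicted probabilities at
   the 0.5 cutoff (a Youden-maximizing rule is available). Significance of
   each model is assessed by a whole-pipeline permutation test: case labels
   are shuffled at fixed group proportions and the *entire* procedure —
   screen plus cross-validated stepwise search — is re-run per permutation;
   the empirical p uses the add-one convention p = (1 + #{null ≥
   observed})/(B + 1), so p is never 0. Pairs of models are compared with
   the paired DeLong test on pooled out-of-fold probabilities, with a
   Bonferroni family of all model pairs (15 for the six standard pools).

## The synthetic cohort generator

No measured cohort ships with the package, so a generator emulates the
study design: 40 cases and 38 controls; 71 ECA features (24 known) with a
pooled reference; 299 GC-TOF features (130 treated as known for the
normalization) with 10% missing-completely-at-random dropout; 3 protein
analytes. Log-scale feature values are a feature baseline plus standardized
effects plus unit-variance Gaussian noise (optionally equicorrelated — the
correlation is exposed as a parameter because no covariance structure is
asserted), then exponentiated, i.e. intensities are log-normal.

Planted structure, all expressed as standardized shifts on the log scale:

| parameter | default | meaning |
|---|---|---|
| `n_signal`, `signal_effect` | 2 features, +2.0 SD | disease markers on ECA, shifted in cases |
| `n_drug_confounded`, `drug_effect` | 10 features, +2.0 SD | GC-TOF features shifted in users of the AD-treatment drugs (assigned round-robin to cholinesterase inhibitor and memantine) |
| `n_apoe_linked`, `apoe_effect` | 2 features, +2.0 SD | GC-TOF features shifted in high-risk ApoE carriers |
| `protein_effects` | Aβ42 −1.5, t-tau +1.5, p-tau +1.5 | the established pathology-marker pattern |
| `drug_prevalence` | demographics-table rates | e.g. cholinesterase inhibitor 37.5% of cases / 0% of controls, memantine 15% / 0% |

Drug flags are assigned by deterministic rounding of prevalence × group
size (so the cohort margins reproduce exactly, e.g. exactly 15 of 40 cases
on a cholinesterase inhibitor) with a random choice of carriers. MMSE is
drawn lower for cases (mean 19.9 vs 29.2). ApoE high-risk prevalence is
0.35 in *both* groups: the generator deliberately keeps ApoE independent of
diagnosis, because an ApoE-diagnosis association would make the ApoE screen
remove genuine disease markers for the same reason the drug screen does
(see below), and no genotype frequencies are asserted by the emulated
design.

What the generator does **not** emulate: inter-metabolite correlation
(independent by default), detection-limit (value-dependent) missingness,
batch or drift structure, and platform-specific error models. Passing tests
therefore demonstrate correctness and calibration of the *procedure* under
a clean log-normal data-generating process, not performance claims about
real CSF data.

## Confounding by treatment, and the recovery experiment

With the default prevalences, AD-treatment drug use is case-exclusive, so
any genuine disease marker is *also* strongly associated with drug use
through the diagnosis; the drug screen then removes it with power near 1.
This is not a defect of the screen — it is exactly the conservatism the
screen is designed for (a treated-cases cohort cannot distinguish disease
response from drug response). Consequently the package's standard
*recovery* experiment (can the pipeline find the two planted disease
markers among 370 metabolites at n = 78?) is run on a drug-free variant of
the default cohort (`GeneratorConfig.without_drugs()`), which isolates the
property being measured. The screen's own behaviour under confounding is
validated separately: at a 2-SD drug effect, confounded features tied to
the cholinesterase inhibitor (15 users) are removed essentially always, and
those tied to memantine (6 users) in about four of five cohorts — the
memantine bound is a small-sample rank-test power limit, not an
implementation artifact.

Even in the drug-free cohort the ApoE screen retains a small chance of
destroying the planted markers: the realized ApoE-risk fraction differs
between diagnostic groups by sampling noise (SD ≈ 0.11 around the 0.35
prevalence at n = 78), disease-shifted features inherit that chance
association, and in about 1% of cohorts (direct simulation) *both* markers
cross the nominal screening threshold and are removed, making recovery
impossible by construction in those replicates. This is a finite-sample
property of screening on a covariate that is only asymptotically
independent of diagnosis, and it is the binding constraint on the recovery
experiment's permutation power (expected ≈ 0.99 over replicate sets of
50).

## Numerical choices

- **Logistic fits** use Newton/IRLS to a gradient tolerance of 1e-8 with a
  100-iteration cap and a step clip of 5 to stabilize early iterations.
  The stepwise candidate scan fits all single-feature extensions
  simultaneously (batched Hessians assembled from BLAS products); scan fits
  use a looser 1e-5 gradient tolerance — the scan only ranks candidates,
  and the accepted model is re-polished at 1e-8.
- **Separation** is flagged when any coefficient magnitude exceeds 30
  (indistinguishable from a step function on log-scale predictors).
  Separation-flagged candidates are skipped during stepwise; if the final
  refit separates, a ridge of 1e-6 stabilizes the reported coefficients
  only.
- **Ties.** Stepwise BIC ties break deterministically by feature-ID order.
  AUC uses midranks, so auc(s) + auc(−s) = 1 exactly. The Kruskal-Wallis
  statistic is tie-corrected; an all-constant feature yields H = 0 by
  convention.
- **Degenerate inputs.** Constant drug flags are skipped with a warning
  (not an error); an empty candidate pool yields the intercept-only model
  with AUC 0.5; a zero known-metabolite sum or non-positive pool reference
  is an error naming the offending sample/feature.
- **Box-plot outliers** follow the emulated figure's convention — more than
  1.5×IQR from the *median* — with the standard Tukey fences available.

## Stepwise-BIC behaviour when p ≫ n

With ~370 null candidates and n = 78, the best single-feature
likelihood-ratio statistic is the maximum of hundreds of ~χ²(1) draws,
which far exceeds the BIC penalty ln(78) ≈ 4.36; each fold's stepwise model
therefore picks up around ten noise variables under the null. This is
intrinsic to stepwise-BIC (the criterion has no multiplicity control over
the scan), and it is why the pipeline reports held-out testing AUC (which
stays at 0.5 under the null) and attaches significance by whole-pipeline
permutation rather than by any in-sample statistic.

## Problem sizes of the standard experiments

- *Null calibration*: 100 replicate null cohorts × (1 + 99 permuted
  re-runs) of the full pipeline. Calibration cohorts use the full n = 78
  but a reduced 43-feature panel: the permutation p is the rank of the
  observed statistic among exchangeable re-runs, so its null uniformity
  does not depend on panel width, and the reduced panel keeps the 10,100
  pipeline executions desk-scale.
- *Recovery*: 50 replicate drug-free cohorts at the full 370-metabolite
  width, B = 24 permutations each (the smallest B whose add-one minimum
  attainable p, 1/25 = 0.04, is below the 0.05 criterion; the observed
  statistic exceeds every permuted one in practice, so power is not
  B-limited).
- *Oracle checks*: exhaustive subset search on 6-feature pools (64 subsets),
  hypergeometric enumeration for Fisher tables, delete-one jackknife for
  the DeLong variance, brute-force concordance for AUC.

## Known limitations

- The screen-outside-CV design leaks screening information into the fold
  AUCs; the permutation test accounts for it at the significance level, but
  the reported mean testing AUC remains optimistic to the extent the screen
  is label-dependent. A strict re-screen-per-fold mode is not provided;
  re-screening happens per *permutation*, which is where the design puts
  the correction.
- Sensitivity/specificity at the fixed 0.5 cutoff are unstable when a model
  degenerates to near-constant probabilities.
- The DeLong comparison assumes both score vectors are evaluated on the
  same samples (paired); no unpaired variant is provided.
- Fold assignment is a seeded function of sample positions; reordering
  samples within a class yields a different (equally valid) partition.
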