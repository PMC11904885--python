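# Methods

## Problem and model

The task is binary: given a peptide (8–14 canonical residues) and an HLA
class I allele group, predict whether the peptide loads onto that
molecule in a cell-free, exogenous setup. Training data are qualitative
MHC binding-assay outcomes; ligand-elution results and predicted binding
affinities are deliberately out of scope, because they reflect the
endogenous presentation pathway rather than in-vitro loading.

The classifier is logistic regression with an elastic-net penalty on 147
CTD (composition/transition/distribution) descriptors. Linearity is a
deliberate modeling assumption: with a few thousand records per allele
group and qualitative (noisy) labels, a sparse linear model is robust,
fast, and its coefficients are directly interpretable in terms of
physicochemical sequence properties.

## CTD descriptors

Seven property schemes partition the 20 canonical amino acids into three
classes each. The shipped tables are the classical three-class CTD
partitions (e.g. charge: positive {K,R} / neutral (16 residues) /
negative {D,E}); they live in `src/mhcload/data/schemes/*.json` and are
validated on load (exact cover of the alphabet, no empty class), so a
different partition can be dropped in without code changes. The
`scheme_fingerprint` stored in every model registry guards against
predicting with coefficients trained under different partitions.

Per property, for the class-index sequence of length L:

- composition: class counts / L (3 values, summing to 1);
- transition: for each unordered class pair {g,h}, the number of adjacent
  positions with classes {g,h} divided by L−1 (3 values);
- distribution: for each class g with occurrences at 1-based positions
  p₁<…<p_n, the five values p₁/L and p_k/L with k = ceil(q·n) for
  q ∈ {0.25, 0.5, 0.75, 1}. An absent class contributes five zeros —
  this keeps the vector dense and bounded, at the cost of conflating
  "absent" with "at position 0"; the paired composition value (0)
  disambiguates.

The percentile rank uses the ceiling convention by default; a
nearest-rank variant (`k = max(1, round(q·n))`) is available as
`distribution_mode="round"` since both conventions circulate in the CTD
literature. All 147 values are kept as [0, 1] fractions rather than
percentages; the scale is absorbed by the solver's internal
standardization, and consistency between training and prediction is what
matters. The quantile multipliers are dyadic (0.25, 0.5, 0.75, 1.0), so
`ceil` sees exact products and the descriptors are platform-independent.

## Curation

Raw assay exports are reduced to one record per (epitope, allele group):

1. outcomes `Positive`, `Positive-Low`, `Positive-Intermediate`,
   `Positive-High` → positive; `Negative` → negative; anything else is
   unmappable and excluded (counted, never imputed);
2. records are dropped when the HLA annotation does not resolve to at
   least an allele group (locus + first nomenclature field, e.g.
   `HLA-A*02`; serological names and `HLA class I` fail), when the
   peptide contains a non-canonical letter, or when a co-factor is
   annotated. Four-digit allele names are truncated to the group for
   modeling and kept verbatim in provenance;
3. replicate assays of one pair merge by majority vote with the replicate
   count rₑ retained; exact ties are dropped. The vote is configurable
   (`any_positive`, `drop_conflicts`) because assay databases do not
   state how conflicting replicates should combine; majority-with-drop is
   the symmetric, conservative default. rₑ is counted per (epitope, HLA)
   pair — not per epitope across HLAs — which is the stricter, less leaky
   reading;
4. a quality cutoff keeps pairs with rₑ ≥ t, t ∈ {1..5} (t = 1 is the
   identity);
5. any allele group with fewer than 100 positive or 100 negative records
   is removed entirely.

Every rule logs a drop count and the provenance report balances exactly:
`n_input = n_output + Σ dropped` (replicate merging is accounted as
`merged_replicates = Σ(rₑ−1)`). This identity is asserted in code and in
the tests, and makes silent record loss impossible.

## Training

**Splits.** All cross-validation is grouped by epitope sequence: the
unique peptides are partitioned, so a peptide measured against several
alleles never straddles a train/test boundary. The outer loop is
Monte-Carlo: `repeats` (default 10) independent 80/20 splits with the test
side receiving round(0.2 · #epitopes) epitopes.

**Inner problem.** For a fixed mixing parameter α, the lambda path runs
from λ_max (the smallest penalty that zeroes all coefficients;
α is floored at 0.001 in the λ_max formula so the ridge limit stays
finite) down to λ_max·1e-4 over 100 log-spaced values (package default;
see below for reduced sizes). λ is chosen as the minimizer of the mean
out-of-fold binomial deviance in a 6-fold epitope-grouped inner CV — the
"min" rule, ties toward the larger (sparser) λ. Features are standardized
to zero mean and unit population variance inside the solver; coefficients
are reported back on the original feature scale.

**α search.** α runs over {0.00, 0.01, …, 1.00}; per (split, α) a model
is fitted on the 80% side and scored on the 20% side. The selection
criterion is the mean outer-fold binomial deviance (misclassification
rate and F1 are recorded alongside and can be chosen instead); deviance
is threshold-free and is the quantity the penalized fit optimizes. Ties
resolve to the smaller α.

**Variants and registry.** Four scope kinds — generic, per-length,
per-HLA, per-(HLA, length) — are each trained across the QC cutoffs
t ∈ {1..5}; per scope cell the t with the lowest CV error is retained.
A variant trains only if its scoped data hold ≥ 50 positives and ≥ 50
negatives; otherwise a refusal with the reason is recorded. At query
time the lowest-CV-error covering model wins, exact ties resolve toward
the more specific scope (HLA+length > HLA > length > generic), and
uncovered queries fall back to the generic model. CV errors of variants
trained on different record subsets are compared as computed; this is a
known statistical caveat of the selection rule, accepted by design.
α is selected per variant, not globally. No class weighting is applied;
class imbalance is visible in the registry's per-model counts.

**Determinism.** A single master seed derives per-(variant, repeat)
streams (multiplicative hash + CRC32 of the variant id, kept below 2³¹),
so any variant is reproducible in isolation; the solver itself contains
no randomness. Identical data + config + seed reproduce the registry
bit-for-bit, and the JSON serialization stores floats by `repr`, so a
write/read cycle is exact.

## Solver

The per-λ problems are solved with iteratively reweighted least squares
around the current linear predictor plus cyclic coordinate descent with
soft thresholding on the weighted quadratic approximation — the standard
algorithm for elastic-net GLMs — warm-started from large to small λ, with
active-set sweeps (iterate the nonzero set until converged, then one full
sweep to verify). IRLS weights p(1−p) are floored at 1e-5. Convergence is
declared when the largest weight-scaled coefficient update in a sweep
falls below `tol` (default 1e-6; at that setting coefficients agree with
a tol=1e-9 solve to <1e-3 and with scikit-learn's SAGA at high precision
to ~4e-6). The kernel is numba-compiled; lasso zeros are exact soft-
threshold zeros, not rounded values. The test suite cross-checks the
solver against R `glmnet` on a shared λ sequence (agreement to 2e-4).

Degenerate inputs: constant feature columns get unit scale during
standardization and necessarily zero coefficients; single-class labels,
non-finite features, α outside [0,1] and empty α grids are rejected with
explicit errors.

## Prediction and evaluation

A query (peptide, HLA) resolves its allele group, featurizes the peptide,
selects the registry model, and reports probability = inverse-logit of
the linear predictor plus a class label: `Loadable` iff probability >
threshold (default 0.5 — the natural logistic cut; overridable). Invalid
peptides yield per-row error notes and the batch continues; unresolvable
HLA names fall back to the generic model with a note.

Evaluation computes sensitivity, specificity, accuracy, balanced accuracy
(= their mean) and F1 from the confusion matrix, optionally per group.
"Mean accuracy across HLAs" is the **unweighted** mean of per-HLA
accuracies, i.e. each allele counts equally regardless of its record
count. A group with a single observed class reports NaN for the undefined
ratio with a warning — report, not fail. Pre-computed label columns from
external tools can be scored side by side (`compare_external`); rows
lacking a tool's label are excluded for that tool only, with counts.

## Synthetic data

The generator emulates an IEDB-style export well enough to exercise every
pipeline stage. Each epitope (unique random peptide, lengths uniform on
8–14) is assayed against every listed allele; the true loading
probability is p = expit(w·(x − x̄) + b + shift_h) with sparse planted
weights w over the CTD names, the linear predictor centered on the
generated panel (keeping classes balanced), and a per-allele offset.
Replicate counts are drawn from a distribution over {1..5} (defaults
0.55/0.15/0.15/0.05/0.10); each replicate's observed label is the
Bernoulli(p) truth flipped independently with the label-noise probability
(default 0.05), so majority-vote and tie handling are genuinely
exercised. Positive labels are spelled uniformly at random across the
four `Positive*` variants; contaminant rows (unresolved HLA,
non-canonical residues, co-factors, unmappable outcomes) are appended at
1% each by default. A sidecar aligned row-for-row with the table records
the truth, the planted model, and two Bayes accuracies: against true
labels, E[max(p, 1−p)], and against noisy labels, E[max(q, 1−q)] with
q = ε + (1−2ε)p.

The default planted model puts weights of magnitude 5–12 on five
descriptors (charge, hydrophobicity and van der Waals composition, helix
propensity composition, one polarizability distribution feature) and
±0.5 per-allele offsets on two alleles, yielding a strongly but not
perfectly separable problem (Bayes accuracy ≈ 0.83 before noise) — large
enough effects for recovery to be testable, small enough that the test is
not vacuous.

What the generator does **not** emulate: real binding-affinity
distributions, sequence motifs (the signal is planted in feature space,
where recovery by a linear model is well-posed), allele-specific binding
grooves, assay batch effects. Passing the recovery tests therefore shows
the pipeline is correct and self-consistent, not that the model attains
any particular accuracy on laboratory data.

## End-to-end benchmark and problem sizes

`mhcload.benchmark.recovery_benchmark` runs
generate → curate → train → predict and scores recovery. Because
symmetric label flips leave the 0.5 decision boundary invariant, a
correctly recovered model should reach the **pre-flip** Bayes accuracy on
held-out pairs when scored against true labels; the benchmark reports
both that accuracy and the test-set Bayes accuracy, and the acceptance
test requires agreement within three binomial standard errors, plus sign
agreement of all planted coefficients.

The benchmark's sizes are chosen for a single-core run of a few minutes:
2000 epitopes × 2 alleles, α grid {0, 0.25, 0.5, 0.75, 1}, 5 Monte-Carlo
repeats, a 12-point λ path down to λ_max·0.03, solver tol 1e-5, and
generic + per-HLA variants at t = 1. λ-path resolution affects the
selected model only marginally here; the full 101-point α grid and
100-point λ path remain the package defaults for real training runs.

## Known limitations

- Allele identity enters only through the registry scoping, not as a
  model feature; alleles without a specific model inherit the generic
  decision boundary.
- CV errors compared across variants are estimated on different subsets
  (see above).
- No support for post-translationally modified or non-canonical residues;
  such peptides are rejected or filtered, by design.
- The distribution block's absent-class zeros make descriptor space
  mildly discontinuous at class extinction; with 3-class partitions over
  8–14-mers this is common and the linear model simply sees it as an
  interaction with composition ≈ 0.
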