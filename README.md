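# mhcload

Predicting whether a peptide can be loaded **exogenously** onto an MHC
class I molecule.

Cell-free workflows — UV-mediated peptide exchange on soluble MHC-I
monomers, multimer production for antigen-specific T-cell detection,
peptide-screening panels — all require the peptide of interest to form a
stable peptide–MHC-I complex *in vitro*, without the chaperone machinery of
the endoplasmic reticulum. A peptide that is presented endogenously is not
guaranteed to load in such a setup, so tools trained for HLA-restriction
prediction (which lean heavily on ligand-elution data) can mislead here.
`mhcload` addresses the loading question directly: it curates qualitative
MHC *binding-assay* outcomes into per-allele training sets and fits
interpretable linear classifiers on physicochemical sequence descriptors.

## The model

Each peptide is described by **CTD descriptors**: for seven
physicochemical properties (hydrophobicity, polarizability, polarity,
normalized van der Waals volume, charge, solvent accessibility, secondary
structure propensity) the 20 amino acids are partitioned into three
classes, and the class-index sequence is summarized by

- **C**omposition — the class fractions c₁, c₂, c₃;
- **T**ransition — the fraction of adjacent residue pairs whose classes
  form each unordered pair {g,h}, g≠h;
- **D**istribution — the normalized positions (position/L) of the first,
  25%, 50%, 75% and 100% occurrence of each class.

That is 3 + 3 + 15 = 21 descriptors per property, 147 in total, all in
[0, 1] and comparable across peptide lengths (MHC-I epitopes are typically
8–14-mers).

On these features a binary **elastic-net logistic regression** is fitted,
minimizing

    (1/n) Σᵢ ℓ(yᵢ, β₀ + xᵢᵀβ) + λ [ α‖β‖₁ + (1−α)/2 ‖β‖₂² ]

with ℓ the binomial deviance. λ is selected on a warm-started
regularization path by a 6-fold inner cross-validation grouped by epitope;
α is selected by **Monte-Carlo cross-validation** — 10 independent
epitope-disjoint 80/20 splits over a grid from 0 to 1 in steps of 0.01 —
so that no peptide sequence ever appears on both sides of a split ("data
bleeding"). Four model variants are trained (HLA-agnostic / HLA-specific ×
length-agnostic / length-specific), each across replicate quality cutoffs
t ∈ {1..5} on the per-pair assay replicate count rₑ, and a registry keeps
the lowest-CV-error model per scope, with tie-breaks toward the more
specific scope and a fallback chain down to the generic model. A variant
is trained only when its scoped data contain at least 50 positives and 50
negatives; curation itself requires at least 100 positive and 100 negative
records per allele group.

The per-lambda solves use the classical IRLS + cyclic coordinate-descent
algorithm for penalized GLMs (numba-compiled), cross-checked in the test
suite against R's `glmnet`.

## Worked example

The package ships a synthetic assay-table generator with a planted linear
signal, so the whole pipeline can be exercised without any downloads:

```sh
mhcload synth --n-epitopes 400 --seed 7 --out assays.tsv --truth truth.json
# wrote 1641 assay rows to assays.tsv; truth sidecar truth.json
mhcload curate --in assays.tsv --out dataset.tsv --min-per-class 50
# curated 1641 assay rows -> 794 records (2 HLAs); provenance sidecar written
mhcload train --dataset dataset.tsv --out registry.json \
    --alpha-grid 0,0.5,1 --repeats 3 --qc-cutoffs 1 --n-lambda 10 --seed 7
# registry with 9 models (15 refusals) written to registry.json

printf 'peptide,hla\nSIINFEKL,HLA-A*02\nFPSLREAAL,HLA-B*07\nKVAELVHFL,HLA-A*02\n' > queries.csv
mhcload predict --registry registry.json --queries queries.csv --out predictions.csv
cat predictions.csv
```

```
peptide,hla,probability,label,model_id,threshold,note
SIINFEKL,HLA-A*02,0.955630133585019,Loadable,hla=any|len=any|t=1,0.5,
FPSLREAAL,HLA-B*07,0.4377022244781652,Not-loadable,hla=HLA-B*07|len=any|t=1,0.5,
KVAELVHFL,HLA-A*02,0.9690227328202442,Loadable,hla=any|len=any|t=1,0.5,
```

Per query the registry resolves the best covering model (`model_id` shows
which one: the B*07 query used the B*07-specific model, the A*02 queries
the generic one), the probability is the inverse logit of the linear
predictor on the 147 CTD features, and the label is `Loadable` iff the
probability strictly exceeds the threshold (default 0.5). The curation
step writes a provenance sidecar whose per-rule drop counts balance the
input row count exactly.

The 1641 assay rows shrink to 794 training records because replicate
assays of the same (epitope, HLA) pair are merged by majority vote (tied
pairs dropped) and contaminant rows — unresolved HLA annotation,
non-canonical residues, co-factors, unmappable outcome strings — are
filtered out, each with a logged count.

The same steps are available as library calls (`mhcload.featurize`,
`mhcload.curate`, `mhcload.build_registry`, `mhcload.predict`, ...), with
the featurizer and the elastic-net solver exposed as sklearn-style
estimators (`CTDFeaturizer`, `ElasticNetLogisticCV`) that compose with
sklearn pipelines.

## Layout

| Path | Contents |
| --- | --- |
| `src/mhcload/schemes.py` | three-class property partitions (JSON data files under `data/schemes/`) |
| `src/mhcload/features.py` | CTD descriptors, `CTDFeaturizer` |
| `src/mhcload/curation.py` | assay-table reading, label harmonization, filters, replicate QC, class-count gates |
| `src/mhcload/model.py` | elastic-net logistic regression with lambda path + grouped inner CV |
| `src/mhcload/training.py` | epitope-disjoint splits, MC-CV alpha search, variants, model registry |
| `src/mhcload/predict.py` | prediction, confusion-matrix metrics, external-tool comparison |
| `src/mhcload/synthetic.py` | IEDB-shaped synthetic tables with planted ground truth |
| `src/mhcload/benchmark.py` | end-to-end recovery benchmark |
| `docs/methods.md` | methods note: model, assumptions, defaults, limitations |
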