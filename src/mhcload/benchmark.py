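"""End-to-end synthetic recovery benchmark.

Runs the whole pipeline — generate a synthetic assay table with a planted
linear signal, curate it, train elastic-net models with epitope-disjoint
Monte-Carlo cross-validation, and predict on held-out epitopes — and
measures how well the planted structure is recovered: held-out accuracy
against the generating truth (to be compared with the recorded
Bayes-optimal accuracy), the sign agreement of the recovered coefficients
with the planted weights, and the cross-validated F1 of the pooled model.

This is the package's core integration check and the basis of
``scripts/acceptance.py``.  Problem sizes default to a run that finishes in
a few minutes on one core: 2000 epitopes on two alleles, a 5-point alpha
grid, 5 Monte-Carlo repeats and a short (12-point) lambda path; the planted
model and its 5% label noise are the generator defaults.
"""

from __future__ import annotations

import tempfile
from pathlib import Path
from typing import Sequence

import numpy as np

from .curation import CuratedDataset, curate, read_assay_table
from .features import CTDFeaturizer
from .predict import evaluate, mean_accuracy, predict
from .schemes import scheme_fingerprint
from .synthetic import default_planted_model, generate_assay_table, truth_pair_labels
from .training import (
    ModelRegistry,
    Refusal,
    TrainedModel,
    TrainingConfig,
    VariantSpec,
    split_by_epitope,
    train_variant,
)


def recovery_benchmark(
    seed: int,
    n_epitopes: int = 2000,
    noise: float = 0.05,
    alpha_grid: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    repeats: int = 5,
    n_lambda: int = 12,
    lambda_min_ratio: float = 0.03,
    tol: float = 1e-5,
    test_fraction: float = 0.2,
    min_per_class: int = 100,
    hla_specific: bool = True,
) -> dict:
    """Generate → curate → train → predict and score the recovery.

    Returns a flat dict of the measured quantities; every entry is computed
    by running the pipeline, nothing is read from configuration except the
    problem sizes above.
    """
    seed = int(seed) % (2**31 - 1)
    planted = default_planted_model(noise=noise)

    with tempfile.TemporaryDirectory() as tmp:
        table_path = Path(tmp) / "assays.tsv"
        _, truth = generate_assay_table(
            n_epitopes=n_epitopes, planted=planted, seed=seed, out=table_path
        )
        records, n_malformed = read_assay_table(table_path)

    dataset = curate(records, min_per_class=min_per_class, n_malformed=n_malformed)
    prov = dataset.provenance
    conservation_gap = prov["n_input"] - prov["n_output"] - sum(prov["dropped"].values())

    train_records, test_records = split_by_epitope(
        dataset.records, test_fraction=test_fraction, seed=seed + 1
    )
    train_ds = CuratedDataset(records=train_records)

    cfg = TrainingConfig(
        alpha_grid=list(alpha_grid),
        repeats=repeats,
        n_lambda=n_lambda,
        lambda_min_ratio=lambda_min_ratio,
        tol=tol,
        qc_cutoffs=(1,),
        seed=seed,
    )
    featurizer = CTDFeaturizer(warn_length_range=None).fit()

    specs = [VariantSpec()]
    if hla_specific:
        specs += [VariantSpec(hla=h) for h in sorted(train_records["hla"].unique())]
    models: list[TrainedModel] = []
    refusals: list[Refusal] = []
    for spec in specs:
        out = train_variant(train_ds, spec, cfg, featurizer)
        (models if isinstance(out, TrainedModel) else refusals).append(out)
    generic = next(mdl for mdl in models if mdl.variant.cell == (None, None))
    registry = ModelRegistry(
        models=models,
        feature_names=tuple(featurizer.feature_names_),
        scheme_fingerprint=scheme_fingerprint(featurizer.schemes_),
        refusals=refusals,
    )

    # score on the held-out epitopes against the generating truth
    pairs = truth_pair_labels(truth).merge(
        test_records[["epitope", "hla"]], on=["epitope", "hla"]
    )
    preds = predict(
        list(zip(pairs["epitope"], pairs["hla"])), registry, featurizer=featurizer
    )
    metrics = evaluate(preds["label"], pairs["true_label"], group_by=pairs["hla"])
    overall = evaluate(preds["label"], pairs["true_label"])

    p = pairs["probability"].to_numpy()
    bayes_test = float(np.mean(np.maximum(p, 1.0 - p)))
    accuracy = float(overall.loc["all", "accuracy"])

    planted_signs = {
        name: np.sign(w) for name, w in planted.weights.items()
    }
    coef = dict(zip(generic.feature_names, generic.coefficients))
    sign_matches = [
        float(np.sign(coef[name]) == s) for name, s in planted_signs.items()
    ]

    return {
        "n_assay_rows": prov["n_input"],
        "n_curated_records": prov["n_output"],
        "n_retained_hlas": len(dataset.retained_hlas),
        "conservation_gap": conservation_gap,
        "n_test_pairs": int(len(pairs)),
        "held_out_accuracy": accuracy,
        "bayes_accuracy_test": bayes_test,
        "bayes_accuracy_true": truth["bayes_accuracy_true"],
        "mean_accuracy_across_hlas": mean_accuracy(metrics),
        "held_out_f1": float(overall.loc["all", "f1"]),
        "held_out_balanced_accuracy": float(overall.loc["all", "balanced_accuracy"]),
        "sign_recovery_fraction": float(np.mean(sign_matches)),
        "n_planted_features": len(planted.weights),
        "generic_alpha": generic.alpha,
        "generic_cv_error": generic.cv_error,
        "generic_cv_f1_median": generic.cv_metrics["f1_median"],
        "n_models": len(models),
    }
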