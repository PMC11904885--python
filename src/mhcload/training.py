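"""Model variants, Monte-Carlo cross-validation and the model registry.

Four classifier variants are trained on a curated dataset:

(i) generic (HLA-agnostic, length-agnostic), (ii) length-specific generic,
(iii) HLA-specific, and (iv) HLA- and length-specific.  Each variant is
additionally trained under replicate quality cutoffs t = 1..5 (records with
``re >= t``), and per scope cell the cutoff with the lowest CV error is
retained.  A variant is trained only if its scoped data contain at least 50
positive and 50 negative records; otherwise it is refused with a reason.

The mixing parameter alpha is selected by Monte-Carlo cross-validation:
``repeats`` independent epitope-disjoint 80/20 splits; per split the model is
fitted on the 80% side (with its own inner 6-fold lambda selection, grouped
by epitope) and scored on the 20% side; the alpha with the lowest mean CV
error wins, ties going to the smaller alpha.  "Epitope-disjoint" means the
unique peptide sequences are partitioned, so an epitope measured against
several HLAs never straddles the split.

At query time :func:`ModelRegistry.select_best` returns, among all retained
models whose scope covers the queried (HLA group, peptide length), the one
with the lowest CV error; exact ties resolve toward the more specific scope
(HLA+length > HLA > length > generic), and queries covered by nothing fall
back to the generic model.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .curation import CuratedDataset, apply_qc_cutoff
from .features import CTDFeaturizer, feature_names
from .model import ElasticNetLogisticCV, binomial_deviance
from .schemes import load_builtin_schemes, scheme_fingerprint

logger = logging.getLogger(__name__)

REGISTRY_FORMAT_VERSION = 1


def default_alpha_grid() -> np.ndarray:
    """The default alpha grid: 0.00 to 1.00 in steps of 0.01 (101 values)."""
    return np.round(np.arange(101) / 100.0, 2)


@dataclass(frozen=True)
class VariantSpec:
    """Scope of one model variant: HLA group and/or peptide length, plus QC cutoff."""

    hla: str | None = None  # None = HLA-agnostic
    length: int | None = None  # None = length-agnostic
    qc_cutoff: int = 1

    @property
    def hla_specific(self) -> bool:
        return self.hla is not None

    @property
    def length_specific(self) -> bool:
        return self.length is not None

    @property
    def specificity(self) -> int:
        """Tie-break rank: HLA+length (3) > HLA (2) > length (1) > generic (0)."""
        return 2 * self.hla_specific + self.length_specific

    def covers(self, hla: str, length: int) -> bool:
        return (self.hla is None or self.hla == hla) and (
            self.length is None or self.length == length
        )

    @property
    def cell(self) -> tuple[str | None, int | None]:
        """Scope cell identity, ignoring the QC cutoff."""
        return (self.hla, self.length)

    @property
    def model_id(self) -> str:
        hla = self.hla if self.hla is not None else "any"
        length = self.length if self.length is not None else "any"
        return f"hla={hla}|len={length}|t={self.qc_cutoff}"


@dataclass
class Refusal:
    """A variant that could not be trained, with the gate that stopped it."""

    spec: VariantSpec
    reason: str
    n_pos: int = 0
    n_neg: int = 0


@dataclass
class TrainedModel:
    """A fitted elastic-net logistic classifier plus its provenance."""

    variant: VariantSpec
    alpha: float
    lambda_: float
    intercept: float
    coefficients: np.ndarray
    feature_names: tuple[str, ...]
    cv_error: float
    cv_metrics: dict
    n_pos: int
    n_neg: int
    seed: int

    @property
    def model_id(self) -> str:
        return self.variant.model_id

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coefficients + self.intercept


@dataclass
class TrainingConfig:
    """Hyperparameters of the training procedure (defaults = study conditions)."""

    alpha_grid: Sequence[float] = field(default_factory=lambda: default_alpha_grid().tolist())
    repeats: int = 10
    inner_folds: int = 6
    test_fraction: float = 0.2
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    min_per_class_train: int = 50
    qc_cutoffs: Sequence[int] = (1, 2, 3, 4, 5)
    cv_metric: str = "deviance"  # deviance | misclassification | f1
    tol: float = 1e-6
    seed: int = 0


def _derive_seed(master_seed: int, *context: str | int) -> int:
    """Deterministic per-(variant, repeat) stream seed below 2**31."""
    key = "|".join(str(c) for c in context)
    return (int(master_seed) * 2654435761 + zlib.crc32(key.encode())) % (2**31 - 1)


def split_by_epitope(
    records: pd.DataFrame | CuratedDataset,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition records by unique epitope sequence into train and test.

    The test side receives ``round(test_fraction * n_unique_epitopes)``
    epitopes; every record of an epitope (across all HLAs) lands on the same
    side, so no sequence is shared between fitting and testing.
    """
    df = records.records if isinstance(records, CuratedDataset) else records
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    epitopes = np.sort(df["epitope"].unique())
    if epitopes.size < 5:
        raise ValueError(
            f"need at least 5 unique epitopes to split, got {epitopes.size}"
        )
    n_test = int(round(test_fraction * epitopes.size))
    n_test = min(max(n_test, 1), epitopes.size - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(epitopes.size)
    test_epitopes = set(epitopes[perm[:n_test]])
    mask = df["epitope"].isin(test_epitopes)
    return df.loc[~mask].reset_index(drop=True), df.loc[mask].reset_index(drop=True)


def _score_split(model: ElasticNetLogisticCV, X_test, y_test) -> dict[str, float]:
    prob = model.predict_proba(X_test)[:, 1]
    pred = (prob > 0.5).astype(int)
    y = np.asarray(y_test)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else float("nan")
    return {
        "deviance": binomial_deviance(y, prob),
        "misclassification": float((pred != y).mean()),
        "accuracy": float((pred == y).mean()),
        "f1": f1,
    }


@dataclass
class AlphaSearchResult:
    best_alpha: float
    cv_error: pd.DataFrame  # index alpha, columns metric means
    per_repeat: pd.DataFrame  # rows (alpha, repeat) with all metrics


def mc_cv_alpha_search(
    records: pd.DataFrame,
    featurizer: CTDFeaturizer,
    alpha_grid: Iterable[float] | None = None,
    repeats: int = 10,
    seed: int = 0,
    config: TrainingConfig | None = None,
) -> AlphaSearchResult:
    """Choose alpha by repeated epitope-disjoint 80/20 validation.

    Features of the unique epitopes are computed once and reused across all
    splits.  The CV error is the configured metric's mean over repeats
    (binomial deviance by default); ties resolve to the smaller alpha.
    """
    cfg = config or TrainingConfig()
    grid = np.asarray(
        list(alpha_grid) if alpha_grid is not None else cfg.alpha_grid, dtype=float
    )
    if grid.size == 0:
        raise ValueError("alpha grid is empty")
    grid = np.sort(grid)

    uniq = records["epitope"].unique()
    X_all = featurizer.transform(uniq)
    row_of = {e: i for i, e in enumerate(uniq)}
    idx = records["epitope"].map(row_of).to_numpy()
    y = records["label"].to_numpy()
    groups = records["epitope"].to_numpy()

    rows = []
    for r in range(repeats):
        split_seed = _derive_seed(seed, "outer-split", r)
        train_df, test_df = split_by_epitope(records, cfg.test_fraction, split_seed)
        tr_mask = records["epitope"].isin(set(train_df["epitope"])).to_numpy()
        Xtr, ytr, gtr = X_all[idx[tr_mask]], y[tr_mask], groups[tr_mask]
        Xte, yte = X_all[idx[~tr_mask]], y[~tr_mask]
        for alpha in grid:
            est = ElasticNetLogisticCV(
                alpha=float(alpha),
                n_lambda=cfg.n_lambda,
                lambda_min_ratio=cfg.lambda_min_ratio,
                inner_folds=cfg.inner_folds,
                tol=cfg.tol,
                random_state=_derive_seed(seed, "fit", r, f"{alpha:.4f}"),
            )
            est.fit(Xtr, ytr, groups=gtr)
            metrics = _score_split(est, Xte, yte)
            rows.append({"alpha": float(alpha), "repeat": r, **metrics})

    per_repeat = pd.DataFrame(rows)
    means = per_repeat.groupby("alpha").mean().drop(columns="repeat")
    crit = "f1" if cfg.cv_metric == "f1" else cfg.cv_metric
    scores = -means[crit] if cfg.cv_metric == "f1" else means[crit]
    # grid sorted ascending and idxmin takes the first minimum -> smaller alpha
    best_alpha = float(scores.idxmin())
    return AlphaSearchResult(best_alpha=best_alpha, cv_error=means, per_repeat=per_repeat)


def _scope_records(dataset: CuratedDataset, spec: VariantSpec) -> pd.DataFrame:
    df = dataset.records
    if spec.hla is not None:
        df = df[df["hla"] == spec.hla]
    if spec.length is not None:
        df = df[df["epitope"].str.len() == spec.length]
    df = df.reset_index(drop=True)
    if len(df):
        df, _ = apply_qc_cutoff(df, spec.qc_cutoff)
    return df


def train_variant(
    dataset: CuratedDataset,
    spec: VariantSpec,
    config: TrainingConfig | None = None,
    featurizer: CTDFeaturizer | None = None,
) -> TrainedModel | Refusal:
    """Train one variant, or refuse if its scoped data fail the 50/50 gate."""
    cfg = config or TrainingConfig()
    featurizer = (featurizer or CTDFeaturizer()).fit()
    scoped = _scope_records(dataset, spec)
    if scoped.empty:
        return Refusal(spec=spec, reason="no records in scope")
    n_pos = int(scoped["label"].sum())
    n_neg = int(len(scoped) - n_pos)
    if n_pos < cfg.min_per_class_train or n_neg < cfg.min_per_class_train:
        reason = (
            f"class counts below training gate "
            f"({n_pos} positive, {n_neg} negative, need "
            f">= {cfg.min_per_class_train} each)"
        )
        logger.info("refusing %s: %s", spec.model_id, reason)
        return Refusal(spec=spec, reason=reason, n_pos=n_pos, n_neg=n_neg)
    if scoped["epitope"].nunique() < 5:
        return Refusal(
            spec=spec, reason="fewer than 5 unique epitopes", n_pos=n_pos, n_neg=n_neg
        )

    search = mc_cv_alpha_search(
        scoped,
        featurizer,
        alpha_grid=cfg.alpha_grid,
        repeats=cfg.repeats,
        seed=_derive_seed(cfg.seed, "variant", spec.model_id),
        config=cfg,
    )
    crit = cfg.cv_metric if cfg.cv_metric != "f1" else "f1"
    cv_error = float(search.cv_error.loc[search.best_alpha, crit])

    # final refit on all scoped data at the selected alpha
    X = featurizer.transform(scoped["epitope"])
    y = scoped["label"].to_numpy()
    fit_seed = _derive_seed(cfg.seed, "final-fit", spec.model_id)
    est = ElasticNetLogisticCV(
        alpha=search.best_alpha,
        n_lambda=cfg.n_lambda,
        lambda_min_ratio=cfg.lambda_min_ratio,
        inner_folds=cfg.inner_folds,
        tol=cfg.tol,
        random_state=fit_seed,
    )
    est.fit(X, y, groups=scoped["epitope"].to_numpy())
    return TrainedModel(
        variant=spec,
        alpha=search.best_alpha,
        lambda_=est.lambda_,
        intercept=est.intercept_,
        coefficients=est.coef_.copy(),
        feature_names=tuple(featurizer.feature_names_),
        cv_error=cv_error,
        cv_metrics={
            "per_alpha_mean": {
                f"{a:.2f}": row.to_dict() for a, row in search.cv_error.iterrows()
            },
            "f1_median": float(
                search.per_repeat.loc[
                    search.per_repeat["alpha"] == search.best_alpha, "f1"
                ].median()
            ),
            "accuracy_mean": float(
                search.per_repeat.loc[
                    search.per_repeat["alpha"] == search.best_alpha, "accuracy"
                ].mean()
            ),
            "criterion": cfg.cv_metric,
        },
        n_pos=n_pos,
        n_neg=n_neg,
        seed=fit_seed,
    )


@dataclass
class ModelRegistry:
    """Retained models per scope cell, plus selection and fallback logic."""

    models: list[TrainedModel]
    feature_names: tuple[str, ...]
    scheme_fingerprint: str
    refusals: list[Refusal] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def generic_model(self) -> TrainedModel | None:
        cands = [m for m in self.models if m.variant.cell == (None, None)]
        return cands[0] if cands else None

    def select_best(self, hla: str, length: int) -> TrainedModel:
        """Lowest-CV-error covering model; ties to the more specific scope."""
        if not self.models:
            raise ValueError("registry holds no models")
        covering = [m for m in self.models if m.variant.covers(hla, length)]
        if not covering:
            generic = self.generic_model()
            if generic is None:
                raise ValueError(
                    f"nothing covers ({hla}, {length}) and no generic model exists"
                )
            logger.info("query (%s, %d): falling back to generic model", hla, length)
            return generic
        return min(covering, key=lambda m: (m.cv_error, -m.variant.specificity))

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "format_version": REGISTRY_FORMAT_VERSION,
            "scheme_fingerprint": self.scheme_fingerprint,
            "feature_names": list(self.feature_names),
            "metadata": self.metadata,
            "models": [
                {
                    "model_id": m.model_id,
                    "hla": m.variant.hla,
                    "length": m.variant.length,
                    "qc_cutoff": m.variant.qc_cutoff,
                    "alpha": m.alpha,
                    "lambda": m.lambda_,
                    "intercept": m.intercept,
                    "coefficients": m.coefficients.tolist(),
                    "cv_error": m.cv_error,
                    "cv_metrics": m.cv_metrics,
                    "n_pos": m.n_pos,
                    "n_neg": m.n_neg,
                    "seed": m.seed,
                }
                for m in self.models
            ],
            "refusals": [
                {
                    "model_id": r.spec.model_id,
                    "reason": r.reason,
                    "n_pos": r.n_pos,
                    "n_neg": r.n_neg,
                }
                for r in self.refusals
            ],
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ModelRegistry":
        text = (
            Path(source).read_text()
            if isinstance(source, Path) or "\n" not in str(source) and Path(str(source)).exists()
            else str(source)
        )
        doc = json.loads(text)
        names = tuple(doc["feature_names"])
        models = [
            TrainedModel(
                variant=VariantSpec(
                    hla=m["hla"], length=m["length"], qc_cutoff=m["qc_cutoff"]
                ),
                alpha=m["alpha"],
                lambda_=m["lambda"],
                intercept=m["intercept"],
                coefficients=np.asarray(m["coefficients"], dtype=float),
                feature_names=names,
                cv_error=m["cv_error"],
                cv_metrics=m.get("cv_metrics", {}),
                n_pos=m["n_pos"],
                n_neg=m["n_neg"],
                seed=m["seed"],
            )
            for m in doc["models"]
        ]
        refusals = [
            Refusal(
                spec=_spec_from_id(r["model_id"]),
                reason=r["reason"],
                n_pos=r.get("n_pos", 0),
                n_neg=r.get("n_neg", 0),
            )
            for r in doc.get("refusals", [])
        ]
        return cls(
            models=models,
            feature_names=names,
            scheme_fingerprint=doc["scheme_fingerprint"],
            refusals=refusals,
            metadata=doc.get("metadata", {}),
        )


def _spec_from_id(model_id: str) -> VariantSpec:
    parts = dict(p.split("=", 1) for p in model_id.split("|"))
    return VariantSpec(
        hla=None if parts["hla"] == "any" else parts["hla"],
        length=None if parts["len"] == "any" else int(parts["len"]),
        qc_cutoff=int(parts["t"]),
    )


def enumerate_variant_cells(dataset: CuratedDataset) -> list[tuple[str | None, int | None]]:
    """All scope cells present in a dataset: generic, per length, per HLA, per both."""
    df = dataset.records
    lengths = sorted(df["epitope"].str.len().unique().tolist())
    hlas = sorted(df["hla"].unique().tolist())
    cells: list[tuple[str | None, int | None]] = [(None, None)]
    cells += [(None, L) for L in lengths]
    cells += [(h, None) for h in hlas]
    cells += [(h, L) for h in hlas for L in lengths]
    return cells


def build_registry(
    dataset: CuratedDataset,
    config: TrainingConfig | None = None,
    featurizer: CTDFeaturizer | None = None,
) -> ModelRegistry:
    """Train every variant x QC-cutoff combination and retain the best per cell.

    For each scope cell the QC cutoff t with the lowest CV error is kept;
    refusals (gate failures) are recorded.  Raises if nothing is trainable.
    """
    cfg = config or TrainingConfig()
    featurizer = (featurizer or CTDFeaturizer()).fit()
    models: list[TrainedModel] = []
    refusals: list[Refusal] = []
    for cell in enumerate_variant_cells(dataset):
        best: TrainedModel | None = None
        for t in cfg.qc_cutoffs:
            spec = VariantSpec(hla=cell[0], length=cell[1], qc_cutoff=int(t))
            result = train_variant(dataset, spec, cfg, featurizer)
            if isinstance(result, Refusal):
                refusals.append(result)
                continue
            if best is None or result.cv_error < best.cv_error:
                best = result
        if best is not None:
            models.append(best)
    if not models:
        raise ValueError("no model variant passed the training gates")
    return ModelRegistry(
        models=models,
        feature_names=tuple(featurizer.feature_names_),
        scheme_fingerprint=scheme_fingerprint(featurizer.schemes_),
        refusals=refusals,
        metadata={
            "seed": cfg.seed,
            "alpha_grid": list(map(float, cfg.alpha_grid)),
            "repeats": cfg.repeats,
            "inner_folds": cfg.inner_folds,
            "qc_cutoffs": list(map(int, cfg.qc_cutoffs)),
            "cv_metric": cfg.cv_metric,
        },
    )


def select_best(registry: ModelRegistry, hla: str, length: int) -> TrainedModel:
    """Functional wrapper over :meth:`ModelRegistry.select_best`."""
    return registry.select_best(hla, length)


def export_coefficients(registry: ModelRegistry) -> pd.DataFrame:
    """One row per model: intercept plus the 147 named coefficients.

    Suitable as input to any external embedding or clustering tool.
    """
    rows = []
    for m in registry.models:
        row = {"model_id": m.model_id, "intercept": m.intercept}
        row.update(dict(zip(m.feature_names, m.coefficients.tolist())))
        rows.append(row)
    return pd.DataFrame(rows).set_index("model_id")
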