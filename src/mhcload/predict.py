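"""Loading predictions and confusion-matrix evaluation.

A query is a (peptide, HLA) pair.  The registry resolves the best covering
model for the pair's allele group and peptide length, the peptide is
featurized, and the loading probability is the inverse logit of the linear
predictor.  The class label is "Loadable" iff the probability strictly
exceeds the threshold (default 0.5).

Evaluation computes the standard confusion-matrix metrics — sensitivity,
specificity, accuracy, balanced accuracy (their mean) and F1 — optionally
per group (e.g. per HLA); the summary "mean accuracy across HLAs" is the
unweighted mean of per-HLA accuracies.  Groups where a metric is undefined
(a single observed class) report NaN for it rather than failing.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .curation import normalize_hla
from .features import CTDFeaturizer, InvalidPeptideError
from .training import ModelRegistry

logger = logging.getLogger(__name__)

LOADABLE = "Loadable"
NOT_LOADABLE = "Not-loadable"


def predict(
    queries: pd.DataFrame | Iterable[tuple[str, str]],
    registry: ModelRegistry,
    threshold: float = 0.5,
    featurizer: CTDFeaturizer | None = None,
) -> pd.DataFrame:
    """Predict loading for (peptide, HLA) queries.

    Returns a frame with columns ``peptide, hla, probability, label,
    model_id, threshold, note``.  Invalid peptides produce a per-row
    ``note`` (probability NaN) and the batch continues; unknown or
    unresolvable HLAs fall back to the generic model with a note.
    """
    if not isinstance(queries, pd.DataFrame):
        queries = pd.DataFrame(list(queries), columns=["peptide", "hla"])
    if not {"peptide", "hla"} <= set(queries.columns):
        raise ValueError("queries need 'peptide' and 'hla' columns")
    featurizer = (featurizer or CTDFeaturizer()).fit()
    if list(featurizer.feature_names_) != list(registry.feature_names):
        raise ValueError("featurizer layout does not match the registry")

    rows = []
    for peptide, hla in zip(queries["peptide"], queries["hla"]):
        note = ""
        group = normalize_hla(str(hla))
        if group is None:
            group = str(hla)
            note = "unresolved HLA; generic fallback"
        try:
            x = featurizer.transform([peptide])[0]
        except InvalidPeptideError as exc:
            rows.append(
                {
                    "peptide": peptide,
                    "hla": group,
                    "probability": np.nan,
                    "label": "",
                    "model_id": "",
                    "threshold": threshold,
                    "note": f"invalid peptide: {exc}",
                }
            )
            continue
        model = registry.select_best(group, len(str(peptide).strip()))
        prob = float(expit(model.linear_predictor(x)))
        rows.append(
            {
                "peptide": str(peptide).strip().upper(),
                "hla": group,
                "probability": prob,
                "label": LOADABLE if prob > threshold else NOT_LOADABLE,
                "model_id": model.model_id,
                "threshold": threshold,
                "note": note,
            }
        )
    return pd.DataFrame(rows)


def _as_binary(values: Sequence) -> np.ndarray:
    arr = pd.Series(values)
    if arr.dtype == object or pd.api.types.is_string_dtype(arr):
        mapping = {
            LOADABLE.lower(): 1,
            NOT_LOADABLE.lower(): 0,
            "positive": 1,
            "negative": 0,
            "1": 1,
            "0": 0,
        }
        out = arr.astype(str).str.strip().str.lower().map(mapping)
        if out.isna().any():
            bad = arr[out.isna()].unique()[:5]
            raise ValueError(f"cannot interpret labels as binary: {bad}")
        return out.to_numpy(dtype=int)
    return arr.astype(int).to_numpy()


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Metrics from confusion counts; undefined ratios are NaN."""
    n = tp + fp + tn + fn
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    bal = (sens + spec) / 2.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else float("nan")
    return {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "n": n,
        "n_pos": tp + fn,
        "n_neg": tn + fp,
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": (tp + tn) / n if n else float("nan"),
        "balanced_accuracy": bal,
        "f1": f1,
    }


def evaluate(
    predicted: Sequence,
    truth: Sequence,
    group_by: Sequence | None = None,
) -> pd.DataFrame:
    """Confusion-matrix metrics, overall or per group.

    ``predicted`` and ``truth`` are aligned label vectors (binary, or
    "Loadable"/"Not-loadable" / "Positive"/"Negative" strings).  With
    ``group_by`` one metric row is computed per group; single-class groups
    warn and report NaN for the undefined metric.
    """
    pred = _as_binary(predicted)
    y = _as_binary(truth)
    if len(pred) != len(y):
        raise ValueError(f"length mismatch: {len(pred)} predictions, {len(y)} truths")
    if group_by is None:
        groups = np.zeros(len(y), dtype=int)
        keys = {0: "all"}
    else:
        ser = pd.Series(list(group_by))
        codes, uniques = pd.factorize(ser)
        groups = codes
        keys = dict(enumerate(uniques))
    rows = []
    for g in sorted(keys):
        m = groups == g
        tp = int(((pred == 1) & (y == 1) & m).sum())
        fp = int(((pred == 1) & (y == 0) & m).sum())
        tn = int(((pred == 0) & (y == 0) & m).sum())
        fn = int(((pred == 0) & (y == 1) & m).sum())
        metrics = confusion_metrics(tp, fp, tn, fn)
        if metrics["n_pos"] == 0 or metrics["n_neg"] == 0:
            warnings.warn(
                f"group {keys[g]!r} has a single observed class; "
                "sensitivity/specificity reported as NaN",
                stacklevel=2,
            )
        rows.append({"group": keys[g], **metrics})
    return pd.DataFrame(rows).set_index("group")


def mean_accuracy(metrics: pd.DataFrame) -> float:
    """Unweighted mean of per-group accuracies (e.g. mean accuracy across HLAs)."""
    return float(metrics["accuracy"].mean())


def compare_external(
    table: pd.DataFrame,
    truth_col: str,
    tool_cols: Mapping[str, str] | Sequence[str],
    group_by: str | None = None,
) -> pd.DataFrame:
    """Score several tools' pre-computed label columns against one truth column.

    ``tool_cols`` maps tool name -> column (or lists columns used as both).
    Rows where a tool's column is missing are excluded for that tool only;
    a tool whose column is absent is skipped with a warning.  Returns one
    metric row per tool (per group when ``group_by`` is set), with the
    number of rows scored in ``n``.
    """
    if not isinstance(tool_cols, Mapping):
        tool_cols = {c: c for c in tool_cols}
    frames = []
    for tool, col in tool_cols.items():
        if col not in table.columns:
            warnings.warn(f"column {col!r} for tool {tool!r} missing; skipped", stacklevel=2)
            continue
        sub = table[table[col].notna() & (table[col].astype(str).str.strip() != "")]
        n_excluded = len(table) - len(sub)
        if n_excluded:
            logger.info("%s: excluded %d rows without a label", tool, n_excluded)
        metrics = evaluate(
            sub[col],
            sub[truth_col],
            group_by=sub[group_by] if group_by else None,
        )
        metrics = metrics.reset_index()
        metrics.insert(0, "tool", tool)
        metrics["n_excluded"] = n_excluded
        frames.append(metrics)
    if not frames:
        raise ValueError("no tool columns found in the table")
    return pd.concat(frames, ignore_index=True)
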