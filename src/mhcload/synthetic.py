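"""Synthetic IEDB-shaped assay tables with planted, known structure.

The generator emulates a public MHC binding-assay export well enough to
exercise every pipeline stage: qualitative outcomes spelled with the four
positive variants, replicate assays per (epitope, HLA) pair, and contaminant
rows (unresolved HLA annotation, non-canonical residues, co-factors,
unmappable outcome strings) injected at configurable rates.

Labels carry a planted linear signal in CTD feature space: for peptide x and
allele h, the true loading probability is

    p = expit( w . (x - xbar) + b + shift_h )

where ``w`` is sparse over the 147 feature names, ``xbar`` centers the
linear predictor on the generated panel (so classes stay balanced), and
``shift_h`` is a per-HLA offset.  Each replicate row's observed label is the
Bernoulli(p) truth flipped independently with the label-noise probability.
A ground-truth sidecar records, row for row, the true label and probability,
plus the planted weights and the Bayes-optimal accuracies, so recovery can
be tested end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .features import CTDFeaturizer, feature_names
from .schemes import CANONICAL_RESIDUES

_RESIDUES = np.array(list(CANONICAL_RESIDUES))
_NONCANONICAL = np.array(list("BJOUXZ"))
_POSITIVE_SPELLINGS = ("Positive", "Positive-Low", "Positive-High", "Positive-Intermediate")

#: IEDB-flavoured column names used for the emitted table.
TABLE_COLUMNS = ("Description", "Allele Name", "Qualitative Measure", "Co-factor")


@dataclass(frozen=True)
class PlantedModel:
    """The linear ground truth behind a synthetic assay table."""

    weights: Mapping[str, float]
    intercept: float = 0.0
    noise: float = 0.05  # independent label-flip probability per replicate
    hla_shifts: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise < 0.5:
            raise ValueError(f"noise must be in [0, 0.5), got {self.noise}")
        known = set(feature_names())
        unknown = sorted(set(self.weights) - known)
        if unknown:
            raise ValueError(f"planted weights over unknown feature names: {unknown}")


def default_planted_model(noise: float = 0.05) -> PlantedModel:
    """Five sparse weights on composition/distribution features, ±0.5 HLA shifts.

    Weight magnitudes are sized so the latent log-odds spread a few units,
    i.e. a strongly but not perfectly separable problem (Bayes accuracy
    around 0.85-0.9 before label noise).
    """
    return PlantedModel(
        weights={
            "charge.C.1": 12.0,
            "hydrophobicity.C.3": 9.0,
            "van_der_waals.C.1": -9.0,
            "structure.C.1": 7.0,
            "polarizability.D.11": -5.0,
        },
        intercept=0.0,
        noise=noise,
        hla_shifts={"HLA-A*02": 0.5, "HLA-B*07": -0.5},
    )


def sample_peptides(
    n: int,
    length_range: tuple[int, int] = (8, 14),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """``n`` unique random peptides over the canonical alphabet.

    Lengths are uniform over ``length_range`` (inclusive); deterministic for
    a given seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    lo, hi = length_range
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid length range {length_range}")
    # 20^8 distinct 8-mers alone; a practical n can always be satisfied
    if n > 20**lo:
        raise ValueError(f"cannot draw {n} unique peptides of length >= {lo}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        length = int(rng.integers(lo, hi + 1))
        pep = "".join(_RESIDUES[rng.integers(0, 20, size=length)])
        if pep not in seen:
            seen.add(pep)
            out.append(pep)
    return out


def _corrupt_peptide(pep: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(0, len(pep)))
    bad = str(rng.choice(_NONCANONICAL))
    return pep[:pos] + bad + pep[pos + 1 :]


def generate_assay_table(
    n_epitopes: int = 2000,
    hlas: Sequence[str] = ("HLA-A*02", "HLA-B*07"),
    planted: PlantedModel | None = None,
    replicate_probs: Mapping[int, float] | None = None,
    unmappable_rate: float = 0.01,
    noncanonical_rate: float = 0.01,
    unresolved_rate: float = 0.01,
    cofactor_rate: float = 0.01,
    length_range: tuple[int, int] = (8, 14),
    seed: int = 0,
    out: str | Path | None = None,
    truth_out: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Emit an assay table in the curation input dialect plus its ground truth.

    Every epitope is assayed against every HLA in ``hlas``; each pair's
    replicate count is drawn from ``replicate_probs`` (default: mostly
    singletons, tail up to 5).  Contaminant rows are appended at the stated
    rates (as fractions of the clean row count).  The returned ``truth``
    dict contains ``rows`` aligned 1:1 with the table, the planted model,
    and the Bayes accuracies; with ``out``/``truth_out`` both are also
    written to disk (TSV / JSON), byte-identically for identical seeds.
    """
    if not hlas:
        raise ValueError("need at least one HLA")
    planted = planted if planted is not None else default_planted_model()
    replicate_probs = replicate_probs or {1: 0.55, 2: 0.15, 3: 0.15, 4: 0.05, 5: 0.10}
    rep_vals = np.array(sorted(replicate_probs))
    rep_p = np.array([replicate_probs[k] for k in rep_vals], dtype=float)
    rep_p = rep_p / rep_p.sum()

    rng = np.random.default_rng(seed)
    peptides = sample_peptides(n_epitopes, length_range, rng=rng)

    featurizer = CTDFeaturizer(warn_length_range=None).fit()
    X = featurizer.transform(peptides)
    names = featurizer.feature_names_
    w = np.array([planted.weights.get(nm, 0.0) for nm in names])
    eta_pep = X @ w
    eta_pep = eta_pep - eta_pep.mean() + planted.intercept  # centered on the panel

    rows: list[dict] = []
    truth_rows: list[dict] = []
    p_clean: list[float] = []
    for i, pep in enumerate(peptides):
        for hla in hlas:
            p = float(expit(eta_pep[i] + planted.hla_shifts.get(hla, 0.0)))
            true_label = int(rng.random() < p)
            n_rep = int(rng.choice(rep_vals, p=rep_p))
            p_clean.append(p)
            for _ in range(n_rep):
                observed = true_label ^ int(rng.random() < planted.noise)
                outcome = (
                    str(rng.choice(_POSITIVE_SPELLINGS)) if observed else "Negative"
                )
                rows.append(
                    {
                        "Description": pep,
                        "Allele Name": f"{hla}:01",
                        "Qualitative Measure": outcome,
                        "Co-factor": "",
                    }
                )
                truth_rows.append(
                    {
                        "epitope": pep,
                        "hla": hla,
                        "kind": "assay",
                        "true_label": true_label,
                        "observed_label": observed,
                        "probability": p,
                    }
                )

    n_clean = len(rows)

    def _contaminant_peptides(k: int) -> list[str]:
        return sample_peptides(k, length_range, rng=rng) if k else []

    n_bad_res = int(round(noncanonical_rate * n_clean))
    for pep in _contaminant_peptides(n_bad_res):
        hla = str(rng.choice(list(hlas)))
        rows.append(
            {
                "Description": _corrupt_peptide(pep, rng),
                "Allele Name": f"{hla}:01",
                "Qualitative Measure": "Negative",
                "Co-factor": "",
            }
        )
        truth_rows.append({"epitope": pep, "hla": hla, "kind": "noncanonical",
                           "true_label": None, "observed_label": None, "probability": None})

    n_unres = int(round(unresolved_rate * n_clean))
    for pep in _contaminant_peptides(n_unres):
        rows.append(
            {
                "Description": pep,
                "Allele Name": "HLA class I",
                "Qualitative Measure": "Negative",
                "Co-factor": "",
            }
        )
        truth_rows.append({"epitope": pep, "hla": None, "kind": "unresolved_hla",
                           "true_label": None, "observed_label": None, "probability": None})

    n_cof = int(round(cofactor_rate * n_clean))
    for pep in _contaminant_peptides(n_cof):
        hla = str(rng.choice(list(hlas)))
        rows.append(
            {
                "Description": pep,
                "Allele Name": f"{hla}:01",
                "Qualitative Measure": "Positive",
                "Co-factor": "beta-2 microglobulin",
            }
        )
        truth_rows.append({"epitope": pep, "hla": hla, "kind": "cofactor",
                           "true_label": None, "observed_label": None, "probability": None})

    n_unmap = int(round(unmappable_rate * n_clean))
    for pep in _contaminant_peptides(n_unmap):
        hla = str(rng.choice(list(hlas)))
        rows.append(
            {
                "Description": pep,
                "Allele Name": f"{hla}:01",
                "Qualitative Measure": "Untested",
                "Co-factor": "",
            }
        )
        truth_rows.append({"epitope": pep, "hla": hla, "kind": "unmappable",
                           "true_label": None, "observed_label": None, "probability": None})

    table = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))

    p_arr = np.asarray(p_clean)
    q_arr = planted.noise + (1.0 - 2.0 * planted.noise) * p_arr
    truth = {
        "seed": int(seed),
        "planted": {
            "weights": dict(planted.weights),
            "intercept": planted.intercept,
            "noise": planted.noise,
            "hla_shifts": dict(planted.hla_shifts),
        },
        "bayes_accuracy_true": float(np.mean(np.maximum(p_arr, 1.0 - p_arr))),
        "bayes_accuracy_noisy": float(np.mean(np.maximum(q_arr, 1.0 - q_arr))),
        "n_clean_rows": n_clean,
        "n_pairs": len(p_clean),
        "rows": truth_rows,
    }

    if out is not None:
        table.to_csv(out, sep="\t", index=False)
    if truth_out is not None:
        Path(truth_out).write_text(json.dumps(truth, indent=2) + "\n")
    return table, truth


def truth_pair_labels(truth: dict) -> pd.DataFrame:
    """Unique (epitope, hla) -> true label/probability table from a sidecar."""
    rows = [r for r in truth["rows"] if r["kind"] == "assay"]
    df = pd.DataFrame(rows).drop_duplicates(subset=["epitope", "hla"])
    return df[["epitope", "hla", "true_label", "probability"]].reset_index(drop=True)
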