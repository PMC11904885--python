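"""Curation of IEDB-style MHC binding-assay export tables.

Public MHC binding-assay exports arrive as delimited tables with one row
per assay (peptide, HLA allele, qualitative outcome, optional co-factor).
Turning them into a training set involves:

1. label harmonization — the qualitative outcomes "Positive", "Positive-Low",
   "Positive-Intermediate" and "Positive-High" collapse to a single positive
   class; "Negative" is the negative class; anything else is unmappable and
   excluded with a count;
2. record filters — drop assays with (i) HLA annotation not resolved to at
   least an allele group (locus + first nomenclature field, e.g. HLA-A*02),
   (ii) non-canonical residues in the peptide, or (iii) a co-factor present;
3. replicate aggregation — multiple assays of the same (epitope, HLA) pair
   collapse to one record carrying the replicate count ``re`` and a
   majority-vote label (exact ties are dropped);
4. a replicate quality cutoff ``re >= t``;
5. a per-HLA class-count gate — every retained allele group must have at
   least ``min_per_class`` positive and negative records (default 100).

Every rule logs how many records it removed; the provenance report balances
exactly against the input row count.
"""

from __future__ import annotations

import json
import logging
import re as _re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .features import is_canonical

logger = logging.getLogger(__name__)

#: Qualitative outcome strings mapping to the positive class (lower-cased).
POSITIVE_OUTCOMES = frozenset(
    {"positive", "positive-low", "positive-high", "positive-intermediate"}
)
NEGATIVE_OUTCOMES = frozenset({"negative"})

#: Column-name aliases for the common IEDB export dialects.
DEFAULT_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "epitope": ("epitope", "peptide", "description", "epitope - name", "epitope description"),
    "hla": ("hla", "allele", "allele name", "mhc - allele name", "mhc restriction - name"),
    "raw_label": (
        "raw_label",
        "label",
        "outcome",
        "qualitative measure",
        "assay - qualitative measure",
        "qualitative measurement",
    ),
    "cofactor": ("cofactor", "co-factor", "assay - co-factor"),
}

_HLA_RE = _re.compile(r"^HLA-([A-Z]+[0-9]*)\*(\d+)")


class CurationError(ValueError):
    pass


def normalize_hla(allele: str) -> str | None:
    """Normalize an HLA allele name to its allele group, or None if unresolved.

    ``HLA-A*02:01:01`` -> ``HLA-A*02``; ``HLA-B*0702`` -> ``HLA-B*07``.
    Annotations without starred nomenclature down to a first field
    (``HLA class I``, ``HLA-A``, serological names) count as unresolved.
    """
    if not isinstance(allele, str):
        return None
    m = _HLA_RE.match(allele.strip().upper())
    if m is None:
        return None
    locus, field1 = m.groups()
    if len(field1) > 2:  # old-style 4-digit without colon: first two digits
        field1 = field1[:2]
    return f"HLA-{locus}*{int(field1):02d}"


@dataclass
class CuratedDataset:
    """A deduplicated, filtered training table plus its curation provenance.

    ``records`` columns: ``epitope``, ``hla`` (allele group), ``label``
    (1 positive / 0 negative), ``re`` (replicate count).
    """

    records: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def retained_hlas(self) -> list[str]:
        return sorted(self.records["hla"].unique())

    def __len__(self) -> int:
        return len(self.records)

    def write(self, path: str | Path, provenance_path: str | Path | None = None) -> None:
        path = Path(path)
        self.records.to_csv(path, sep="\t", index=False)
        side = Path(provenance_path) if provenance_path else path.with_suffix(path.suffix + ".provenance.json")
        side.write_text(json.dumps(self.provenance, indent=2, sort_keys=True) + "\n")

    @classmethod
    def read(cls, path: str | Path, provenance_path: str | Path | None = None) -> "CuratedDataset":
        path = Path(path)
        records = pd.read_csv(path, sep="\t")
        side = Path(provenance_path) if provenance_path else path.with_suffix(path.suffix + ".provenance.json")
        provenance = json.loads(side.read_text()) if side.exists() else {}
        return cls(records=records, provenance=provenance)


def _resolve_columns(columns, column_map: dict[str, str] | None):
    lookup = {c.strip().lower(): c for c in columns}
    resolved: dict[str, str | None] = {}
    for role, aliases in DEFAULT_COLUMN_ALIASES.items():
        if column_map and role in column_map:
            name = column_map[role]
            if name is None:
                resolved[role] = None
                continue
            if name not in columns:
                raise CurationError(
                    f"mapped column {name!r} for {role!r} not present; available: {list(columns)}"
                )
            resolved[role] = name
            continue
        resolved[role] = next(
            (lookup[a] for a in aliases if a in lookup), None
        )
    for role in ("epitope", "hla", "raw_label"):
        if resolved[role] is None:
            raise CurationError(
                f"no column found for {role!r}; available columns: {list(columns)}. "
                "Provide a column_map."
            )
    return resolved


def read_assay_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
    strict: bool = False,
) -> tuple[pd.DataFrame, int]:
    """Read a delimited assay export into the canonical record layout.

    Returns ``(records, n_malformed)`` where records has columns
    ``epitope``, ``hla``, ``raw_label``, ``cofactor``.  Rows with an empty
    epitope, HLA or outcome cell are malformed: counted and excluded
    (``strict=True`` raises instead).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.empty:
        raise CurationError(f"{path} contains no data rows")
    cols = _resolve_columns(df.columns, column_map)
    out = pd.DataFrame(
        {
            "epitope": df[cols["epitope"]].str.strip(),
            "hla": df[cols["hla"]].str.strip(),
            "raw_label": df[cols["raw_label"]].str.strip(),
            "cofactor": (
                df[cols["cofactor"]].str.strip() if cols["cofactor"] else ""
            ),
        }
    )
    malformed = (out["epitope"] == "") | (out["hla"] == "") | (out["raw_label"] == "")
    n_malformed = int(malformed.sum())
    if n_malformed and strict:
        raise CurationError(f"{n_malformed} malformed rows in {path}")
    if n_malformed:
        logger.warning("%s: excluded %d malformed rows", path, n_malformed)
    return out.loc[~malformed].reset_index(drop=True), n_malformed


def harmonize_labels(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Collapse qualitative outcomes to a binary ``label`` column.

    Returns ``(records, n_unmappable)``; unmappable outcome strings are a
    data condition (excluded and counted), never an error.
    """
    low = records["raw_label"].str.strip().str.lower()
    label = pd.Series(pd.NA, index=records.index, dtype="Int64")
    label[low.isin(POSITIVE_OUTCOMES)] = 1
    label[low.isin(NEGATIVE_OUTCOMES)] = 0
    keep = label.notna()
    n_unmappable = int((~keep).sum())
    if n_unmappable:
        logger.info("excluded %d records with unmappable outcomes", n_unmappable)
    out = records.loc[keep].copy()
    out["label"] = label[keep].astype(int)
    return out.reset_index(drop=True), n_unmappable


def filter_records(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the record filters; each row is charged to the first rule it hits.

    Adds the normalized allele-group column ``hla`` (original annotation kept
    as ``hla_full``).  Returned counts: ``unresolved_hla``,
    ``noncanonical_peptide``, ``cofactor_present``.
    """
    rec = records.copy()
    groups = rec["hla"].map(normalize_hla)
    unresolved = groups.isna()
    noncanonical = ~rec["epitope"].map(is_canonical) & ~unresolved
    cofactor = (
        rec.get("cofactor", pd.Series("", index=rec.index)).fillna("").astype(str).str.strip()
        != ""
    ) & ~unresolved & ~noncanonical
    counts = {
        "unresolved_hla": int(unresolved.sum()),
        "noncanonical_peptide": int(noncanonical.sum()),
        "cofactor_present": int(cofactor.sum()),
    }
    keep = ~(unresolved | noncanonical | cofactor)
    out = rec.loc[keep].copy()
    out["hla_full"] = out["hla"]
    out["hla"] = groups[keep]
    out["epitope"] = out["epitope"].str.strip().str.upper()
    return out.reset_index(drop=True), counts


def aggregate_replicates(
    records: pd.DataFrame, conflict_policy: str = "majority"
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Collapse repeated assays of one (epitope, HLA) pair to a single record.

    ``re`` is the number of source assays.  Conflicting replicate outcomes
    resolve by ``conflict_policy``:

    * ``majority`` — majority vote; exact ties dropped (default),
    * ``any_positive`` — positive if any replicate is positive,
    * ``drop_conflicts`` — keep only unanimous pairs.

    Returned counts (in source-assay rows, so totals balance):
    ``merged_replicates`` and ``tied_replicates``.
    """
    if conflict_policy not in {"majority", "any_positive", "drop_conflicts"}:
        raise CurationError(f"unknown conflict policy {conflict_policy!r}")
    grouped = records.groupby(["epitope", "hla"], sort=True)["label"].agg(
        re="size", n_pos="sum"
    )
    grouped = grouped.reset_index()
    n_neg = grouped["re"] - grouped["n_pos"]
    if conflict_policy == "majority":
        tied = grouped["n_pos"] == n_neg
        label = (grouped["n_pos"] > n_neg).astype(int)
    elif conflict_policy == "any_positive":
        tied = pd.Series(False, index=grouped.index)
        label = (grouped["n_pos"] > 0).astype(int)
    else:  # drop_conflicts
        tied = (grouped["n_pos"] > 0) & (n_neg > 0)
        label = (grouped["n_pos"] > 0).astype(int)
    counts = {
        "tied_replicates": int(grouped.loc[tied, "re"].sum()),
        "merged_replicates": int((grouped.loc[~tied, "re"] - 1).sum()),
    }
    out = grouped.loc[~tied, ["epitope", "hla", "re"]].copy()
    out["label"] = label[~tied]
    return out.reset_index(drop=True), counts


def apply_qc_cutoff(
    records: pd.DataFrame, t: int, max_t: int = 5
) -> tuple[pd.DataFrame, int]:
    """Keep aggregated records with replicate count ``re >= t``; t=1 is the identity."""
    if not (1 <= t <= max_t):
        raise CurationError(f"QC cutoff t must be in 1..{max_t}, got {t}")
    keep = records["re"] >= t
    n_dropped = int((~keep).sum())
    out = records.loc[keep].reset_index(drop=True)
    if out.empty:
        warnings.warn(f"QC cutoff t={t} removed every record", stacklevel=2)
    return out, n_dropped


def enforce_min_class_counts(
    records: pd.DataFrame, min_per_class: int = 100
) -> tuple[pd.DataFrame, int, list[str]]:
    """Drop all records of any HLA with < ``min_per_class`` positives or negatives."""
    if records.empty:
        warnings.warn("no records left before the per-HLA class-count gate", stacklevel=2)
        return records.copy(), 0, []
    pos = records.groupby("hla")["label"].sum()
    tot = records.groupby("hla")["label"].size()
    ok = (pos >= min_per_class) & ((tot - pos) >= min_per_class)
    retained = sorted(ok.index[ok])
    keep = records["hla"].isin(retained)
    n_dropped = int((~keep).sum())
    out = records.loc[keep].reset_index(drop=True)
    if out.empty:
        warnings.warn("per-HLA class-count gate removed every record", stacklevel=2)
    return out, n_dropped, retained


def curate(
    records: pd.DataFrame,
    min_per_class: int = 100,
    qc_cutoff: int = 1,
    conflict_policy: str = "majority",
    n_malformed: int = 0,
) -> CuratedDataset:
    """Run the full curation pipeline on raw assay records.

    ``records`` must carry ``epitope``, ``hla``, ``raw_label`` (and
    optionally ``cofactor``) as produced by :func:`read_assay_table`.
    The provenance report satisfies, exactly::

        n_input = len(dataset) + sum(dropped.values())
    """
    n_input = len(records)
    harmonized, n_unmappable = harmonize_labels(records)
    filtered, filter_counts = filter_records(harmonized)
    aggregated, agg_counts = aggregate_replicates(filtered, conflict_policy)
    qc_passed, n_below_qc = apply_qc_cutoff(aggregated, qc_cutoff)
    final, n_below_min, retained = enforce_min_class_counts(qc_passed, min_per_class)
    dropped = {
        "unmappable_outcome": n_unmappable,
        **filter_counts,
        **agg_counts,
        "below_qc_cutoff": n_below_qc,
        "hla_below_min_class": n_below_min,
    }
    provenance = {
        "n_input": n_input,
        "n_malformed_excluded_on_read": n_malformed,
        "n_output": len(final),
        "dropped": dropped,
        "parameters": {
            "min_per_class": min_per_class,
            "qc_cutoff": qc_cutoff,
            "conflict_policy": conflict_policy,
        },
        "retained_hlas": retained,
        "class_counts": {
            hla: {
                "positive": int(final.loc[final["hla"] == hla, "label"].sum()),
                "negative": int((final["hla"] == hla).sum() - final.loc[final["hla"] == hla, "label"].sum()),
            }
            for hla in retained
        },
    }
    assert n_input == len(final) + sum(dropped.values()), "provenance does not balance"
    return CuratedDataset(records=final, provenance=provenance)


def curate_file(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
    **kwargs,
) -> CuratedDataset:
    """Convenience wrapper: :func:`read_assay_table` then :func:`curate`."""
    records, n_malformed = read_assay_table(path, column_map=column_map, sep=sep)
    return curate(records, n_malformed=n_malformed, **kwargs)
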