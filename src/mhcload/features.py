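"""Composition/Transition/Distribution (CTD) descriptors for peptides.

For every three-class property partition (see :mod:`mhcload.schemes`) a
peptide of length ``L`` is reduced to a class-index string over {1,2,3} and
summarised by

* **Composition** ``c_g`` — fraction of residues in class ``g`` (3 values,
  summing to 1);
* **Transition** ``t_gh`` — fraction of the ``L-1`` adjacent residue pairs
  whose classes form the unordered pair {g,h}, for (1,2), (1,3), (2,3)
  (3 values);
* **Distribution** ``d_gq`` — the 1-based sequence position of the first,
  25%, 50%, 75% and 100% occurrence of class ``g``, divided by ``L``
  (15 values; a class with no occurrences contributes five zeros).

With seven properties this yields 7 x (3 + 3 + 15) = 147 descriptors, all in
[0, 1] and comparable across peptide lengths — the feature space used by the
loading classifier.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .schemes import (
    CANONICAL_RESIDUES,
    PROPERTY_ORDER,
    PropertyScheme,
    load_builtin_schemes,
)

_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)
_QUANTILES = (0.25, 0.5, 0.75, 1.0)
#: Unordered class pairs defining t1, t2, t3.
TRANSITION_PAIRS = ((1, 2), (1, 3), (2, 3))

N_FEATURES = 7 * (3 + 3 + 15)


class InvalidPeptideError(ValueError):
    """A peptide failed residue/length validation."""

    def __init__(self, message: str, peptide: str = "", position: int | None = None):
        super().__init__(message)
        self.peptide = peptide
        self.position = position  # 1-based, None if not residue-specific


def clean_peptide(peptide: str) -> str:
    """Upper-case, strip and validate a peptide sequence.

    Raises :class:`InvalidPeptideError` naming the 1-based position of the
    first non-canonical residue (B, J, O, U, X, Z and anything else outside
    the 20-letter alphabet are rejected).
    """
    if not isinstance(peptide, str):
        raise InvalidPeptideError(f"peptide must be a string, got {type(peptide).__name__}")
    seq = peptide.strip().upper()
    if not seq:
        raise InvalidPeptideError("empty peptide", peptide=peptide)
    for i, res in enumerate(seq, start=1):
        if res not in _CANONICAL_SET:
            raise InvalidPeptideError(
                f"non-canonical residue {res!r} at position {i} in {seq!r}",
                peptide=seq,
                position=i,
            )
    return seq


def is_canonical(peptide: str) -> bool:
    """True if the stripped, upper-cased sequence is non-empty and canonical."""
    seq = str(peptide).strip().upper()
    return bool(seq) and set(seq) <= _CANONICAL_SET


def assign_classes(peptide: str, scheme: PropertyScheme) -> str:
    """Map a peptide to its class-index string under one property scheme."""
    seq = clean_peptide(peptide)
    return "".join(str(scheme.class_map[res]) for res in seq)


def _as_class_array(class_seq: str | Sequence[int]) -> np.ndarray:
    if isinstance(class_seq, str):
        arr = np.frombuffer(class_seq.encode("ascii"), dtype=np.uint8) - ord("0")
    else:
        arr = np.asarray(class_seq, dtype=np.int64)
    if arr.size == 0:
        raise InvalidPeptideError("empty class sequence")
    if not np.isin(arr, (1, 2, 3)).all():
        raise InvalidPeptideError("class sequence may only contain classes 1, 2, 3")
    return arr.astype(np.int64)


def composition(class_seq: str | Sequence[int]) -> np.ndarray:
    """Class fractions (c1, c2, c3); always sums to 1."""
    arr = _as_class_array(class_seq)
    counts = np.bincount(arr, minlength=4)[1:4]
    return counts / arr.size


def transition(class_seq: str | Sequence[int]) -> np.ndarray:
    """Adjacent-pair class-change fractions (t12, t13, t23) over L-1 pairs."""
    arr = _as_class_array(class_seq)
    if arr.size < 2:
        raise InvalidPeptideError("transition features need length >= 2")
    a, b = arr[:-1], arr[1:]
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    out = np.empty(3)
    for k, (g, h) in enumerate(TRANSITION_PAIRS):
        out[k] = np.count_nonzero((lo == g) & (hi == h))
    return out / (arr.size - 1)


def distribution(class_seq: str | Sequence[int], mode: str = "ceil") -> np.ndarray:
    """Normalized first/25%/50%/75%/100% occurrence positions per class.

    For class ``g`` occurring ``n_g`` times at 1-based positions
    ``p_1 < ... < p_{n_g}``, the five values are ``p_1/L`` and ``p_k/L`` with
    ``k = ceil(q * n_g)`` for q in {0.25, 0.5, 0.75, 1}.  ``mode="round"``
    switches to the nearest-rank convention ``k = max(1, round(q * n_g))``.
    Absent classes contribute five zeros.
    """
    arr = _as_class_array(class_seq)
    L = arr.size
    out = np.zeros(15)
    for gi, g in enumerate((1, 2, 3)):
        pos = np.flatnonzero(arr == g) + 1  # 1-based
        n_g = pos.size
        if n_g == 0:
            continue
        out[5 * gi] = pos[0] / L
        for qi, q in enumerate(_QUANTILES, start=1):
            if mode == "ceil":
                k = math.ceil(q * n_g)
            elif mode == "round":
                k = max(1, round(q * n_g))
            else:
                raise ValueError(f"unknown distribution mode {mode!r}")
            out[5 * gi + qi] = pos[k - 1] / L
    return out


def feature_names(schemes: Mapping[str, PropertyScheme] | None = None) -> list[str]:
    """The 147 feature identifiers, in the fixed layout order.

    Per property (in :data:`~mhcload.schemes.PROPERTY_ORDER`):
    ``<prop>.C.1..3``, ``<prop>.T.12/.13/.23``, ``<prop>.D.<g><q>`` with
    g in 1..3 and q in 1..5 (q=1 the first occurrence, q=2..5 the
    25/50/75/100% occurrences).
    """
    props = list(schemes) if schemes is not None else list(PROPERTY_ORDER)
    names: list[str] = []
    for prop in props:
        names += [f"{prop}.C.{g}" for g in (1, 2, 3)]
        names += [f"{prop}.T.{g}{h}" for g, h in TRANSITION_PAIRS]
        names += [f"{prop}.D.{g}{q}" for g in (1, 2, 3) for q in (1, 2, 3, 4, 5)]
    return names


@dataclass(frozen=True)
class FeatureVector:
    """A peptide's 147 named CTD descriptor values."""

    peptide: str
    values: np.ndarray
    names: tuple[str, ...]

    @property
    def length(self) -> int:
        return len(self.peptide)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def featurize(
    peptide: str,
    schemes: Mapping[str, PropertyScheme] | None = None,
    distribution_mode: str = "ceil",
    length_range: tuple[int, int] | None = (8, 14),
) -> FeatureVector:
    """Compute the full 147-dimensional CTD vector for one peptide.

    Warns (without failing) for lengths outside the typical MHC class I
    range of 8-14 residues.
    """
    schemes = schemes if schemes is not None else load_builtin_schemes()
    seq = clean_peptide(peptide)
    if len(seq) < 2:
        raise InvalidPeptideError(
            f"peptide {seq!r} shorter than 2 residues: transitions undefined",
            peptide=seq,
        )
    if length_range is not None and not (length_range[0] <= len(seq) <= length_range[1]):
        warnings.warn(
            f"peptide length {len(seq)} outside the typical MHC-I range "
            f"{length_range[0]}-{length_range[1]}",
            stacklevel=2,
        )
    blocks = []
    for scheme in schemes.values():
        cls = assign_classes(seq, scheme)
        blocks.append(composition(cls))
        blocks.append(transition(cls))
        blocks.append(distribution(cls, mode=distribution_mode))
    values = np.concatenate(blocks)
    return FeatureVector(peptide=seq, values=values, names=tuple(feature_names(schemes)))


class CTDFeaturizer(TransformerMixin, BaseEstimator):
    """Transformer mapping peptide sequences to CTD descriptor matrices.

    Stateless (``fit`` only records the feature layout); composes with
    sklearn pipelines.  ``transform`` takes an iterable of peptide strings
    and returns an ``(n_peptides, 147)`` float array.

    Parameters
    ----------
    schemes : mapping of name -> PropertyScheme, optional
        Property partitions to use; defaults to the seven shipped schemes.
    distribution_mode : {"ceil", "round"}
        Percentile-rank convention for the distribution block.
    warn_length_range : (int, int) or None
        Lengths outside this range trigger a warning (never an error).
    """

    def __init__(
        self,
        schemes: Mapping[str, PropertyScheme] | None = None,
        distribution_mode: str = "ceil",
        warn_length_range: tuple[int, int] | None = (8, 14),
    ):
        self.schemes = schemes
        self.distribution_mode = distribution_mode
        self.warn_length_range = warn_length_range

    def _resolved_schemes(self) -> Mapping[str, PropertyScheme]:
        return self.schemes if self.schemes is not None else load_builtin_schemes()

    def fit(self, X: Iterable[str] | None = None, y=None) -> "CTDFeaturizer":
        schemes = self._resolved_schemes()
        self.schemes_ = dict(schemes)
        self.feature_names_ = feature_names(schemes)
        self.n_features_out_ = len(self.feature_names_)
        return self

    def transform(self, X: Iterable[str]) -> np.ndarray:
        if not hasattr(self, "feature_names_"):
            self.fit()
        peptides = list(X)
        out = np.empty((len(peptides), self.n_features_out_))
        for i, pep in enumerate(peptides):
            out[i] = featurize(
                pep,
                schemes=self.schemes_,
                distribution_mode=self.distribution_mode,
                length_range=self.warn_length_range,
            ).values
        return out

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        if not hasattr(self, "feature_names_"):
            self.fit()
        return np.asarray(self.feature_names_, dtype=object)
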