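"""Three-class physicochemical partitions of the amino-acid alphabet.

CTD (composition/transition/distribution) descriptors reduce a peptide to
class-index sequences under a handful of physicochemical properties.  Each
:class:`PropertyScheme` partitions the 20 canonical residues into exactly
three classes (e.g. charge: positive / neutral / negative).  The seven
schemes shipped with the package — hydrophobicity, polarizability, polarity,
normalized van der Waals volume, charge, solvent accessibility and secondary
structure propensity — are the classical three-class tables of the CTD
descriptor lineage.  They live in ``data/schemes/*.json`` so that alternative
partitions can be dropped in without touching code.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Property order used everywhere a feature vector is laid out.
PROPERTY_ORDER = (
    "hydrophobicity",
    "polarizability",
    "polarity",
    "van_der_waals",
    "charge",
    "solvent",
    "structure",
)


class SchemeError(ValueError):
    """Raised when a residue-class table is not a valid 3-class partition."""


@dataclass(frozen=True)
class PropertyScheme:
    """A named partition of the canonical residues into classes 1, 2 and 3."""

    name: str
    class_map: Mapping[str, int]
    class_labels: tuple[str, str, str] = ("1", "2", "3")

    def __post_init__(self) -> None:
        covered = set(self.class_map)
        canonical = set(CANONICAL_RESIDUES)
        if covered != canonical:
            missing = sorted(canonical - covered)
            extra = sorted(covered - canonical)
            raise SchemeError(
                f"scheme {self.name!r} must cover exactly the 20 canonical "
                f"residues (missing {missing}, unexpected {extra})"
            )
        classes = set(self.class_map.values())
        if not classes <= {1, 2, 3}:
            raise SchemeError(
                f"scheme {self.name!r} uses class indices {sorted(classes)}; "
                "only 1, 2 and 3 are allowed"
            )
        if classes != {1, 2, 3}:
            raise SchemeError(
                f"scheme {self.name!r} has an empty class: present {sorted(classes)}"
            )
        if len(self.class_labels) != 3:
            raise SchemeError(f"scheme {self.name!r} needs exactly 3 class labels")

    def residues_in_class(self, class_index: int) -> str:
        return "".join(
            sorted(r for r, c in self.class_map.items() if c == class_index)
        )

    @classmethod
    def from_dict(cls, doc: Mapping) -> "PropertyScheme":
        """Build a scheme from the shipped JSON layout.

        Expected keys: ``name``, ``class_labels`` (3 strings) and ``classes``,
        a mapping from "1"/"2"/"3" to a residue string.
        """
        try:
            classes = doc["classes"]
            name = doc["name"]
        except KeyError as exc:  # pragma: no cover - malformed user file
            raise SchemeError(f"scheme document missing key {exc}") from exc
        class_map: dict[str, int] = {}
        for idx_str, residues in classes.items():
            idx = int(idx_str)
            for res in residues.upper():
                if res in class_map:
                    raise SchemeError(
                        f"scheme {name!r}: residue {res} assigned to more than one class"
                    )
                class_map[res] = idx
        labels = tuple(doc.get("class_labels", ("1", "2", "3")))
        return cls(name=name, class_map=class_map, class_labels=labels)

    @classmethod
    def from_file(cls, path) -> "PropertyScheme":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def load_builtin_schemes() -> dict[str, PropertyScheme]:
    """Load the seven shipped property schemes, keyed and ordered by name."""
    out: dict[str, PropertyScheme] = {}
    pkg = resources.files("mhcload") / "data" / "schemes"
    for name in PROPERTY_ORDER:
        with (pkg / f"{name}.json").open() as fh:
            scheme = PropertyScheme.from_dict(json.load(fh))
        if scheme.name != name:
            raise SchemeError(f"file {name}.json declares scheme {scheme.name!r}")
        out[name] = scheme
    return out


def scheme_fingerprint(schemes: Mapping[str, PropertyScheme]) -> str:
    """Stable hash of a scheme collection, stored in model registries.

    Guards against predicting with coefficients trained under different
    residue partitions.
    """
    payload = {
        name: {str(c): s.residues_in_class(c) for c in (1, 2, 3)}
        for name, s in sorted(schemes.items())
    }
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
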