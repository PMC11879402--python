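"""Regulator classes and the combinatorial model universe.

Six regulator classes can predict a gene's expression: miRNA expression,
transcription-factor expression, lncRNA expression, cis-methylation,
gene-level copy number, and cis-SNP dosages.  A predictive model is any
non-empty subset of these classes, so with all six present there are
2**6 - 1 = 63 models per gene, and every class appears in exactly 32 of
them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

MIRNA = "MIRNA"
TF = "TF"
LNCRNA = "LNCRNA"
METH = "METH"
CNV = "CNV"
SNP = "SNP"

#: Fixed canonical order of the regulator classes.  Subset enumeration,
#: bitmasks and tie-breaking all use this order.
CLASS_ORDER: tuple[str, ...] = (MIRNA, TF, LNCRNA, METH, CNV, SNP)

#: Classes whose features carry genomic coordinates and are admitted to a
#: gene's model through its cis-window.
POSITIONAL_CLASSES: tuple[str, ...] = (LNCRNA, METH, SNP)

#: Classes admitted through a curated regulator->target map.
TRANS_CLASSES: tuple[str, ...] = (MIRNA, TF)

_CLASS_INDEX = {c: i for i, c in enumerate(CLASS_ORDER)}


def class_index(cls: str) -> int:
    """Position of ``cls`` in the canonical order (raises on unknown)."""
    try:
        return _CLASS_INDEX[cls]
    except KeyError:
        raise ValueError(f"unknown regulator class {cls!r}; "
                         f"expected one of {CLASS_ORDER}") from None


@dataclass(frozen=True)
class ModelSpec:
    """One predictive model: a subset of the six regulator classes.

    The empty spec is allowed as an object (it is the intercept-only null
    baseline) but is never fitted as a model.
    """

    classes: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        for c in self.classes:
            class_index(c)
        object.__setattr__(self, "classes", frozenset(self.classes))

    @property
    def bitmask(self) -> int:
        """Integer encoding: bit ``i`` set iff ``CLASS_ORDER[i]`` included."""
        m = 0
        for c in self.classes:
            m |= 1 << class_index(c)
        return m

    @classmethod
    def from_bitmask(cls, mask: int) -> "ModelSpec":
        members = [CLASS_ORDER[i] for i in range(len(CLASS_ORDER))
                   if mask & (1 << i)]
        return cls(frozenset(members))

    @classmethod
    def from_classes(cls, *classes: str) -> "ModelSpec":
        return cls(frozenset(classes))

    @property
    def sort_key(self) -> tuple:
        idx = tuple(sorted(class_index(c) for c in self.classes))
        return (len(self.classes), idx)

    @property
    def label(self) -> str:
        if not self.classes:
            return "NULL"
        return "+".join(sorted(self.classes, key=class_index))

    def __contains__(self, cls: str) -> bool:
        return cls in self.classes

    def __len__(self) -> int:
        return len(self.classes)

    def __iter__(self):
        return iter(sorted(self.classes, key=class_index))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ModelSpec({self.label})"


NULL_SPEC = ModelSpec(frozenset())


def enumerate_models(classes=CLASS_ORDER) -> list[ModelSpec]:
    """All non-empty subsets of ``classes`` in canonical order.

    Order: by subset size, then lexicographically on the fixed class order,
    so the enumeration (and every downstream file) is deterministic.

    Raises
    ------
    ValueError
        If ``classes`` is empty.
    """
    classes = tuple(sorted(set(classes), key=class_index))
    if not classes:
        raise ValueError("need at least one regulator class")
    specs = []
    for size in range(1, len(classes) + 1):
        for combo in itertools.combinations(classes, size):
            specs.append(ModelSpec(frozenset(combo)))
    return specs
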