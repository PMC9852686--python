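"""Diagnostic class set and the clinical priority hierarchy.

A large-bowel biopsy pipeline assigns each tile one of ten diagnostic
classes.  Aggregation to slide, specimen and case level uses a strict total
order on the classes ("the hierarchy"): the dominant diagnosis of any group
of units is the member class with the *smallest* rank number, i.e. the most
clinically significant one.  Rank 1 (adenocarcinoma) always wins; normal
large-bowel mucosa (rank 10) only survives when nothing else is present.
"""

from __future__ import annotations

import enum
from collections.abc import Iterable, Mapping


class DiagnosticClass(enum.Enum):
    """One of the ten tile/slide/case diagnostic classes.

    The enum value is the hierarchy rank (1 = highest clinical priority).
    Connective tissue sits at rank 9, between immunohistochemistry and
    normal large bowel; it essentially never dominates a slide, so its exact
    position is inconsequential but keeps the order total.
    """

    adenocarcinoma = 1
    adenoma = 2
    anal_mucosa = 3
    hp_ssl = 4  # hyperplastic polyp / sessile serrated lesion
    inflammation = 5
    normal_small_bowel = 6
    artifact = 7
    immunohistochemistry = 8
    connective_tissue = 9
    normal_large_bowel = 10

    @property
    def rank(self) -> int:
        return self.value

    def __str__(self) -> str:  # CSV-friendly
        return self.name


#: Classes in hierarchy order (rank 1 first).
CLASSES: tuple[DiagnosticClass, ...] = tuple(
    sorted(DiagnosticClass, key=lambda c: c.value)
)

#: Neoplastic classes ("neoplasia" in reporting aggregates).
NEOPLASIA = frozenset(
    {DiagnosticClass.adenocarcinoma, DiagnosticClass.adenoma}
)

RankTable = Mapping[DiagnosticClass, int]


def class_from_name(name: str) -> DiagnosticClass:
    """Look up a class by its string name, with a helpful error."""
    try:
        return DiagnosticClass[name]
    except KeyError:
        valid = ", ".join(c.name for c in CLASSES)
        raise ValueError(f"unknown diagnostic class {name!r}; expected one of: {valid}") from None


def hierarchy_max(
    classes: Iterable[DiagnosticClass],
    ranks: RankTable | None = None,
) -> DiagnosticClass:
    """Return the highest-priority (minimum-rank) class of a non-empty group.

    ``ranks`` overrides the default rank table; it must remain a strict
    total order over the classes involved.
    """
    items = list(classes)
    if not items:
        raise ValueError("hierarchy_max of an empty collection")
    if ranks is None:
        return min(items, key=lambda c: c.value)
    return min(items, key=lambda c: ranks[c])


def class_from_code(code: int) -> DiagnosticClass:
    """Map an integer label code (the rank) back to its class."""
    return DiagnosticClass(code)
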