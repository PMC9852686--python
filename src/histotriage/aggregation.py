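"""Dominant-diagnosis aggregation: tile -> slide -> specimen -> case.

Tiles whose classification probability score is below 0.75 are excluded
(the boundary score of exactly 0.75 is kept).  The dominant diagnosis of a
slide is the highest-ranked class — the minimum rank number in the
clinical hierarchy — among the surviving tile labels; specimen and case
diagnoses roll up the same way.  One confidently-classified adenocarcinoma
tile anywhere in a case therefore makes the whole case adenocarcinoma.

A slide is never left undiagnosed: when every tile falls below the
threshold, the hierarchy is applied to the unfiltered labels and the
result is flagged ``low_confidence``.  Optionally, tiles carrying named
classes (typically ``artifact``) can be excluded before ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .classifier import TileClassification
from .hierarchy import DiagnosticClass, RankTable, hierarchy_max

DEFAULT_THRESHOLD = 0.75


@dataclass
class SlideDiagnosis:
    slide_id: str
    diagnosis: DiagnosticClass
    supporting_tiles: int  # threshold-passing tiles with that label
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.supporting_tiles < 1 and not self.low_confidence:
            raise ValueError("a confident slide diagnosis needs >= 1 supporting tile")


@dataclass
class CaseDiagnosis:
    case_id: str
    diagnosis: DiagnosticClass
    specimen_diagnoses: dict[str, DiagnosticClass]

    def __post_init__(self) -> None:
        # The case diagnosis must come from its own specimens; the exact
        # hierarchy-maximum property is enforced where the rank table is known.
        if self.diagnosis not in self.specimen_diagnoses.values():
            raise ValueError("case diagnosis must be one of the specimen diagnoses")


def filter_tiles(
    classifications: Iterable[TileClassification],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[TileClassification]:
    """Keep exactly the tiles whose score is >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return [c for c in classifications if c.score >= threshold]


def dominant_slide_diagnosis(
    classifications: list[TileClassification],
    threshold: float = DEFAULT_THRESHOLD,
    exclude_classes: Iterable[DiagnosticClass] = (),
    ranks: RankTable | None = None,
) -> SlideDiagnosis:
    """Highest-ranked label among threshold-passing tiles of one slide.

    ``exclude_classes`` drops tiles with those labels before ranking (the
    alternate handling of artifact tiles); if that or the score filter
    leaves nothing, the hierarchy is applied to all remaining/unfiltered
    labels and the result is flagged low-confidence.
    """
    if not classifications:
        raise ValueError("no tile classifications for slide")
    slide_id = classifications[0].slide_id
    excluded = set(exclude_classes)
    candidates = [c for c in classifications if c.label not in excluded]
    low_confidence = False
    if not candidates:  # everything excluded: fall back to all tiles
        candidates = list(classifications)
        low_confidence = True
    surviving = filter_tiles(candidates, threshold)
    if not surviving:
        surviving = candidates
        low_confidence = True
    diagnosis = hierarchy_max((c.label for c in surviving), ranks)
    supporting = sum(
        1 for c in surviving if c.label is diagnosis and c.score >= threshold
    )
    return SlideDiagnosis(
        slide_id=slide_id,
        diagnosis=diagnosis,
        supporting_tiles=supporting,
        low_confidence=low_confidence,
    )


def specimen_diagnosis(
    slide_diagnoses: Iterable[SlideDiagnosis | DiagnosticClass],
    ranks: RankTable | None = None,
) -> DiagnosticClass:
    """Hierarchy maximum over a specimen's slide diagnoses."""
    classes = [
        d.diagnosis if isinstance(d, SlideDiagnosis) else d for d in slide_diagnoses
    ]
    if not classes:
        raise ValueError("no slide diagnoses for specimen")
    return hierarchy_max(classes, ranks)


def case_diagnosis(
    specimen_diagnoses: Mapping[str, DiagnosticClass],
    case_id: str = "",
    ranks: RankTable | None = None,
) -> CaseDiagnosis:
    """Hierarchy maximum over specimen diagnoses, keeping the per-specimen map."""
    if not specimen_diagnoses:
        raise ValueError("no specimen diagnoses for case")
    return CaseDiagnosis(
        case_id=case_id,
        diagnosis=hierarchy_max(specimen_diagnoses.values(), ranks),
        specimen_diagnoses=dict(specimen_diagnoses),
    )
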