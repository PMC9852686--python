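"""Pathway allocation, reporting priority, and the reporting-queue simulator.

The triage study design: incoming biopsy cases are split by the parity of
the numeric component of their laboratory case number (odd -> AI pathway,
even -> routine pathway).  AI-pathway cases whose case-level AI diagnosis
is neoplasia (adenoma or adenocarcinoma) or inflammation are flagged
*urgent* and jump the reporting queue; everything else — and the whole
routine pathway — is reported first-in-first-out.  Turnaround time is
measured from completion of slide scanning to report authorization and
rendered as ``dd:hh``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime, timedelta

from .hierarchy import DiagnosticClass

#: Case-level AI diagnoses that are prioritized for reporting.
URGENT_CLASSES = frozenset(
    {
        DiagnosticClass.adenocarcinoma,
        DiagnosticClass.adenoma,
        DiagnosticClass.inflammation,
    }
)

_CASE_ID_RE = re.compile(r"^SP(?P<num>\d+)(?:-(?P<spec>[^-]+)(?:-(?P<slide>[^-]+))?)?$")


class CaseIdentifierError(ValueError):
    """A case/specimen/slide identifier string does not parse."""


@dataclass
class CaseDiagnosisRef:
    """Minimal stand-in protocol: anything with a ``diagnosis`` attribute."""

    diagnosis: DiagnosticClass


@dataclass
class CaseRecord:
    """A laboratory case: specimens, slides, timestamps and triage state.

    ``specimens`` maps the specimen letter (A, B, ...) to its slide ids.
    ``slide_data`` optionally carries in-memory slide images and ground
    truth when the record comes from the synthetic generator.
    """

    case_id: str
    case_number: int
    specimens: dict[str, list[str]] = field(default_factory=dict)
    scan_complete: datetime | None = None
    pathway: str | None = None  # "ai" | "routine"
    ai_diagnosis: object | None = None  # CaseDiagnosis (aggregation) when AI pathway
    truth_diagnosis: DiagnosticClass | None = None
    report_authorized: datetime | None = None
    unreported: bool = False
    slide_data: dict | None = None

    def __post_init__(self) -> None:
        if (
            self.report_authorized is not None
            and self.scan_complete is not None
            and self.report_authorized < self.scan_complete
        ):
            raise ValueError(
                f"{self.case_id}: report authorized before scan completion"
            )


@dataclass
class ReportingCapacity:
    """Pathologist availability: a list of (session time, cases reportable)."""

    sessions: list[tuple[datetime, int]]

    def __post_init__(self) -> None:
        for when, n in self.sessions:
            if n < 0:
                raise ValueError(f"negative session capacity at {when}")


def parse_case_identifier(text: str) -> tuple[str, str | None, int | None]:
    """Parse ``SP<digits>[-<letter>[-<number>]]`` into its components.

    Returns ``(case_id, specimen_letter, slide_number)``; the latter two are
    None when absent.  Raises :class:`CaseIdentifierError` naming the
    offending component.
    """
    if not text.startswith("SP"):
        raise CaseIdentifierError(f"{text!r}: missing SP prefix")
    m = _CASE_ID_RE.match(text)
    if m is None or not m.group("num"):
        raise CaseIdentifierError(f"{text!r}: case number must be SP followed by digits")
    specimen = m.group("spec")
    if specimen is not None and not re.fullmatch(r"[A-Z]", specimen):
        raise CaseIdentifierError(
            f"{text!r}: specimen component {specimen!r} must be a single capital letter"
        )
    slide = m.group("slide")
    slide_no: int | None = None
    if slide is not None:
        if not slide.isdigit():
            raise CaseIdentifierError(
                f"{text!r}: slide component {slide!r} must be a number"
            )
        slide_no = int(slide)
    return f"SP{m.group('num')}", specimen, slide_no


def format_case_identifier(
    case_id: str, specimen: str | None = None, slide: int | None = None
) -> str:
    """Inverse of :func:`parse_case_identifier`."""
    out = case_id
    if specimen is not None:
        out += f"-{specimen}"
        if slide is not None:
            out += f"-{slide}"
    return out


def case_number_of(case_id: str) -> int:
    """Numeric component of a case id (``SP2312345`` -> 2312345)."""
    base, _, _ = parse_case_identifier(case_id)
    return int(base[2:])


def allocate_pathway(case_number: int) -> str:
    """Odd case numbers go to the AI pathway, even to the routine pathway."""
    if case_number < 0:
        raise ValueError("case number must be non-negative")
    return "ai" if case_number % 2 == 1 else "routine"


def priority_for(diagnosis: DiagnosticClass, urgent_classes=URGENT_CLASSES) -> str:
    """Reporting priority for a case-level AI diagnosis.

    Urgent iff the diagnosis is neoplasia (adenocarcinoma or adenoma) or
    inflammation; every other class is reported routinely.
    """
    if not isinstance(diagnosis, DiagnosticClass):
        raise TypeError(f"expected DiagnosticClass, got {diagnosis!r}")
    return "urgent" if diagnosis in urgent_classes else "routine"


def _case_priority(case: CaseRecord, urgent_classes) -> str:
    if case.pathway != "ai" or case.ai_diagnosis is None:
        return "routine"
    return priority_for(case.ai_diagnosis.diagnosis, urgent_classes)


def simulate_reporting(
    cases: list[CaseRecord],
    capacity: ReportingCapacity,
    seed: int = 0,
    urgent_classes=URGENT_CLASSES,
) -> list[CaseRecord]:
    """Fill ``report_authorized`` by running the session-based reporting queue.

    At each session, reportable slots are consumed first by urgent
    AI-pathway cases (FIFO by scan completion within the priority band),
    then by all remaining eligible cases FIFO by scan completion.
    Routine-pathway cases are never prioritized regardless of diagnosis.
    Cases that remain unreported when capacity runs out are flagged
    ``unreported``.  The simulation is deterministic; ``seed`` is accepted
    for interface uniformity and ties are broken by case number.
    """
    for case in cases:
        if case.scan_complete is None or case.pathway is None:
            raise ValueError(f"{case.case_id}: scan_complete and pathway required")
        if case.pathway == "ai" and case.ai_diagnosis is None:
            raise ValueError(f"{case.case_id}: AI-pathway case lacks an AI diagnosis")

    pending = sorted(cases, key=lambda c: (c.scan_complete, c.case_number))
    for when, n_slots in sorted(capacity.sessions, key=lambda s: s[0]):
        eligible = [c for c in pending if c.scan_complete <= when]
        urgent = [c for c in eligible if _case_priority(c, urgent_classes) == "urgent"]
        rest = [c for c in eligible if _case_priority(c, urgent_classes) != "urgent"]
        reported_now = (urgent + rest)[:n_slots]
        for case in reported_now:
            case.report_authorized = when
        done = set(id(c) for c in reported_now)
        pending = [c for c in pending if id(c) not in done]
    for case in pending:
        case.unreported = True
    return cases


def turnaround(case: CaseRecord) -> timedelta:
    """Report authorization minus scan completion; non-negative."""
    if case.scan_complete is None or case.report_authorized is None:
        raise ValueError(f"{case.case_id}: both timestamps required for turnaround")
    delta = case.report_authorized - case.scan_complete
    if delta < timedelta(0):
        raise ValueError(f"{case.case_id}: report authorized before scan completion")
    return delta


def turnaround_hours(delta: timedelta) -> int:
    """Whole hours, truncated."""
    return int(delta.total_seconds() // 3600)


def format_dd_hh(delta: timedelta) -> str:
    """Render a duration as days and hours, ``dd:hh`` (hours truncated)."""
    hours = turnaround_hours(delta)
    return f"{hours // 24:02d}:{hours % 24:02d}"


def uniform_capacity(
    start: datetime, n_sessions: int, interval_hours: float, cases_per_session: int
) -> ReportingCapacity:
    """Convenience: evenly spaced sessions of equal capacity."""
    return ReportingCapacity(
        sessions=[
            (start + timedelta(hours=i * interval_hours), cases_per_session)
            for i in range(n_sessions)
        ]
    )
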