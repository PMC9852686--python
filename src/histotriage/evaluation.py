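"""Evaluation: confusion matrices, sensitivity/specificity aggregates,
concordance, and the turnaround-time comparison.

Performance is summarised the way a histopathology triage study reports
it: confusion matrices of AI versus ground-truth diagnoses at slide,
specimen and case level; sensitivity and specificity for clinically
meaningful aggregates of classes (neoplasia; neoplasia plus inflammation;
those plus HP/SSL; normal mucosa); raw concordance; and a comparison of
mean turnaround times between the routine and AI-triage pathways with a
two-tailed Welch t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .hierarchy import CLASSES, DiagnosticClass

#: The reported diagnosis aggregates, in display order.
DEFAULT_AGGREGATES: dict[str, frozenset[DiagnosticClass]] = {
    "adenomas_and_adenocarcinomas": frozenset(
        {DiagnosticClass.adenoma, DiagnosticClass.adenocarcinoma}
    ),
    "adenomas_adenocarcinomas_and_inflammation": frozenset(
        {
            DiagnosticClass.adenoma,
            DiagnosticClass.adenocarcinoma,
            DiagnosticClass.inflammation,
        }
    ),
    "adenomas_adenocarcinomas_inflammation_and_hp_ssl": frozenset(
        {
            DiagnosticClass.adenoma,
            DiagnosticClass.adenocarcinoma,
            DiagnosticClass.inflammation,
            DiagnosticClass.hp_ssl,
        }
    ),
    "normal_small_or_large_bowel": frozenset(
        {DiagnosticClass.normal_small_bowel, DiagnosticClass.normal_large_bowel}
    ),
}


@dataclass
class ConfusionMatrix:
    level: str  # "slide" | "specimen" | "case"
    classes: list[DiagnosticClass]
    counts: np.ndarray  # rows = truth, columns = AI prediction

    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self):
        import pandas as pd

        names = [c.name for c in self.classes]
        return pd.DataFrame(self.counts, index=names, columns=names)


@dataclass
class MetricsRow:
    aggregate_name: str
    positive_set: frozenset[DiagnosticClass]
    level: str
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass
class TATComparison:
    group_name: str
    n_routine: int
    n_ai: int
    mean_routine: float  # hours
    mean_ai: float  # hours
    p_value: float | None  # None when either arm has < 2 cases


def _check_keys(pred: Mapping, truth: Mapping) -> None:
    if not pred or not truth:
        raise ValueError("prediction and truth maps must be non-empty")
    missing = set(truth) - set(pred)
    extra = set(pred) - set(truth)
    if missing or extra:
        raise ValueError(
            f"unit mismatch: missing predictions for {sorted(map(str, missing))[:5]}, "
            f"unexpected predictions for {sorted(map(str, extra))[:5]}"
        )
    bad = [u for u in truth if not isinstance(truth[u], DiagnosticClass)]
    bad += [u for u in pred if not isinstance(pred[u], DiagnosticClass)]
    if bad:
        raise ValueError(f"non-class labels for units {sorted(map(str, bad))[:5]}")


def confusion_matrix(
    pred: Mapping[str, DiagnosticClass],
    truth: Mapping[str, DiagnosticClass],
    level: str = "case",
    classes: Sequence[DiagnosticClass] = CLASSES,
) -> ConfusionMatrix:
    """Counts[i][j] = number of units with truth class i and AI class j."""
    _check_keys(pred, truth)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for unit, t in truth.items():
        counts[index[t], index[pred[unit]]] += 1
    return ConfusionMatrix(level=level, classes=list(classes), counts=counts)


def sensitivity_specificity(
    pred: Mapping[str, DiagnosticClass],
    truth: Mapping[str, DiagnosticClass],
    positive_set: Iterable[DiagnosticClass],
    aggregate_name: str = "",
    level: str = "case",
) -> MetricsRow:
    """Binary sensitivity/specificity after collapsing classes to a
    positive aggregate.

    A unit is predicted-positive iff its AI class is in ``positive_set``
    and truth-positive iff its truth class is.  The positive set may be
    neither empty nor the whole class universe (either would make one of
    the rates 0/0 by construction); a rate whose denominator happens to be
    empty in the data is returned as NaN.
    """
    _check_keys(pred, truth)
    pos = frozenset(positive_set)
    universe = frozenset(CLASSES)
    if not pos or pos >= universe:
        raise ValueError("positive_set must be a proper non-empty subset of classes")
    tp = fp = tn = fn = 0
    for unit, t in truth.items():
        p_pos = pred[unit] in pos
        t_pos = t in pos
        if t_pos and p_pos:
            tp += 1
        elif t_pos:
            fn += 1
        elif p_pos:
            fp += 1
        else:
            tn += 1
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return MetricsRow(
        aggregate_name=aggregate_name or "+".join(sorted(c.name for c in pos)),
        positive_set=pos,
        level=level,
        sensitivity=sens,
        specificity=spec,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


def concordance(
    pred: Mapping[str, DiagnosticClass], truth: Mapping[str, DiagnosticClass]
) -> tuple[int, int, int]:
    """Exact agreement: (concordant count, total, percentage).

    The percentage is rounded half-up to an integer for display; callers
    needing the raw fraction can divide the first two values.
    """
    _check_keys(pred, truth)
    concordant = sum(1 for u in truth if pred[u] is truth[u])
    total = len(truth)
    pct = int(
        (Decimal(100 * concordant) / Decimal(total)).quantize(
            Decimal("1"), rounding=ROUND_HALF_UP
        )
    )
    return concordant, total, pct


def _as_hours(values) -> np.ndarray:
    out = []
    for v in values:
        if isinstance(v, timedelta):
            out.append(v.total_seconds() / 3600.0)
        else:
            out.append(float(v))
    return np.asarray(out, dtype=float)


def tat_comparison(
    routine_durations,
    ai_durations,
    group_name: str = "",
    equal_var: bool = False,
) -> TATComparison:
    """Mean turnaround per pathway and a two-tailed two-sample t-test.

    Durations may be timedeltas or hour counts.  Welch's unequal-variance
    form is the default; pass ``equal_var=True`` for the pooled test.
    Groups with fewer than 2 cases in either arm report means only
    (p_value None).
    """
    routine = _as_hours(routine_durations)
    ai = _as_hours(ai_durations)
    if routine.size == 0 or ai.size == 0:
        raise ValueError("both pathway groups must be non-empty")
    p_value: float | None = None
    if routine.size >= 2 and ai.size >= 2:
        result = sps.ttest_ind(routine, ai, equal_var=equal_var)
        p_value = float(result.pvalue)
    return TATComparison(
        group_name=group_name,
        n_routine=int(routine.size),
        n_ai=int(ai.size),
        mean_routine=float(routine.mean()),
        mean_ai=float(ai.mean()),
        p_value=p_value,
    )


def metrics_table(
    pred_by_level: Mapping[str, Mapping[str, DiagnosticClass]],
    truth_by_level: Mapping[str, Mapping[str, DiagnosticClass]],
    aggregates: Mapping[str, frozenset[DiagnosticClass]] | None = None,
) -> list[MetricsRow]:
    """One MetricsRow per (aggregate, level); levels typically specimen and case."""
    aggregates = dict(aggregates or DEFAULT_AGGREGATES)
    rows = []
    for level, pred in pred_by_level.items():
        truth = truth_by_level[level]
        for name, pos in aggregates.items():
            rows.append(
                sensitivity_specificity(
                    pred, truth, pos, aggregate_name=name, level=level
                )
            )
    return rows


def metrics_frame(rows: list[MetricsRow]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "aggregate": r.aggregate_name,
                "level": r.level,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "tp": r.tp,
                "fp": r.fp,
                "tn": r.tn,
                "fn": r.fn,
            }
            for r in rows
        ]
    )
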