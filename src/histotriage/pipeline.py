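"""End-to-end pipeline runner: tile -> classify -> aggregate -> triage -> evaluate.

Reads a cohort directory (slide images plus ``manifest.csv``), runs every
stage with the configured parameters, writes each intermediate as CSV in
the output directory along with a line-oriented log, and returns a run
summary.  The run is fully reproducible from (inputs, config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import aggregation, evaluation, tiling, triage
from .classifier import MockClassifier, TrainedClassifier, classify
from .hierarchy import CLASSES, DiagnosticClass, class_from_name, hierarchy_max


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str
    tile_size: int = 512
    min_tissue_fraction: float = 0.10
    scan_factor_from: float = 5.0  # manifest images are already at x5 by default
    scan_factor_to: float = 5.0
    log_sigma: float = 4.0
    threshold: float = 0.75
    exclude_classes: tuple[str, ...] = ()
    urgent_classes: tuple[str, ...] = ("adenocarcinoma", "adenoma", "inflammation")
    classifier: dict = field(
        default_factory=lambda: {"type": "mock", "error_rate": 0.0}
    )
    capacity: dict = field(
        default_factory=lambda: {
            "n_sessions": 30,
            "interval_hours": 24.0,
            "cases_per_session": 20,
        }
    )
    run_triage: bool = True
    run_evaluation: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.tile_size < 1:
            raise ValueError("tile_size must be positive")
        if not 0.0 <= self.min_tissue_fraction <= 1.0:
            raise ValueError("min_tissue_fraction must be in [0, 1]")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        if self.scan_factor_from < self.scan_factor_to:
            raise ValueError("scan_factor_from must be >= scan_factor_to")
        for name in (*self.exclude_classes, *self.urgent_classes):
            class_from_name(name)
        if self.classifier.get("type") not in ("mock", "model"):
            raise ValueError("classifier.type must be 'mock' or 'model'")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RunSummary:
    output_dir: str
    n_cases: int
    n_slides: int
    n_tiles: int
    case_diagnoses: dict
    metrics: pd.DataFrame | None
    concordance: tuple[int, int, int] | None
    paths: dict[str, str]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending unit."""


def _build_classifier(config: PipelineConfig):
    spec = config.classifier
    if spec["type"] == "mock":
        return MockClassifier(
            error_rate=float(spec.get("error_rate", 0.0)),
            seed=int(spec.get("seed", config.seed)),
        )
    return TrainedClassifier.load(spec["path"])


def run_pipeline(config: PipelineConfig) -> RunSummary:
    """Execute every stage; see the module docstring.

    Startup validation (config ranges, input manifest present) happens
    before any output is written, so a misconfigured run leaves no partial
    outputs behind.
    """
    config.validate()
    input_dir = Path(config.input_dir)
    manifest_path = input_dir / "manifest.csv"
    if not input_dir.is_dir() or not manifest_path.exists():
        raise PipelineError(f"startup: input manifest not found at {manifest_path}")

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(f"{datetime.now(timezone.utc).isoformat()} {msg}")

    manifest = pd.read_csv(manifest_path).sort_values("slide_id").reset_index(drop=True)
    model = _build_classifier(config)
    exclude = tuple(class_from_name(n) for n in config.exclude_classes)
    urgent = frozenset(class_from_name(n) for n in config.urgent_classes)

    # --- tile + classify + slide-level aggregation -----------------------
    clf_rows, slide_rows = [], []
    slide_ai: dict[str, DiagnosticClass] = {}
    slide_truth: dict[str, DiagnosticClass] = {}
    n_tiles_total = 0
    for rec in manifest.itertuples():
        try:
            image = np.asarray(Image.open(input_dir / rec.image_path).convert("RGB"))
            _, mask, tiles = tiling.tile_slide(
                image,
                slide_id=rec.slide_id,
                tile_size=config.tile_size,
                min_tissue_fraction=config.min_tissue_fraction,
                sigma=config.log_sigma,
                scan_factor_from=config.scan_factor_from,
                scan_factor_to=config.scan_factor_to,
            )
        except Exception as exc:
            raise PipelineError(f"tiling: slide {rec.slide_id}: {exc}") from exc
        log(f"slide {rec.slide_id}: {len(tiles)} tiles "
            f"(tissue fraction {mask.tissue_fraction:.3f})")
        n_tiles_total += len(tiles)
        try:
            classifications = [classify(t, model) for t in tiles]
        except Exception as exc:
            raise PipelineError(f"classify: slide {rec.slide_id}: {exc}") from exc
        for c in classifications:
            row = {
                "slide_id": c.slide_id,
                "row0": c.row0,
                "col0": c.col0,
                "label": c.label.name,
                "score": round(c.score, 6),
            }
            row.update(
                {f"p_{cls.name}": round(float(p), 6)
                 for cls, p in zip(CLASSES, c.probabilities)}
            )
            clf_rows.append(row)
        if classifications:
            sd = aggregation.dominant_slide_diagnosis(
                classifications, threshold=config.threshold, exclude_classes=exclude
            )
        else:  # tissue-free slide: never rejected, reported as background mucosa
            sd = aggregation.SlideDiagnosis(
                slide_id=rec.slide_id,
                diagnosis=DiagnosticClass.normal_large_bowel,
                supporting_tiles=0,
                low_confidence=True,
            )
        slide_ai[rec.slide_id] = sd.diagnosis
        slide_truth[rec.slide_id] = class_from_name(rec.truth_class)
        slide_rows.append(
            {
                "slide_id": rec.slide_id,
                "n_tiles": len(tiles),
                "diagnosis": sd.diagnosis.name,
                "supporting_tiles": sd.supporting_tiles,
                "low_confidence": sd.low_confidence,
            }
        )
        log(f"slide {rec.slide_id}: diagnosis {sd.diagnosis.name}"
            + (" (low confidence)" if sd.low_confidence else ""))

    # --- specimen and case rollup ---------------------------------------
    spec_ai: dict[str, DiagnosticClass] = {}
    spec_truth: dict[str, DiagnosticClass] = {}
    for spec_id, group in manifest.groupby("specimen_id"):
        ids = sorted(group["slide_id"])
        spec_ai[spec_id] = aggregation.specimen_diagnosis([slide_ai[s] for s in ids])
        spec_truth[spec_id] = hierarchy_max(slide_truth[s] for s in ids)

    case_ai: dict[str, aggregation.CaseDiagnosis] = {}
    case_truth: dict[str, DiagnosticClass] = {}
    cases: list[triage.CaseRecord] = []
    for case_id, group in manifest.groupby("case_id"):
        specs = {
            sid.split("-")[-1]: spec_ai[sid] for sid in sorted(group["specimen_id"].unique())
        }
        cd = aggregation.case_diagnosis(specs, case_id=case_id)
        case_ai[case_id] = cd
        case_truth[case_id] = hierarchy_max(
            spec_truth[sid] for sid in group["specimen_id"].unique()
        )
        number = triage.case_number_of(case_id)
        specimens: dict[str, list[str]] = {}
        for sid, sgroup in group.groupby("specimen_id"):
            specimens[sid.split("-")[-1]] = sorted(sgroup["slide_id"])
        cases.append(
            triage.CaseRecord(
                case_id=case_id,
                case_number=number,
                specimens=specimens,
                scan_complete=datetime.fromisoformat(
                    group["scan_complete_timestamp"].iloc[0]
                ),
                pathway=triage.allocate_pathway(number),
                ai_diagnosis=cd,
                truth_diagnosis=case_truth[case_id],
            )
        )
        log(f"case {case_id}: AI {cd.diagnosis.name}, truth {case_truth[case_id].name}")

    # --- triage simulation -----------------------------------------------
    if config.run_triage and cases:
        cap = config.capacity
        start = cap.get("start")
        if start is not None:
            start_dt = datetime.fromisoformat(start)
        else:
            start_dt = max(c.scan_complete for c in cases) + timedelta(hours=1)
        capacity = triage.uniform_capacity(
            start_dt,
            int(cap.get("n_sessions", 30)),
            float(cap.get("interval_hours", 24.0)),
            int(cap.get("cases_per_session", 20)),
        )
        try:
            triage.simulate_reporting(cases, capacity, seed=config.seed,
                                      urgent_classes=urgent)
        except Exception as exc:
            raise PipelineError(f"triage: {exc}") from exc

    # --- write outputs ----------------------------------------------------
    paths: dict[str, str] = {}

    def write(name: str, frame: pd.DataFrame) -> None:
        p = out / name
        frame.to_csv(p, index=False)
        paths[name] = str(p)

    write("classifications.csv", pd.DataFrame(clf_rows))
    diag_rows = [dict(level="slide", unit_id=r["slide_id"],
                      diagnosis=r["diagnosis"], truth=slide_truth[r["slide_id"]].name,
                      low_confidence=r["low_confidence"]) for r in slide_rows]
    diag_rows += [dict(level="specimen", unit_id=s, diagnosis=spec_ai[s].name,
                       truth=spec_truth[s].name, low_confidence=False)
                  for s in sorted(spec_ai)]
    diag_rows += [dict(level="case", unit_id=c, diagnosis=case_ai[c].diagnosis.name,
                       truth=case_truth[c].name, low_confidence=False)
                  for c in sorted(case_ai)]
    write("diagnoses.csv", pd.DataFrame(diag_rows))
    write("slide_diagnoses.csv", pd.DataFrame(slide_rows))

    case_rows = []
    for c in sorted(cases, key=lambda c: c.case_id):
        tat_h = (
            triage.turnaround_hours(triage.turnaround(c))
            if c.report_authorized is not None
            else None
        )
        case_rows.append(
            {
                "case_id": c.case_id,
                "pathway": c.pathway,
                # effective priority: the routine arm is always FIFO
                "priority": (
                    triage.priority_for(c.ai_diagnosis.diagnosis, urgent)
                    if c.pathway == "ai"
                    else "routine"
                ),
                "ai_diagnosis": c.ai_diagnosis.diagnosis.name,
                "truth_diagnosis": c.truth_diagnosis.name,
                "scan_complete": c.scan_complete.isoformat(),
                "report_authorized": (
                    c.report_authorized.isoformat() if c.report_authorized else ""
                ),
                "turnaround_hours": tat_h if tat_h is not None else "",
                "turnaround_dd_hh": (
                    triage.format_dd_hh(triage.turnaround(c))
                    if c.report_authorized is not None
                    else ""
                ),
                "unreported": c.unreported,
            }
        )
    write("cases.csv", pd.DataFrame(case_rows))

    metrics_df = None
    conc = None
    if config.run_evaluation:
        pred_by_level = {"specimen": spec_ai, "case": {c: d.diagnosis for c, d in case_ai.items()}}
        truth_by_level = {"specimen": spec_truth, "case": case_truth}
        rows = evaluation.metrics_table(pred_by_level, truth_by_level)
        metrics_df = evaluation.metrics_frame(rows)
        write("metrics.csv", metrics_df)
        for level in ("specimen", "case"):
            cm = evaluation.confusion_matrix(
                pred_by_level[level], truth_by_level[level], level=level
            )
            p = out / f"confusion_{level}.csv"
            cm.to_frame().to_csv(p)
            paths[f"confusion_{level}.csv"] = str(p)
        conc = evaluation.concordance(pred_by_level["specimen"], truth_by_level["specimen"])
        summary = {
            "n_cases": len(cases),
            "n_slides": len(slide_rows),
            "n_tiles": n_tiles_total,
            "specimen_concordance": {
                "concordant": conc[0], "total": conc[1], "percent": conc[2]
            },
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        paths["summary.json"] = str(out / "summary.json")

    with open(out / "pipeline.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    paths["pipeline.log"] = str(out / "pipeline.log")

    return RunSummary(
        output_dir=str(out),
        n_cases=len(cases),
        n_slides=len(slide_rows),
        n_tiles=n_tiles_total,
        case_diagnoses={c: d.diagnosis for c, d in case_ai.items()},
        metrics=metrics_df,
        concordance=conc,
        paths=paths,
    )
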