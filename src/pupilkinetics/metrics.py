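"""Interval-matching evaluation: Recall, Precision, GTCR, H, PL.

Detected segments are matched against manually annotated reaction intervals.
The counts are:

* ``tp`` — ground-truth intervals detected (covered by a retained prediction),
* ``fn`` — ground-truth intervals missed,
* ``pc`` — retained predictions that detect at least one ground truth
  ("correct predictions"),
* ``fp`` — retained predictions that detect none.

Metrics::

    Recall    = tp / (tp + fn)
    Precision = pc / (pc + fp)
    GTCR      = pc / tp          (Ground Truth Coverage Rate)
    H         = harmonic mean of the three

GTCR penalises a single long prediction that blankets many annotations: such
a prediction scores perfect recall and precision yet tells the clinician
little about where each reaction happened.  Note the precision numerator is
the number of correct *predictions* (``pc``), not ``tp``: with one prediction
covering three annotations and two stray predictions, precision is 1/3 — two
out of three predictions are wrong — which only the ``pc``-based form yields.

PL is the mean retained-prediction duration and GTL the mean annotation
duration, both in seconds.  Their ratio ``min/max`` defines an adaptive IoU
threshold: before matching, predictions whose temporal IoU with every
annotation is at or below the threshold can be discarded, suppressing
overlong predictions when PL and GTL diverge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .errors import AnnotationError

INTENSITIES = ("weak", "medium", "strong")
CLARITIES = ("obvious", "unclear")

Interval = tuple[int, int]


@dataclass(frozen=True)
class GTInterval:
    start_frame: int
    end_frame: int
    intensity: str = "medium"
    clarity: str = "obvious"

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise AnnotationError("annotation end must exceed start")
        if self.intensity not in INTENSITIES:
            raise AnnotationError(f"unknown intensity {self.intensity!r}")
        if self.clarity not in CLARITIES:
            raise AnnotationError(f"unknown clarity {self.clarity!r}")


@dataclass
class GroundTruthAnnotation:
    """Non-overlapping, sorted reaction annotations for one video."""

    intervals: list[GTInterval]

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda g: g.start_frame)
        for a, b in zip(self.intervals[:-1], self.intervals[1:]):
            if b.start_frame < a.end_frame:
                raise AnnotationError(
                    f"overlapping annotations [{a.start_frame},{a.end_frame}) and "
                    f"[{b.start_frame},{b.end_frame})"
                )

    def restrict(self, groups: Iterable[str]) -> "GroundTruthAnnotation":
        groups = set(groups)
        unknown = groups - set(INTENSITIES)
        if unknown:
            raise AnnotationError(f"unknown intensity groups {sorted(unknown)}")
        return GroundTruthAnnotation(
            [g for g in self.intervals if g.intensity in groups]
        )


@dataclass(frozen=True)
class MatchConfig:
    """Matching rules.

    apply_iou_filter     : drop predictions failing the adaptive IoU
                           threshold before matching (on for real runs).
    containment_fraction : fraction of an annotation a prediction must cover
                           to detect it; 1.0 = full containment.
    """

    apply_iou_filter: bool = True
    containment_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.containment_fraction <= 1.0:
            raise ValueError("containment_fraction must lie in (0, 1]")


@dataclass
class MatchResult:
    tp: int
    fn: int
    fp: int
    pc: int
    assignment: dict[int, list[int]]  # gt index -> retained prediction indices
    retained: list[int]  # indices of predictions surviving the IoU filter
    gtl_seconds: float
    pl_seconds: float  # mean duration of retained predictions
    iou_tr: float


@dataclass
class EvaluationResult:
    tp: int
    fn: int
    fp: int
    pc: int
    recall: float
    precision: float
    gtcr: float
    h: float
    pl_seconds: float
    gtl_seconds: float
    iou_tr: float

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "fp": self.fp,
            "pc": self.pc,
            "recall": round(self.recall, 6),
            "precision": round(self.precision, 6),
            "gtcr": round(self.gtcr, 6),
            "h": round(self.h, 6),
            "pl_seconds": round(self.pl_seconds, 6),
            "gtl_seconds": round(self.gtl_seconds, 6),
            "iou_tr": round(self.iou_tr, 6),
        }


def iou_threshold(gtl_seconds: float, pl_seconds: float) -> float:
    """Adaptive IoU threshold: min(GTL, PL) / max(GTL, PL)."""
    if gtl_seconds <= 0 or pl_seconds <= 0:
        raise ValueError("GTL and PL must be positive")
    return min(gtl_seconds, pl_seconds) / max(gtl_seconds, pl_seconds)


def temporal_iou(a: Interval, b: Interval) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union > 0 else 0.0


def harmonic_mean(recall: float, precision: float, gtcr: float) -> float:
    """H = 3 / (1/Recall + 1/Precision + 1/GTCR); 0 if any component is 0."""
    if recall <= 0 or precision <= 0 or gtcr <= 0:
        return 0.0
    return 3.0 / (1.0 / recall + 1.0 / precision + 1.0 / gtcr)


def _check_predictions(predictions: Sequence[Interval]) -> list[Interval]:
    preds = [(int(s), int(e)) for s, e in predictions]
    for s, e in preds:
        if e <= s:
            raise ValueError(f"prediction end must exceed start: [{s},{e})")
    return sorted(preds)


def match(
    predictions: Sequence[Interval],
    gt: GroundTruthAnnotation,
    cfg: MatchConfig,
    fps: float,
) -> MatchResult:
    """Match predictions to annotations and count tp/fn/fp/pc.

    The IoU threshold is computed once from the current annotation and
    prediction sets (no fixed-point iteration) and predictions are retained
    when their IoU with *some* annotation strictly exceeds it.  A ground
    truth counts as detected when a retained prediction covers at least
    ``containment_fraction`` of it.
    """
    preds = _check_predictions(predictions)
    gts = [(g.start_frame, g.end_frame) for g in gt.intervals]
    gtl = sum(e - s for s, e in gts) / len(gts) / fps if gts else 0.0
    pl_all = sum(e - s for s, e in preds) / len(preds) / fps if preds else 0.0
    iou_tr = iou_threshold(gtl, pl_all) if (gts and preds) else 0.0

    if cfg.apply_iou_filter and gts and preds:
        retained = [
            i
            for i, p in enumerate(preds)
            if any(temporal_iou(p, g) > iou_tr for g in gts)
        ]
    else:
        retained = list(range(len(preds)))

    assignment: dict[int, list[int]] = {}
    correct: set[int] = set()
    for j, g in enumerate(gts):
        glen = g[1] - g[0]
        hits = []
        for i in retained:
            p = preds[i]
            inter = max(0, min(p[1], g[1]) - max(p[0], g[0]))
            if inter / glen >= cfg.containment_fraction:
                hits.append(i)
        if hits:
            assignment[j] = hits
            correct.update(hits)

    tp = len(assignment)
    fn = len(gts) - tp
    pc = len(correct)
    fp = len(retained) - pc
    pl_ret = (
        sum(preds[i][1] - preds[i][0] for i in retained) / len(retained) / fps
        if retained
        else 0.0
    )
    return MatchResult(
        tp=tp,
        fn=fn,
        fp=fp,
        pc=pc,
        assignment=assignment,
        retained=retained,
        gtl_seconds=gtl,
        pl_seconds=pl_ret,
        iou_tr=iou_tr,
    )


def counts_to_metrics(
    tp: int,
    fn: int,
    fp: int,
    pc: int,
    pl_seconds: float = 0.0,
    gtl_seconds: float = 0.0,
    iou_tr: float = 0.0,
) -> EvaluationResult:
    """Metrics from raw counts; any zero denominator yields 0 (and H = 0)."""
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    precision = pc / (pc + fp) if pc + fp > 0 else 0.0
    gtcr = pc / tp if tp > 0 else 0.0
    return EvaluationResult(
        tp=tp,
        fn=fn,
        fp=fp,
        pc=pc,
        recall=recall,
        precision=precision,
        gtcr=gtcr,
        h=harmonic_mean(recall, precision, gtcr),
        pl_seconds=pl_seconds,
        gtl_seconds=gtl_seconds,
        iou_tr=iou_tr,
    )


def evaluate(
    predictions: Sequence[Interval],
    gt: GroundTruthAnnotation,
    cfg: MatchConfig,
    fps: float,
) -> EvaluationResult:
    """Match then compute Recall, Precision, GTCR, H and PL for one video."""
    m = match(predictions, gt, cfg, fps)
    return counts_to_metrics(
        m.tp, m.fn, m.fp, m.pc, m.pl_seconds, m.gtl_seconds, m.iou_tr
    )


def evaluate_by_intensity(
    predictions: Sequence[Interval],
    gt: GroundTruthAnnotation,
    cfg: MatchConfig,
    fps: float,
    groups: Iterable[str],
) -> EvaluationResult:
    """Evaluate against the annotations of the named intensity groups only.

    Predictions are *not* restricted, so precision typically drops as the
    groups shrink (predictions of excluded reactions become false positives).
    """
    groups = list(groups)
    if not groups:
        raise AnnotationError("groups must be non-empty")
    return evaluate(predictions, gt.restrict(groups), cfg, fps)


def read_ground_truth(path: str | Path) -> tuple[GroundTruthAnnotation, float]:
    """Read an annotation file: {"fps": float, "reactions": [...]}"""
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    fps = float(doc["fps"])
    intervals = [
        GTInterval(
            start_frame=int(r["start_frame"]),
            end_frame=int(r["end_frame"]),
            intensity=r.get("intensity", "medium"),
            clarity=r.get("clarity", "obvious"),
        )
        for r in doc["reactions"]
    ]
    return GroundTruthAnnotation(intervals), fps


def write_ground_truth(
    gt: GroundTruthAnnotation, fps: float, path: str | Path
) -> None:
    doc = {
        "fps": fps,
        "reactions": [
            {
                "start_frame": g.start_frame,
                "end_frame": g.end_frame,
                "intensity": g.intensity,
                "clarity": g.clarity,
            }
            for g in gt.intervals
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, sort_keys=True, indent=2)
        fh.write("\n")
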