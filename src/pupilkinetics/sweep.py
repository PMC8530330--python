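"""Grid search over cutoff frequency, Delta and analysis mode.

Every (cutoff, delta, mode) cell is scored by detecting on each video,
pooling the match counts across videos, and computing the metrics from the
pooled counts.  The selected configuration maximises H, subject to an upper
bound on the average prediction length: configurations whose predictions are
far longer than a typical reaction (minutes against a one-second event) are
excluded even when their H is higher, because such predictions are useless
to a clinician scanning a video.

Filtering is done once per (video, cutoff, mode); the delta grid only
re-thresholds the cached candidate segments, so the sweep is linear in the
number of cutoffs, not grid cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .detection import (
    DetectionConfig,
    FilterSpec,
    candidate_segments,
    detection_state,
)
from .errors import ConfigError
from .metrics import (
    EvaluationResult,
    GroundTruthAnnotation,
    MatchConfig,
    counts_to_metrics,
    match,
)
from .signals import WidthSignal

PAPER_CUTOFFS = (0.01, 0.05, 0.1, 0.15, 0.2)
PAPER_DELTAS = tuple(round(0.02 * k, 2) for k in range(11))  # 0 .. 0.2


@dataclass(frozen=True)
class SweepGrid:
    cutoffs_hz: tuple[float, ...] = PAPER_CUTOFFS
    deltas: tuple[float, ...] = PAPER_DELTAS
    modes: tuple[str, ...] = ("pupil",)
    max_pl_seconds: float | None = 60.0
    order: int = 5

    def __post_init__(self) -> None:
        if not (self.cutoffs_hz and self.deltas and self.modes):
            raise ConfigError("sweep grid must have cutoffs, deltas and modes")
        if any(not 0 <= d <= 1 for d in self.deltas):
            raise ConfigError("deltas must lie in [0, 1]")


@dataclass(frozen=True)
class SweepRow:
    cutoff_hz: float
    delta: float
    mode: str
    h: float
    recall: float
    precision: float
    gtcr: float
    pl_seconds: float
    n_predictions: int


@dataclass
class SweepResult:
    rows: list[SweepRow]
    best: SweepRow | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _pooled_metrics(
    per_video: Sequence[tuple[int, int, int, int, float, int]],
) -> EvaluationResult:
    """Sum counts over videos, then compute metrics from the pooled counts."""
    tp = sum(v[0] for v in per_video)
    fn = sum(v[1] for v in per_video)
    fp = sum(v[2] for v in per_video)
    pc = sum(v[3] for v in per_video)
    total_dur = sum(v[4] for v in per_video)
    total_n = sum(v[5] for v in per_video)
    pl = total_dur / total_n if total_n else 0.0
    return counts_to_metrics(tp, fn, fp, pc, pl_seconds=pl)


def sweep(
    signals: Mapping[str, WidthSignal],
    gts: Mapping[str, GroundTruthAnnotation],
    grid: SweepGrid,
    match_cfg: MatchConfig | None = None,
) -> SweepResult:
    """Run the grid search across the given videos.

    ``signals`` and ``gts`` are aligned by video id.  Deterministic: there is
    no randomness anywhere in detection or evaluation.
    """
    if match_cfg is None:
        match_cfg = MatchConfig()
    ids = sorted(signals.keys())
    missing = [v for v in ids if v not in gts]
    if missing:
        raise ConfigError(f"no ground truth for videos {missing}")

    rows: list[SweepRow] = []
    for cutoff in grid.cutoffs_hz:
        for mode in grid.modes:
            # cache candidates per video at this (cutoff, mode)
            cached = {}
            for vid in ids:
                sig = signals[vid]
                cfg = DetectionConfig(
                    filter=FilterSpec(cutoff_hz=cutoff, order=grid.order, fps=sig.fps),
                    delta=0.0,
                    mode=mode,
                )
                state = detection_state(sig, cfg)
                cached[vid] = candidate_segments(state, mode)
            for delta in grid.deltas:
                per_video = []
                n_pred = 0
                for vid in ids:
                    sig = signals[vid]
                    preds = [
                        (s.start_frame, s.end_frame)
                        for s in cached[vid]
                        if s.relative_size >= delta
                    ]
                    n_pred += len(preds)
                    m = match(preds, gts[vid], match_cfg, sig.fps)
                    per_video.append(
                        (
                            m.tp,
                            m.fn,
                            m.fp,
                            m.pc,
                            m.pl_seconds * len(m.retained),
                            len(m.retained),
                        )
                    )
                res = _pooled_metrics(per_video)
                rows.append(
                    SweepRow(
                        cutoff_hz=cutoff,
                        delta=delta,
                        mode=mode,
                        h=res.h,
                        recall=res.recall,
                        precision=res.precision,
                        gtcr=res.gtcr,
                        pl_seconds=res.pl_seconds,
                        n_predictions=n_pred,
                    )
                )

    eligible = rows
    if grid.max_pl_seconds is not None:
        eligible = [r for r in rows if r.pl_seconds <= grid.max_pl_seconds]
    best = max(eligible, key=lambda r: r.h) if eligible else None
    return SweepResult(rows=rows, best=best)
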