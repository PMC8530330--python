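"""Extrema-based pupil-reaction detection.

The smoothed width signal is cut at its local extrema; every span between two
neighbouring extrema is a candidate reaction.  A candidate is kept when its
size — the signal change between its two extrema — reaches ``delta`` times
DM, where DM is the difference between the median limbus and median pupil
widths over the whole video.  DM anchors the threshold to the anatomy of the
eye in this recording rather than to absolute pixels, so the same ``delta``
is comparable across videos, zoom levels and resolutions.

Two analysis modes exist: ``pupil`` runs on the smoothed pupil width alone;
``difference`` runs on the smoothed (limbus - pupil) width, exploiting the
fact that the limbus stays essentially constant while the pupil reacts, which
cancels size changes caused by camera zoom or whole-eye motion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DegenerateSignalError
from .filtering import FilterSpec, lowpass
from .signals import WidthSignal

MODE_PUPIL = "pupil"
MODE_DIFFERENCE = "difference"
CONSTRICTION = "constriction"
DILATION = "dilation"


@dataclass(frozen=True)
class DetectionConfig:
    """Detector configuration: smoothing, relevance threshold, analysis mode.

    delta : relevance threshold as a fraction of DM; a candidate segment is a
        reaction only if its absolute size is at least ``delta * DM``.
        0 emits every candidate.
    """

    filter: FilterSpec = field(default_factory=FilterSpec)
    delta: float = 0.12
    mode: str = MODE_PUPIL

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must lie in [0, 1], got {self.delta}")
        if self.mode not in (MODE_PUPIL, MODE_DIFFERENCE):
            raise ValueError(f"mode must be 'pupil' or 'difference', got {self.mode!r}")


@dataclass(frozen=True)
class ReactionSegment:
    """A detected reaction: the span between two neighbouring extrema.

    ``size_px`` is signed on the analysed signal (value at the end extremum
    minus value at the start extremum); ``direction`` is expressed on the
    pupil scale, so a shrinking pupil is a constriction in either mode.
    ``ratio_change`` is the pupil/limbus ratio at the end minus at the start,
    on the smoothed signals — the clinically reported reaction size.
    """

    start_frame: int
    end_frame: int
    size_px: float
    relative_size: float
    direction: str
    ratio_change: float

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError("end_frame must exceed start_frame")

    def length_frames(self) -> int:
        return self.end_frame - self.start_frame

    def to_dict(self, fps: float) -> dict:
        return {
            "start_frame": self.start_frame,
            "end_frame": self.end_frame,
            "start_s": round(self.start_frame / fps, 6),
            "end_s": round(self.end_frame / fps, 6),
            "size_px": round(self.size_px, 6),
            "relative_size": round(self.relative_size, 6),
            "direction": self.direction,
            "ratio_change": round(self.ratio_change, 6),
        }


def compute_dm(signal: WidthSignal) -> float:
    """DM = median(limbus width) - median(pupil width), on the interpolated
    but unfiltered signals.  Medians make the reference robust to reactions
    and residual segmentation noise."""
    dm = float(np.median(signal.limbus_width) - np.median(signal.pupil_width))
    if dm <= 0:
        raise DegenerateSignalError(
            f"median limbus width must exceed median pupil width (DM={dm:.3f})"
        )
    return dm


def find_extrema(filtered: np.ndarray) -> np.ndarray:
    """Indices of strict local extrema, plus both boundary frames.

    An interior extremum is a frame where the first difference changes sign;
    plateaus contribute their first frame only.  The first and last frames
    are always included so the leading and trailing monotone runs form
    candidates too.
    """
    x = np.asarray(filtered, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to find extrema")
    d = np.diff(x)
    nz = np.flatnonzero(d)
    last = x.size - 1
    if nz.size < 2:
        return np.array([0, last])
    signs = np.sign(d[nz])
    turns = nz[:-1][signs[:-1] != signs[1:]] + 1
    return np.concatenate(([0], turns, [last]))


def _analyzed_signal(signal: WidthSignal, config: DetectionConfig) -> np.ndarray:
    if config.mode == MODE_PUPIL:
        raw = signal.pupil_width
    else:
        raw = signal.limbus_width - signal.pupil_width
    return lowpass(raw, config.filter)


@dataclass(frozen=True)
class DetectionState:
    """Intermediate detector state, exposed for inspection and sweeps."""

    dm: float
    analyzed_signal: np.ndarray
    extrema: np.ndarray
    pupil_filtered: np.ndarray
    limbus_filtered: np.ndarray


def detection_state(signal: WidthSignal, config: DetectionConfig) -> DetectionState:
    dm = compute_dm(signal)
    analyzed = _analyzed_signal(signal, config)
    return DetectionState(
        dm=dm,
        analyzed_signal=analyzed,
        extrema=find_extrema(analyzed),
        pupil_filtered=lowpass(signal.pupil_width, config.filter),
        limbus_filtered=lowpass(signal.limbus_width, config.filter),
    )


def candidate_segments(state: DetectionState, mode: str) -> list[ReactionSegment]:
    """All spans between neighbouring extrema, before thresholding."""
    sign_to_pupil = 1.0 if mode == MODE_PUPIL else -1.0
    if np.any(state.limbus_filtered <= 0):
        raise DegenerateSignalError("smoothed limbus width must stay positive")
    ratio = state.pupil_filtered / state.limbus_filtered
    out: list[ReactionSegment] = []
    ext = state.extrema
    for a, b in zip(ext[:-1], ext[1:]):
        size = float(state.analyzed_signal[b] - state.analyzed_signal[a])
        pupil_change = size * sign_to_pupil
        out.append(
            ReactionSegment(
                start_frame=int(a),
                end_frame=int(b),
                size_px=size,
                relative_size=abs(size) / state.dm,
                direction=CONSTRICTION if pupil_change < 0 else DILATION,
                ratio_change=float(ratio[b] - ratio[a]),
            )
        )
    return out


def detect_reactions(
    signal: WidthSignal, config: DetectionConfig
) -> list[ReactionSegment]:
    """Detect pupil reactions in one video's width signal.

    Returns temporally ordered, non-overlapping segments (neighbours share an
    endpoint frame) whose size is at least ``config.delta * DM``.
    """
    state = detection_state(signal, config)
    return [
        seg
        for seg in candidate_segments(state, config.mode)
        if seg.relative_size >= config.delta
    ]


def reaction_ratio_change(
    signal: WidthSignal,
    seg: ReactionSegment,
    filter_spec: FilterSpec | None = None,
) -> float:
    """Pupil/limbus ratio at the segment end minus at its start.

    Evaluated on the smoothed signals when ``filter_spec`` is given (as the
    detector does), otherwise on the raw interpolated signals.
    """
    if not (0 <= seg.start_frame < seg.end_frame < signal.n_frames):
        raise ValueError("segment out of signal bounds")
    if filter_spec is not None:
        pupil = lowpass(signal.pupil_width, filter_spec)
        limbus = lowpass(signal.limbus_width, filter_spec)
    else:
        pupil, limbus = signal.pupil_width, signal.limbus_width
    if limbus[seg.start_frame] <= 0 or limbus[seg.end_frame] <= 0:
        raise DegenerateSignalError("limbus width must be positive")
    return float(
        pupil[seg.end_frame] / limbus[seg.end_frame]
        - pupil[seg.start_frame] / limbus[seg.start_frame]
    )


def reactions_to_json(
    segments: Sequence[ReactionSegment],
    dm: float,
    config: DetectionConfig,
    fps: float,
    path: str | Path | None = None,
) -> dict:
    """Serialize a detection run; written with sorted keys and 6-decimal
    floats for reproducible diffs."""
    doc = {
        "reactions": [s.to_dict(fps) for s in segments],
        "dm": round(dm, 6),
        "config": {
            "cutoff_hz": config.filter.cutoff_hz,
            "order": config.filter.order,
            "fps": config.filter.fps,
            "delta": config.delta,
            "mode": config.mode,
        },
    }
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, sort_keys=True, indent=2)
            fh.write("\n")
    return doc


def intervals_from_json(doc: dict) -> list[tuple[int, int]]:
    """Extract (start_frame, end_frame) pairs from a detection report."""
    return [(int(r["start_frame"]), int(r["end_frame"])) for r in doc["reactions"]]
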