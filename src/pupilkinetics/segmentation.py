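"""Per-frame pupil/iris segmentation records.

The detector does not touch video: an upstream segmentation network (or the
synthetic renderer in :mod:`pupilkinetics.simulate`) produces one record per
frame holding the pupil and iris regions, and this module reads, writes and
validates those records.  Boxes are 0-based and half-open, ``(x_min, y_min,
x_max, y_max)`` with ``x_min < x_max`` — the x-extent ``x_max - x_min`` is the
width used everywhere downstream.

A frame is usable only when both classes were segmented exactly once and the
pupil box lies fully inside the iris box; everything else is reported (never
raised) with a machine-readable reason so that interpolation can fill the gap.

File format: JSON-Lines, one object per frame::

    {"frame": 12, "pupil": {"box": [x0, y0, x1, y1], "rle": {...}},
                  "iris":  {"box": [...]}}

An absent class key means the class was not detected in that frame.  Optional
masks travel as a simple row-major run-length encoding ``{"size": [h, w],
"counts": [...]}`` with runs alternating background-first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import EmptyMaskError, SegmentFormatError

Box = tuple[int, int, int, int]

VALID = "ok"
MISSING_CLASS = "missing_class"
PUPIL_NOT_INSIDE_IRIS = "pupil_not_inside_iris"
TOO_MANY_SEGMENTS = "too_many_segments"


def _check_box(box: Sequence[int], where: str) -> Box:
    if len(box) != 4:
        raise SegmentFormatError(f"{where}: box must have 4 entries, got {len(box)}")
    x0, y0, x1, y1 = (int(v) for v in box)
    if not (x0 < x1 and y0 < y1):
        raise SegmentFormatError(
            f"{where}: degenerate box ({x0}, {y0}, {x1}, {y1}); "
            "require x_min < x_max and y_min < y_max"
        )
    return (x0, y0, x1, y1)


@dataclass(frozen=True)
class FrameSegment:
    """One frame's pupil and iris regions.

    ``n_pupil_regions``/``n_iris_regions`` record how many regions the
    producer emitted per class; more than one is invalid downstream.
    """

    frame_index: int
    pupil_box: Box | None = None
    iris_box: Box | None = None
    pupil_mask: np.ndarray | None = field(default=None, repr=False)
    iris_mask: np.ndarray | None = field(default=None, repr=False)
    source: str = "box"
    n_pupil_regions: int | None = None
    n_iris_regions: int | None = None

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise SegmentFormatError(f"negative frame_index {self.frame_index}")

    def pupil_count(self) -> int:
        if self.n_pupil_regions is not None:
            return self.n_pupil_regions
        return 0 if self.pupil_box is None else 1

    def iris_count(self) -> int:
        if self.n_iris_regions is not None:
            return self.n_iris_regions
        return 0 if self.iris_box is None else 1


@dataclass(frozen=True)
class ValidityReport:
    frame_index: int
    valid: bool
    reason: str

    def __post_init__(self) -> None:
        assert self.valid == (self.reason == VALID)


def encode_rle(mask: np.ndarray) -> dict:
    """Row-major run-length encoding, runs alternating background-first."""
    mask = np.asarray(mask, dtype=bool)
    flat = mask.ravel()
    if flat.size == 0:
        return {"size": list(mask.shape), "counts": []}
    change = np.flatnonzero(flat[1:] != flat[:-1]) + 1
    bounds = np.concatenate(([0], change, [flat.size]))
    counts = np.diff(bounds).tolist()
    if flat[0]:  # leading background run of zero length
        counts = [0] + counts
    return {"size": [int(mask.shape[0]), int(mask.shape[1])], "counts": counts}


def decode_rle(rle: dict) -> np.ndarray:
    h, w = (int(v) for v in rle["size"])
    counts = rle["counts"]
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    val = False
    for run in counts:
        run = int(run)
        if val:
            flat[pos : pos + run] = True
        pos += run
        val = not val
    if pos != h * w:
        raise SegmentFormatError(f"RLE covers {pos} pixels, expected {h * w}")
    return flat.reshape(h, w)


def tight_box(mask: np.ndarray) -> Box:
    """Minimal half-open axis-aligned box containing all foreground pixels."""
    mask = np.asarray(mask, dtype=bool)
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size == 0:
        raise EmptyMaskError("mask has no foreground pixels")
    cols = np.flatnonzero(mask.any(axis=0))
    return (int(cols[0]), int(rows[0]), int(cols[-1]) + 1, int(rows[-1]) + 1)


def validate_frame(seg: FrameSegment) -> ValidityReport:
    """Apply the frame-validity rules.

    A frame is valid iff each class has exactly one region and the pupil box
    is fully contained in the iris box (box-level containment).  Reports,
    never raises.
    """
    if seg.pupil_count() > 1 or seg.iris_count() > 1:
        return ValidityReport(seg.frame_index, False, TOO_MANY_SEGMENTS)
    if seg.pupil_box is None or seg.iris_box is None:
        return ValidityReport(seg.frame_index, False, MISSING_CLASS)
    px0, py0, px1, py1 = seg.pupil_box
    ix0, iy0, ix1, iy1 = seg.iris_box
    inside = px0 >= ix0 and px1 <= ix1 and py0 >= iy0 and py1 <= iy1
    if not inside:
        return ValidityReport(seg.frame_index, False, PUPIL_NOT_INSIDE_IRIS)
    return ValidityReport(seg.frame_index, True, VALID)


def _parse_class(obj, line_no: int, cls: str):
    """Return (box, mask, count) for one class entry of a record."""
    if obj is None:
        return None, None, 0
    if isinstance(obj, list):
        if len(obj) != 1:
            return None, None, len(obj)
        obj = obj[0]
    if not isinstance(obj, dict):
        raise SegmentFormatError(f"line {line_no}: '{cls}' must be an object or list")
    mask = decode_rle(obj["rle"]) if obj.get("rle") is not None else None
    box = None
    if obj.get("box") is not None:
        box = _check_box(obj["box"], f"line {line_no}: {cls}")
    if mask is not None:
        mbox = tight_box(mask)
        if box is None:
            box = mbox
        elif box != mbox:
            raise SegmentFormatError(
                f"line {line_no}: {cls} mask tight box {mbox} != stored box {box}"
            )
    if box is None:
        raise SegmentFormatError(f"line {line_no}: '{cls}' entry has neither box nor rle")
    return box, mask, 1


def read_frame_segments(path: str | Path) -> list[FrameSegment]:
    """Read a JSON-Lines segmentation file, sorted by frame index.

    Raises :class:`SegmentFormatError` naming the offending line on malformed
    input and on duplicate frame indices.
    """
    segs: list[FrameSegment] = []
    seen: set[int] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SegmentFormatError(f"line {line_no}: invalid JSON ({exc})") from exc
            if "frame" not in rec:
                raise SegmentFormatError(f"line {line_no}: missing 'frame' key")
            frame = int(rec["frame"])
            if frame < 0:
                raise SegmentFormatError(f"line {line_no}: negative frame index {frame}")
            if frame in seen:
                raise SegmentFormatError(f"line {line_no}: duplicate frame index {frame}")
            seen.add(frame)
            pbox, pmask, pcount = _parse_class(rec.get("pupil"), line_no, "pupil")
            ibox, imask, icount = _parse_class(rec.get("iris"), line_no, "iris")
            segs.append(
                FrameSegment(
                    frame_index=frame,
                    pupil_box=pbox,
                    iris_box=ibox,
                    pupil_mask=pmask,
                    iris_mask=imask,
                    source="mask" if (pmask is not None or imask is not None) else "box",
                    n_pupil_regions=pcount,
                    n_iris_regions=icount,
                )
            )
    segs.sort(key=lambda s: s.frame_index)
    return segs


def write_frame_segments(segments: Iterable[FrameSegment], path: str | Path) -> None:
    """Write segmentation records as JSON-Lines (inverse of the reader)."""
    with open(path, "w", encoding="utf-8") as fh:
        for seg in sorted(segments, key=lambda s: s.frame_index):
            rec: dict = {"frame": seg.frame_index}
            for cls, box, mask in (
                ("pupil", seg.pupil_box, seg.pupil_mask),
                ("iris", seg.iris_box, seg.iris_mask),
            ):
                if box is None:
                    continue
                entry: dict = {"box": list(box)}
                if mask is not None:
                    entry["rle"] = encode_rle(mask)
                rec[cls] = entry
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
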