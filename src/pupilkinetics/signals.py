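"""Width-signal extraction and temporal interpolation.

Only frames that passed the validity filter contribute a measurement: the
pupil width is the x-extent of the pupil box and the limbus width the
x-extent of the iris box (its outer border is the limbus).  The x-extent is
used because the eye moves vertically far more than horizontally during
surgery, making the horizontal extent the stabler size proxy.

Gaps are closed by carrying the last measured pair forward; a leading run of
missing frames takes the first measured pair.  Pupil and limbus are always
filled jointly from the same donor frame so their difference stays
consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import NoValidFramesError, SegmentFormatError
from .segmentation import FrameSegment, ValidityReport


@dataclass
class WidthSignal:
    """Dense per-frame pupil and limbus widths on the video time line.

    ``measured[i]`` is True where frame ``i`` contributed its own
    measurement and False where the value was filled by interpolation.
    """

    fps: float
    pupil_width: np.ndarray
    limbus_width: np.ndarray
    measured: np.ndarray

    def __post_init__(self) -> None:
        self.pupil_width = np.asarray(self.pupil_width, dtype=float)
        self.limbus_width = np.asarray(self.limbus_width, dtype=float)
        self.measured = np.asarray(self.measured, dtype=bool)
        if not (len(self.pupil_width) == len(self.limbus_width) == len(self.measured)):
            raise ValueError("pupil_width, limbus_width and measured must align")
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return len(self.pupil_width)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "pupil_width": self.pupil_width,
                "limbus_width": self.limbus_width,
                "measured": self.measured,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def measure_widths(
    segments: Sequence[FrameSegment], reports: Sequence[ValidityReport]
) -> dict[int, tuple[float, float]]:
    """Map frame index -> (pupil width, limbus width) over the valid frames.

    ``reports`` must correspond one-to-one (in order) to ``segments``;
    invalid frames are simply absent from the result.
    """
    if len(segments) != len(reports):
        raise SegmentFormatError(
            f"{len(segments)} segments but {len(reports)} validity reports"
        )
    widths: dict[int, tuple[float, float]] = {}
    for seg, rep in zip(segments, reports):
        if seg.frame_index != rep.frame_index:
            raise SegmentFormatError(
                f"report for frame {rep.frame_index} paired with segment "
                f"{seg.frame_index}"
            )
        if not rep.valid:
            continue
        px0, _, px1, _ = seg.pupil_box  # type: ignore[misc]
        ix0, _, ix1, _ = seg.iris_box  # type: ignore[misc]
        widths[seg.frame_index] = (float(px1 - px0), float(ix1 - ix0))
    return widths


def interpolate(
    sparse: Mapping[int, tuple[float, float]], total_frames: int, fps: float
) -> WidthSignal:
    """Fill the sparse width map onto the full frame time line.

    Missing frames take the most recent preceding measurement; a leading run
    of missing frames takes the first following one.  Idempotent: applying it
    to an already dense map is the identity.
    """
    if not sparse:
        raise NoValidFramesError("no valid frames: cannot interpolate widths")
    frames = np.fromiter(sparse.keys(), dtype=int)
    if total_frames < frames.max() + 1:
        raise ValueError(
            f"total_frames={total_frames} smaller than max frame index {frames.max()}"
        )
    measured = np.zeros(total_frames, dtype=bool)
    measured[frames] = True
    # donor[i] = index of the measurement used at frame i (forward fill,
    # then the first measured frame for the leading gap)
    donor = np.where(measured, np.arange(total_frames), -1)
    donor = np.maximum.accumulate(donor)
    donor[donor < 0] = frames.min()
    pupil = np.empty(total_frames)
    limbus = np.empty(total_frames)
    lookup_p = {f: v[0] for f, v in sparse.items()}
    lookup_l = {f: v[1] for f, v in sparse.items()}
    pw = np.zeros(total_frames)
    lw = np.zeros(total_frames)
    for f in frames:
        pw[f] = lookup_p[int(f)]
        lw[f] = lookup_l[int(f)]
    pupil = pw[donor]
    limbus = lw[donor]
    if np.any(pupil <= 0) or np.any(limbus <= 0):
        raise ValueError("widths must be strictly positive")
    return WidthSignal(fps=fps, pupil_width=pupil, limbus_width=limbus, measured=measured)
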