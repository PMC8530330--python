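# Methods

## Problem and model

During cataract surgery the pupil can constrict (miosis) or dilate abruptly —
reactions a clinician wants located after the fact when reviewing recordings.
`pupilkinetics` detects these reactions from *width signals*: per-frame
horizontal extents of the pupil and of the limbus (the outer iris border),
produced upstream by any per-frame segmentation of the eye.  The package
deliberately starts downstream of segmentation: its inputs are JSON-Lines
records of pupil/iris boxes (or masks, from which tight boxes are computed),
not video.

The detection model rests on two anatomical assumptions:

1. the limbus width is essentially constant over a surgery, so the gap
   between the median limbus and median pupil widths (**DM**) is a stable,
   per-video size reference;
2. a reaction is a monotone excursion of the pupil width, so after adequate
   smoothing every reaction lies inside one span between neighbouring local
   extrema of the signal.

The pipeline is: validity filtering → width measurement → temporal
interpolation → zero-phase low-pass filtering → extrema segmentation →
size thresholding.

## Stage-by-stage choices

**Validity.** A frame contributes a measurement only when both classes were
segmented exactly once and the pupil box lies fully inside the iris box
(box-level containment).  Frames with more than one region per class are
rejected rather than disambiguated: nothing in the signal model tells us
which duplicate is the eye.  Boxes are 0-based and half-open, so a box's
width is exactly `x_max − x_min` with no ±1 ambiguity.

**Widths.** Only the horizontal box extent is used; the eye moves vertically
much more than horizontally under the microscope, so the x-extent is the
more stable size proxy.  Heights are never consulted.

**Interpolation.** Missing frames take the last preceding measured pair;
a leading gap takes the first measured pair.  Pupil and limbus are filled
jointly from the same donor frame — filling them from different donors could
manufacture spurious steps in the difference signal.  The operation is
idempotent and never invents values: every filled width equals some measured
width.

**Filtering.** A Butterworth low-pass, applied forward then backward so the
net phase is zero and detected boundaries stay aligned with the time line.
The cutoff `f` is physical (Hz) and normalised by Nyquist internally; the
working grid is {0.01, 0.05, 0.1, 0.15, 0.2} Hz.  The filter order is not
dictated by the method; the default is 5 (a sharp knee at these very low
cutoffs) and it is exposed in `FilterSpec`.  Two numerical choices matter
and are deliberate:

* the filter runs as cascaded second-order sections — at normalised cutoffs
  of order 10⁻³ the expanded polynomial (b, a) form is ill-conditioned
  enough to break even unit DC gain at the 10⁻⁶ level;
* the odd-extension padding of the forward-backward pass is scaled to the
  slowest pole's decay length (18 e-foldings, i.e.
  `18 / (2π · sin(π/2N) · f / fps)` samples), capped at the signal length.
  A short fixed padding (a few times the order) leaves edge transients that
  visibly break time-reversal symmetry at `f = 0.1 Hz`; with the scaled
  padding the forward and reversed results agree to better than 10⁻⁶ on
  signals longer than the transient.  On signals shorter than the required
  padding the cap degrades edge accuracy gracefully; the hard minimum is
  `3·order + 1` samples.

**Detection.** DM is computed from the interpolated but *unfiltered*
signals — medians are robust to both reactions and noise, and filtering
would only bias the tails.  The analysed signal is either the smoothed pupil
width (`pupil` mode) or the smoothed limbus−pupil width (`difference` mode,
which cancels zoom/motion common-mode changes).  Local extrema are strict
sign changes of the first difference; plateaus collapse to their first
frame; both boundary frames count as extrema so leading/trailing monotone
runs can be candidates.  A candidate between neighbouring extrema is emitted
iff its absolute size is ≥ `delta · DM`; `delta = 0` emits every candidate.
In difference mode the sign is inverted before assigning a direction, so
"constriction" always means a shrinking pupil.  Adjacent same-direction
candidates are never merged.  Each emitted segment also carries the
pupil-to-iris ratio change between its endpoints (on the smoothed signals),
the zoom-independent size a clinician reads.

**Evaluation.** Counts: `tp` ground truths detected, `fn` missed, `pc`
predictions detecting ≥ 1 ground truth, `fp` predictions detecting none.
Recall = tp/(tp+fn), **Precision = pc/(pc+fp)**, GTCR = pc/tp,
H = harmonic mean of the three (0 if any component is 0, the harmonic-mean
limit).  The precision numerator is a documented choice: the conventional
`tp/(tp+fp)` is inconsistent with the defining worked example — one
prediction blanketing three annotations plus two strays must score 1/3
("two out of three predictions are wrong"), which only the
correct-predictions form produces.  A ground truth is "detected" when a
retained prediction covers `containment_fraction` of it (default 1.0 — the
containment rule read literally; partial-overlap variants are configurable
but no shipped fixture depends on them).  The adaptive IoU pre-filter drops
predictions whose temporal IoU with every annotation is ≤
`min(GTL, PL)/max(GTL, PL)`; it is computed once from the current sets (no
fixed-point iteration), defaults to on for real runs and off for the worked
fixtures (whose long blanket predictions it would remove by construction).
With non-overlapping predictions — which the detector guarantees — `pc ≤ tp`
and GTCR ≤ 1; arbitrary overlapping prediction sets can violate this.

**Sweep.** Grid cells are scored by summing tp/fn/fp/pc across videos and
computing metrics from the pooled counts (count pooling; per-video metric
averaging would weight a 2-reaction video like a 30-reaction one).  The
best cell maximises H subject to `PL ≤ max_pl_seconds` (default 60 s):
configurations predicting minute-long segments for one-second events are
rejected outright, whatever their H.  Within one cutoff the number of
emitted predictions is non-increasing in `delta`; PL itself is not monotone
(raising `delta` removes short candidates too).

## The synthetic generator

Real surgery videos and annotations cannot ship, so tests and the worked
examples run on simulated width traces that reproduce the documented
statistics of the 25 fps annotation dataset:

| parameter | default | source/rationale |
|---|---|---|
| fps | 25 | recording rate of the annotated dataset |
| duration | 480 s | ≈ mean annotated video length (118,413 frames / 10 videos) |
| reactions per video | 13 | ≈ 135 annotated reactions / 10 videos |
| intensity mix | 72.6 / 14.8 / 12.6 % | annotated weak/medium/strong shares |
| reaction duration | mean 1.0 s, sd 0.67 s | annotated duration moments |
| unclear-annotation rate | 50 / 0 / 5.9 % per intensity | annotated clarity shares |
| baselines | pupil 120 px, limbus 300 px | plausible extents in a 540×720 frame |
| noise sd | 2 px (≈ 0.011·DM) | segmentation jitter scale |
| dropout rate | 5 % | frames lost to failed/invalid segmentation |

Durations are drawn from a lower-truncated normal (floor 2 frames) whose
*underlying* moments are solved numerically so the **post-truncation** mean
and sd equal 1.0 s and 0.67 s — naive truncation would inflate the mean by
≈ 0.11 s.  Reaction sizes are uniform within per-intensity ranges of the
nominal limbus−pupil gap — weak (0.05, 0.10), medium (0.10, 0.20), strong
(0.20, 0.40) — which are the simulator's own convention for the unquantified
intensity labels, not a claim about the annotation rule.  Each reaction is a
logistic ramp (time constant duration/10, so ≥ 98 % of the transition falls
inside the annotated interval) to a new pupil level; the cumulative level
offset is confined to [−0.5, +0.15] of the nominal gap so the pupil neither
vanishes nor outgrows the iris.  Reactions are placed ≥ 6 s apart and ≥ 15 s
from the video edges.  The limbus is constant plus noise.  Everything is
reproducible bit-for-bit from the seed.

What the generator does **not** emulate: camera zoom drift, occlusion by
instruments, the eye leaving the illuminated area, correlated segmentation
failure bursts, or reactions that only partially revert.  Passing the
recovery tests therefore shows the detector is correct under the stated
signal model, not that the published dataset-level scores (which depend on
the real videos) are reproduced.

The renderer turns a simulated video into segmentation records: concentric
pupil/iris boxes (optionally with elliptic masks whose tight boxes equal the
stored boxes exactly) for measured frames, an iris-only record for dropped
frames.  Boxes are constructed directly with the exact rounded widths rather
than by rasterising first, so the render → measure round trip is exact to
rounding (≤ 0.5 px).

## Problem sizes used by the test suite

The shipped tests run the detector recovery check on 50 seeded default
videos (8 min at 25 fps each), the delta-grid monotonicity check on 20
videos of 4 min, mode equivalence on 5, and the rendering round trip on 5
videos of 2 min; filter-response checks use 20-minute sinusoids so edge
transients are negligible in the measured band.  These sizes make the whole
suite run in well under a minute while keeping every statistical margin
comfortable (the pooled medium+strong recall at the acceptance operating
point, cutoff 0.1 Hz and delta 0.1, is ≈ 1.0 against a 0.9 bound; the only
structural miss mode is a medium reaction drawn within ≈ 3 % of the
threshold).

## Known limitations

* Detection is offline (zero-phase filtering is non-causal by construction).
* Intensity categorisation of detections is out of scope; intensities exist
  only on annotations and in the simulator.
* The evaluation pools counts across videos; other pooling conventions
  (macro-averaging) would give different dataset-level numbers.
* Width is a box extent: sub-pixel ellipse fits would be more precise but
  are not part of the method.
* With `containment_fraction = 1.0` a prediction ending one frame inside a
  ground truth does not count; real annotation jitter may warrant a slightly
  smaller fraction, which is exposed in `MatchConfig`.
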