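"""Score three prediction sets of increasing sloppiness against the same
four annotated pupil reactions, showing why GTCR is needed alongside
Recall and Precision.

Run: python examples/worked_evaluation_example.py
"""

from pupilkinetics import MatchConfig, evaluate, fig7_fixture

cfg = MatchConfig(apply_iou_filter=False)  # score the raw prediction sets

print(f"{'set':<7}{'recall':>8}{'precision':>11}{'GTCR':>7}{'H':>7}")
for variant in ("pred1", "pred2", "pred3"):
    preds, gt = fig7_fixture(variant)
    r = evaluate(preds, gt, cfg, fps=25.0)
    print(
        f"{variant:<7}{100 * r.recall:>7.0f}%{100 * r.precision:>10.0f}%"
        f"{100 * r.gtcr:>6.0f}%{100 * r.h:>6.1f}%"
    )

# pred1 (three exact matches, one miss) scores H = 90 %.  pred3 — one long
# prediction blanketing all four annotations — has perfect recall AND
# perfect precision, but GTCR = 25 % exposes that a single prediction is
# doing the work of four, dropping H to 50 %.
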