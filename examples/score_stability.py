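"""Score constructed stage courses: amounts, MVV and the stability score.

Builds three 20-minute per-second stage sequences — a purely relaxed-wake
course, a gradual decline, and a course that reaches sleep onset early —
and prints their stage amounts, mean vigilance value (MVV, 1-7 scale) and
arousal stability score (ASS, 1-14 scale; higher = more stable arousal).
"""

import vigistate as vg

courses = {
    "relaxed wake (0/A1 only)": vg.block_course([("A1", 600), ("0", 600)]),
    "gradual decline": vg.block_course([
        ("A1", 300), ("A2", 240), ("B1", 240), ("B23", 420)]),
    "early sleep onset": vg.block_course([
        ("A1", 120), ("B23", 59), ("C", 1), ("B23", 1020)]),
}

for name, course in courses.items():
    ass = vg.arousal_stability_score(course)
    mvv = vg.mean_vigilance_value(course)
    amounts = vg.stage_amounts(course).total
    print(f"\n{name}")
    print(f"  ASS = {ass.score:2d}  (decisive criterion: "
          f"{ass.decisive_criterion}, quartile: {ass.decisive_quartile})")
    print(f"  total MVV = {mvv.total:.2f}")
    top = amounts.sort_values(ascending=False).head(3)
    print("  dominant stages: "
          + ", ".join(f"{k} {v:.1f}%" for k, v in top.items()))

print("\nA high ASS means the course never left the wake stages; an early "
      "C second (spindle/K-complex) pushes the score toward 1.")
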