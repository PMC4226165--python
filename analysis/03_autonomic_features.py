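#!/usr/bin/env python
"""Extract HRV spectral features from the beat series (4 Hz resampled
tachogram, linear detrend, rectangular-window periodogram, LF 0.04-0.15 /
HF 0.15-0.40 Hz), merge them into the autonomic panels, and build the
task-minus-baseline change scores, plus the 3-way (condition x period x
block) repeated-measures ANOVA on the panels.

Reads results/cohort/{beats,panels}.csv; writes under results/analysis/.

Run:  python analysis/03_autonomic_features.py
"""

import argparse
from pathlib import Path

from entrobeat import hrv, io
from entrobeat.pipeline import (anova_autonomic, autonomic_summary,
                                _merged_change_scores)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    ap.add_argument("--rate", type=float, default=4.0)
    args = ap.parse_args()

    beats = io.read_beats(args.cohort / "beats.csv")
    panels = io.read_panels(args.cohort / "panels.csv")

    bands = hrv.hrv_table(beats, rate=args.rate)
    io.write_csv(bands, args.out / "hrv_bands.csv")
    by_cond = bands.groupby(["condition", "period"])[["hf_pct", "lf_hf"]].mean()
    print("HRV band summary (means):")
    print(by_cond.round(3).to_string())

    changes = _merged_change_scores(panels, beats, args.rate)
    io.write_csv(changes, args.out / "change_scores.csv")
    ne = changes[changes.variable == "norepinephrine"]
    for cond, grp in ne.groupby("condition"):
        print(f"  dNE {cond}: mean {grp['delta'].mean():+.2f} pg/ml "
              f"(sd {grp['delta'].std(ddof=1):.2f})")

    io.write_csv(autonomic_summary(panels), args.out / "autonomic_summary.csv")
    anova = anova_autonomic(panels)
    io.write_csv(anova, args.out / "anova_autonomic.csv")
    ne_cp = anova.query("variable == 'norepinephrine' and "
                        "effect == 'condition x period'")
    if len(ne_cp):
        row = ne_cp.iloc[0]
        print(f"  ANOVA norepinephrine condition x period: "
              f"F({row.df1:.0f},{row.df2:.0f}) = {row.F:.2f}, "
              f"p = {row.p_gg:.3f}")


if __name__ == "__main__":
    main()
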