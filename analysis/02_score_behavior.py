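#!/usr/bin/env python
"""Score the cohort's choice behavior: response bias, reward acquisition,
and the smoothed conditional-entropy index of exploration, per block,
plus the condition x block repeated-measures ANOVA.

Reads results/cohort/trial_log.csv; writes behavioral tables under
results/analysis/.

Run:  python analysis/02_score_behavior.py
"""

import argparse
from pathlib import Path

from entrobeat import behavior, io, stats
from entrobeat.pipeline import BEHAVIOR_VARS, behavioral_summary


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    ap.add_argument("--c", type=float, default=1.0, dest="smoothing_c",
                    help="entropy smoothing constant")
    args = ap.parse_args()

    log = io.read_trial_log(args.cohort / "trial_log.csv")
    indices = behavior.score_trial_log(log, c=args.smoothing_c)
    summary = behavioral_summary(indices)
    io.write_csv(indices, args.out / "behavioral_indices.csv")
    io.write_csv(summary, args.out / "behavioral_summary.csv")

    print("behavioral indices, mean (SE) over subjects:")
    for _, row in summary.iterrows():
        print(f"  {row['condition']:11s} {row['measure']:20s} "
              f"{row['mean']:.3f} ({row['se']:.3f})")

    rows = []
    for var in BEHAVIOR_VARS:
        res = stats.rm_anova(indices, dv=var, subject="subject_id",
                             within=["condition", "block"])
        for e in res.effects:
            rows.append({"variable": var, "effect": e.effect, "F": e.F,
                         "df1": e.df[0], "df2": e.df[1],
                         "epsilon": e.epsilon, "p_gg": e.p_gg,
                         "partial_eta_sq": e.partial_eta_squared})
        cond = res["condition"]
        print(f"  ANOVA {var}: condition F(1,{cond.df[1]}) = {cond.F:.2f}, "
              f"p = {cond.p_gg:.3f}, partial eta^2 = "
              f"{cond.partial_eta_squared:.2f}")
    import pandas as pd
    io.write_csv(pd.DataFrame(rows), args.out / "anova_behavior.csv")


if __name__ == "__main__":
    main()
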