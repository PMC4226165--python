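#!/usr/bin/env python
"""Link exploration to autonomic and brain measures: per-condition
correlation matrices over the behavioral indices and autonomic change
scores, stepwise regression of entropy on the autonomic change scores,
ROI-level covariate-correlation screens (p < .001, signed), and
seed-based connectivity from the right anterior insula ROI.

Reads results/cohort/ and results/analysis/; writes linkage tables under
results/analysis/.

Run:  python analysis/04_brain_autonomic_linkage.py
"""

import argparse
from pathlib import Path

import pandas as pd

from entrobeat import io
from entrobeat.pipeline import RunConfig, link_tables


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--analysis", type=Path, default=Path("results/analysis"))
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    indices = io.read_indices(args.analysis / "behavioral_indices.csv")
    changes = pd.read_csv(args.analysis / "change_scores.csv", comment="#")
    roi_tables = {}
    for cond in ("contingent", "random"):
        path = args.cohort / f"roi_{cond}.csv"
        if path.exists():
            roi_tables[cond] = io.read_roi(path)

    cfg = RunConfig(trial_log_path="-", out_dir=str(args.out))
    tables = link_tables(indices, changes, roi_tables, cfg)
    for name, df in tables.items():
        io.write_csv(df, args.out / f"{name}.csv")

    for cond in ("contingent", "random"):
        cm = tables[f"correlations_{cond}"].set_index("variable")
        r = float(cm.loc["entropy", "norepinephrine"])
        print(f"{cond}: r(entropy, dNE) = {r:+.2f}")
        reg = tables[f"regression_{cond}"]
        sel = ", ".join(f"{p} (beta={b:+.2f})" for p, b in
                        zip(reg["predictor"], reg["beta"])
                        if p != "(none selected)") or "none"
        print(f"  stepwise predictors of entropy: {sel}")
        key = f"roi_correlations_{cond}"
        if key in tables:
            flagged = tables[key].query("flagged")
            for _, row in flagged.iterrows():
                print(f"  ROI flag: {row.roi} vs {row.covariate} "
                      f"r = {row.r:+.2f} (p = {row.p:.2g})")
    if "seed_connectivity_contingent" in tables:
        conn = tables["seed_connectivity_contingent"].query("flagged")
        for _, row in conn.iterrows():
            print(f"  seed connectivity (R anterior insula): {row.roi} "
                  f"r = {row.r:+.2f}")


if __name__ == "__main__":
    main()
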