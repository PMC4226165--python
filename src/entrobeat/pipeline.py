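"""End-to-end orchestration: synthesize/load -> score -> HRV -> linkage.

``run_full`` produces the report bundle for one run: a behavioral summary
(per-condition means and standard errors of response bias, reward
acquisition, and entropy), an autonomic summary (baseline/task means per
block), per-condition correlation matrices over the three behavioral
indices and seven autonomic change scores, a stepwise regression of
entropy on the autonomic change scores, repeated-measures ANOVA tables,
flagged-ROI correlation tables, seed-based ROI connectivity, and a
machine-readable manifest.  Identical config + seed yields byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, behavior, hrv, io, stats
from .cohort import CONDITIONS, CohortConfig, sample_cohort

BEHAVIOR_VARS = ("response_bias", "reward_acquisition", "entropy")
LINK_LABELS = ("bias", "reward", "entropy", "mbp", "hr", "tpr",
               "lf_hf", "hf_pct", "epinephrine", "norepinephrine")
AUTONOMIC_VARS = ("mbp", "hr", "tpr", "lf_hf", "hf_pct",
                  "epinephrine", "norepinephrine")


@dataclass
class RunConfig:
    """Inputs are either file paths to the four CSV families or a
    :class:`~entrobeat.cohort.CohortConfig` for synthesis (not neither)."""

    cohort: CohortConfig | None = None
    trial_log_path: str | None = None
    panels_path: str | None = None
    beats_path: str | None = None
    roi_paths: dict = field(default_factory=dict)  # condition -> path
    conditions: tuple = CONDITIONS
    smoothing_c: float = 1.0
    hrv_rate: float = 4.0
    p_enter: float = 0.05
    p_remove: float = 0.10
    roi_alpha: float = 0.001
    seed_roi: str = "R anterior insula"
    out_dir: str = "results/run"
    seed: int = 0

    def __post_init__(self):
        if self.cohort is None and self.trial_log_path is None:
            raise ValueError("RunConfig needs either input paths or a CohortConfig")


def manifest_for(config: RunConfig) -> tuple[dict, str]:
    payload = {
        "package": "entrobeat", "version": __version__,
        "seed": config.seed, "smoothing_c": config.smoothing_c,
        "hrv_rate": config.hrv_rate, "p_enter": config.p_enter,
        "p_remove": config.p_remove, "roi_alpha": config.roi_alpha,
        "seed_roi": config.seed_roi, "conditions": list(config.conditions),
        "synthetic": config.cohort is not None,
    }
    if config.cohort is not None:
        payload["cohort"] = {
            "n_subjects": config.cohort.n_subjects,
            "entropy_mean": dict(config.cohort.entropy_mean),
            "entropy_sd": config.cohort.entropy_sd,
            "rho_entropy_ne": dict(config.cohort.rho_entropy_ne),
            "ne_delta_mean": dict(config.cohort.ne_delta_mean),
            "ne_delta_sd": config.cohort.ne_delta_sd,
            "master_seed": config.cohort.master_seed,
        }
    blob = json.dumps(payload, sort_keys=True).encode()
    return payload, hashlib.sha256(blob).hexdigest()[:16]


def behavioral_summary(indices: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean (SE) of the three behavioral indices, averaging
    blocks within subject first."""
    per_subject = (indices.groupby(["condition", "subject_id"], sort=True)
                   [list(BEHAVIOR_VARS)].mean().reset_index())
    rows = []
    for cond, grp in per_subject.groupby("condition", sort=True):
        for var in BEHAVIOR_VARS:
            vals = grp[var]
            rows.append({"condition": cond, "measure": var,
                         "mean": vals.mean(),
                         "se": vals.std(ddof=1) / np.sqrt(len(vals))})
    return pd.DataFrame(rows)


def autonomic_summary(panels: pd.DataFrame) -> pd.DataFrame:
    """Baseline/task mean (SE) per variable, block, and condition."""
    g = (panels.groupby(["variable", "condition", "block", "period"], sort=True)
         ["value"].agg(["mean", lambda v: v.std(ddof=1) / np.sqrt(len(v))]))
    g.columns = ["mean", "se"]
    return g.reset_index()


def _merged_change_scores(panels: pd.DataFrame,
                          beats: pd.DataFrame | None,
                          rate: float) -> pd.DataFrame:
    """Change scores with HRV variables recomputed from beat series.

    When a beat table is present, LF/HF and HF% come from the spectral
    pipeline (as they would in the study), replacing the panel entries;
    other panel variables pass through unchanged.
    """
    panels = panels.copy()
    if beats is not None and len(beats):
        bands = hrv.hrv_table(beats, rate=rate)
        long = bands.melt(id_vars=["subject_id", "condition", "block", "period"],
                          value_vars=["lf_hf", "hf_pct"],
                          var_name="variable", value_name="value")
        panels = panels[~panels["variable"].isin(["lf_hf", "hf_pct"])]
        panels = pd.concat([panels, long], ignore_index=True)
    return hrv.change_scores(panels)


def link_tables(indices: pd.DataFrame, changes: pd.DataFrame,
                roi_tables: dict, config: RunConfig) -> dict:
    """Correlation matrices, stepwise regression of entropy on autonomic
    change scores, ANOVA tables, flagged-ROI tables, seed connectivity."""
    out: dict = {}
    per_subject = (indices.groupby(["condition", "subject_id"], sort=True)
                   [list(BEHAVIOR_VARS)].mean().reset_index())
    wide_changes = changes.pivot_table(index=["subject_id", "condition"],
                                       columns="variable", values="delta"
                                       ).reset_index()
    merged = per_subject.merge(wide_changes, on=["subject_id", "condition"])
    rename = {"response_bias": "bias", "reward_acquisition": "reward"}
    merged = merged.rename(columns=rename)
    for cond in config.conditions:
        sub = merged[merged["condition"] == cond].set_index("subject_id")
        table = sub[list(LINK_LABELS)]
        cm = stats.pearson_matrix(table)
        out[f"correlations_{cond}"] = cm.to_frame("r").reset_index(
            names="variable")
        out[f"correlation_p_{cond}"] = cm.to_frame("p").reset_index(
            names="variable")
        reg = stats.stepwise_regression(
            sub["entropy"].to_numpy(), sub[list(AUTONOMIC_VARS)],
            p_enter=config.p_enter, p_remove=config.p_remove)
        out[f"regression_{cond}"] = pd.DataFrame([{
            "predictor": name, "beta": b, "p": p,
            "r_squared": reg.r_squared,
            "adjusted_r_squared": reg.adjusted_r_squared,
            "F": reg.f_statistic, "df1": reg.df[0], "df2": reg.df[1],
        } for name, b, p in zip(reg.predictors, reg.standardized_betas,
                                reg.p_values)] or
            [{"predictor": "(none selected)", "beta": np.nan, "p": np.nan,
              "r_squared": 0.0, "adjusted_r_squared": 0.0, "F": np.nan,
              "df1": 0, "df2": reg.df[1]}])
        if cond in roi_tables:
            roi = roi_tables[cond]
            flagged = []
            for cov_name, series in (("norepinephrine",
                                      sub["norepinephrine"]),
                                     ("entropy", sub["entropy"])):
                for rc in stats.roi_covariate_correlation(
                        roi, series, alpha=config.roi_alpha):
                    flagged.append({"condition": cond, "covariate": cov_name,
                                    "roi": rc.roi_label, "r": rc.r, "p": rc.p,
                                    "sign": rc.sign, "flagged": rc.flagged})
            out[f"roi_correlations_{cond}"] = pd.DataFrame(flagged)
            if config.seed_roi in roi.columns:
                conn = stats.seed_connectivity(roi, config.seed_roi,
                                               alpha=config.roi_alpha)
                out[f"seed_connectivity_{cond}"] = pd.DataFrame(
                    [{"seed": config.seed_roi, "roi": rc.roi_label,
                      "r": rc.r, "p": rc.p, "flagged": rc.flagged}
                     for rc in conn])
    # ANOVAs: 2-way on behavior, 3-way on autonomic panels
    anova_rows = []
    for var in BEHAVIOR_VARS:
        res = stats.rm_anova(indices, dv=var, subject="subject_id",
                             within=["condition", "block"])
        for e in res.effects:
            anova_rows.append({
                "variable": var, "effect": e.effect, "F": e.F,
                "df1": e.df[0], "df2": e.df[1], "epsilon": e.epsilon,
                "p_gg": e.p_gg, "partial_eta_sq": e.partial_eta_squared})
    out["anova_behavior"] = pd.DataFrame(anova_rows)
    return out


def anova_autonomic(panels: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for var, grp in panels.groupby("variable", sort=True):
        res = stats.rm_anova(grp, dv="value", subject="subject_id",
                             within=["condition", "period", "block"])
        for e in res.effects:
            rows.append({"variable": var, "effect": e.effect, "F": e.F,
                         "df1": e.df[0], "df2": e.df[1], "epsilon": e.epsilon,
                         "p_gg": e.p_gg,
                         "partial_eta_sq": e.partial_eta_squared})
    return pd.DataFrame(rows)


def run_full(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns the tables as a dict of DataFrames; files are written under
    ``config.out_dir`` with the manifest hash on every table.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload, mhash = manifest_for(config)

    if config.cohort is not None:
        dataset = sample_cohort(config.cohort)
        trial_log = dataset.trial_logs
        panels = dataset.panels
        beats = dataset.beat_series
        roi_tables = dataset.roi_tables
        io.write_csv(dataset.latent, out_dir / "latent_truth.csv", mhash)
    else:
        trial_log = io.read_trial_log(config.trial_log_path)
        panels = io.read_panels(config.panels_path)
        beats = (io.read_beats(config.beats_path)
                 if config.beats_path else None)
        roi_tables = {cond: io.read_roi(path)
                      for cond, path in config.roi_paths.items()}

    indices = behavior.score_trial_log(trial_log, c=config.smoothing_c)
    changes = _merged_change_scores(panels, beats, config.hrv_rate)
    tables = {
        "behavioral_indices": indices,
        "behavioral_summary": behavioral_summary(indices),
        "autonomic_summary": autonomic_summary(panels),
        "change_scores": changes,
        "anova_autonomic": anova_autonomic(panels),
    }
    tables.update(link_tables(indices, changes, roi_tables, config))

    log_counts = {}
    for name, df in tables.items():
        io.write_csv(df, out_dir / f"{name}.csv", mhash)
        log_counts[name] = len(df)
    payload["tables"] = log_counts
    payload["manifest_hash"] = mhash
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return tables
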