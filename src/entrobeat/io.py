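"""CSV schemas and validated readers/writers.

All files are UTF-8, comma-separated, dot-decimal, with a header row;
missing values are empty fields; indices are 0-based.  Readers raise
:class:`DataError` naming the file, row, and column on schema violations.
Report tables may carry a leading ``# manifest=<hash>`` comment line;
readers skip ``#`` comments.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

TRIAL_LOG_COLUMNS = ["subject_id", "condition", "block", "trial",
                     "choice", "outcome", "side_adv"]
BEATS_COLUMNS = ["subject_id", "condition", "block", "period", "beat_time_s"]
PANEL_COLUMNS = ["subject_id", "condition", "block", "period", "variable", "value"]
INDICES_COLUMNS = ["subject_id", "condition", "block", "response_bias",
                   "reward_acquisition", "entropy"]

_CATEGORICAL = {
    "choice": {"adv", "disadv", "none"},
    "outcome": {"gain", "loss"},
    "side_adv": {"L", "R"},
    "period": {"baseline", "task"},
}


class DataError(ValueError):
    pass


def _read(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except FileNotFoundError:
        raise DataError(f"{path}: file not found") from None
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    for col, allowed in _CATEGORICAL.items():
        if col not in df.columns:
            continue
        bad = ~df[col].isin(allowed)
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise DataError(
                f"{path}: row {row}, column {col!r}: invalid value "
                f"{df[col].iloc[row]!r} (allowed: {sorted(allowed)})")
    return df


def read_trial_log(path: str | Path) -> pd.DataFrame:
    df = _read(path, TRIAL_LOG_COLUMNS)
    if df["outcome"].where(df["choice"] != "none", "loss").ne(df["outcome"]).any():
        bad = df.index[(df["choice"] == "none") & (df["outcome"] != "loss")][0]
        raise DataError(f"{path}: row {bad}, column 'outcome': timeout trials "
                        "must be losses")
    return df


def read_beats(path: str | Path) -> pd.DataFrame:
    df = _read(path, BEATS_COLUMNS)
    if (df["beat_time_s"] < 0).any():
        row = int(df.index[df["beat_time_s"] < 0][0])
        raise DataError(f"{path}: row {row}, column 'beat_time_s': negative time")
    return df


def read_panels(path: str | Path) -> pd.DataFrame:
    return _read(path, PANEL_COLUMNS)


def read_indices(path: str | Path) -> pd.DataFrame:
    return _read(path, INDICES_COLUMNS)


def read_roi(path: str | Path) -> pd.DataFrame:
    """ROI table: wide CSV with subject_id index column, one column per ROI."""
    df = _read(path, ["subject_id"])
    if df["subject_id"].duplicated().any():
        raise DataError(f"{path}: duplicate subject_id rows")
    return df.set_index("subject_id")


def write_csv(df: pd.DataFrame, path: str | Path, manifest_hash: str | None = None,
              index: bool = False, sig_digits: int = 6) -> None:
    """Write a table, rounding floats only at serialization."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if manifest_hash:
            fh.write(f"# manifest={manifest_hash}\n")
        df.to_csv(fh, index=index, float_format=f"%.{sig_digits}g")
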