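"""Frequency-domain heart-rate-variability features and autonomic
change scores.

The tachogram (interbeat interval as a function of time) is resampled to
an equidistant 4 Hz grid, linearly detrended, and transformed with a
rectangular-window FFT periodogram.  Band powers are integrated over the
low-frequency band LF = [0.04, 0.15) Hz (mixed sympathetic/vagal) and the
high-frequency band HF = [0.15, 0.40) Hz (respiratory sinus arrhythmia,
vagal).  Percentages are taken of the LF+HF total, their natural logs are
reported for statistical use, and LF/HF (absolute powers) indexes
sympathovagal balance.

Change scores subtract each block's baseline panel from its task panel
and average the three per-block differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

PANEL_VARIABLES = ("mbp", "hr", "tpr", "lf_hf", "hf_pct",
                   "epinephrine", "norepinephrine")


class HrvError(ValueError):
    pass


@dataclass
class BeatSeries:
    """Beat occurrence times in seconds (strictly increasing).

    ``ibi`` is the interbeat-interval series in milliseconds, one value per
    interval, indexed by the time of the beat that closes it.
    """

    beat_times: np.ndarray

    def __post_init__(self):
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.beat_times.ndim != 1 or self.beat_times.size < 2:
            raise HrvError("need at least 2 beats")
        d = np.diff(self.beat_times)
        if (d <= 0).any():
            raise HrvError("beat times must be strictly increasing")
        ibi = d * 1000.0
        if (ibi < 300).any() or (ibi > 2000).any():
            warnings.warn("interbeat intervals outside 300-2000 ms",
                          stacklevel=2)
        self.ibi = ibi

    @property
    def duration(self) -> float:
        return float(self.beat_times[-1] - self.beat_times[0])

    def mean_hr(self) -> float:
        """Heart rate in bpm from the mean interbeat interval."""
        return 60000.0 / float(self.ibi.mean())


@dataclass
class Spectrum:
    frequencies: np.ndarray  # Hz
    psd: np.ndarray          # ms^2 / Hz

    def total_power(self) -> float:
        return float(np.trapezoid(self.psd, self.frequencies))


@dataclass
class BandPowers:
    lf_abs: float
    hf_abs: float
    total: float
    lf_pct: float
    hf_pct: float
    ln_lf_pct: float
    ln_hf_pct: float
    lf_hf_ratio: float


def resample_tachogram(beats: BeatSeries, rate: float = 4.0,
                       kind: str = "linear") -> tuple[np.ndarray, np.ndarray]:
    """Interpolate the tachogram onto a uniform grid.

    The IBI value is placed at the time of the beat closing each interval
    and interpolated (linearly by default, ``kind='cubic'`` optional) onto
    a ``rate``-Hz grid spanning the recording.  Returns ``(t, ibi_ms)``.
    """
    if beats.duration < 60:
        warnings.warn("recording shorter than 60 s; spectral estimates "
                      "will be coarse", stacklevel=2)
    t0, t1 = beats.beat_times[0], beats.beat_times[-1]
    grid = np.arange(t0, t1 + 0.5 / rate, 1.0 / rate)
    grid = grid[grid <= t1]
    knots = beats.beat_times[1:]
    if kind == "linear":
        vals = np.interp(grid, knots, beats.ibi)
    elif kind == "cubic":
        from scipy.interpolate import CubicSpline
        cs = CubicSpline(knots, beats.ibi)
        vals = cs(np.clip(grid, knots[0], knots[-1]))
    else:
        raise HrvError(f"unknown interpolation kind: {kind!r}")
    return grid, vals


def psd(series: np.ndarray, rate: float = 4.0) -> Spectrum:
    """Rectangular-window periodogram of a linearly detrended series.

    The full (unsegmented) record is used; the one-sided density scaling
    satisfies Parseval: the integral of the PSD over [0, Nyquist] equals
    the variance of the detrended series to within discretization error.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 64:
        raise HrvError("need at least 64 samples for a usable spectrum")
    freqs, pxx = signal.periodogram(series, fs=rate, window="boxcar",
                                    detrend="linear", scaling="density")
    return Spectrum(frequencies=freqs, psd=pxx)


def _band_integral(spec: Spectrum, lo: float, hi: float) -> float:
    """Trapezoidal integral of the PSD over the half-open band [lo, hi)."""
    mask = (spec.frequencies >= lo) & (spec.frequencies < hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(spec.psd[mask], spec.frequencies[mask]))


def band_powers(spec: Spectrum) -> BandPowers:
    """LF/HF band powers, percentages of the LF+HF total, logs, and ratio."""
    lf = _band_integral(spec, *LF_BAND)
    hf = _band_integral(spec, *HF_BAND)
    total = _band_integral(spec, LF_BAND[0], HF_BAND[1])
    if hf == 0:
        raise HrvError("LF/HF ratio undefined: zero HF power")
    if total == 0:
        raise HrvError("band percentages undefined: zero total power")
    lf_pct = 100.0 * lf / total
    hf_pct = 100.0 * hf / total
    return BandPowers(
        lf_abs=lf, hf_abs=hf, total=total,
        lf_pct=lf_pct, hf_pct=hf_pct,
        ln_lf_pct=float(np.log(lf_pct)) if lf_pct > 0 else -np.inf,
        ln_hf_pct=float(np.log(hf_pct)),
        lf_hf_ratio=lf / hf,
    )


def hrv_features(beats: BeatSeries, rate: float = 4.0) -> BandPowers:
    """Full pipeline: resample -> detrended periodogram -> band powers."""
    _, series = resample_tachogram(beats, rate=rate)
    return band_powers(psd(series, rate=rate))


def hrv_table(beats_df: pd.DataFrame, rate: float = 4.0) -> pd.DataFrame:
    """Band powers per (subject, condition, block, period) from a long
    beat-series table (columns subject_id, condition, block, period,
    beat_time_s)."""
    rows = []
    keys = ["subject_id", "condition", "block", "period"]
    for key, grp in beats_df.groupby(keys, sort=True):
        bp = hrv_features(BeatSeries(np.sort(grp["beat_time_s"].to_numpy())),
                          rate=rate)
        rec = dict(zip(keys, key))
        rec.update(lf_abs=bp.lf_abs, hf_abs=bp.hf_abs, total=bp.total,
                   lf_pct=bp.lf_pct, hf_pct=bp.hf_pct,
                   ln_lf_pct=bp.ln_lf_pct, ln_hf_pct=bp.ln_hf_pct,
                   lf_hf=bp.lf_hf_ratio)
        rows.append(rec)
    return pd.DataFrame(rows)


def change_scores(panels: pd.DataFrame) -> pd.DataFrame:
    """Task-minus-baseline deltas averaged over blocks, per variable.

    ``panels`` is long format with columns subject_id, condition, block,
    period ('baseline'/'task'), variable, value.  Every (subject,
    condition, block, variable) must have a matched baseline/task pair.
    Returns columns subject_id, condition, variable, delta.
    """
    required = {"subject_id", "condition", "block", "period", "variable", "value"}
    missing = required - set(panels.columns)
    if missing:
        raise HrvError(f"panel table missing columns: {sorted(missing)}")
    wide = panels.pivot_table(index=["subject_id", "condition", "block", "variable"],
                              columns="period", values="value", aggfunc="first")
    for col in ("baseline", "task"):
        if col not in wide.columns or wide[col].isna().any():
            bad = (wide.index[wide[col].isna()][0] if col in wide.columns
                   else wide.index[0])
            raise HrvError(
                f"missing {col} value for subject={bad[0]} condition={bad[1]} "
                f"block={bad[2]} variable={bad[3]}")
    wide = wide.reset_index()
    wide["delta"] = wide["task"] - wide["baseline"]
    out = (wide.groupby(["subject_id", "condition", "variable"], sort=True)["delta"]
           .mean().reset_index())
    return out


def synthesize_beats(duration: float, mean_ibi_ms: float = 920.0,
                     lf_power: float = 900.0, hf_power: float = 1100.0,
                     lf_freq: float = 0.095, hf_freq: float = 0.275,
                     noise_sd_ms: float = 3.0,
                     rng: np.random.Generator | None = None) -> BeatSeries:
    """Beat series whose tachogram carries known LF and HF power.

    The instantaneous IBI is the mean plus two sinusoids (amplitude
    A = sqrt(2 * power) so each tone contributes ``power`` ms^2 of
    variance) plus white noise; beats are laid down by integrating the
    instantaneous IBI.  Because the tachogram is effectively sampled at
    the beat rate and linearly interpolated (a triangular kernel with
    power transfer ~ sinc^4(f * T) at mean beat interval T), each tone is
    pre-emphasized by the inverse kernel gain so that the *analyzed*
    tachogram carries the stated band power.  Used for end-to-end
    recovery tests and by the synthetic-cohort generator.
    """
    if rng is None:
        rng = np.random.default_rng()

    def _kernel_gain(f: float) -> float:
        # amplitude transfer of linear interpolation at mean beat spacing
        return float(np.sinc(f * mean_ibi_ms / 1000.0) ** 2)

    a_lf = np.sqrt(2.0 * lf_power) / _kernel_gain(lf_freq)
    a_hf = np.sqrt(2.0 * hf_power) / _kernel_gain(hf_freq)
    ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
    times = [0.0]
    t = 0.0
    while t < duration:
        ibi = (mean_ibi_ms
               + a_lf * np.sin(2 * np.pi * lf_freq * t + ph1)
               + a_hf * np.sin(2 * np.pi * hf_freq * t + ph2)
               + rng.normal(0.0, noise_sd_ms))
        ibi = max(ibi, 300.0)
        t += ibi / 1000.0
        times.append(t)
    return BeatSeries(np.asarray(times))
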