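"""Per-beat regressors and their aggregation over a record.

Each accepted beat yields one feature vector; a record's representative
vector is the per-feature **median** across its accepted beats (robust to
residual artifacts that slip through the quality gate).  Features whose
defining amplitude is nonpositive (e.g. the log-amplitude of an absent
diastolic peak) are flagged missing (NaN) and excluded feature-wise from
the aggregate - never imputed.

Feature set
-----------
``ptt_ms``               R peak -> pulse foot (B1), ms
``t_<pt>_ms``            fiducial time relative to B1 for B0, SEP, DER3,
                         SEPMAX, SRP, DP, End, ms
``log_amp_<pt>``         natural log of the baseline-corrected amplitude
                         (level minus the level at B1) at SEP, SRP, DP
``aug_index_pct``        100 x amplitude(SRP) / amplitude(SEP), baseline
                         corrected (reflection-to-ejection ratio)
``perf_index_pct``       100 x pulsatile (AC) / static (DC) amplitude
``bp_0_2`` ``bp_2_5`` ``bp_5_10``  normalized spectral band powers, Hz bands
``spec_centroid_hz``     spectral centroid of the beat spectrum
``beat_ms``              beat duration, ms
``upstroke_ms``          systolic upstroke time B1 -> SEP, ms
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import RecordRejectedError
from .fiducials import BeatPair, FiducialSet

__all__ = [
    "FEATURE_NAMES",
    "compute_ptt",
    "compute_beat_features",
    "aggregate_record",
]

_REL_POINTS = ("b0", "sep", "der3", "sepmax", "srp", "dp", "end")
_LOG_POINTS = ("sep", "srp", "dp")

FEATURE_NAMES: tuple[str, ...] = (
    ("ptt_ms",)
    + tuple(f"t_{p}_ms" for p in _REL_POINTS)
    + tuple(f"log_amp_{p}" for p in _LOG_POINTS)
    + (
        "aug_index_pct",
        "perf_index_pct",
        "bp_0_2",
        "bp_2_5",
        "bp_5_10",
        "spec_centroid_hz",
        "beat_ms",
        "upstroke_ms",
    )
)


def compute_ptt(r_peak_time: float, b1_time: float) -> float:
    """Pulse transit time in ms: ECG R peak to the pulse-wave foot B1."""
    if b1_time <= r_peak_time:
        raise ValueError(
            f"pulse foot at {b1_time} s does not follow the R peak at "
            f"{r_peak_time} s"
        )
    return (b1_time - r_peak_time) * 1000.0


def _band_powers(y: np.ndarray, fs: float) -> tuple[float, float, float, float]:
    """Normalized 0-2 / 2-5 / 5-10 Hz band powers and the spectral centroid."""
    x = y - np.mean(y)
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    total = float(spec.sum())
    if total <= 0:
        return math.nan, math.nan, math.nan, math.nan
    bands = []
    for lo, hi in ((0.0, 2.0), (2.0, 5.0), (5.0, 10.0)):
        sel = (freqs >= lo) & (freqs < hi)
        bands.append(float(spec[sel].sum()) / total)
    centroid = float((freqs * spec).sum() / total)
    return bands[0], bands[1], bands[2], centroid


def compute_beat_features(
    fiducials: FiducialSet,
    beat: BeatPair,
    fs: float | None = None,
) -> pd.Series:
    """Feature vector of one accepted beat (missing features are NaN)."""
    fs = fs or beat.fs
    t = fiducials.times
    a = fiducials.amplitudes
    out: dict[str, float] = {}
    out["ptt_ms"] = compute_ptt(beat.r_time, t["b1"])

    for p in _REL_POINTS:
        out[f"t_{p}_ms"] = (
            (t[p] - t["b1"]) * 1000.0 if np.isfinite(t[p]) else math.nan
        )

    base = a["b1"]
    for p in _LOG_POINTS:
        amp = a[p] - base if np.isfinite(a[p]) else math.nan
        out[f"log_amp_{p}"] = math.log(amp) if amp > 0 else math.nan

    amp_sep = a["sep"] - base
    amp_srp = a["srp"] - base
    out["aug_index_pct"] = (
        100.0 * amp_srp / amp_sep if amp_sep > 0 and np.isfinite(amp_srp)
        else math.nan
    )

    y = np.asarray(beat.ppg, dtype=float)
    ac = float(y.max() - y.min())
    dc = float(y.mean())
    out["perf_index_pct"] = 100.0 * ac / dc if dc > 0 else math.nan

    b0_2, b2_5, b5_10, centroid = _band_powers(y, fs)
    out["bp_0_2"], out["bp_2_5"], out["bp_5_10"] = b0_2, b2_5, b5_10
    out["spec_centroid_hz"] = centroid

    out["beat_ms"] = beat.duration * 1000.0
    out["upstroke_ms"] = (t["sep"] - t["b1"]) * 1000.0
    return pd.Series(out, index=list(FEATURE_NAMES), dtype=float)


def aggregate_record(
    per_beat: list[pd.Series] | pd.DataFrame,
    min_beats: int = 10,
) -> pd.Series:
    """Median feature vector across accepted beats of one record.

    Missing-feature beats are excluded per feature.  The count of
    contributing beats is attached as ``n_beats`` (overall) and the
    minimum per-feature count as ``n_beats_min_feature``.
    """
    df = per_beat if isinstance(per_beat, pd.DataFrame) else pd.DataFrame(per_beat)
    if len(df) < min_beats:
        raise RecordRejectedError(
            f"only {len(df)} accepted beats; at least {min_beats} required"
        )
    agg = df.median(axis=0, skipna=True)
    counts = df.notna().sum(axis=0)
    agg["n_beats"] = float(len(df))
    agg["n_beats_min_feature"] = float(counts.min())
    return agg
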