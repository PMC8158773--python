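"""Cardiocycle segmentation, quality gating and pulse-wave fiducial points.

Eight landmarks are located on each accepted pulse wave (times in
seconds, amplitudes in PPG units):

==========  ==============================================================
``b1``      beginning of the wave (foot, by intersecting tangents)
``b0``      point of maximum upstroke slope on the anterior front
``sep``     peak of the systolic ejection wave
``der3``    first positive peak of the third derivative after B1
``sepmax``  first inflection of the pulse wave after SEP
``srp``     peak of the reflected systolic wave (local maximum, shoulder,
            or backward component of the two-wave decomposition)
``dp``      peak of the diastolic wave; may be genuinely absent
``end``     end of the wave (here: the segment boundary at the next R peak)
==========  ==============================================================

Derivatives are taken on a zero-phase low-pass-filtered copy of the beat
(Butterworth, default cutoff 15 Hz) because second and third derivatives
amplify noise quadratically and cubically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, signal

from .errors import (
    FiducialFailureError,
    InsufficientDataError,
    NoSignalError,
    RecordRejectedError,
)
from .io import Recording

__all__ = [
    "BeatPair",
    "FiducialSet",
    "WaveDecomposition",
    "detect_r_peaks",
    "segment_beats",
    "quality_gate",
    "detect_fiducials",
    "decompose_waves",
]

FIDUCIAL_ORDER = ("b1", "b0", "sep", "der3", "sepmax", "srp", "dp", "end")


@dataclass
class BeatPair:
    """One cardiocycle: the R-peak time and its PPG segment."""

    r_time: float
    start_time: float
    ppg: np.ndarray
    fs: float
    quality: float = math.nan
    accepted: bool = True
    index: int = 0

    @property
    def duration(self) -> float:
        return self.ppg.size / self.fs

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


@dataclass
class FiducialSet:
    """Times (s, absolute) and amplitudes of the eight labelled points."""

    times: dict[str, float]
    amplitudes: dict[str, float]
    dp_present: bool = True

    def ordered_times(self) -> list[float]:
        return [self.times[k] for k in FIDUCIAL_ORDER]

    def check_order(self) -> bool:
        t = self.times
        ok = t["b1"] < t["b0"] < t["sep"] < t["end"]
        ok &= t["srp"] >= t["sep"]
        ok &= t["b1"] < t["der3"] < t["end"]
        ok &= t["b1"] < t["sepmax"] < t["end"]
        if self.dp_present and np.isfinite(t["dp"]):
            ok &= t["dp"] > t["srp"]
        return bool(ok)


@dataclass
class WaveDecomposition:
    """Two-component (forward + reflected) Gaussian fit of the pulse wave."""

    forward: tuple[float, float, float]   # amplitude, center (s abs), width (s)
    backward: tuple[float, float, float]
    baseline: float
    residual_norm: float                  # ||resid|| / ||signal - baseline||
    reliable: bool


# ---------------------------------------------------------------------------
# R peaks
# ---------------------------------------------------------------------------

def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 2
              ) -> np.ndarray:
    nyq = fs / 2.0
    hi = min(hi, 0.95 * nyq)
    sos = signal.butter(order, [lo / nyq, hi / nyq], btype="band", output="sos")
    return signal.sosfiltfilt(sos, x)


def detect_r_peaks(
    recording: Recording,
    refractory_s: float = 0.3,
    band: tuple[float, float] = (5.0, 30.0),
) -> np.ndarray:
    """R-peak times (s), one per cardiac cycle, strictly increasing.

    Energy-based detector: band-pass, square, smooth, adaptive threshold,
    then refine each candidate to the local ECG maximum.
    """
    ecg = np.asarray(recording.ecg, dtype=float)
    fs = recording.fs
    if fs < 100:
        raise ValueError("sampling rate must be at least 100 Hz")
    if ecg.size < int(fs) or np.all(np.isnan(ecg)) or np.nanstd(ecg) == 0:
        raise NoSignalError("ECG channel is flat, empty or all-NaN")
    filt = _bandpass(ecg, fs, *band)
    energy = filt**2
    win = max(1, int(0.10 * fs))
    energy = np.convolve(energy, np.ones(win) / win, mode="same")
    dist = max(1, int(refractory_s * fs))
    cand, _ = signal.find_peaks(energy, distance=dist)
    if cand.size == 0:
        raise NoSignalError("no QRS-like energy peaks found")
    # adaptive threshold from the upper candidate population
    top = np.sort(energy[cand])[-max(3, cand.size // 3):]
    thr = 0.25 * float(np.median(top))
    keep = cand[energy[cand] >= thr]
    if keep.size == 0:
        raise NoSignalError("ECG energy below detection threshold everywhere")
    # refine to the raw-signal maximum in a +-50 ms window
    half = int(0.05 * fs)
    peaks = []
    for c in keep:
        lo_i = max(0, c - half)
        hi_i = min(ecg.size, c + half + 1)
        peaks.append(lo_i + int(np.argmax(filt[lo_i:hi_i])))
    peaks = np.unique(np.asarray(peaks, dtype=int))
    # enforce the refractory period after refinement
    final = [peaks[0]]
    for p in peaks[1:]:
        if p - final[-1] >= dist:
            final.append(p)
        elif filt[p] > filt[final[-1]]:
            final[-1] = p
    return np.asarray(final, dtype=float) / fs


# ---------------------------------------------------------------------------
# segmentation and quality
# ---------------------------------------------------------------------------

def segment_beats(recording: Recording, r_peaks: Sequence[float]) -> list[BeatPair]:
    """Split the PPG into per-beat segments spanning R-peak to R-peak.

    Boundary (partial) beats before the first and after the last R peak
    are dropped; the returned segments tile [first R, last R) exactly.
    """
    r = np.asarray(r_peaks, dtype=float)
    if r.size < 2:
        raise InsufficientDataError("need at least 2 R peaks to segment beats")
    fs = recording.fs
    beats = []
    for k in range(r.size - 1):
        i0 = int(round(r[k] * fs))
        i1 = int(round(r[k + 1] * fs))
        if i1 <= i0 or i1 > recording.n_samples:
            continue
        beats.append(
            BeatPair(
                r_time=float(r[k]),
                start_time=i0 / fs,
                ppg=recording.ppg[i0:i1].copy(),
                fs=fs,
                index=k,
            )
        )
    if len(beats) < 1:
        raise InsufficientDataError("no complete beats inside the record")
    return beats


_TEMPLATE_LEN = 200


def _resample_beat(ppg: np.ndarray, n: int = _TEMPLATE_LEN) -> np.ndarray:
    x = np.linspace(0.0, 1.0, ppg.size)
    return np.interp(np.linspace(0.0, 1.0, n), x, ppg)


def quality_gate(beats: list[BeatPair], threshold: float = 0.9) -> list[BeatPair]:
    """Score each beat against the record's median template and flag it.

    The quality score is the Pearson correlation between the beat
    (resampled to a fixed length) and the element-wise median of all
    resampled beats; a beat is accepted iff score >= threshold.  Raising
    the threshold can only shrink the accepted set (monotonicity).
    """
    if len(beats) < 3:
        raise InsufficientDataError("need at least 3 beats for the quality gate")
    mat = np.vstack([_resample_beat(b.ppg) for b in beats])
    template = np.median(mat, axis=0)
    t_sd = template.std()
    for b, row in zip(beats, mat):
        r_sd = row.std()
        if t_sd == 0 and r_sd == 0:
            score = 1.0
        elif t_sd == 0 or r_sd == 0:
            score = 0.0
        else:
            score = float(np.corrcoef(row, template)[0, 1])
        b.quality = score
        b.accepted = score >= threshold
    if not any(b.accepted for b in beats):
        raise RecordRejectedError(
            "all beats rejected by the quality gate (poor-quality record)"
        )
    return beats


# ---------------------------------------------------------------------------
# fiducial detection
# ---------------------------------------------------------------------------

def _lowpass(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    nyq = fs / 2.0
    if cutoff >= 0.95 * nyq:
        return x.astype(float)
    sos = signal.butter(4, cutoff / nyq, btype="low", output="sos")
    padlen = min(x.size - 1, 3 * 20)
    return signal.sosfiltfilt(sos, x, padlen=padlen)


def detect_fiducials(
    beat: BeatPair,
    fs: float | None = None,
    smooth_cutoff_hz: float = 15.0,
) -> FiducialSet:
    """Locate the eight pulse-wave landmarks on one accepted beat."""
    fs = fs or beat.fs
    y = np.asarray(beat.ppg, dtype=float)
    if y.size < 16:
        raise FiducialFailureError("beat segment too short for smoothing")
    if float(np.ptp(y)) <= 1e-9 * (abs(float(np.mean(y))) + 1.0):
        raise FiducialFailureError("no detectable upstroke (flat PPG segment)")
    ys = _lowpass(y, fs, smooth_cutoff_hz)
    t = beat.start_time + np.arange(y.size) / fs
    d1 = np.gradient(ys) * fs
    d2 = np.gradient(d1) * fs
    d3 = np.gradient(d2) * fs
    amp_range = float(ys.max() - ys.min())
    if amp_range <= 0 or not np.isfinite(amp_range):
        raise FiducialFailureError("no detectable upstroke (flat PPG segment)")

    # systolic peak: first prominent maximum in the front 70% of the beat
    lim = max(3, int(0.7 * y.size))
    pk, props = signal.find_peaks(ys[:lim], prominence=0.25 * amp_range)
    if pk.size == 0:
        pk = np.array([int(np.argmax(ys[:lim]))])
    i_sep = int(pk[0])
    if i_sep < 2:
        raise FiducialFailureError("no rising edge before the systolic peak")

    # maximum upstroke on the rising edge
    i_b0 = int(np.argmax(d1[: i_sep + 1]))
    slope = d1[i_b0]
    if slope <= 0:
        raise FiducialFailureError("no detectable upstroke")

    # intersecting tangents: tangent at B0 meets the pre-upstroke minimum level
    y_min = float(np.min(ys[: i_b0 + 1]))
    t_b1 = t[i_b0] - (ys[i_b0] - y_min) / slope
    t_b1 = max(t[0], min(t_b1, t[i_b0]))

    i_b1 = int(np.clip(round((t_b1 - t[0]) * fs), 0, y.size - 1))

    # first positive third-derivative peak after B1
    p3, _ = signal.find_peaks(d3[i_b1:])
    p3 = p3[d3[i_b1:][p3] > 0]
    i_der3 = i_b1 + int(p3[0]) if p3.size else min(i_b1 + 1, y.size - 1)

    # first inflection after SEP: upward zero-crossing of the 2nd derivative
    zc = np.nonzero((d2[i_sep:-1] < 0) & (d2[i_sep + 1:] >= 0))[0]
    i_sepmax = i_sep + int(zc[0]) + 1 if zc.size else min(i_sep + 1, y.size - 1)

    # reflected systolic wave: next local maximum after SEP ...
    pk_all, _ = signal.find_peaks(ys)
    later = pk_all[pk_all > i_sep]
    srp_from_peak = int(later[0]) if later.size else None
    i_srp = srp_from_peak
    if i_srp is None:
        # ... or a shoulder: local maximum of the 1st derivative on the
        # descending limb (deceleration pause left by the reflected wave)
        dpk, _ = signal.find_peaks(d1[i_sepmax:])
        if dpk.size:
            i_srp = i_sepmax + int(dpk[0])
    if i_srp is None:
        # last resort: backward component of the two-wave decomposition
        dec = decompose_waves(beat, fs=fs)
        if dec.reliable:
            i_srp = int(np.clip(round((dec.backward[1] - t[0]) * fs), 0,
                                y.size - 1))
        else:
            i_srp = i_sepmax
    i_srp = max(i_srp, i_sep)

    # diastolic wave: first local maximum after the dicrotic notch
    dp_present = False
    i_dp = None
    notch_cands, _ = signal.find_peaks(-ys[i_srp:])
    if notch_cands.size:
        i_notch = i_srp + int(notch_cands[0])
        dpks, _ = signal.find_peaks(ys[i_notch:])
        if dpks.size:
            i_dp = i_notch + int(dpks[0])
            dp_present = True
    if later is not None and later.size > 1 and not dp_present:
        i_dp, dp_present = int(later[1]), True

    times = {
        "b1": float(t_b1),
        "b0": float(t[i_b0]),
        "sep": float(t[i_sep]),
        "der3": float(t[i_der3]),
        "sepmax": float(t[i_sepmax]),
        "srp": float(t[i_srp]),
        "dp": float(t[i_dp]) if dp_present else math.nan,
        "end": float(t[0] + y.size / fs),
    }
    amps = {
        "b1": float(np.interp(t_b1, t, ys)),
        "b0": float(ys[i_b0]),
        "sep": float(ys[i_sep]),
        "der3": float(ys[i_der3]),
        "sepmax": float(ys[i_sepmax]),
        "srp": float(ys[i_srp]),
        "dp": float(ys[i_dp]) if dp_present else math.nan,
        "end": float(ys[-1]),
    }
    fid = FiducialSet(times=times, amplitudes=amps, dp_present=dp_present)
    if not (times["b1"] < times["b0"] < times["sep"] < times["end"]):
        raise FiducialFailureError("fiducial ordering violated; beat rejected")
    return fid


# ---------------------------------------------------------------------------
# forward / backward decomposition
# ---------------------------------------------------------------------------

def _two_gauss(t, a1, m1, s1, a2, m2, s2, base):
    return (base
            + a1 * np.exp(-((t - m1) ** 2) / (2 * s1**2))
            + a2 * np.exp(-((t - m2) ** 2) / (2 * s2**2)))


def decompose_waves(
    beat: BeatPair,
    fs: float | None = None,
    residual_threshold: float = 0.10,
) -> WaveDecomposition:
    """Fit forward + reflected Gaussian components to one pulse wave.

    A diverged or poor fit is reported via ``reliable=False`` rather than
    raised.  The forward component is, by relabelling, the one peaking
    first; its amplitude is expected to dominate.
    """
    fs = fs or beat.fs
    y_full = np.asarray(beat.ppg, dtype=float)
    t_full = beat.start_time + np.arange(y_full.size) / fs
    # restrict the fit to the systolic window: from the pre-upstroke
    # minimum to the dicrotic notch preceding a diastolic peak, so a
    # third (diastolic) component does not bias the two-component fit
    ys = _lowpass(y_full, fs, 15.0) if y_full.size > 60 else y_full
    rng_amp = float(ys.max() - ys.min())
    i_max = int(np.argmax(ys))
    i_start = int(np.argmin(ys[: i_max + 1])) if i_max > 0 else 0
    maxima, _ = signal.find_peaks(ys, prominence=0.05 * rng_amp if rng_amp > 0
                                  else None)
    i_end = y_full.size
    if maxima.size >= 3:
        # notch = minimum between the second and third prominent peaks
        seg = ys[maxima[1]: maxima[2] + 1]
        i_end = int(maxima[1] + np.argmin(seg)) + 1
    y = y_full[i_start:i_end]
    t = t_full[i_start:i_end]
    base0 = float(np.min(y))
    amp0 = float(np.max(y) - base0)
    if amp0 <= 0:
        return WaveDecomposition((0, 0, 1), (0, 0, 1), base0, np.inf, False)
    dur = y.size / fs
    i_pk = int(np.argmax(y))
    m1_0 = t[i_pk]
    m2_0 = min(m1_0 + 0.3 * dur, t[-1])
    p0 = [amp0, m1_0, 0.05 * dur + 0.02, 0.4 * amp0, m2_0, 0.08 * dur + 0.02,
          base0]
    lb = [1e-9, t[0], 1e-3, 0.0, t[0], 1e-3, base0 - amp0]
    ub = [3 * amp0, t[-1], dur, 3 * amp0, t[-1], dur, base0 + amp0]
    try:
        res = optimize.least_squares(
            lambda p: _two_gauss(t, *p) - y, p0, bounds=(lb, ub),
            method="trf", max_nfev=2000,
        )
        a1, m1, s1, a2, m2, s2, base = res.x
    except Exception:
        return WaveDecomposition((0, 0, 1), (0, 0, 1), base0, np.inf, False)
    comps = sorted([(a1, m1, s1), (a2, m2, s2)], key=lambda c: c[1])
    denom = float(np.linalg.norm(y - base))
    rnorm = float(np.linalg.norm(_two_gauss(t, a1, m1, s1, a2, m2, s2, base) - y))
    rel = rnorm / denom if denom > 0 else np.inf
    return WaveDecomposition(
        forward=tuple(map(float, comps[0])),
        backward=tuple(map(float, comps[1])),
        baseline=float(base),
        residual_norm=rel,
        reliable=bool(res.success) and rel <= residual_threshold,
    )
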