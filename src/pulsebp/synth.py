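"""Synthetic cohorts of synchronized ECG + PPG recordings with known truth.

The study population this emulates is an adult hypertension-clinic cohort:
systolic pressure distributed around 125 mmHg (SD 18.8, range 90-175) and
diastolic around 76 mmHg (SD 12.4, range 54-105), measured by three cuff
readings whose mean serves as the reference.  Each subject contributes a
~3 min two-channel recording at 1000 Hz.

Signal model
------------
* ECG: a flat baseline with one narrow Gaussian R deflection per beat.
  Only R-peak timing feeds the downstream algorithm, so P/T waves are
  deliberately absent.
* PPG: per beat, a DC baseline plus three positive Gaussian components -
  the systolic ejection wave (peak SEP), the reflected systolic wave
  (peak SRP) and the diastolic wave (peak DP).  The component centers are
  shifted numerically so that the intersecting-tangent foot of the
  composite wave (fiducial B1) falls exactly at R-peak time + PTT.
* Physiology coupling: pulse transit time is an affine, decreasing
  function of true SBP; the reflected-to-ejection amplitude ratio is an
  affine, increasing function of true DBP.  Both maps are invertible so a
  noise-free cohort can be decoded exactly.

All randomness flows from a single seed through a documented splitting
rule: ``SeedSequence(seed)`` is spawned once per subject, in subject
order; each subject's stream drives, in order, BP rejection sampling has
already happened at cohort level, then heart rate, morphology jitter,
beat timing, PTT jitter, channel noise, and the three cuff readings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

from .io import Recording

__all__ = [
    "MorphologyParams",
    "CohortParams",
    "GroundTruth",
    "CohortResult",
    "default_morphology",
    "true_fiducials",
    "synthesize_beat",
    "synthesize_recording",
    "generate_cohort",
    "simulate_cuff_readings",
]

_DENSE_FS = 20_000.0  # grid for extracting exact fiducials from the model

_FIDUCIAL_NAMES = ("b1", "b0", "sep", "der3", "sepmax", "srp", "dp", "end")


@dataclass(frozen=True)
class MorphologyParams:
    """Parameters of one subject's pulse-wave shape.

    Component centers are expressed relative to the (uncalibrated) pulse
    onset; amplitudes in arbitrary PPG units; times in seconds.
    """

    a_sep: float = 1.0
    a_srp: float = 0.55
    a_dp: float = 0.25
    c_sep: float = 0.14
    c_srp: float = 0.30
    c_dp: float = 0.55
    w_sep: float = 0.045
    w_srp: float = 0.070
    w_dp: float = 0.060
    baseline: float = 20.0
    ptt: float = 0.25          # pulse onset delay after the R peak, s
    period: float = 1.0        # beat period, s
    ecg_r_width: float = 0.008
    ecg_r_amp: float = 1.0

    def __post_init__(self) -> None:
        if self.a_sep <= 0 or self.a_srp < 0 or self.a_dp < 0:
            raise ValueError("ejection amplitude must be > 0, others >= 0")
        if self.a_srp >= self.a_sep:
            raise ValueError("reflected amplitude must be below ejection amplitude")
        centers = [self.c_sep]
        if self.a_srp > 0:
            centers.append(self.c_srp)
        if self.a_dp > 0:
            centers.append(self.c_dp)
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("component centers must be strictly increasing")
        if max(centers) >= self.period:
            raise ValueError("component centers exceed the beat period")
        if not 0 < self.ptt < self.period:
            raise ValueError("PTT must lie strictly inside the beat period")
        if min(self.w_sep, self.w_srp, self.w_dp) <= 0:
            raise ValueError("component widths must be positive")

    # -- continuous model -------------------------------------------------
    def pulse(self, t: np.ndarray) -> np.ndarray:
        """Composite pulse wave (above baseline) at times relative to onset."""
        t = np.asarray(t, dtype=float)
        y = self.a_sep * np.exp(-((t - self.c_sep) ** 2) / (2 * self.w_sep**2))
        if self.a_srp > 0:
            y = y + self.a_srp * np.exp(-((t - self.c_srp) ** 2) / (2 * self.w_srp**2))
        if self.a_dp > 0:
            y = y + self.a_dp * np.exp(-((t - self.c_dp) ** 2) / (2 * self.w_dp**2))
        return y


def default_morphology(**overrides) -> MorphologyParams:
    """The reference pulse morphology used across the test suite."""
    return MorphologyParams(**overrides)


# ---------------------------------------------------------------------------
# exact fiducials of the continuous model
# ---------------------------------------------------------------------------

def _foot_shift(morph: MorphologyParams) -> float:
    """Time of the intersecting-tangent foot of the raw composite wave.

    The foot is where the tangent at the maximum-upstroke point crosses
    the pre-upstroke minimum level; the generator shifts the whole pulse
    by this amount so the foot sits exactly at onset time 0.
    """
    t = np.arange(-0.2, morph.c_sep + 4 * morph.w_sep, 1.0 / _DENSE_FS)
    y = morph.pulse(t)
    d1 = np.gradient(y, t)
    i_peak = int(np.argmax(y))
    i_b0 = int(np.argmax(d1[: i_peak + 1]))
    y_min = float(np.min(y[: i_b0 + 1]))
    slope = d1[i_b0]
    return float(t[i_b0] - (y[i_b0] - y_min) / slope)


def calibrate_foot(morph: MorphologyParams) -> MorphologyParams:
    """Shift component centers so the tangent foot is exactly at onset 0."""
    shift = _foot_shift(morph)
    return replace(
        morph,
        c_sep=morph.c_sep - shift,
        c_srp=morph.c_srp - shift,
        c_dp=morph.c_dp - shift,
    )


def true_fiducials(morph: MorphologyParams) -> dict[str, float]:
    """Exact fiducial times of the calibrated continuous pulse, rel. to onset.

    Times are extracted on a 20 kHz grid from the noise-free analytic
    model using the mathematical definitions of the eight landmarks:
    B1 the tangent foot (0 by calibration), B0 the maximum-upstroke
    point, SEP the first prominent maximum, DER3 the first positive peak
    of the third derivative after B1, SEPMAX the first inflection after
    SEP, SRP the next local maximum (reflected wave), DP the diastolic
    maximum after the dicrotic notch, End the onset of the next beat.
    SRP/DP are NaN when the morphology has no such component.
    """
    m = calibrate_foot(morph)
    t = np.arange(-0.05, m.period, 1.0 / _DENSE_FS)
    y = m.pulse(t)
    d1 = np.gradient(y, t)
    d2 = np.gradient(d1, t)
    d3 = np.gradient(d2, t)

    peaks, _ = signal.find_peaks(y, height=0.5 * float(np.max(y)))
    i_sep = int(peaks[0])
    i_b0 = int(np.argmax(d1[: i_sep + 1]))

    out: dict[str, float] = {
        "b1": 0.0,
        "b0": float(t[i_b0]),
        "sep": float(t[i_sep]),
        "end": float(m.period),
    }
    # first positive third-derivative peak after the foot
    i0 = int(np.searchsorted(t, 0.0))
    p3, _ = signal.find_peaks(d3[i0:])
    p3 = p3[d3[i0:][p3] > 0]
    out["der3"] = float(t[i0 + p3[0]]) if p3.size else math.nan
    # first inflection (second-derivative upward zero-crossing) after SEP
    after = np.nonzero((d2[i_sep:-1] < 0) & (d2[i_sep + 1:] >= 0))[0]
    out["sepmax"] = float(t[i_sep + after[0] + 1]) if after.size else math.nan
    # reflected and diastolic maxima
    all_peaks, _ = signal.find_peaks(y)
    later = all_peaks[all_peaks > i_sep]
    out["srp"] = float(t[later[0]]) if later.size else math.nan
    out["dp"] = float(t[later[1]]) if later.size > 1 else math.nan
    return out


def true_amplitudes(morph: MorphologyParams, fid: dict[str, float]) -> dict[str, float]:
    """Absolute signal level (baseline included) at each true fiducial."""
    m = calibrate_foot(morph)
    return {
        k: (m.baseline + float(m.pulse(np.array([v]))[0]) if np.isfinite(v)
            else math.nan)
        for k, v in fid.items()
    }


# ---------------------------------------------------------------------------
# single-beat and whole-record synthesis
# ---------------------------------------------------------------------------

def synthesize_beat(
    morph: MorphologyParams,
    fs: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = 0,
) -> tuple[np.ndarray, np.ndarray, dict[str, float]]:
    """One cardiocycle sampled at ``fs``: (ecg, ppg, ground-truth entry).

    The segment spans [0, period) with the R peak at t = 0; the PPG foot
    therefore falls at t = PTT.  Ground-truth times in the returned dict
    are absolute within the segment (seconds); ``ptt_ms`` is in ms.
    """
    if fs < 100:
        raise ValueError("sampling rate must be at least 100 Hz")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(morph.period * fs))
    t = np.arange(n) / fs
    ecg = morph.ecg_r_amp * np.exp(-(t**2) / (2 * morph.ecg_r_width**2))
    m = calibrate_foot(morph)
    ppg = morph.baseline + m.pulse(t - morph.ptt)
    if noise_sd > 0:
        ppg = ppg + rng.normal(0.0, noise_sd, size=n)
        ecg = ecg + rng.normal(0.0, noise_sd, size=n)
    fid = true_fiducials(morph)
    truth = {"r_time": 0.0, "ptt_ms": morph.ptt * 1000.0}
    for k, v in fid.items():
        truth[k] = morph.ptt + v if np.isfinite(v) else math.nan
    return ecg, ppg, truth


def synthesize_recording(
    morph: MorphologyParams,
    duration_s: float = 180.0,
    fs: float = 1000.0,
    *,
    subject_id: str = "S000",
    ecg_noise_sd: float = 0.0,
    ppg_noise_sd: float = 0.0,
    period_jitter_sd: float = 0.0,
    ptt_jitter_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[Recording, pd.DataFrame]:
    """A full two-channel record plus its per-beat ground-truth table."""
    if fs < 100:
        raise ValueError("sampling rate must be at least 100 Hz")
    rng = rng if rng is not None else np.random.default_rng(0)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    ecg = np.zeros(n)
    ppg = np.full(n, morph.baseline, dtype=float)
    m = calibrate_foot(morph)
    fid_rel = true_fiducials(morph)

    r_times: list[float] = []
    rows: list[dict[str, float]] = []
    r = 0.2
    beat = 0
    while r + morph.period < duration_s - 0.2:
        ptt = morph.ptt
        if ptt_jitter_sd > 0:
            ptt = max(0.05, ptt + rng.normal(0.0, ptt_jitter_sd))
        onset = r + ptt
        # R deflection
        lo = max(0, int((r - 0.05) * fs))
        hi = min(n, int((r + 0.05) * fs))
        ecg[lo:hi] += morph.ecg_r_amp * np.exp(
            -((t[lo:hi] - r) ** 2) / (2 * morph.ecg_r_width**2)
        )
        # pulse wave (component tails may spill into neighbouring beats)
        lo = max(0, int((onset - 0.3) * fs))
        hi = min(n, int((onset + morph.period + 0.5) * fs))
        ppg[lo:hi] += m.pulse(t[lo:hi] - onset)
        row = {"beat": beat, "r_time": r, "ptt_ms": ptt * 1000.0}
        for k, v in fid_rel.items():
            row[k] = onset + v if np.isfinite(v) else math.nan
        rows.append(row)
        r_times.append(r)
        period = morph.period
        if period_jitter_sd > 0:
            period = max(0.3, period + rng.normal(0.0, period_jitter_sd))
        r += period
        beat += 1
    if ecg_noise_sd > 0:
        ecg += rng.normal(0.0, ecg_noise_sd, size=n)
    if ppg_noise_sd > 0:
        ppg += rng.normal(0.0, ppg_noise_sd, size=n)
    rec = Recording(subject_id=subject_id, fs=fs, ecg=ecg, ppg=ppg)
    return rec, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortParams:
    """Study-condition parameters of the synthetic cohort."""

    n: int = 30
    seed: int = 0
    sbp_mean: float = 125.0
    sbp_sd: float = 18.8
    sbp_range: tuple[float, float] = (90.0, 175.0)
    dbp_mean: float = 76.0
    dbp_sd: float = 12.4
    dbp_range: tuple[float, float] = (54.0, 105.0)
    bp_corr: float = 0.6
    pulse_pressure_min: float = 10.0
    # PTT(SBP) coupling: ptt_ms = intercept + slope * sbp + jitter
    ptt_intercept_ms: float = 380.0
    ptt_slope: float = -1.0
    ptt_jitter_sd_ms: float = 0.0
    # reflection-ratio(DBP) coupling: a_srp/a_sep = r0 + r1 * dbp
    refl_intercept: float = 0.20
    refl_slope: float = 0.004
    refl_jitter_sd: float = 0.0
    hr_mean: float = 70.0
    hr_sd: float = 8.0
    hr_range: tuple[float, float] = (45.0, 110.0)
    duration_s: float = 180.0
    fs: float = 1000.0
    ecg_noise_sd: float = 0.0
    ppg_noise_sd: float = 0.0
    period_jitter_sd: float = 0.0
    cuff_sd_mmhg: float = 3.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be at least 1")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        for mean, sd, (lo, hi), name in (
            (self.sbp_mean, self.sbp_sd, self.sbp_range, "SBP"),
            (self.dbp_mean, self.dbp_sd, self.dbp_range, "DBP"),
            (self.hr_mean, self.hr_sd, self.hr_range, "HR"),
        ):
            if not lo < hi:
                raise ValueError(f"{name} truncation bounds are inverted")
            if mean < lo - 5 * sd or mean > hi + 5 * sd:
                raise ValueError(
                    f"infeasible truncation for {name}: mean {mean} is more than "
                    f"5 sd outside [{lo}, {hi}]"
                )
        if self.ptt_slope >= 0:
            raise ValueError("PTT must decrease with SBP (negative slope)")

    # invertible coupling maps ---------------------------------------------
    def ptt_from_sbp(self, sbp: float | np.ndarray) -> float | np.ndarray:
        return self.ptt_intercept_ms + self.ptt_slope * np.asarray(sbp, float)

    def sbp_from_ptt(self, ptt_ms: float | np.ndarray) -> float | np.ndarray:
        return (np.asarray(ptt_ms, float) - self.ptt_intercept_ms) / self.ptt_slope

    def refl_from_dbp(self, dbp: float | np.ndarray) -> float | np.ndarray:
        return self.refl_intercept + self.refl_slope * np.asarray(dbp, float)

    def dbp_from_refl(self, ratio: float | np.ndarray) -> float | np.ndarray:
        return (np.asarray(ratio, float) - self.refl_intercept) / self.refl_slope


@dataclass
class GroundTruth:
    """Per-subject truth plus per-beat fiducial truth (test oracle)."""

    subjects: pd.DataFrame
    beats: pd.DataFrame


@dataclass
class CohortResult:
    recordings: list[Recording]
    truth: GroundTruth
    cuff: pd.DataFrame
    params: CohortParams


def _matched_truncnorm(mean: float, sd: float, lo: float, hi: float):
    """Parent normal whose truncation to [lo, hi] has the stated mean/sd.

    The cohort statistics are observed (hence truncated) moments, so the
    parent location/scale are solved for rather than used directly.
    """

    def eqs(p):
        mu, sigma = p
        sigma = abs(sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        d = stats.truncnorm(a, b, loc=mu, scale=sigma)
        return [d.mean() - mean, d.std() - sd]

    (mu, sigma), info, ok, _ = optimize.fsolve(
        eqs, [mean, sd], full_output=True
    )
    if ok != 1:  # fall back to the untruncated parameters
        mu, sigma = mean, sd
    return float(mu), float(abs(sigma))


def _draw_bp(params: CohortParams, rng: np.random.Generator) -> np.ndarray:
    """(n, 2) array of (SBP, DBP) from the truncated correlated model.

    SBP is drawn exactly from its moment-matched truncated marginal via
    the inverse CDF; DBP is drawn from the conditional normal given the
    SBP parent value, with rejection only on the DBP box and the minimum
    pulse pressure, so the SBP marginal is untouched by the coupling.
    """
    mu_s, sig_s = _matched_truncnorm(params.sbp_mean, params.sbp_sd, *params.sbp_range)
    mu_d, sig_d = _matched_truncnorm(params.dbp_mean, params.dbp_sd, *params.dbp_range)
    r = params.bp_corr
    a, b = (params.sbp_range[0] - mu_s) / sig_s, (params.sbp_range[1] - mu_s) / sig_s
    sbp = stats.truncnorm.ppf(rng.random(params.n), a, b, loc=mu_s, scale=sig_s)
    cond_mu = mu_d + r * (sig_d / sig_s) * (sbp - mu_s)
    cond_sd = sig_d * math.sqrt(1.0 - r * r)
    dbp = np.full(params.n, np.nan)
    pending = np.arange(params.n)
    for _ in range(1000):
        z = cond_mu[pending] + cond_sd * rng.standard_normal(pending.size)
        ok = (
            (z >= params.dbp_range[0]) & (z <= params.dbp_range[1])
            & (sbp[pending] - z >= params.pulse_pressure_min)
        )
        dbp[pending[ok]] = z[ok]
        pending = pending[~ok]
        if pending.size == 0:
            break
    if pending.size:
        # pathological parameterization: clamp the stragglers
        hi = np.minimum(params.dbp_range[1],
                        sbp[pending] - params.pulse_pressure_min)
        dbp[pending] = np.clip(cond_mu[pending], params.dbp_range[0], hi)
    return np.column_stack([sbp, dbp])


def simulate_cuff_readings(
    true_sbp: float,
    true_dbp: float,
    reading_sd: float = 3.0,
    seed: int | np.random.Generator | None = 0,
) -> dict[str, float]:
    """Three independent noisy cuff readings and their arithmetic mean."""
    if reading_sd < 0:
        raise ValueError("reading noise sd must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sbp = true_sbp + rng.normal(0.0, reading_sd, size=3) if reading_sd > 0 \
        else np.full(3, float(true_sbp))
    dbp = true_dbp + rng.normal(0.0, reading_sd, size=3) if reading_sd > 0 \
        else np.full(3, float(true_dbp))
    out = {f"sbp_{i + 1}": float(sbp[i]) for i in range(3)}
    out.update({f"dbp_{i + 1}": float(dbp[i]) for i in range(3)})
    out["sbp_mean"] = float(np.mean(sbp))
    out["dbp_mean"] = float(np.mean(dbp))
    return out


def _subject_morphology(
    params: CohortParams, sbp: float, dbp: float, hr: float,
    rng: np.random.Generator,
) -> MorphologyParams:
    base = default_morphology()
    period = 60.0 / hr
    ptt_ms = float(params.ptt_from_sbp(sbp))
    if params.ptt_jitter_sd_ms > 0:
        ptt_ms += rng.normal(0.0, params.ptt_jitter_sd_ms)
    ratio = float(np.clip(params.refl_from_dbp(dbp)
                          + (rng.normal(0.0, params.refl_jitter_sd)
                             if params.refl_jitter_sd > 0 else 0.0),
                          0.05, 0.9))
    # keep component centers inside shorter beats
    squeeze = min(1.0, period / base.period)
    return replace(
        base,
        a_srp=ratio * base.a_sep,
        c_sep=base.c_sep * squeeze,
        c_srp=base.c_srp * squeeze,
        c_dp=base.c_dp * squeeze,
        w_sep=base.w_sep * squeeze,
        w_srp=base.w_srp * squeeze,
        w_dp=base.w_dp * squeeze,
        ptt=ptt_ms / 1000.0,
        period=period,
    )


def generate_cohort(params: CohortParams) -> CohortResult:
    """Generate the full synthetic study: recordings, truth and cuff tables."""
    root = np.random.SeedSequence(params.seed)
    bp_rng = np.random.default_rng(root.spawn(1)[0])
    bp = _draw_bp(params, bp_rng)
    streams = np.random.SeedSequence(params.seed).spawn(params.n + 1)[1:]

    recordings: list[Recording] = []
    subj_rows = []
    beat_tables = []
    cuff_rows = []
    for i in range(params.n):
        rng = np.random.default_rng(streams[i])
        sbp, dbp = float(bp[i, 0]), float(bp[i, 1])
        hr = float(np.clip(rng.normal(params.hr_mean, params.hr_sd),
                           *params.hr_range))
        morph = _subject_morphology(params, sbp, dbp, hr, rng)
        sid = f"S{i:04d}"
        rec, beats = synthesize_recording(
            morph,
            duration_s=params.duration_s,
            fs=params.fs,
            subject_id=sid,
            ecg_noise_sd=params.ecg_noise_sd,
            ppg_noise_sd=params.ppg_noise_sd,
            period_jitter_sd=params.period_jitter_sd,
            rng=rng,
        )
        beats.insert(0, "subject_id", sid)
        cuff = simulate_cuff_readings(sbp, dbp, params.cuff_sd_mmhg, rng)
        cuff_rows.append({"subject_id": sid, **cuff})
        subj_rows.append(
            {
                "subject_id": sid,
                "true_sbp": sbp,
                "true_dbp": dbp,
                "hr_bpm": hr,
                "true_ptt_ms": morph.ptt * 1000.0,
                "refl_ratio": morph.a_srp / morph.a_sep,
            }
        )
        recordings.append(rec)
        beat_tables.append(beats)
    truth = GroundTruth(
        subjects=pd.DataFrame(subj_rows),
        beats=pd.concat(beat_tables, ignore_index=True),
    )
    return CohortResult(
        recordings=recordings,
        truth=truth,
        cuff=pd.DataFrame(cuff_rows),
        params=params,
    )
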