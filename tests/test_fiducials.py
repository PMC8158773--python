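"""Detection accuracy against generator truth, gating and decomposition."""

import numpy as np
import pytest

from pulsebp import synth
from pulsebp.errors import (
    FiducialFailureError,
    InsufficientDataError,
    NoSignalError,
    RecordRejectedError,
)
from pulsebp.fiducials import (
    BeatPair,
    decompose_waves,
    detect_fiducials,
    detect_r_peaks,
    quality_gate,
    segment_beats,
)
from pulsebp.io import Recording


def _beat(ppg, fs=1000.0):
    return BeatPair(r_time=0.0, start_time=0.0, ppg=np.asarray(ppg, float),
                    fs=fs)


class TestRPeaks:
    def test_zero_noise_recovery_within_2ms(self):
        rec, beats = synth.synthesize_recording(
            synth.default_morphology(), duration_s=60.0, fs=1000.0
        )
        det = detect_r_peaks(rec)
        true_r = beats["r_time"].to_numpy()
        assert det.size == true_r.size
        assert np.max(np.abs(det - true_r)) <= 0.002
        assert np.all(np.diff(det) > 0)

    def test_flat_signal_raises_no_signal(self):
        rec = Recording("f", 500.0, np.zeros(5000), np.ones(5000))
        with pytest.raises(NoSignalError):
            detect_r_peaks(rec)

    def test_snr_10db_recovers_99pct_within_10ms(self):
        """At 10 dB peak SNR, at least 99% of true R peaks are matched."""
        rng = np.random.default_rng(7)
        rec, beats = synth.synthesize_recording(
            synth.default_morphology(), duration_s=180.0, fs=1000.0,
            ecg_noise_sd=1.0 / np.sqrt(10.0), rng=rng,
        )
        det = detect_r_peaks(rec)
        true_r = beats["r_time"].to_numpy()
        matched = sum(np.min(np.abs(det - r)) <= 0.010 for r in true_r)
        assert matched >= 0.99 * true_r.size


class TestSegmentation:
    @pytest.fixture(scope="class")
    def record_and_peaks(self):
        rec, _ = synth.synthesize_recording(
            synth.default_morphology(), duration_s=180.0, fs=500.0
        )
        return rec, detect_r_peaks(rec)

    def test_beat_count_180s_at_60bpm(self, record_and_peaks):
        rec, r = record_and_peaks
        beats = segment_beats(rec, r)
        assert abs(len(beats) - 179) <= 1

    def test_segments_tile_without_gaps(self, record_and_peaks):
        rec, r = record_and_peaks
        beats = segment_beats(rec, r)
        for a, b in zip(beats, beats[1:]):
            assert a.end_time == pytest.approx(b.start_time, abs=1e-9)

    def test_segment_onsets_equal_r_peaks(self, record_and_peaks):
        rec, r = record_and_peaks
        beats = segment_beats(rec, r)
        for b in beats:
            assert b.r_time in r
            assert b.start_time == pytest.approx(b.r_time, abs=1.0 / rec.fs)

    def test_fewer_than_two_peaks_is_error(self, record_and_peaks):
        rec, _ = record_and_peaks
        with pytest.raises(InsufficientDataError):
            segment_beats(rec, [1.0])


class TestQualityGate:
    def _clean_beats(self, n=20):
        _, ppg, _ = synth.synthesize_beat(synth.default_morphology(), fs=500)
        return [_beat(ppg.copy(), fs=500) for _ in range(n)]

    def test_identical_beats_all_score_one(self):
        beats = quality_gate(self._clean_beats(), threshold=0.9)
        assert all(b.accepted for b in beats)
        assert all(b.quality == pytest.approx(1.0) for b in beats)

    def test_saturation_spike_rejected_at_09(self):
        beats = self._clean_beats()
        beats[10].ppg[100:175] = beats[10].ppg.max() + 5.0
        beats = quality_gate(beats, threshold=0.9)
        assert not beats[10].accepted
        assert all(b.accepted for i, b in enumerate(beats) if i != 10)

    def test_zero_threshold_accepts_everything(self):
        beats = self._clean_beats()
        beats[3].ppg[:] = beats[3].ppg[::-1]
        assert all(b.accepted for b in quality_gate(beats, threshold=0.0))

    def test_monotone_in_threshold(self, rng):
        """Raising the threshold never accepts a previously rejected beat."""
        beats = self._clean_beats()
        for i, b in enumerate(beats):
            b.index = i
            b.ppg += rng.normal(0, 0.15, b.ppg.size)

        def accepted_at(thr):
            copies = [_beat(b.ppg.copy(), 500) for b in beats]
            for i, c in enumerate(copies):
                c.index = i
            try:
                gated = quality_gate(copies, thr)
            except RecordRejectedError:
                return set()
            return {c.index for c in gated if c.accepted}

        prev = accepted_at(0.2)
        for thr in (0.5, 0.8, 0.95):
            cur = accepted_at(thr)
            assert cur <= prev
            prev = cur

    def test_all_rejected_raises_record_rejected(self, rng):
        beats = self._clean_beats(6)
        for b in beats:
            b.ppg = rng.normal(0, 1, b.ppg.size)  # destroy all structure
        with pytest.raises(RecordRejectedError):
            quality_gate(beats, threshold=0.9999)


class TestFiducials:
    def test_noise_free_grid_recovery_within_10ms(self, grid_morphologies):
        """B1, SEP, SRP, DP within +-10 ms of generator truth on every
        morphology of the default grid."""
        assert len(grid_morphologies) >= 20
        for m in grid_morphologies:
            _, ppg, truth = synth.synthesize_beat(m, fs=1000, noise_sd=0.0)
            det = detect_fiducials(_beat(ppg))
            for key in ("b1", "sep", "srp", "dp"):
                assert np.isfinite(truth[key]), key
                assert abs(det.times[key] - truth[key]) <= 0.010, (key, m)

    def test_single_gaussian_b0_at_mu_minus_sigma(self):
        m = synth.MorphologyParams(a_srp=0.0, a_dp=0.0, c_sep=0.15,
                                   w_sep=0.05)
        fs = 1000.0
        _, ppg, _ = synth.synthesize_beat(m, fs=fs)
        det = detect_fiducials(_beat(ppg))
        mu = m.ptt + synth.calibrate_foot(m).c_sep
        assert abs(det.times["b0"] - (mu - m.w_sep)) <= 1.5 / fs

    def test_ordering_invariants_hold(self, grid_morphologies):
        for m in grid_morphologies[::4]:
            _, ppg, _ = synth.synthesize_beat(m, fs=1000)
            det = detect_fiducials(_beat(ppg))
            assert det.check_order()
            t = det.times
            assert t["b1"] >= 0 and t["end"] <= len(ppg) / 1000.0 + 1e-9

    def test_flat_segment_raises_fiducial_failure(self):
        with pytest.raises(FiducialFailureError):
            detect_fiducials(_beat(np.full(500, 20.0)))


class TestDecomposition:
    def test_two_component_parameter_recovery(self):
        """Exactly-two-Gaussian beat: centers within 5 ms, amplitudes
        within 2%, residual essentially zero."""
        m = synth.MorphologyParams(a_sep=1.0, a_srp=0.5, a_dp=0.0,
                                   c_sep=0.14, c_srp=0.32,
                                   w_sep=0.05, w_srp=0.08)
        _, ppg, _ = synth.synthesize_beat(m, fs=1000)
        dec = decompose_waves(_beat(ppg))
        mc = synth.calibrate_foot(m)
        assert dec.forward[1] == pytest.approx(m.ptt + mc.c_sep, abs=0.005)
        assert dec.backward[1] == pytest.approx(m.ptt + mc.c_srp, abs=0.005)
        assert dec.forward[0] == pytest.approx(1.0, rel=0.02)
        assert dec.backward[0] == pytest.approx(0.5, rel=0.02)
        assert dec.residual_norm < 1e-6
        assert dec.reliable

    def test_forward_dominates_backward_on_default_beats(
            self, grid_morphologies):
        for m in grid_morphologies[::4]:
            _, ppg, _ = synth.synthesize_beat(m, fs=1000)
            dec = decompose_waves(_beat(ppg))
            assert dec.forward[0] >= dec.backward[0]
            assert dec.forward[1] <= dec.backward[1]

    def test_degenerate_beat_flagged_not_raised(self):
        dec = decompose_waves(_beat(np.full(400, 5.0)))
        assert not dec.reliable
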