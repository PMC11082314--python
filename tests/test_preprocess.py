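"""Filtering, normalization and epoching behavior on analytic probes."""

import numpy as np
import pytest

from emgdecode.datatypes import GestureEvent, MVCProfile, Recording
from emgdecode.preprocess import (
    extract_phasic_epochs,
    extract_tonic_epochs,
    filter_emg,
    flag_artifacts,
    normalize_mvc,
    resample,
)


def _probe_recording(signal, fs=2048.0, events=()):
    signal = np.atleast_2d(signal)
    if signal.shape[0] == 1:
        signal = np.vstack([signal, signal])
    return Recording(
        subject_id="S01",
        session_id="sess1",
        hand="right",
        fs=fs,
        channel_names=[f"EMG{i}" for i in range(signal.shape[0])],
        signal=signal,
        events=list(events),
    )


def _sine(freq, fs, dur=2.0):
    t = np.arange(int(dur * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestResample:
    def test_identity_at_target_rate(self):
        rec = _probe_recording(_sine(10, 2048.0))
        assert resample(rec, 2048.0) is rec

    def test_2000_to_2048_matches_analytic_sine(self):
        fs0 = 2000.0
        rec = _probe_recording(_sine(10, fs0), fs=fs0)
        out = resample(rec, 2048.0)
        t = np.arange(out.n_samples) / 2048.0
        want = np.sin(2 * np.pi * 10 * t)
        interior = slice(200, -200)
        assert np.abs(out.signal[0, interior] - want[interior]).max() < 1e-3
        assert abs(out.duration_s - rec.duration_s) <= 1.0 / 2000.0

    def test_event_times_unchanged(self):
        ev = GestureEvent("thumb", 0.5, 1.0, 1.8)
        rec = _probe_recording(_sine(10, 2000.0), fs=2000.0, events=[ev])
        out = resample(rec, 2048.0)
        assert out.events[0].recognition_s == 1.0

    def test_invalid_target_raises(self):
        rec = _probe_recording(_sine(10, 2000.0), fs=2000.0)
        with pytest.raises(ValueError):
            resample(rec, 0.0)


class TestFilterEmg:
    def test_mains_frequency_attenuated(self):
        rec = filter_emg(_probe_recording(_sine(50, 2048.0)))
        in_rms = np.sqrt(np.mean(_sine(50, 2048.0) ** 2))
        out_rms = np.sqrt(np.mean(rec.signal[0, 512:-512] ** 2))
        assert out_rms <= 0.05 * in_rms

    def test_passband_preserved(self):
        rec = filter_emg(_probe_recording(_sine(100, 2048.0)))
        amp = np.max(np.abs(rec.signal[0, 512:-512]))
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_dc_rejected(self):
        rec = filter_emg(_probe_recording(np.full(4096, 2.0)))
        assert np.abs(rec.signal[0, 512:-512]).max() < 1e-6 * 2.0

    def test_zero_phase_on_broadband_burst(self):
        rng = np.random.default_rng(0)
        x = np.zeros(4096)
        x[2000:2100] = rng.standard_normal(100)
        rec = filter_emg(_probe_recording(x))
        xc = np.correlate(rec.signal[0], x, mode="full")
        lag = np.argmax(xc) - (len(x) - 1)
        assert lag == 0

    def test_passband_idempotence(self):
        rec = _probe_recording(_sine(100, 2048.0))
        once = filter_emg(rec)
        twice = filter_emg(once)
        a1 = np.max(np.abs(once.signal[0, 512:-512]))
        a2 = np.max(np.abs(twice.signal[0, 512:-512]))
        assert abs(a2 - a1) < 0.1 * a1

    def test_low_sampling_rate_raises(self):
        rec = _probe_recording(_sine(10, 900.0), fs=900.0)
        with pytest.raises(ValueError):
            filter_emg(rec)


class TestNormalizeMvc:
    def test_unit_profile_is_identity(self):
        rec = _probe_recording(_sine(10, 2048.0))
        out = normalize_mvc(rec, MVCProfile(np.ones(2)))
        np.testing.assert_array_equal(out.signal, rec.signal)

    def test_divides_per_channel(self):
        rec = _probe_recording(np.vstack([2 * _sine(10, 2048.0), 4 * _sine(10, 2048.0)]))
        out = normalize_mvc(rec, MVCProfile([2.0, 4.0]))
        assert np.max(np.abs(out.signal[0])) == pytest.approx(1.0, rel=1e-6)
        assert np.max(np.abs(out.signal[1])) == pytest.approx(1.0, rel=1e-6)

    def test_zero_entry_rejected(self):
        with pytest.raises(ValueError):
            MVCProfile([1.0, 0.0])

    def test_channel_count_mismatch_raises(self):
        rec = _probe_recording(_sine(10, 2048.0))
        with pytest.raises(ValueError):
            normalize_mvc(rec, MVCProfile(np.ones(5)))


def _session_recording(fs=2048.0, n_events=4):
    rng = np.random.default_rng(0)
    events = []
    t = 1.0
    for i in range(n_events):
        events.append(GestureEvent("thumb", t, t + 0.4, t + 2.4))
        t += 4.0
    dur = t + 1.0
    sig = rng.standard_normal((8, int(dur * fs)))
    return _probe_recording(sig, fs=fs, events=events)


class TestEpochExtraction:
    def test_one_phasic_epoch_per_event(self):
        rec = _session_recording(n_events=4)
        epochs = extract_phasic_epochs(rec)
        assert len(epochs) == 4
        assert epochs.n_samples == round(0.5 * rec.fs)
        assert epochs.component == "phasic"

    def test_phasic_window_precedes_recognition(self):
        rec = _session_recording(n_events=2)
        epochs = extract_phasic_epochs(rec)
        i0 = int(round(epochs.t_start_s[0] * rec.fs))
        np.testing.assert_array_equal(
            epochs.data[0], rec.signal[:, i0 : i0 + epochs.n_samples]
        )
        assert epochs.t_start_s[0] == pytest.approx(rec.events[0].recognition_s - 0.5)

    def test_early_event_skipped_with_warning(self):
        events = [
            GestureEvent("index", 0.1, 0.3, 2.3),
            GestureEvent("thumb", 3.0, 3.4, 5.4),
            GestureEvent("pinky", 7.0, 7.4, 9.4),
        ]
        rng = np.random.default_rng(0)
        rec = _probe_recording(rng.standard_normal((8, int(11 * 2048))), events=events)
        with pytest.warns(UserWarning, match="skipped"):
            epochs = extract_phasic_epochs(rec)
        assert len(epochs) == 2

    def test_tonic_window_starts(self):
        rec = _session_recording(n_events=1)
        epochs = extract_tonic_epochs(rec)
        rel = epochs.t_start_s - rec.events[0].recognition_s
        np.testing.assert_allclose(rel, [0.5, 0.756, 1.012, 1.268, 1.524], atol=1e-9)

    def test_default_policy_five_windows_per_event(self):
        rec = _session_recording(n_events=4)
        assert len(extract_tonic_epochs(rec)) == 20

    def test_strict_policy_four_windows_per_event(self):
        rec = _session_recording(n_events=4)
        assert len(extract_tonic_epochs(rec, policy="strict")) == 16

    def test_tonic_phasic_ratio_on_synthetic_session(self, small_config):
        from emgdecode.synthio import synthesize_recording

        rec, _ = synthesize_recording("S01", "sess1", "right", small_config)
        n_phasic = len(extract_phasic_epochs(rec))
        n_tonic = len(extract_tonic_epochs(rec))
        assert n_phasic == 24 and n_tonic == 120

    def test_epoch_samples_override(self):
        rec = _session_recording(n_events=1)
        epochs = extract_phasic_epochs(rec, epoch_samples=512)
        assert epochs.data.shape == (1, 8, 512)

    def test_epochs_never_mix_events(self):
        """Every epoch is a contiguous slice within one event's windows."""
        rec = _session_recording(n_events=3)
        epochs = extract_tonic_epochs(rec)
        for i in range(len(epochs)):
            start = epochs.t_start_s[i]
            owners = [
                ev
                for ev in rec.events
                if ev.recognition_s + 0.5 - 1e-9 <= start <= ev.recognition_s + 1.524 + 1e-9
            ]
            assert len(owners) == 1
            i0 = int(round(start * rec.fs))
            np.testing.assert_array_equal(
                epochs.data[i], rec.signal[:, i0 : i0 + epochs.n_samples]
            )


class TestArtifactFlags:
    def test_clean_recording_unflagged(self):
        rec = _session_recording()
        assert flag_artifacts(rec) == []

    def test_injected_steps_detected(self):
        rec = _session_recording()
        sig = rec.signal.copy()
        sd = sig[3].std()
        rng = np.random.default_rng(1)
        for pos in rng.integers(1000, sig.shape[1] - 1000, 10):
            sig[3, pos : pos + 40] += 20 * sd  # brief square step up and back down
        flagged = flag_artifacts(rec.copy_with(signal=sig))
        assert any(f.reason == "step_artifact" and f.channel == "EMG3" for f in flagged)

    def test_flatline_detected(self):
        rec = _session_recording()
        sig = rec.signal.copy()
        sig[5] = 0.0
        flagged = flag_artifacts(rec.copy_with(signal=sig))
        assert any(f.reason == "flatline" and f.channel == "EMG5" for f in flagged)
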