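"""Filtering, MVC normalization and phasic/tonic epoch extraction.

Processing order: resample to 2,048 Hz, 50 Hz notch (5 Hz bandwidth),
30-500 Hz band-pass (4th-order Butterworth), both applied forward-backward
(zero phase), then per-channel division by the MVC maxima.

Epoching is anchored on the posture-recognition event: the phasic window
is the 500 ms *before* recognition; tonic windows are 500 ms long with a
256 ms stride, starting 500 ms after recognition. The default tonic policy
keeps the five windows whose starts lie at +500, +756, +1012, +1268 and
+1524 ms (the last window extends to +2,024 ms), matching a 1:5
phasic:tonic epoch ratio; a strict-containment policy (windows must end by
+2,000 ms -> four windows) is available.
"""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
from scipy.signal import butter, filtfilt, iirnotch, resample_poly, sosfiltfilt

from .datatypes import EpochSet, MVCProfile, QualityFlag, Recording, concatenate_epochsets

TARGET_FS = 2048.0
PHASIC_WINDOW_S = 0.5
TONIC_WINDOW_S = 0.5
TONIC_STRIDE_S = 0.256
TONIC_FIRST_START_S = 0.5


def resample(recording: Recording, target_fs: float = TARGET_FS) -> Recording:
    """Polyphase resampling to ``target_fs``; event times stay in seconds."""
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if recording.fs == target_fs:
        return recording
    ratio = Fraction(target_fs / recording.fs).limit_denominator(1000)
    signal = resample_poly(recording.signal, ratio.numerator, ratio.denominator, axis=1)
    return recording.copy_with(signal=signal, fs=target_fs)


def filter_emg(
    recording: Recording,
    notch_freq: float = 50.0,
    notch_bandwidth: float = 5.0,
    band: tuple = (30.0, 500.0),
    order: int = 4,
) -> Recording:
    """Zero-phase 50 Hz notch + 30-500 Hz Butterworth band-pass."""
    fs = recording.fs
    if fs <= 2 * band[1]:
        raise ValueError(f"sampling rate {fs} too low for a {band[1]} Hz band edge")
    b, a = iirnotch(notch_freq, notch_freq / notch_bandwidth, fs=fs)
    x = filtfilt(b, a, recording.signal, axis=1)
    sos = butter(order, band, btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, x, axis=1)
    return recording.copy_with(signal=x)


def normalize_mvc(recording: Recording, mvc: MVCProfile) -> Recording:
    """Divide each channel by its MVC maximum absolute amplitude."""
    if len(mvc) != recording.n_channels:
        raise ValueError(
            f"MVC profile has {len(mvc)} channels, recording has {recording.n_channels}"
        )
    return recording.copy_with(signal=recording.signal / mvc.max_abs[:, None])


def _window_indices(recording: Recording, start_s: float, n_samples: int):
    i0 = int(round(start_s * recording.fs))
    if i0 < 0 or i0 + n_samples > recording.n_samples:
        return None
    return i0


def extract_phasic_epochs(recording: Recording, epoch_samples: int | None = None) -> EpochSet:
    """One 500 ms epoch per gesture, ending at posture recognition.

    Events whose recognition falls within the first 500 ms are skipped
    with a warning. ``epoch_samples`` optionally truncates each window to
    its first that-many samples (for pipelines expecting e.g. 512).
    """
    fs = recording.fs
    full = int(round(PHASIC_WINDOW_S * fs))
    n_keep = epoch_samples or full
    if n_keep > full:
        raise ValueError("epoch_samples exceeds the 500 ms window")
    rows, labels, starts = [], [], []
    for ev in recording.events:
        start_s = ev.recognition_s - PHASIC_WINDOW_S
        i0 = _window_indices(recording, start_s, full)
        if i0 is None:
            warnings.warn(
                f"event at recognition {ev.recognition_s:.3f}s skipped: window out of range"
            )
            continue
        rows.append(recording.signal[:, i0 : i0 + n_keep])
        labels.append(ev.label)
        starts.append(start_s)
    n = len(rows)
    return EpochSet(
        data=np.stack(rows) if rows else np.empty((0, recording.n_channels, n_keep)),
        labels=np.array(labels, dtype=object),
        subject=np.full(n, recording.subject_id, dtype=object),
        session=np.full(n, recording.session_id, dtype=object),
        hand=np.full(n, recording.hand, dtype=object),
        component="phasic",
        fs=fs,
        window_s=PHASIC_WINDOW_S,
        t_start_s=np.array(starts, dtype=float),
    )


def extract_tonic_epochs(
    recording: Recording,
    policy: str = "ratio5",
    epoch_samples: int | None = None,
) -> EpochSet:
    """Overlapping 500 ms posture-hold epochs, 256 ms stride, per gesture.

    ``policy='ratio5'`` (default) keeps windows starting up to +1,524 ms
    after recognition (five per event); ``policy='strict'`` requires the
    window to end by +2,000 ms (four per event). Windows running past the
    recording end are skipped with a warning.
    """
    if policy not in ("ratio5", "strict"):
        raise ValueError("policy must be 'ratio5' or 'strict'")
    fs = recording.fs
    full = int(round(TONIC_WINDOW_S * fs))
    n_keep = epoch_samples or full
    if n_keep > full:
        raise ValueError("epoch_samples exceeds the 500 ms window")
    rows, labels, starts = [], [], []
    eps = 1e-9
    for ev in recording.events:
        k = 0
        while True:
            rel_start = TONIC_FIRST_START_S + k * TONIC_STRIDE_S
            if policy == "ratio5":
                if rel_start > 1.524 + eps:
                    break
            else:
                if rel_start + TONIC_WINDOW_S > 2.0 + eps:
                    break
            start_s = ev.recognition_s + rel_start
            i0 = _window_indices(recording, start_s, full)
            if i0 is None:
                warnings.warn(f"tonic window at {start_s:.3f}s skipped: out of range")
            else:
                rows.append(recording.signal[:, i0 : i0 + n_keep])
                labels.append(ev.label)
                starts.append(start_s)
            k += 1
    n = len(rows)
    return EpochSet(
        data=np.stack(rows) if rows else np.empty((0, recording.n_channels, n_keep)),
        labels=np.array(labels, dtype=object),
        subject=np.full(n, recording.subject_id, dtype=object),
        session=np.full(n, recording.session_id, dtype=object),
        hand=np.full(n, recording.hand, dtype=object),
        component="tonic",
        fs=fs,
        window_s=TONIC_WINDOW_S,
        t_start_s=np.array(starts, dtype=float),
    )


def flag_artifacts(
    recording: Recording,
    step_threshold: float = 8.0,
    min_events: int = 5,
    saturation_fraction: float = 0.01,
) -> list[QualityFlag]:
    """Deterministic per-channel quality screening.

    * ``step_artifact``: at least ``min_events`` absolute first differences
      exceeding ``step_threshold`` times the channel standard deviation
      (repeated sharp amplitude changes, e.g. failing electrode batteries);
    * ``saturation``: more than ``saturation_fraction`` of samples pinned
      at the channel's absolute maximum;
    * ``flatline``: zero variance.
    """
    flags = []
    rec_id = f"{recording.subject_id}_{recording.session_id}_{recording.hand}"
    for c, name in enumerate(recording.channel_names):
        x = recording.signal[c]
        sd = x.std()
        if sd == 0:
            flags.append(QualityFlag(rec_id, name, "flatline", 0.0))
            continue
        peak = np.max(np.abs(x))
        if peak > 0:
            pinned = np.abs(x) >= 0.999 * peak
            if pinned.mean() > saturation_fraction:
                t = float(np.argmax(pinned) / recording.fs)
                flags.append(QualityFlag(rec_id, name, "saturation", t))
        steps = np.abs(np.diff(x)) > step_threshold * sd
        if steps.sum() >= min_events:
            t = float((np.argmax(steps) + 1) / recording.fs)
            flags.append(QualityFlag(rec_id, name, "step_artifact", t))
    return flags


def preprocess_recording(
    recording: Recording, mvc: MVCProfile, target_fs: float = TARGET_FS
) -> Recording:
    """resample -> notch -> band-pass -> MVC-normalize."""
    rec = resample(recording, target_fs)
    rec = filter_emg(rec)
    return normalize_mvc(rec, mvc)


def build_epochsets(
    dataset,
    tonic_policy: str = "ratio5",
    epoch_samples: int | None = None,
    drop_flagged: bool = False,
) -> tuple[EpochSet, EpochSet]:
    """Preprocess and epoch an iterable of (recording, mvc) pairs.

    Returns the concatenated (phasic, tonic) epoch sets. With
    ``drop_flagged`` set, recordings with any quality flag are excluded
    (flags are surfaced via a warning, never silently).
    """
    phasic, tonic = [], []
    for rec, mvc in dataset:
        clean = preprocess_recording(rec, mvc)
        if drop_flagged:
            flags = flag_artifacts(clean)
            if flags:
                warnings.warn(f"dropping flagged recording: {flags}")
                continue
        phasic.append(extract_phasic_epochs(clean, epoch_samples=epoch_samples))
        tonic.append(extract_tonic_epochs(clean, policy=tonic_policy, epoch_samples=epoch_samples))
    return concatenate_epochsets(phasic), concatenate_epochsets(tonic)
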