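"""Core data containers for multichannel sEMG recordings and epoched datasets.

The containers are deliberately light: plain dataclasses over numpy arrays,
with invariant checks at construction time. Heavy lifting (filtering,
epoching, classification) lives in the sibling modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

GESTURE_CLASSES = ("thumb", "index", "middle", "pinky")


@dataclass(frozen=True)
class GestureEvent:
    """One guided gesture: movement onset, posture recognition, release.

    Times are in seconds from the start of the recording. ``onset_s`` is when
    the hand starts moving toward the target posture, ``recognition_s`` when
    the posture is recognized (the anchor for all epoching) and ``release_s``
    when the return-to-rest movement starts, after the ~2 s hold.
    """

    label: str
    onset_s: float
    recognition_s: float
    release_s: float

    def __post_init__(self) -> None:
        if self.label not in GESTURE_CLASSES:
            raise ValueError(f"unknown gesture label {self.label!r}")
        if not (self.onset_s < self.recognition_s < self.release_s):
            raise ValueError(
                "event times must satisfy onset < recognition < release, got "
                f"{self.onset_s}, {self.recognition_s}, {self.release_s}"
            )


@dataclass
class Recording:
    """One subject-session-hand multichannel EMG trace with gesture events.

    ``signal`` has shape (E, T) in normalized amplitude units; ``events`` are
    sorted by onset and non-overlapping.
    """

    subject_id: str
    session_id: str
    hand: str
    fs: float
    channel_names: list[str]
    signal: np.ndarray
    events: list[GestureEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.signal.shape[0] < 2:
            raise ValueError("need at least 2 channels")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError("channel_names length must match signal rows")
        if self.hand not in ("left", "right"):
            raise ValueError("hand must be 'left' or 'right'")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        dur = self.signal.shape[1] / self.fs
        events = sorted(self.events, key=lambda e: e.onset_s)
        for prev, nxt in zip(events, events[1:]):
            if nxt.onset_s < prev.release_s:
                raise ValueError("events overlap")
        for ev in events:
            if ev.release_s >= dur:
                raise ValueError("event times exceed recording duration")
        self.events = events

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kw) -> "Recording":
        out = replace(self, **kw)
        return out


@dataclass(frozen=True)
class MVCProfile:
    """Per-channel maximum absolute amplitude from MVC calibration."""

    max_abs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "max_abs", np.asarray(self.max_abs, dtype=float))
        if self.max_abs.ndim != 1:
            raise ValueError("MVC profile must be a 1-D vector")
        if not np.all(self.max_abs > 0):
            raise ValueError("MVC maxima must be strictly positive")

    def __len__(self) -> int:
        return self.max_abs.size


@dataclass
class EpochSet:
    """N labeled fixed-length windows (N x E x S) with provenance.

    ``component`` tags whether the windows cover the movement burst
    ("phasic") or the posture hold ("tonic"). ``t_start_s`` records the
    source-window start of each epoch inside its recording, so provenance
    (no sample mixing across events) stays checkable.
    """

    data: np.ndarray
    labels: np.ndarray
    subject: np.ndarray
    session: np.ndarray
    hand: np.ndarray
    component: str
    fs: float
    window_s: float
    t_start_s: np.ndarray = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        self.subject = np.asarray(self.subject)
        self.session = np.asarray(self.session)
        self.hand = np.asarray(self.hand)
        if self.data.ndim != 3:
            raise ValueError("data must be N x E x S")
        n = self.data.shape[0]
        for name in ("labels", "subject", "session", "hand"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} must have length N={n}")
        if self.component not in ("phasic", "tonic"):
            raise ValueError("component must be 'phasic' or 'tonic'")
        if np.isnan(self.data).any():
            raise ValueError("epoch data contains NaN")
        if self.t_start_s is None:
            self.t_start_s = np.full(n, np.nan)
        self.t_start_s = np.asarray(self.t_start_s, dtype=float)

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def subset(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(
            data=self.data[idx],
            labels=self.labels[idx],
            subject=self.subject[idx],
            session=self.session[idx],
            hand=self.hand[idx],
            component=self.component,
            fs=self.fs,
            window_s=self.window_s,
            t_start_s=self.t_start_s[idx],
        )


def concatenate_epochsets(sets: Sequence[EpochSet]) -> EpochSet:
    """Stack epoch sets with identical geometry and component tag."""
    if not sets:
        raise ValueError("nothing to concatenate")
    first = sets[0]
    for s in sets[1:]:
        if s.component != first.component or s.fs != first.fs:
            raise ValueError("incompatible epoch sets")
        if s.data.shape[1:] != first.data.shape[1:]:
            raise ValueError("incompatible epoch shapes")
    return EpochSet(
        data=np.concatenate([s.data for s in sets]),
        labels=np.concatenate([s.labels for s in sets]),
        subject=np.concatenate([s.subject for s in sets]),
        session=np.concatenate([s.session for s in sets]),
        hand=np.concatenate([s.hand for s in sets]),
        component=first.component,
        fs=first.fs,
        window_s=first.window_s,
        t_start_s=np.concatenate([s.t_start_s for s in sets]),
    )


@dataclass(frozen=True)
class QualityFlag:
    """One detected signal-quality problem on one channel."""

    recording_id: str
    channel: str
    reason: str  # step_artifact | saturation | flatline
    time_s: float

    def __post_init__(self) -> None:
        if self.reason not in ("step_artifact", "saturation", "flatline"):
            raise ValueError(f"unknown flag reason {self.reason!r}")
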