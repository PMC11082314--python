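"""Hilbert-envelope extraction and the neural-integrator move/hold split.

The instantaneous amplitude (envelope) of the band-passed EMG is the
magnitude of its analytic signal, sqrt(x^2 + xh^2), smoothed by a
zero-phase 20 Hz low-pass. Rectification is implicit in the magnitude; no
separate absolute-value step is applied.

The move/hold decomposition models the envelope S as the sum of a phasic
"move" command M and a tonic "hold" command H, where H is the running time
integral of M (the neural-integrator hypothesis). With f the sampling
frequency and the integrator state initialized at zero, the per-sample
iteration is

    M_T = S_T - H_{T-1},        H_T = H_{T-1} + M_T / f.

The first line makes S_T = M_T + H_{T-1} an exact identity, so the
``hold`` array stored here is the *lagged* integrator state H_{T-1}: with
that alignment ``signal == move + hold`` holds at machine precision sample
by sample, and ``hold`` is exactly the exclusive running sum of ``move``
divided by f. The post-update state H_T is the same array advanced by one
sample. For a step input S = c the recursion has the closed form
M_T = c (1 - 1/f)^T and H_T = c (1 - (1 - 1/f)^{T+1}).

Negative move transients (when S decays faster than the integrator) are
kept as-is: the recursion defines them and clipping would break the
conservation identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, hilbert, lfilter, sosfiltfilt


@dataclass
class Envelope:
    """Nonnegative instantaneous-amplitude traces (E, T) at ``fs`` Hz."""

    values: np.ndarray
    fs: float
    smoothing_cutoff: float = 20.0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("envelope contains non-finite values")


@dataclass
class Decomposition:
    """Envelope split S = M + H with H the lagged integrator state."""

    envelope: Envelope
    move: np.ndarray
    hold: np.ndarray
    t0_index: int

    @property
    def hold_state(self) -> np.ndarray:
        """Post-update integrator state H_T (hold advanced one sample)."""
        h = np.empty_like(self.hold)
        h[:, :-1] = self.hold[:, 1:]
        # last post-update value from the recursion
        f = self.envelope.fs
        h[:, -1] = self.hold[:, -1] + self.move[:, -1] / f
        return h


def envelope(signal: np.ndarray, fs: float, smoothing_cutoff: float = 20.0) -> Envelope:
    """Analytic-signal magnitude per channel, low-pass smoothed (zero phase)."""
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    if signal.shape[1] < 64:
        raise ValueError("need at least 64 samples")
    amp = np.abs(hilbert(signal, axis=1))
    if smoothing_cutoff:
        sos = butter(4, smoothing_cutoff, btype="low", fs=fs, output="sos")
        amp = sosfiltfilt(sos, amp, axis=1)
    return Envelope(values=amp, fs=fs, smoothing_cutoff=smoothing_cutoff)


def remove_baseline(env: Envelope, rest_intervals, mode: str = "subtract") -> Envelope:
    """Remove the per-channel resting-pose baseline from an envelope.

    ``rest_intervals`` is a sequence of (start_s, stop_s) pairs covering
    resting-pose activity; each channel gets its own median baseline.

    ``mode='subtract'`` (default) subtracts the median and clips at 0.
    ``mode='power'`` removes the baseline in the power domain,
    sqrt(max(env^2 - baseline^2, 0)): because the envelope of the sum of
    an activation and an independent noise floor adds in quadrature,
    power-domain removal is unbiased for the activation amplitude where
    linear subtraction over-corrects by roughly the full noise floor.
    """
    if not len(rest_intervals):
        raise ValueError("rest_intervals must be nonempty")
    if mode not in ("subtract", "power"):
        raise ValueError("mode must be 'subtract' or 'power'")
    fs = env.fs
    idx = np.zeros(env.values.shape[1], dtype=bool)
    for start, stop in rest_intervals:
        i0, i1 = int(round(start * fs)), int(round(stop * fs))
        idx[max(i0, 0) : min(i1, idx.size)] = True
    if not idx.any():
        raise ValueError("rest intervals select no samples")
    baseline = np.median(env.values[:, idx], axis=1, keepdims=True)
    if mode == "subtract":
        values = np.clip(env.values - baseline, 0.0, None)
    else:
        values = np.sqrt(np.clip(env.values**2 - baseline**2, 0.0, None))
    return Envelope(values=values, fs=fs, smoothing_cutoff=env.smoothing_cutoff)


def decompose_move_hold(env: Envelope, t0_index: int = 0) -> Decomposition:
    """Split the envelope into move and hold commands from ``t0_index``.

    ``t0_index`` should be aligned with the beginning of the move command
    (gesture onset). Before t0 both commands are zero.
    """
    s = env.values
    n = s.shape[1]
    if not (0 <= t0_index < n):
        raise ValueError(f"t0_index {t0_index} outside [0, {n})")
    f = env.fs
    move = np.zeros_like(s)
    hold = np.zeros_like(s)
    seg = s[:, t0_index:]
    # H_T = (1 - 1/f) H_{T-1} + S_T / f  -> first-order IIR along time
    a = 1.0 - 1.0 / f
    h_state = lfilter([1.0 / f], [1.0, -a], seg, axis=1)
    h_lag = np.concatenate([np.zeros((s.shape[0], 1)), h_state[:, :-1]], axis=1)
    move[:, t0_index:] = seg - h_lag
    hold[:, t0_index:] = h_lag
    return Decomposition(envelope=env, move=move, hold=hold, t0_index=t0_index)


def hold_similarity(
    hold_commands: np.ndarray,
    raw_envelopes: np.ndarray,
    hold_slice: slice,
    rest_slice: slice,
) -> "pandas.DataFrame":  # noqa: F821
    """Per-channel agreement between hold-command and raw tonic amplitude.

    Parameters
    ----------
    hold_commands, raw_envelopes : arrays (G, E, T)
        Per-gesture hold commands and raw envelopes on a common time base.
    hold_slice, rest_slice : slice
        Sample ranges of the posture hold and of resting-pose activity.

    For each channel, each gesture contributes one point
    (x = mean raw envelope over the hold minus the rest baseline,
    y = mean hold command over the hold); the table reports the Pearson r
    of the points and the identity-line R^2 of y against x
    (1 - SS_res/SS_tot with predictions = x, so a constant offset can push
    R^2 negative while r stays high).
    """
    import pandas as pd

    hold_commands = np.asarray(hold_commands, dtype=float)
    raw_envelopes = np.asarray(raw_envelopes, dtype=float)
    if hold_commands.shape != raw_envelopes.shape or hold_commands.ndim != 3:
        raise ValueError("expected matching (G, E, T) arrays")
    g, e, _ = hold_commands.shape
    if g < 2:
        raise ValueError("need at least 2 gestures for correlation")
    x = (
        raw_envelopes[:, :, hold_slice].mean(axis=2)
        - raw_envelopes[:, :, rest_slice].mean(axis=2)
    )
    y = hold_commands[:, :, hold_slice].mean(axis=2)
    rows = []
    for c in range(e):
        xc, yc = x[:, c], y[:, c]
        sx, sy = xc.std(), yc.std()
        r = np.nan if sx == 0 or sy == 0 else float(np.corrcoef(xc, yc)[0, 1])
        ss_tot = np.sum((xc - xc.mean()) ** 2)
        r2 = np.nan if ss_tot == 0 else float(1.0 - np.sum((yc - xc) ** 2) / ss_tot)
        rows.append({"channel": c, "pearson_r": r, "r_squared": r2})
    return pd.DataFrame(rows)
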