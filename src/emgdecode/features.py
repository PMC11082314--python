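"""Time-domain feature set for single-channel EMG epochs.

Eleven features per channel: mean absolute value (MAV), root mean square
(RMS), maximum absolute amplitude (MAA), waveform length (WL),
zero-crossings (ZC), slope-sign changes (SSC), Wilson amplitude (WA),
maximum fractal length (MFL), kurtosis (KRT), Hurst exponent (HUR, rescaled
range) and sample entropy (SEN). Concatenated over the E channels of an
epoch they form the feature vector consumed by the logistic-regression
baseline pipeline.

Conventions worth noting:

* the sign function is three-valued with sgn(0) = 0;
* ZC, SSC and WA are *signed* sums of sign terms, exactly as printed in the
  EMG literature this set is drawn from — they can be negative on monotone
  segments;
* WA thresholds on the per-epoch standard deviation, and SEN's tolerance is
  x_std / 10, which makes both gain-invariant;
* MFL is log10 of the summed squared first differences;
* SEN uses embedding m = 2 with template-extension length m + 1 = 3,
  Chebyshev distance, self-matches excluded.
"""

from __future__ import annotations

import warnings

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, TransformerMixin

FEATURE_NAMES = (
    "MAV",
    "RMS",
    "MAA",
    "WL",
    "ZC",
    "SSC",
    "WA",
    "MFL",
    "KRT",
    "HUR",
    "SEN",
)


class DegenerateInputError(ValueError):
    """Raised when an epoch has no variance (KRT/SEN undefined)."""


def sgn(x):
    """Three-valued sign function with sgn(0) = 0."""
    return np.sign(x)


def td_features(x: np.ndarray) -> dict[str, float]:
    """The nine closed-form time-domain features of one channel epoch.

    Parameters
    ----------
    x : 1-D array, length N >= 3, nonzero variance (required for kurtosis).
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    xbar = x.mean()
    xstd = np.sqrt(np.mean((x - xbar) ** 2))
    if xstd == 0:
        raise DegenerateInputError("zero-variance epoch: kurtosis undefined")
    dx = np.diff(x)
    return {
        "MAV": float(np.mean(np.abs(x))),
        "RMS": float(np.sqrt(np.mean(x**2))),
        "MAA": float(np.max(np.abs(x))),
        "WL": float(np.sum(np.abs(dx))),
        "ZC": float(np.sum(sgn(-x[:-1] * x[1:]))),
        "SSC": float(np.sum(sgn(-dx[1:] * dx[:-1]))),
        "WA": float(np.sum(sgn(np.abs(dx) - xstd))),
        "MFL": float(np.log10(np.sum(dx**2))),
        "KRT": float(np.mean((x - xbar) ** 4) / xstd**4),
    }


def sample_entropy(x: np.ndarray, m: int = 2, tolerance: float | None = None) -> float:
    """Sample entropy -ln(A/B) with Chebyshev distance, self-matches excluded.

    ``B`` counts template pairs of length ``m`` within ``tolerance``, ``A``
    the same for length ``m + 1``; both use the N - m templates whose
    (m+1)-extension exists, the standard pairing. ``tolerance`` defaults to
    one tenth of the (population) standard deviation.

    Returns ``inf`` with a warning when no extended pair matches (A = 0),
    and raises on zero variance or when B = 0 cannot even be formed.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n <= m + 1:
        raise ValueError(f"need more than m+1={m + 1} samples, got {n}")
    if tolerance is None:
        xstd = np.sqrt(np.mean((x - x.mean()) ** 2))
        if xstd == 0:
            raise DegenerateInputError("zero-variance epoch: tolerance undefined")
        tolerance = xstd / 10.0
    # N - m templates of each length, so every m-template has an extension
    tm = sliding_window_view(x, m)[: n - m]
    tm1 = sliding_window_view(x, m + 1)
    b = int(np.count_nonzero(pdist(tm, metric="chebyshev") <= tolerance))
    a = int(np.count_nonzero(pdist(tm1, metric="chebyshev") <= tolerance))
    if b == 0:
        warnings.warn("sample entropy: no length-m template pairs matched")
        return float("inf")
    if a == 0:
        warnings.warn("sample entropy: no length-(m+1) template pairs matched")
        return float("inf")
    return float(-np.log(a / b))


def hurst_rescaled_range(x: np.ndarray, min_window: int = 8) -> float:
    """Hurst exponent via the rescaled-range (R/S) procedure.

    The window ladder is dyadic: n = min_window, 2*min_window, ..., N // 2.
    For each n the series is cut into floor(N/n) non-overlapping blocks;
    R/S is the range of the mean-adjusted cumulative sum over the block
    standard deviation, averaged over blocks. The estimate is the
    least-squares slope of log(R/S) against log(n).
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 8 * min_window:
        raise ValueError(f"need at least {8 * min_window} samples, got {n}")
    if np.all(x == x[0]):
        raise DegenerateInputError("constant input: R/S undefined")
    sizes = []
    w = min_window
    while w <= n // 2:
        sizes.append(w)
        w *= 2
    log_n, log_rs = [], []
    for w in sizes:
        k = n // w
        blocks = x[: k * w].reshape(k, w)
        centered = blocks - blocks.mean(axis=1, keepdims=True)
        y = np.cumsum(centered, axis=1)
        r = y.max(axis=1) - y.min(axis=1)
        s = blocks.std(axis=1)
        ok = s > 0
        if not ok.any():
            continue
        log_n.append(np.log(w))
        log_rs.append(np.log(np.mean(r[ok] / s[ok])))
    if len(log_n) < 2:
        raise DegenerateInputError("too few usable R/S points")
    slope = np.polyfit(log_n, log_rs, 1)[0]
    return float(slope)


def channel_features(x: np.ndarray) -> np.ndarray:
    """All 11 features of one channel, ordered as FEATURE_NAMES."""
    vals = td_features(x)
    vals["HUR"] = hurst_rescaled_range(x)
    vals["SEN"] = sample_entropy(x)
    return np.array([vals[k] for k in FEATURE_NAMES])


def feature_names(n_channels: int) -> list[str]:
    return [f"ch{e}_{f}" for e in range(n_channels) for f in FEATURE_NAMES]


def featurize_epochs(data: np.ndarray) -> np.ndarray:
    """Feature matrix (N, E*11) for an (N, E, S) epoch array.

    Rows whose epoch is degenerate (zero variance on some channel) are
    filled with NaN and reported with a warning rather than aborting the
    whole batch.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("expected N x E x S array")
    n, e, _ = data.shape
    out = np.empty((n, e * len(FEATURE_NAMES)))
    bad = []
    for i in range(n):
        try:
            out[i] = np.concatenate([channel_features(data[i, c]) for c in range(e)])
        except DegenerateInputError:
            out[i] = np.nan
            bad.append(i)
    if bad:
        warnings.warn(f"degenerate epochs masked with NaN: {bad}")
    return out


def featurize_epochset(epochs) -> "pandas.DataFrame":  # noqa: F821
    """Named feature table for an EpochSet."""
    import pandas as pd

    mat = featurize_epochs(epochs.data)
    return pd.DataFrame(mat, columns=feature_names(epochs.n_channels))


class TimeDomainFeatures(BaseEstimator, TransformerMixin):
    """Stateless transformer: (N, E, S) epochs -> (N, E*11) feature matrix."""

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 3:
            raise ValueError("expected N x E x S array")
        self.n_features_in_ = X.shape[1] * len(FEATURE_NAMES)
        return self

    def transform(self, X):
        return featurize_epochs(X)

    def get_feature_names_out(self, input_features=None):
        n_channels = self.n_features_in_ // len(FEATURE_NAMES)
        return np.array(feature_names(n_channels))
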