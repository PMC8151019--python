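"""The force-invariant feature set: log spectral moments + channel correlations.

Per channel, seven scalars are computed in the time domain — the mean
absolute value MV, the even power-spectral moments P0, P2, P4, P6 (sums of
squared repeated first differences, equal to frequency-weighted sums of the
power spectral density by Parseval's theorem), and the first/second average
amplitude changes AC1, AC2 — and each is mapped through the natural
logarithm to give f1..f7.  The log turns the multiplicative amplitude gain
that accompanies a stronger contraction into an additive offset, and
compresses the dynamic range so low-force windows are as discriminable as
high-force ones.

On top of the per-channel block, the Pearson correlation coefficient of
every unordered channel pair is appended.  Correlation is invariant to
per-channel gain, so this block reflects only *which* muscles co-activate —
the spatial pattern of a gesture — and not how hard they contract.  For n
channels the vector has length ``7 n + n (n - 1) / 2`` (84 for n = 8).
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from ..signal_io import Window

#: default floor inside the logarithm, keeps silent windows finite
LOG_FLOOR = 1e-12

#: per-channel feature names in vector order (f1..f7 are their logs)
CHANNEL_FEATURES = ("mv", "p0", "p2", "p4", "p6", "ac1", "ac2")


def power_spectrum_moment(x: np.ndarray, order: int) -> float:
    """Even power-spectral moment of a single channel, order in {0, 2, 4, 6}.

    Computed in the time domain as the sum of squares of the
    ``order / 2``-times repeatedly differenced signal; the sum runs over
    the entries that are actually defined (N - order/2 of them).
    """
    if order not in (0, 2, 4, 6):
        raise ValueError(f"order must be one of 0, 2, 4, 6, got {order}")
    x = np.asarray(x, dtype=float).ravel()
    k = order // 2
    if x.size < k + 1:
        raise ValueError(f"need at least {k + 1} samples for order {order}")
    d = np.diff(x, n=k) if k else x
    return float(np.sum(d * d))


def amplitude_change(x: np.ndarray, order: int) -> float:
    """Mean absolute value of the order-th difference (order 1 or 2).

    Denominator N-1 for the first difference and N-2 for the second,
    i.e. the mean over the defined difference entries.
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    x = np.asarray(x, dtype=float).ravel()
    if x.size < order + 1:
        raise ValueError(f"need at least {order + 1} samples for order {order}")
    return float(np.mean(np.abs(np.diff(x, n=order))))


def mean_value(x: np.ndarray) -> float:
    """Mean absolute value of the channel, a signal-strength measure."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(x)))


def log_transform(v: float, floor: float = LOG_FLOOR) -> float:
    """Natural log with a configurable floor: ``ln(max(v, floor))``."""
    if v < 0:
        raise ValueError(f"log feature requires a nonnegative value, got {v}")
    return math.log(max(v, floor))


def correlation_coefficient(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length channels.

    Returns 0 with a warning if either channel has zero variance.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"channel length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    dx = x - x.mean()
    dy = y - y.mean()
    den = math.sqrt(float(np.sum(dx * dx)) * float(np.sum(dy * dy)))
    if den == 0.0:
        warnings.warn("zero-variance channel in correlation; returning 0", stacklevel=2)
        return 0.0
    return float(np.clip(np.sum(dx * dy) / den, -1.0, 1.0))


def channel_pairs(n: int) -> list[tuple[int, int]]:
    """Unordered channel pairs in fixed lexicographic order (0-based)."""
    return [(i, j) for i in range(n - 1) for j in range(i + 1, n)]


def _channel_features(ch: np.ndarray) -> list[float]:
    return [
        mean_value(ch),
        power_spectrum_moment(ch, 0),
        power_spectrum_moment(ch, 2),
        power_spectrum_moment(ch, 4),
        power_spectrum_moment(ch, 6),
        amplitude_change(ch, 1),
        amplitude_change(ch, 2),
    ]


def extract(window: Window, log: bool = True, floor: float = LOG_FLOOR) -> np.ndarray:
    """Full feature vector of a (preprocessed) window.

    Channel-major block of f1..f7 = ln(MV, P0, P2, P4, P6, AC1, AC2)
    followed by the correlation of every unordered channel pair; with
    ``log=False`` the raw un-logged scalars are used instead (the
    comparison condition of the scatter-plot experiments).
    """
    X = window.samples
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 channels for the correlation block")
    values: list[float] = []
    for ch in X:
        feats = _channel_features(ch)
        if log:
            feats = [log_transform(v, floor) for v in feats]
        values.extend(feats)
    for i, j in channel_pairs(n):
        values.append(correlation_coefficient(X[i], X[j]))
    return np.asarray(values, dtype=float)


def feature_dim(n_channels: int) -> int:
    """Vector length: 7 per channel plus one per unordered pair."""
    return 7 * n_channels + n_channels * (n_channels - 1) // 2


def feature_names(n_channels: int, log: bool = True) -> list[str]:
    prefix = "f" if log else ""
    names = []
    for c in range(1, n_channels + 1):
        for k, base in enumerate(CHANNEL_FEATURES, start=1):
            names.append(f"ch{c}_f{k}" if log else f"ch{c}_{base}")
    names.extend(f"cc_{i + 1}_{j + 1}" for i, j in channel_pairs(n_channels))
    return names
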