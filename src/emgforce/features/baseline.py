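"""Six classical EMG feature sets used as comparison baselines.

TD       Hudgins time-domain set: MAV, waveform length, zero crossings,
         slope-sign changes (4 per channel).
TDF      extended time-domain set: integrated EMG, waveform length,
         variance, ZC, SSC, Wilson amplitude (6 per channel).
AR_RMS   order-6 autoregressive coefficients (Burg) + RMS (7 per channel).
TDPSD    time-dependent power-spectrum descriptors: root-squared moments
         m0, m0-m2, m0-m4, sparseness, irregularity factor, waveform-length
         ratio, fused between the raw and log-squared signal paths
         (6 per channel).
TSD      temporal-spatial descriptors: seven log descriptors (root-squared
         moments, sparseness, irregularity factor, coefficient of
         variation, Teager-Kaiser energy) on every channel *and* on every
         pairwise channel difference Cx - Cy.
WAVELET  energy, variance, standard deviation, waveform length and Shannon
         entropy of the six subbands of a 5-level Symmlet-8 decomposition
         (30 per channel).

Expected dimensions for 8 channels: TD 32, TDF 48, AR_RMS 56, TDPSD 48,
TSD 252, WAVELET 240.
"""

from __future__ import annotations

import warnings

import numpy as np
import pywt
from statsmodels.regression.linear_model import burg

from ..signal_io import Window
from .invariant import channel_pairs

_EPS = 1e-12

METHODS = ("TD", "TDF", "AR_RMS", "TDPSD", "TSD", "WAVELET")


# ---------------------------------------------------------------- primitives

def waveform_length(x: np.ndarray) -> float:
    return float(np.sum(np.abs(np.diff(x))))


def zero_crossings(x: np.ndarray, threshold: float = 0.0) -> int:
    """Sign alternations whose amplitude jump exceeds the threshold."""
    x = np.asarray(x, dtype=float)
    return int(np.sum((x[:-1] * x[1:] < 0) & (np.abs(np.diff(x)) >= threshold)))


def slope_sign_changes(x: np.ndarray, threshold: float = 0.0) -> int:
    """Local extrema whose two adjacent slopes both exceed the threshold."""
    x = np.asarray(x, dtype=float)
    left = x[1:-1] - x[:-2]
    right = x[1:-1] - x[2:]
    return int(np.sum(left * right > threshold))


def wilson_amplitude(x: np.ndarray, threshold: float) -> int:
    """Successive-difference magnitudes exceeding the threshold."""
    return int(np.sum(np.abs(np.diff(np.asarray(x, dtype=float))) > threshold))


def root_squared_moment(x: np.ndarray, order: int) -> float:
    """sqrt of the order-th time-domain spectral moment (order 0, 2 or 4)."""
    if order not in (0, 2, 4):
        raise ValueError(f"order must be 0, 2 or 4, got {order}")
    d = np.diff(np.asarray(x, dtype=float), n=order // 2) if order else np.asarray(x, float)
    return float(np.sqrt(np.sum(d * d)))


def teager_kaiser_energy(x: np.ndarray) -> float:
    """Summed Teager-Kaiser energy operator x[i]^2 - x[i-1] x[i+1]."""
    x = np.asarray(x, dtype=float)
    return float(np.sum(x[1:-1] ** 2 - x[:-2] * x[2:]))


# --------------------------------------------------------------- extractors

def extract_td(w: Window, threshold: float = 0.0) -> np.ndarray:
    out = []
    for ch in w.samples:
        out += [
            float(np.mean(np.abs(ch))),
            waveform_length(ch),
            zero_crossings(ch, threshold),
            slope_sign_changes(ch, threshold),
        ]
    return np.asarray(out, dtype=float)


def extract_tdf(w: Window, wamp_threshold: float = 0.01, threshold: float = 0.0) -> np.ndarray:
    out = []
    for ch in w.samples:
        out += [
            float(np.sum(np.abs(ch))),
            waveform_length(ch),
            float(np.var(ch)),
            zero_crossings(ch, threshold),
            slope_sign_changes(ch, threshold),
            wilson_amplitude(ch, wamp_threshold),
        ]
    return np.asarray(out, dtype=float)


def extract_ar_rms(w: Window, ar_order: int = 6) -> np.ndarray:
    """Burg AR coefficients + RMS per channel."""
    out = []
    for i, ch in enumerate(w.samples):
        rms = float(np.sqrt(np.mean(ch**2)))
        if np.std(ch) == 0.0:
            coefs = np.zeros(ar_order)
        else:
            try:
                coefs, _ = burg(ch, order=ar_order, demean=True)
            except Exception as exc:
                raise ValueError(f"AR estimation failed on channel {i + 1}") from exc
        out += list(np.asarray(coefs, dtype=float)) + [rms]
    return np.asarray(out, dtype=float)


def _compressed_moments(x: np.ndarray) -> tuple[float, float, float]:
    """Root-squared moments m0, m2, m4 after power-law compression (lambda=0.1)."""
    m0 = root_squared_moment(x, 0) ** 0.1 / 0.1
    m2 = root_squared_moment(x, 2) ** 0.1 / 0.1
    m4 = root_squared_moment(x, 4) ** 0.1 / 0.1
    return m0, m2, m4


def _tdpsd_descriptors(x: np.ndarray) -> np.ndarray:
    """Six log-magnitude descriptors of one signal path."""
    m0, m2, m4 = _compressed_moments(x)
    d1 = np.diff(x)
    d2 = np.diff(d1)
    sparseness = m0 / (np.sqrt(np.abs((m0 - m2) * (m0 - m4))) + _EPS)
    irregularity = m2 / (np.sqrt(m0 * m4) + _EPS)
    wl_ratio = np.sum(np.abs(d1)) / (np.sum(np.abs(d2)) + _EPS)
    feats = np.array([m0, m0 - m2, m0 - m4, sparseness, irregularity, wl_ratio])
    return np.log(np.abs(feats) + _EPS)


def extract_tdpsd(w: Window) -> np.ndarray:
    """Orientation between descriptors of the raw and log-squared signal."""
    out = []
    for ch in w.samples:
        a = _tdpsd_descriptors(ch)
        b = _tdpsd_descriptors(np.log(ch**2 + _EPS))
        den = a**2 + b**2
        fused = np.where(den > 0, -2.0 * a * b / (den + _EPS), 0.0)
        out.append(fused)
    return np.concatenate(out)


def _tsd_descriptors(x: np.ndarray) -> np.ndarray:
    """Seven log descriptors of one signal (channel or channel difference)."""
    m0, m2, m4 = _compressed_moments(x)
    sparseness = m0 / (np.sqrt(np.abs((m0 - m2) * (m0 - m4))) + _EPS)
    irregularity = m2 / (np.sqrt(m0 * m4) + _EPS)
    cov = float(np.std(x)) / (np.abs(np.mean(x)) + _EPS)
    tke = teager_kaiser_energy(x)
    feats = np.array([m0, m0 - m2, m0 - m4, sparseness, irregularity, cov, tke])
    return np.log(np.abs(feats) + _EPS)


def extract_tsd(w: Window) -> np.ndarray:
    X = w.samples
    if X.shape[0] < 2:
        raise ValueError("TSD needs at least 2 channels")
    blocks = [_tsd_descriptors(ch) for ch in X]
    blocks += [_tsd_descriptors(X[i] - X[j]) for i, j in channel_pairs(X.shape[0])]
    return np.concatenate(blocks)


def _subband_stats(c: np.ndarray) -> list[float]:
    energy = float(np.sum(c**2))
    if energy > 0:
        p = c**2 / energy
        p = p[p > 0]
        entropy = float(-np.sum(p * np.log(p)))
    else:
        entropy = 0.0
    return [
        energy,
        float(np.var(c)),
        float(np.std(c)),
        waveform_length(c) if c.size > 1 else 0.0,
        entropy,
    ]


def extract_wavelet(w: Window, wavelet: str = "sym8", levels: int = 5) -> np.ndarray:
    """Five statistics on each subband of an orthogonal multilevel DWT.

    Periodized transform, so the subband energies sum exactly to the
    signal energy.
    """
    if w.n < 2**levels:
        raise ValueError(f"window of {w.n} samples too short for {levels} levels")
    out = []
    for ch in w.samples:
        with warnings.catch_warnings():
            # boundary effects on short windows are expected and accepted
            warnings.filterwarnings("ignore", message="Level value", category=UserWarning)
            coeffs = pywt.wavedec(ch, wavelet, level=levels, mode="periodization")
        for c in coeffs:  # approximation + `levels` detail subbands
            out += _subband_stats(np.asarray(c, dtype=float))
    return np.asarray(out, dtype=float)


_EXTRACTORS = {
    "TD": extract_td,
    "TDF": extract_tdf,
    "AR_RMS": extract_ar_rms,
    "TDPSD": extract_tdpsd,
    "TSD": extract_tsd,
    "WAVELET": extract_wavelet,
}

_PER_CHANNEL_NAMES = {
    "TD": ("mav", "wl", "zc", "ssc"),
    "TDF": ("iemg", "wl", "var", "zc", "ssc", "wamp"),
    "AR_RMS": ("ar1", "ar2", "ar3", "ar4", "ar5", "ar6", "rms"),
    "TDPSD": ("m0", "m0m2", "m0m4", "sparse", "irreg", "wlr"),
}


def extract_baseline(w: Window, method: str, **params) -> np.ndarray:
    """Dispatch to one of the six baseline extractors by name."""
    key = method.upper().replace("-", "_")
    if key not in _EXTRACTORS:
        raise ValueError(f"unknown baseline method {method!r}; choose from {METHODS}")
    return _EXTRACTORS[key](w, **params)


def feature_dim(method: str, n_channels: int) -> int:
    """Closed-form output dimension of a baseline method for n channels."""
    key = method.upper().replace("-", "_")
    n = n_channels
    dims = {
        "TD": 4 * n,
        "TDF": 6 * n,
        "AR_RMS": 7 * n,
        "TDPSD": 6 * n,
        "TSD": 7 * (n + n * (n - 1) // 2),
        "WAVELET": 5 * 6 * n,
    }
    if key not in dims:
        raise ValueError(f"unknown baseline method {method!r}")
    return dims[key]


def feature_names(method: str, n_channels: int) -> list[str]:
    key = method.upper().replace("-", "_")
    tag = key.lower()
    names: list[str] = []
    if key in _PER_CHANNEL_NAMES:
        for c in range(1, n_channels + 1):
            names += [f"{tag}_ch{c}_{f}" for f in _PER_CHANNEL_NAMES[key]]
    elif key == "TSD":
        sigs = [f"ch{c}" for c in range(1, n_channels + 1)]
        sigs += [f"d{i + 1}_{j + 1}" for i, j in channel_pairs(n_channels)]
        feats = ("m0", "m0m2", "m0m4", "sparse", "irreg", "cov", "tke")
        for s in sigs:
            names += [f"{tag}_{s}_{f}" for f in feats]
    elif key == "WAVELET":
        bands = ("a5", "d5", "d4", "d3", "d2", "d1")
        stats = ("energy", "var", "std", "wl", "entropy")
        for c in range(1, n_channels + 1):
            for b in bands:
                names += [f"{tag}_ch{c}_{b}_{s}" for s in stats]
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    return names
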