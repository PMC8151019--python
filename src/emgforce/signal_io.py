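"""Trial containers, overlapped windowing, and the preprocessing filter cascade.

A *trial* is one multichannel surface-EMG recording of a subject holding a
gesture at one force level.  Trials are cut into overlapped rectangular
windows (the unit of feature extraction) and each window is passed through a
cascade of causal digital filters: 20 Hz high-pass (movement artefact),
500 Hz low-pass (high-frequency noise) and a 50 Hz notch (power line).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.io import loadmat

logger = logging.getLogger(__name__)

#: canonical force-level ordering used throughout the package
FORCES = ("low", "medium", "high")

#: filename convention for on-disk trial recordings
TRIAL_FILENAME_RE = re.compile(
    r"(?P<subject>[^_]+)_g(?P<gesture>\d+)_(?P<force>low|medium|high)_t(?P<trial>\d+)\.mat$"
)


@dataclass
class Trial:
    """One multichannel EMG recording with its condition labels.

    ``samples`` is a ``(channels, time)`` float array; amplitudes are in
    volts or arbitrary units — every feature downstream is either
    scale-covariant or scale-invariant, so the unit does not matter.
    """

    samples: np.ndarray
    fs: float
    subject_id: str
    gesture: int
    force: str
    trial_index: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, time) matrix")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.force not in FORCES:
            raise ValueError(f"unknown force level {self.force!r}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Window:
    """A fixed-length multichannel segment cut from a trial.

    Inherits the parent trial's labels; ``start_index`` is the 0-based
    sample offset of the window within the trial (inclusive start,
    exclusive end).
    """

    samples: np.ndarray
    fs: float
    subject_id: str
    gesture: int
    force: str
    trial_index: int
    start_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, N) matrix")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n(self) -> int:
        """Window length in samples."""
        return self.samples.shape[1]


@dataclass(frozen=True)
class FilterSpec:
    """Cascaded preprocessing filters: high-pass -> low-pass -> notch.

    Butterworth high/low-pass stages of the given order plus a second-order
    IIR notch with quality factor ``notch_q``.  Applied causally (single
    forward pass) per channel, consistent with a real-time pipeline.
    """

    highpass_hz: float = 20.0
    lowpass_hz: float = 500.0
    notch_hz: float = 50.0
    order: int = 4
    notch_q: float = 30.0

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if not (0 < self.highpass_hz < self.lowpass_hz < nyq):
            raise ValueError(
                f"filter cutoffs ({self.highpass_hz}, {self.lowpass_hz}) Hz "
                f"must satisfy 0 < highpass < lowpass < fs/2 = {nyq} Hz"
            )
        if not (0 < self.notch_hz < nyq):
            raise ValueError(f"notch frequency {self.notch_hz} Hz must be below Nyquist")

    def sos(self, fs: float) -> np.ndarray:
        """Second-order-section representation of the whole cascade."""
        self.validate(fs)
        return _design_cascade(self, float(fs))

    def frequency_response(self, fs: float, freqs: np.ndarray) -> np.ndarray:
        """Complex response of the cascade at the given frequencies (Hz)."""
        _, h = sps.sosfreqz(self.sos(fs), worN=np.asarray(freqs, dtype=float), fs=fs)
        return h


@lru_cache(maxsize=32)
def _design_cascade(spec: FilterSpec, fs: float) -> np.ndarray:
    hp = sps.butter(spec.order, spec.highpass_hz, btype="highpass", fs=fs, output="sos")
    lp = sps.butter(spec.order, spec.lowpass_hz, btype="lowpass", fs=fs, output="sos")
    b, a = sps.iirnotch(spec.notch_hz, spec.notch_q, fs=fs)
    notch = sps.tf2sos(b, a)
    return np.vstack([hp, lp, notch])


def segment_windows(
    trial: Trial,
    window_ms: float = 150.0,
    overlap_ms: float = 50.0,
    step_ms: float | None = None,
) -> list[Window]:
    """Cut a trial into overlapped rectangular windows.

    Window starts advance by ``window_ms - overlap_ms`` (or by an explicit
    ``step_ms``, which permits steps larger than the window, i.e. gaps).
    Only complete windows are returned, in temporal order.  A trial shorter
    than one window yields an empty list with a logged warning.
    """
    n = int(round(window_ms * trial.fs / 1000.0))
    if step_ms is None:
        if overlap_ms >= window_ms:
            raise ValueError("overlap must be shorter than the window")
        step = int(round((window_ms - overlap_ms) * trial.fs / 1000.0))
    else:
        step = int(round(step_ms * trial.fs / 1000.0))
    if step < 1:
        raise ValueError("window step must be at least one sample")
    if trial.n_samples < n:
        logger.warning(
            "trial %s g%d %s t%d (%d samples) shorter than one %d-sample window",
            trial.subject_id, trial.gesture, trial.force, trial.trial_index,
            trial.n_samples, n,
        )
        return []
    return [
        Window(
            samples=trial.samples[:, s : s + n],
            fs=trial.fs,
            subject_id=trial.subject_id,
            gesture=trial.gesture,
            force=trial.force,
            trial_index=trial.trial_index,
            start_index=s,
        )
        for s in range(0, trial.n_samples - n + 1, step)
    ]


def preprocess_window(window: Window, spec: FilterSpec | None = None) -> Window:
    """Apply the filter cascade to every channel of a window (causally)."""
    spec = spec or FilterSpec()
    sos = spec.sos(window.fs)
    filtered = sps.sosfilt(sos, window.samples, axis=1)
    return replace(window, samples=filtered)


def load_dataset(
    path: str | Path,
    channel_limit: int = 8,
    max_trials: int = 5,
    var: str = "emg",
    fs_var: str = "fs",
    default_fs: float = 2000.0,
    filename_re: re.Pattern = TRIAL_FILENAME_RE,
) -> list[Trial]:
    """Load a directory of per-trial MAT recordings.

    Each file holds one trial matrix (samples in rows, channels in columns)
    under variable ``var``; subject / gesture / force / trial labels are
    parsed from the filename.  Only the first ``channel_limit`` channels and
    the first ``max_trials`` trials per gesture x force are retained.
    """
    path = Path(path)
    files = sorted(path.glob("*.mat"))
    if not files:
        raise FileNotFoundError(f"no MAT recordings found in {path}")
    trials: list[Trial] = []
    for f in files:
        m = filename_re.search(f.name)
        if m is None:
            raise ValueError(f"cannot parse trial labels from filename {f.name!r}")
        try:
            data = loadmat(f)
        except Exception as exc:  # pragma: no cover - corrupt file path
            raise ValueError(f"unreadable MAT file {f}") from exc
        if var not in data:
            raise ValueError(f"variable {var!r} missing from {f}")
        trial_index = int(m["trial"])
        if trial_index > max_trials:
            continue
        arr = np.asarray(data[var], dtype=float)
        fs = float(np.squeeze(data[fs_var])) if fs_var in data else default_fs
        trials.append(
            Trial(
                samples=arr.T[:channel_limit],
                fs=fs,
                subject_id=str(m["subject"]),
                gesture=int(m["gesture"]),
                force=str(m["force"]),
                trial_index=trial_index,
            )
        )
    return trials


def write_manifest(trials: list[Trial], path: str | Path) -> None:
    """Write a CSV manifest (one row per trial) describing a dataset."""
    import pandas as pd

    rows = [
        {
            "subject": t.subject_id,
            "gesture": t.gesture,
            "force": t.force,
            "trial_index": t.trial_index,
            "n_channels": t.n_channels,
            "n_samples": t.n_samples,
            "fs": t.fs,
        }
        for t in trials
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
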