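"""Synthetic multichannel surface-EMG generator.

Each gesture is modelled by a fixed channels x sources *mixing matrix*:
band-limited (20-450 Hz) Gaussian latent sources, standing in for the
activity of the underlying muscle groups, are mixed into the electrode
channels, scaled by a force-level gain, and corrupted by independent
broadband sensor noise.  Because the force gain multiplies every channel of
the mixed signal equally, the inter-channel correlation structure of a
gesture is (up to sensor noise) identical across force levels while every
amplitude-covariant feature grows with force — exactly the structure a
force-invariant feature set is designed to exploit.  Subjects are modelled
as jittered copies of the shared gesture profiles.

The generated grid mirrors the reference recording protocol: 9 subjects x
6 gestures x 3 forces x 5 trials of 8-channel EMG sampled at 2000 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.io import savemat

from .signal_io import FORCES, Trial


@dataclass
class SynthConfig:
    """Generator configuration; defaults emulate the reference protocol."""

    n_subjects: int = 9
    n_gestures: int = 6
    n_trials: int = 5
    n_channels: int = 8
    n_sources: int = 4
    duration_s: float = 10.0
    fs: float = 2000.0
    band: tuple[float, float] = (20.0, 450.0)
    force_gains: dict = field(default_factory=lambda: {"low": 1.0, "medium": 2.0, "high": 3.5})
    noise_level: float = 0.03
    subject_jitter: float = 0.1
    #: sd of the per-trial lognormal gain jitter (imperfect force maintenance)
    trial_gain_sd: float = 0.15
    #: sd of the slow within-trial lognormal amplitude drift
    drift_sd: float = 0.2
    #: bandwidth of the drift envelope in Hz
    drift_hz: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        gains = [self.force_gains[f] for f in FORCES]
        if not all(a < b for a, b in zip(gains, gains[1:])):
            raise ValueError("force gains must be strictly increasing low < medium < high")
        lo, hi = self.band
        if not (0 < lo < hi < self.fs / 2):
            raise ValueError("band must lie within (0, fs/2)")
        if self.duration_s <= 0 or self.n_channels < 2:
            raise ValueError("need positive duration and at least 2 channels")


def _band_sos(cfg: SynthConfig) -> np.ndarray:
    return sps.butter(4, cfg.band, btype="bandpass", fs=cfg.fs, output="sos")


def gesture_profiles(cfg: SynthConfig) -> list[np.ndarray]:
    """The shared per-gesture mixing matrices (channels x sources).

    Each gesture gets an independent random mixing matrix shaped by a
    per-channel activation envelope, so both the per-channel activation
    weights and the induced correlation structure differ between gestures.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    profiles = []
    for _ in range(cfg.n_gestures):
        envelope = rng.uniform(0.3, 1.5, size=cfg.n_channels)
        mix = rng.normal(size=(cfg.n_channels, cfg.n_sources)) / np.sqrt(cfg.n_sources)
        profiles.append(envelope[:, None] * mix)
    return profiles


def generate_trial(profile: np.ndarray, gain: float, cfg: SynthConfig, seed) -> np.ndarray:
    """One trial's sample matrix (channels x time); deterministic per seed.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`.  With
    the same seed, changing only the gain rescales the mixed signal exactly
    (sources and sensor noise are redrawn identically).
    """
    rng = np.random.default_rng(seed)
    n_samples = int(round(cfg.duration_s * cfg.fs))
    sources = rng.standard_normal((profile.shape[1], n_samples))
    sources = sps.sosfiltfilt(_band_sos(cfg), sources, axis=1)
    noise = cfg.noise_level * rng.standard_normal((profile.shape[0], n_samples))
    # Imperfect force maintenance: a subject tracking a nominal force level
    # produces a slowly drifting, trial-dependent amplitude.  Both effects are
    # multiplicative and common to all channels, so correlations are untouched.
    trial_factor = float(np.exp(cfg.trial_gain_sd * rng.standard_normal()))
    envelope = np.ones(n_samples)
    if cfg.drift_sd > 0:
        slow = sps.sosfiltfilt(
            sps.butter(2, cfg.drift_hz, btype="lowpass", fs=cfg.fs, output="sos"),
            rng.standard_normal(n_samples),
        )
        sd = slow.std()
        if sd > 0:
            envelope = np.exp(cfg.drift_sd * slow / sd)
    return gain * trial_factor * envelope * (profile @ sources) + noise


def generate_dataset(cfg: SynthConfig) -> list[Trial]:
    """The full subject x gesture x force x trial grid of synthetic trials."""
    base_profiles = gesture_profiles(cfg)
    trials: list[Trial] = []
    for s in range(1, cfg.n_subjects + 1):
        jrng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202, s]))
        profiles = [
            p + cfg.subject_jitter * jrng.normal(size=p.shape) for p in base_profiles
        ]
        for g in range(1, cfg.n_gestures + 1):
            for fi, force in enumerate(FORCES):
                gain = cfg.force_gains[force]
                for t in range(1, cfg.n_trials + 1):
                    seed = np.random.SeedSequence([cfg.seed, s, g, fi, t])
                    trials.append(
                        Trial(
                            samples=generate_trial(profiles[g - 1], gain, cfg, seed),
                            fs=cfg.fs,
                            subject_id=f"S{s}",
                            gesture=g,
                            force=force,
                            trial_index=t,
                        )
                    )
    return trials


def write_mat_dataset(trials: list[Trial], path: str | Path) -> list[Path]:
    """Write trials in the MAT layout the loader reads (samples x channels)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for t in trials:
        f = path / f"{t.subject_id}_g{t.gesture}_{t.force}_t{t.trial_index}.mat"
        savemat(f, {"emg": t.samples.T, "fs": t.fs})
        written.append(f)
    return written
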