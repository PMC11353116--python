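"""Signal conditioning ahead of feature extraction.

The chain, applied per recording: a mains notch filter (50 Hz) on every
channel, a 30–70 Hz Butterworth bandpass on the EMG, percentile clipping of
motion/EMG-contamination outliers in EEG and EM (0.01th / 99.99th
percentiles; values beyond the thresholds are set to the thresholds), and a
per-channel z-score ``(x - mean) / std``.

All filters are applied zero-phase (forward–backward), so epoch boundaries
are not phase-shifted. All stages are length-preserving and deterministic.
Normalization uses the population standard deviation (ddof=0) and is
computed per recording, so held-out subjects need no training-set
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .io_poly import ConfigurationError, Recording

__all__ = [
    "PreprocessConfig",
    "notch_filter",
    "bandpass_emg",
    "clip_outliers",
    "zscore_normalize",
    "preprocess_recording",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable preprocessing parameters.

    Defaults follow standard rodent-biosignal practice: mains notch at
    50 Hz with quality factor 30, order-4 Butterworth 30–70 Hz EMG band,
    and 0.01 / 99.99 percentile clipping of EEG and EM outliers.
    """

    notch_hz: float = 50.0
    notch_q: float = 30.0
    emg_band_hz: tuple[float, float] = (30.0, 70.0)
    butter_order: int = 4
    clip_percentiles: tuple[float, float] = (0.01, 99.99)
    epsilon_std: float = 1e-12

    def __post_init__(self) -> None:
        lo, hi = self.clip_percentiles
        if not (0 <= lo < hi <= 100):
            raise ConfigurationError(
                f"clip percentiles must satisfy 0 <= lo < hi <= 100, got {lo},{hi}"
            )
        b_lo, b_hi = self.emg_band_hz
        if not (0 < b_lo < b_hi):
            raise ConfigurationError(f"bad EMG band {self.emg_band_hz}")


def notch_filter(
    x: np.ndarray, fs: float, cfg: PreprocessConfig = PreprocessConfig()
) -> np.ndarray:
    """Zero-phase IIR notch removing mains interference at ``cfg.notch_hz``."""
    if fs <= 2 * cfg.notch_hz:
        raise ConfigurationError(
            f"sample rate {fs} Hz too low for a {cfg.notch_hz} Hz notch"
        )
    b, a = sps.iirnotch(cfg.notch_hz, cfg.notch_q, fs=fs)
    return sps.filtfilt(b, a, np.asarray(x, dtype=float))


def bandpass_emg(
    x: np.ndarray, fs: float, cfg: PreprocessConfig = PreprocessConfig()
) -> np.ndarray:
    """Zero-phase Butterworth bandpass restricting EMG to its muscle band."""
    lo, hi = cfg.emg_band_hz
    if fs <= 2 * hi:
        raise ConfigurationError(
            f"sample rate {fs} Hz too low for a {lo}-{hi} Hz bandpass"
        )
    sos = sps.butter(cfg.butter_order, (lo, hi), btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def clip_outliers(
    x: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()
) -> np.ndarray:
    """Clamp extreme-tail samples to the recording's empirical percentiles.

    Samples already inside [P_lower, P_upper] are unchanged. Percentiles
    use the inward order-statistic definition (``higher`` for the lower
    bound, ``lower`` for the upper), so both thresholds are actual data
    values and re-clipping a clipped signal changes nothing (exact
    idempotence, which interpolated percentiles cannot guarantee).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("clip_outliers: empty input")
    lo = np.percentile(x, cfg.clip_percentiles[0], method="higher")
    hi = np.percentile(x, cfg.clip_percentiles[1], method="lower")
    return np.clip(x, lo, hi)


def zscore_normalize(
    x: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()
) -> np.ndarray:
    """Standardize to zero mean and unit population standard deviation.

    A (near-)constant signal (std <= ``cfg.epsilon_std``) maps to all
    zeros rather than dividing by ~0.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("zscore_normalize: empty input")
    mu = x.mean()
    sigma = x.std(ddof=0)
    if sigma <= cfg.epsilon_std:
        return np.zeros_like(x)
    return (x - mu) / sigma


def preprocess_recording(
    rec: Recording, cfg: PreprocessConfig = PreprocessConfig()
) -> Recording:
    """Run the full conditioning chain on one recording.

    Order: notch all channels; EMG bandpass; clip EEG and EM outliers;
    z-score every channel. EM-absent recordings skip the EM steps.
    """
    fs = rec.sample_rate_hz
    eeg = notch_filter(rec.eeg, fs, cfg)
    emg = notch_filter(rec.emg, fs, cfg)
    emg = bandpass_emg(emg, fs, cfg)
    eeg = clip_outliers(eeg, cfg)
    eeg = zscore_normalize(eeg, cfg)
    emg = zscore_normalize(emg, cfg)
    em = None
    if rec.em is not None:
        em = notch_filter(rec.em, fs, cfg)
        em = clip_outliers(em, cfg)
        em = zscore_normalize(em, cfg)
    return replace(rec, eeg=eeg, emg=emg, em=em)
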