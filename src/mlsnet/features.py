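"""The ten expert features computed per 4-s epoch.

Ordered feature vector (fixed positions; the classifier and the EM null
mask both rely on this ordering):

==  =======================================  ==========================
f1  EEG delta power, 0.5–4 Hz                normalized-signal units²
f2  EEG theta power, 6–9 Hz                  units²
f3  EEG alpha power, 8–12 Hz                 units²
f4  EEG upper-gamma power, 52–70 Hz          units²
f5  theta/delta power ratio f2/f1            dimensionless
f6  EMG root-mean-square                     units
f7  EEG mean amplitude (mean |x|)            units
f8  EM mean amplitude (mean |x|)             units
f9  EM event frequency above the wake        Hz
    threshold A_wake
f10 EM event frequency above the REM         Hz
    threshold A_rem
==  =======================================  ==========================

Band power is the sum of squared DFT magnitudes over the bins whose
frequencies fall inside the band, averaged over the (configurable) number
of time windows per epoch — one rectangular window spanning the whole
epoch by default.

EM event features count upward threshold crossings per second. The
per-subject-population thresholds ``A_state = mean + 1.96*std`` are fit on
EM samples within wake-labelled (resp. REM-labelled) epochs of the
*fitting* data only (training folds in cross-validation), so no label
information leaks from held-out subjects.

Recordings without an EM channel get the null-mask value (0, the
column mean after standardization) in f8–f10; ``mask_em_features``
applies the same mask explicitly for the EM-exclusion ablation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_poly import (
    NREM,
    REM,
    WAKE,
    ConfigurationError,
    EpochedRecording,
    Hypnogram,
)

__all__ = [
    "BandSpec",
    "EMThresholds",
    "FeatureScaler",
    "FEATURE_NAMES",
    "EM_FEATURE_SLICE",
    "CANONICAL_BANDS",
    "EXTRA_BANDS",
    "spectral_power",
    "theta_delta_ratio",
    "rms",
    "mean_amplitude",
    "fit_em_thresholds",
    "em_event_frequency",
    "extract_features",
    "base_features",
    "em_rate_features",
    "mask_em_features",
]

FEATURE_NAMES = ("f1", "f2", "f3", "f4", "f5", "f6", "f7", "f8", "f9", "f10")

# Columns holding EM-derived features (f8, f9, f10) — the null-mask slice.
EM_FEATURE_SLICE = slice(7, 10)

# Ratio sentinel when delta power is exactly zero but theta is not.
RATIO_CAP = 1e6


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [f_low, f_high] in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_low < self.f_high):
            raise ConfigurationError(f"bad band {self}")


# The four bands of the canonical feature vector. The delta lower edge is
# 0.5 Hz by default (a 0.45 Hz variant exists in the literature and can be
# passed explicitly).
CANONICAL_BANDS = {
    "delta": BandSpec("delta", 0.5, 4.0),
    "theta": BandSpec("theta", 6.0, 9.0),
    "alpha": BandSpec("alpha", 8.0, 12.0),
    "upper_gamma": BandSpec("upper_gamma", 52.0, 70.0),
}

# Additional bands reported useful for wake/sleep discrimination; available
# to callers but not part of the canonical 10-feature vector.
EXTRA_BANDS = {
    "upper_theta": BandSpec("upper_theta", 7.0, 8.5),
    "broadband": BandSpec("broadband", 0.0, 30.0),
}


@dataclass(frozen=True)
class EMThresholds:
    """Per-fitting-population EM exceedance thresholds (mean + 1.96*std)."""

    a_wake: float
    a_rem: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a_wake) and np.isfinite(self.a_rem)):
            raise ValueError(f"non-finite EM thresholds: {self}")


class ThresholdFitError(ValueError):
    """The fitting data lacks a class needed to fit an EM threshold."""


# ---------------------------------------------------------------------------
# Per-epoch primitives


def spectral_power(
    x: np.ndarray, fs: float, band: BandSpec, n_windows: int = 1
) -> float:
    """Band power: sum of squared DFT magnitudes over in-band bins.

    The epoch is split into ``n_windows`` equal rectangular windows
    (default 1, i.e. a single DFT over the whole epoch); the per-window
    band sums are averaged.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("spectral_power: need at least 2 samples")
    if band.f_high > fs / 2 + 1e-9:
        raise ConfigurationError(
            f"band {band.name} [{band.f_low},{band.f_high}] exceeds Nyquist {fs / 2}"
        )
    if n_windows < 1 or x.size // n_windows < 2:
        raise ConfigurationError(f"invalid window count {n_windows}")
    wlen = x.size // n_windows
    segs = x[: n_windows * wlen].reshape(n_windows, wlen)
    spec = np.fft.rfft(segs, axis=1)
    freqs = np.fft.rfftfreq(wlen, d=1.0 / fs)
    in_band = (freqs >= band.f_low) & (freqs <= band.f_high)
    return float(np.mean(np.sum(np.abs(spec[:, in_band]) ** 2, axis=1)))


def theta_delta_ratio(p_theta: float, p_delta: float) -> float:
    """Theta/delta band-power ratio, elevated in REM sleep.

    Zero delta power with nonzero theta returns the capped sentinel
    ``RATIO_CAP``; 0/0 returns 0.
    """
    if p_delta < 0 or p_theta < 0:
        raise ValueError("band powers must be nonnegative")
    if p_delta == 0:
        return 0.0 if p_theta == 0 else RATIO_CAP
    return min(p_theta / p_delta, RATIO_CAP)


def rms(x: np.ndarray) -> float:
    """Root mean square, sqrt(mean(x^2))."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("rms: empty input")
    return float(np.sqrt(np.mean(x**2)))


def mean_amplitude(x: np.ndarray) -> float:
    """Mean absolute sample value (sign-free amplitude on zero-mean signals)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("mean_amplitude: empty input")
    return float(np.mean(np.abs(x)))


# ---------------------------------------------------------------------------
# EM thresholds and event counting


def fit_em_thresholds(
    em: np.ndarray,
    hypnogram: Hypnogram,
    fs: float,
    epoch_length_s: float,
) -> EMThresholds:
    """Fit A_wake and A_rem on a preprocessed EM signal with known labels.

    ``A_state = mean + 1.96*std`` over EM samples inside epochs labelled
    ``state``. The upper bound of the mean±1.96·std band is used because
    events are counted as *exceedances* of the threshold.

    ``em`` may be the concatenation of several subjects' EM signals with
    ``hypnogram`` the matching concatenated labels (the usual training-fold
    pooling).
    """
    em = np.asarray(em, dtype=float)
    spe = round(epoch_length_s * fs)
    n_epochs = min(len(hypnogram), em.size // spe)
    out = {}
    for state, attr in ((WAKE, "a_wake"), (REM, "a_rem")):
        idx = [i for i in range(n_epochs) if hypnogram.labels[i] == state]
        if not idx:
            raise ThresholdFitError(
                f"fitting data contains no {state} epochs; cannot fit EM threshold"
            )
        samples = np.concatenate([em[i * spe : (i + 1) * spe] for i in idx])
        out[attr] = float(samples.mean() + 1.96 * samples.std(ddof=0))
    return EMThresholds(**out)


def em_event_frequency(
    x: np.ndarray, threshold: float, epoch_length_s: float
) -> float:
    """Rate (Hz) of upward threshold crossings within one epoch.

    An upward crossing is a sample strictly above the threshold whose
    predecessor is at or below it; the first sample counts if already
    above (it begins an excursion).
    """
    if epoch_length_s <= 0:
        raise ValueError("epoch_length_s must be positive")
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return 0.0
    above = x > threshold
    crossings = int(above[0]) + int(np.sum(above[1:] & ~above[:-1]))
    return crossings / epoch_length_s


# ---------------------------------------------------------------------------
# Feature-matrix assembly


def base_features(ep: EpochedRecording, n_windows: int = 1) -> np.ndarray:
    """Threshold-independent columns f1–f8 for every epoch.

    f8 (EM mean amplitude) is 0 when the EM channel is absent.
    """
    n = ep.n_epochs
    fs = ep.sample_rate_hz
    out = np.zeros((n, 8))
    wlen = ep.samples_per_epoch // n_windows
    segs = ep.eeg[:, : n_windows * wlen].reshape(n, n_windows, wlen)
    spec2 = np.abs(np.fft.rfft(segs, axis=2)) ** 2
    freqs = np.fft.rfftfreq(wlen, d=1.0 / fs)
    for j, band in enumerate(
        (CANONICAL_BANDS[k] for k in ("delta", "theta", "alpha", "upper_gamma"))
    ):
        in_band = (freqs >= band.f_low) & (freqs <= band.f_high)
        out[:, j] = spec2[:, :, in_band].sum(axis=2).mean(axis=1)
    out[:, 4] = [theta_delta_ratio(t, d) for t, d in zip(out[:, 1], out[:, 0])]
    out[:, 5] = np.sqrt(np.mean(ep.emg**2, axis=1))
    out[:, 6] = np.mean(np.abs(ep.eeg), axis=1)
    if ep.has_em:
        out[:, 7] = np.mean(np.abs(ep.em), axis=1)
    return out


def em_rate_features(ep: EpochedRecording, thr: EMThresholds) -> np.ndarray:
    """Columns f9–f10: EM event rates above the wake and REM thresholds."""
    n = ep.n_epochs
    out = np.zeros((n, 2))
    if not ep.has_em:
        return out
    for i in range(n):
        out[i, 0] = em_event_frequency(ep.em[i], thr.a_wake, ep.epoch_length_s)
        out[i, 1] = em_event_frequency(ep.em[i], thr.a_rem, ep.epoch_length_s)
    return out


def extract_features(
    ep: EpochedRecording,
    thr: EMThresholds | None = None,
    n_windows: int = 1,
) -> np.ndarray:
    """Full ``n_epochs x 10`` feature matrix in the fixed f1..f10 order.

    ``thr`` is required when the recording has an EM channel; for EM-absent
    recordings it is ignored and f8–f10 carry the null-mask value (0).
    """
    base = base_features(ep, n_windows=n_windows)
    if ep.has_em:
        if thr is None:
            raise ConfigurationError(
                "extract_features: EM channel present but no EMThresholds given"
            )
        em = em_rate_features(ep, thr)
    else:
        em = np.zeros((ep.n_epochs, 2))
    return np.hstack([base, em])


def mask_em_features(F: np.ndarray) -> np.ndarray:
    """Replace the EM columns (f8–f10) with the null mask (0); idempotent.

    The null value 0 equals the column mean after standardization, so a
    masked feature carries no class information.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or F.shape[1] != 10:
        raise ValueError(f"expected an (n, 10) feature matrix, got {F.shape}")
    out = F.copy()
    out[:, EM_FEATURE_SLICE] = 0.0
    return out


class FeatureScaler:
    """Column-wise z-scoring fit on training folds only.

    After ``transform``, each training column has mean 0 and unit std, so
    the EM null mask (0) sits at the column mean. Constant columns are
    left centered with unit divisor.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None

    def fit(self, F: np.ndarray) -> "FeatureScaler":
        F = np.asarray(F, dtype=float)
        self.mean_ = F.mean(axis=0)
        std = F.std(axis=0, ddof=0)
        std[std < 1e-12] = 1.0
        self.std_ = std
        return self

    def transform(self, F: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("FeatureScaler used before fit")
        return (np.asarray(F, dtype=float) - self.mean_) / self.std_

    def fit_transform(self, F: np.ndarray) -> np.ndarray:
        return self.fit(F).transform(F)
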