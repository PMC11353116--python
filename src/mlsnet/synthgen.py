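"""Synthetic mouse polysomnography with labelled vigilance states.

The generator emulates the statistical structure the classifier relies
on, without claiming physiological detail:

* a semi-Markov hypnogram — state bouts with geometric lengths whose
  per-state means and long-run occupancies match a typical mouse
  (WAKE 54.5%, NREM 37.2%, REM 8.2%);
* state-dependent EEG spectra: a pink-noise floor plus a delta
  (1–3.5 Hz) oscillation in NREM, a modest theta (6.5–8.5 Hz) oscillation
  in REM, and weak broadband activity in WAKE;
* state-dependent EMG: white noise, high variance in WAKE, low in sleep;
* state-dependent eye-movement events: stereotyped biphasic deflections
  on a noise baseline, arriving as a Poisson process at about 0.90 Hz in
  WAKE, 0.25 Hz in REM and 0.05 Hz in NREM.

Per-epoch lognormal amplitude jitter keeps the feature distributions of
the three states overlapping, so default-condition classification is hard
enough not to saturate. REM's EEG signature is deliberately weak relative
to its EM signature: in real mice, eye-movement frequency is the robust
REM/NREM discriminator, and the EM-exclusion ablation should reproduce
that dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io_poly import (
    NREM,
    REM,
    STATES,
    WAKE,
    ConfigurationError,
    Hypnogram,
    Recording,
    write_hypnogram,
    write_recording_columnar,
)

__all__ = [
    "SynthConfig",
    "sample_state_sequence",
    "synthesize_epoch",
    "generate_recording",
    "generate_dataset",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic dataset.

    Defaults are the desk-scale analogue of the seven-mouse design:
    7 subjects, 1 h each at 500 Hz with 4-s epochs, mouse-like state
    proportions, bout lengths and eye-movement rates. The amplitude
    constants are calibration choices (see docs/methods.md); they set how
    separable the states are and are part of the study conditions, not
    free dials.
    """

    n_subjects: int = 7
    duration_s: float = 3600.0
    sample_rate_hz: float = 500.0
    epoch_length_s: float = 4.0
    # long-run occupancy targets (WAKE, NREM, REM)
    state_proportions: tuple[float, float, float] = (0.545, 0.372, 0.082)
    # mean bout lengths in epochs (WAKE, NREM, REM)
    mean_bout_epochs: tuple[float, float, float] = (45.0, 30.0, 18.0)
    # EEG oscillation amplitudes on the unit pink-noise floor; deliberately
    # weak relative to the jittered floor so state spectra overlap and the
    # REM/NREM discrimination rides substantially on the EM channel
    nrem_delta_amp: float = 0.65
    rem_theta_amp: float = 0.18
    wake_theta_amp: float = 0.2
    # EMG white-noise standard deviations (WAKE, NREM, REM); nuchal atonia
    # makes the two sleep states indistinguishable on EMG
    emg_std: tuple[float, float, float] = (3.0, 0.9, 0.9)
    # EM event rates in Hz (WAKE, NREM, REM) and event shape
    em_rates_hz: tuple[float, float, float] = (0.90, 0.05, 0.25)
    em_event_amp: float = 10.0
    em_event_duration_s: float = 0.1
    em_noise_std: float = 0.6
    # multiplicative per-epoch lognormal amplitude jitter (sigma of log)
    amplitude_jitter: float = 0.8
    # per-subject lognormal jitter on state-level EMG/EEG emphases
    subject_jitter: float = 0.10
    noise_floor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        # printed percentages may carry rounding error (e.g. 54.5+37.2+8.2)
        if abs(sum(self.state_proportions) - 1.0) > 5e-3:
            raise ConfigurationError("state proportions must sum to 1")
        if min(self.state_proportions) < 0 or min(self.em_rates_hz) < 0:
            raise ConfigurationError("proportions and rates must be nonnegative")
        if min(self.mean_bout_epochs) < 1:
            raise ConfigurationError("mean bout lengths must be >= 1 epoch")

    @property
    def samples_per_epoch(self) -> int:
        return round(self.epoch_length_s * self.sample_rate_hz)

    @property
    def epochs_per_subject(self) -> int:
        return int(self.duration_s // self.epoch_length_s)


# ---------------------------------------------------------------------------
# Hypnogram sampling


def sample_state_sequence(
    cfg: SynthConfig, n_epochs: int | None = None, rng=None
) -> Hypnogram:
    """Semi-Markov state sequence with geometric bout lengths.

    Bout entries are drawn with weight proportional to
    ``occupancy / mean bout length`` (excluding the current state), which
    makes long-run occupancies track the configured proportions.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if n_epochs is None:
        n_epochs = cfg.epochs_per_subject
    props = np.asarray(cfg.state_proportions, dtype=float)
    props = props / props.sum()
    means = np.asarray(cfg.mean_bout_epochs, dtype=float)
    entry_w = props / means
    labels: list[str] = []
    current = int(rng.choice(3, p=props))
    while len(labels) < n_epochs:
        bout = max(1, int(rng.geometric(1.0 / means[current])))
        labels.extend([STATES[current]] * min(bout, n_epochs - len(labels)))
        w = entry_w.copy()
        w[current] = 0.0
        current = int(rng.choice(3, p=w / w.sum()))
    return Hypnogram(np.array(labels, dtype=object), cfg.epoch_length_s)


# ---------------------------------------------------------------------------
# Epoch synthesis


def _pink_noise(n: int, rng) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def _oscillation(
    n: int, fs: float, f_lo: float, f_hi: float, amp: float, rng
) -> np.ndarray:
    f = rng.uniform(f_lo, f_hi)
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * f * t + phase)


def _em_events(n: int, fs: float, rate_hz: float, amp: float, dur_s: float, rng):
    """Poisson-arriving biphasic deflections (one sine cycle each)."""
    out = np.zeros(n)
    n_events = rng.poisson(rate_hz * n / fs)
    width = max(4, round(dur_s * fs))
    cycle = amp * np.sin(2 * np.pi * np.arange(width) / width)
    for _ in range(n_events):
        start = rng.integers(0, max(1, n - width))
        out[start : start + width] += cycle[: n - start]
    return out


def synthesize_epoch(
    state: str, cfg: SynthConfig, rng, subject_gains: dict | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One epoch of (eeg, emg, em) samples for a given vigilance state."""
    if state not in STATES:
        raise ConfigurationError(f"unknown state {state!r}")
    n = cfg.samples_per_epoch
    fs = cfg.sample_rate_hz
    g = subject_gains or {}
    jit = lambda: float(np.exp(cfg.amplitude_jitter * rng.standard_normal()))

    # the noise floor is jittered per epoch as well, so band powers overlap
    # across states instead of separating on the oscillation term alone
    eeg = cfg.noise_floor * jit() * _pink_noise(n, rng)
    if state == NREM:
        eeg += _oscillation(
            n, fs, 1.0, 3.5, cfg.nrem_delta_amp * g.get("delta", 1.0) * jit(), rng
        )
    elif state == REM:
        eeg += _oscillation(
            n, fs, 6.5, 8.5, cfg.rem_theta_amp * g.get("theta", 1.0) * jit(), rng
        )
    else:
        eeg += _oscillation(
            n, fs, 6.0, 10.0, cfg.wake_theta_amp * jit(), rng
        )

    emg_std = dict(zip(STATES, cfg.emg_std))[state] * g.get("emg", 1.0) * jit()
    emg = emg_std * rng.standard_normal(n)

    rate = dict(zip(STATES, cfg.em_rates_hz))[state]
    em = cfg.em_noise_std * rng.standard_normal(n)
    em += _em_events(n, fs, rate, cfg.em_event_amp * jit(), cfg.em_event_duration_s, rng)
    return eeg, emg, em


# ---------------------------------------------------------------------------
# Full datasets


def generate_recording(
    cfg: SynthConfig, subject_id: str, rng
) -> tuple[Recording, Hypnogram]:
    """One subject: sampled hypnogram + concatenated per-epoch signals."""
    hyp = sample_state_sequence(cfg, rng=rng)
    gains = {
        key: float(np.exp(cfg.subject_jitter * rng.standard_normal()))
        for key in ("delta", "theta", "emg")
    }
    n = cfg.samples_per_epoch
    n_epochs = len(hyp)
    eeg = np.empty(n_epochs * n)
    emg = np.empty(n_epochs * n)
    em = np.empty(n_epochs * n)
    for i, state in enumerate(hyp.labels):
        e, m, v = synthesize_epoch(state, cfg, rng, gains)
        eeg[i * n : (i + 1) * n] = e
        emg[i * n : (i + 1) * n] = m
        em[i * n : (i + 1) * n] = v
    rec = Recording(
        subject_id=subject_id,
        sample_rate_hz=cfg.sample_rate_hz,
        eeg=eeg,
        emg=emg,
        em=em,
    )
    return rec, hyp


def generate_dataset(
    cfg: SynthConfig, out_dir: str | Path | None = None
) -> tuple[list[tuple[Recording, Hypnogram]], dict]:
    """Independent recordings for ``cfg.n_subjects`` subjects + manifest.

    Each subject gets its own seeded random stream, so datasets are
    reproducible and subjects are independent. With ``out_dir`` set, the
    recordings (columnar text), hypnograms (CSV) and a YAML manifest are
    written to disk.
    """
    root = np.random.default_rng(cfg.seed)
    subject_seeds = root.integers(0, 2**31 - 1, size=cfg.n_subjects)
    data = []
    manifest: dict = {
        "seed": cfg.seed,
        "n_subjects": cfg.n_subjects,
        "epoch_length_s": cfg.epoch_length_s,
        "sample_rate_hz": cfg.sample_rate_hz,
        "subjects": [],
    }
    for j in range(cfg.n_subjects):
        sid = f"synth{j:02d}"
        rng = np.random.default_rng(int(subject_seeds[j]))
        rec, hyp = generate_recording(cfg, sid, rng)
        data.append((rec, hyp))
        entry = {"subject_id": sid, "n_epochs": len(hyp)}
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            rec_path = out / f"{sid}.rec.txt"
            hyp_path = out / f"{sid}.hyp.csv"
            write_recording_columnar(rec, rec_path)
            write_hypnogram(hyp, hyp_path)
            entry["recording"] = rec_path.name
            entry["hypnogram"] = hyp_path.name
        manifest["subjects"].append(entry)
    if out_dir is not None:
        with open(Path(out_dir) / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
    return data, manifest
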