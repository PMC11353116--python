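"""Polysomnography containers and I/O.

A recording is one EEG, one EMG and (optionally) one eye-movement (EM)
channel sampled synchronously. Sleep scoring operates on fixed-length
non-overlapping epochs (4 s by default for mouse data), each carrying one
vigilance-state label: WAKE, NREM or REM.

Supported containers: European Data Format (EDF, read via MNE) and a plain
columnar text format (header line ``# sample_rate_hz=<rate>``, then one
whitespace- or comma-separated row of channel values per sample).
Hypnograms are CSV files with columns ``epoch_index,label``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "WAKE",
    "NREM",
    "REM",
    "STATES",
    "Recording",
    "EpochedRecording",
    "Hypnogram",
    "DatasetSummary",
    "FormatError",
    "IntegrityError",
    "ConfigurationError",
    "LabelError",
    "read_recording",
    "write_recording_columnar",
    "segment_epochs",
    "read_hypnogram",
    "write_hypnogram",
    "dataset_summary",
]

# Canonical state alphabet and its fixed ordering (used for confusion
# matrices, feature ranking and one-hot targets alike).
WAKE = "WAKE"
NREM = "NREM"
REM = "REM"
STATES: tuple[str, str, str] = (WAKE, NREM, REM)

# Accepted label tokens, case-insensitive, canonicalized on read.
_LABEL_TOKENS: Mapping[str, str] = {
    "w": WAKE,
    "wake": WAKE,
    "nr": NREM,
    "nrem": NREM,
    "r": REM,
    "rem": REM,
}


class FormatError(ValueError):
    """File does not parse in the named dialect."""


class IntegrityError(ValueError):
    """Parsed content is internally inconsistent (lengths, duplicates)."""


class ConfigurationError(ValueError):
    """Caller-supplied configuration is invalid for the data at hand."""


class LabelError(ValueError):
    """A label token is outside the three-state alphabet."""


def canonical_label(token: str) -> str:
    """Map a label token (W/Wake/NR/NREM/R/REM, any case) to canonical form."""
    try:
        return _LABEL_TOKENS[token.strip().lower()]
    except KeyError:
        raise LabelError(
            f"unknown sleep-state label {token!r}; expected one of "
            f"{sorted(set(_LABEL_TOKENS))}"
        ) from None


@dataclass
class Recording:
    """Synchronized multichannel polysomnography for one subject.

    ``em`` may be None: EM-absent recordings (e.g. EEG/EMG-only datasets)
    are first-class and never silently replaced by a zero channel.
    """

    subject_id: str
    sample_rate_hz: float
    eeg: np.ndarray
    emg: np.ndarray
    em: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ConfigurationError("sample_rate_hz must be positive")
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.em is not None:
            self.em = np.asarray(self.em, dtype=float)
        lengths = {len(ch) for ch in self.channels().values()}
        if len(lengths) > 1:
            raise IntegrityError(f"channel lengths differ: {lengths}")

    def channels(self) -> dict[str, np.ndarray]:
        out = {"eeg": self.eeg, "emg": self.emg}
        if self.em is not None:
            out["em"] = self.em
        return out

    @property
    def n_samples(self) -> int:
        return len(self.eeg)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def has_em(self) -> bool:
        return self.em is not None


@dataclass
class EpochedRecording:
    """Per-channel ``n_epochs x samples_per_epoch`` matrices.

    Epochs are consecutive, non-overlapping, half-open intervals
    [i*L, (i+1)*L) in recording time; a trailing partial epoch is dropped.
    """

    subject_id: str
    sample_rate_hz: float
    epoch_length_s: float
    eeg: np.ndarray
    emg: np.ndarray
    em: np.ndarray | None = None

    @property
    def n_epochs(self) -> int:
        return self.eeg.shape[0]

    @property
    def samples_per_epoch(self) -> int:
        return self.eeg.shape[1]

    @property
    def has_em(self) -> bool:
        return self.em is not None

    def channels(self) -> dict[str, np.ndarray]:
        out = {"eeg": self.eeg, "emg": self.emg}
        if self.em is not None:
            out["em"] = self.em
        return out


@dataclass
class Hypnogram:
    """Per-epoch vigilance labels over the canonical three-state alphabet."""

    labels: np.ndarray  # array of str in STATES
    epoch_length_s: float = 4.0

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=object)
        bad = set(labels) - set(STATES)
        if bad:
            raise LabelError(f"non-canonical labels present: {sorted(bad)}")
        self.labels = labels

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hypnogram):
            return NotImplemented
        return (
            self.epoch_length_s == other.epoch_length_s
            and len(self) == len(other)
            and bool(np.all(self.labels == other.labels))
        )


@dataclass
class DatasetSummary:
    """Class counts and percentages over one or more pooled hypnograms."""

    counts: dict[str, int]
    total: int
    percentages: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise IntegrityError("class counts do not sum to total")
        self.percentages = {
            s: 100.0 * self.counts.get(s, 0) / self.total for s in STATES
        }

    def as_table(self) -> str:
        lines = [f"{'Stage':<6} {'Epochs':>10} {'Percent':>8}"]
        for s in STATES:
            lines.append(
                f"{s:<6} {self.counts.get(s, 0):>10d} "
                f"{self.percentages[s]:>7.1f}%"
            )
        lines.append(f"{'Total':<6} {self.total:>10d} {100.0:>7.1f}%")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Recording I/O


def _read_columnar(path: Path, subject_id: str) -> Recording:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#") or "sample_rate_hz" not in header:
            raise FormatError(
                f"{path}: columnar header must be '# sample_rate_hz=<rate>'"
            )
        try:
            rate = float(header.split("=", 1)[1])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}: cannot parse sample rate") from exc
        name_line = fh.readline().strip()
        names = [n.strip().lower() for n in name_line.replace(",", " ").split()]
        try:
            data = np.loadtxt(fh, delimiter=None if "," not in name_line else ",")
        except ValueError as exc:
            raise FormatError(f"{path}: cannot parse sample rows") from exc
    if data.ndim == 1:
        data = data[:, None]
    if data.shape[1] != len(names):
        raise IntegrityError(
            f"{path}: {len(names)} column names but {data.shape[1]} columns"
        )
    cols = {n: data[:, i] for i, n in enumerate(names)}
    if "eeg" not in cols or "emg" not in cols:
        raise ConfigurationError(
            f"{path}: columnar file must name eeg and emg columns, got {names}"
        )
    return Recording(
        subject_id=subject_id,
        sample_rate_hz=rate,
        eeg=cols["eeg"],
        emg=cols["emg"],
        em=cols.get("em"),
    )


def _read_edf(path: Path, subject_id: str, channel_map: Mapping[str, str]) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises several concrete types
        raise FormatError(f"{path}: not a readable EDF file ({exc})") from exc
    available = {name.lower(): name for name in raw.ch_names}
    picked: dict[str, np.ndarray] = {}
    for role in ("eeg", "emg", "em"):
        wanted = channel_map.get(role, role).lower()
        if wanted in available:
            # pick by index: names like "eeg" are ambiguous as string picks.
            # MNE scales EDF voltages to volts; consistent scaling cancels
            # in z-scoring, so the array is used as-is.
            idx = raw.ch_names.index(available[wanted])
            picked[role] = raw.get_data(picks=[idx])[0]
    if "eeg" not in picked or "emg" not in picked:
        raise ConfigurationError(
            f"{path}: could not map channels {raw.ch_names} to eeg/emg; "
            "provide a channel_map"
        )
    return Recording(
        subject_id=subject_id,
        sample_rate_hz=float(raw.info["sfreq"]),
        eeg=picked["eeg"],
        emg=picked["emg"],
        em=picked.get("em"),
    )


def read_recording(
    path: str | Path,
    format: str = "columnar",
    subject_id: str | None = None,
    channel_map: Mapping[str, str] | None = None,
) -> Recording:
    """Read a Recording from an EDF or columnar text file.

    Parameters
    ----------
    path
        File to read.
    format
        ``"edf"`` or ``"columnar"``.
    subject_id
        Identity attached to the recording; defaults to the file stem.
    channel_map
        Optional mapping from roles (``eeg``/``emg``/``em``) to channel
        names in the file; by default the role names themselves are used
        (case-insensitive).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sid = subject_id if subject_id is not None else path.stem
    if format == "columnar":
        return _read_columnar(path, sid)
    if format == "edf":
        return _read_edf(path, sid, channel_map or {})
    raise ConfigurationError(f"unknown recording format {format!r}")


def write_recording_columnar(rec: Recording, path: str | Path) -> None:
    """Write a Recording in the columnar text format (lossy to ~17 digits)."""
    chans = rec.channels()
    names = list(chans)
    data = np.column_stack([chans[n] for n in names])
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz={rec.sample_rate_hz:.10g}\n")
        fh.write(",".join(names) + "\n")
        np.savetxt(fh, data, fmt="%.17g", delimiter=",")


# ---------------------------------------------------------------------------
# Epoch segmentation


def segment_epochs(rec: Recording, epoch_length_s: float = 4.0) -> EpochedRecording:
    """Cut a recording into consecutive non-overlapping fixed-length epochs.

    ``epoch_length_s * sample_rate_hz`` must be integral (within 1e-6);
    a trailing partial epoch is dropped, never padded.
    """
    spe_float = epoch_length_s * rec.sample_rate_hz
    spe = round(spe_float)
    if spe <= 0 or abs(spe_float - spe) > 1e-6:
        raise ConfigurationError(
            f"epoch length {epoch_length_s}s at {rec.sample_rate_hz}Hz gives "
            f"non-integral samples per epoch ({spe_float})"
        )
    n_epochs = rec.n_samples // spe

    def cut(x: np.ndarray | None) -> np.ndarray | None:
        if x is None:
            return None
        return x[: n_epochs * spe].reshape(n_epochs, spe).copy()

    return EpochedRecording(
        subject_id=rec.subject_id,
        sample_rate_hz=rec.sample_rate_hz,
        epoch_length_s=float(epoch_length_s),
        eeg=cut(rec.eeg),
        emg=cut(rec.emg),
        em=cut(rec.em),
    )


# ---------------------------------------------------------------------------
# Hypnogram I/O


def read_hypnogram(path: str | Path, epoch_length_s: float = 4.0) -> Hypnogram:
    """Read a hypnogram CSV (columns ``epoch_index,label``, 0-based index)."""
    rows: dict[int, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise FormatError(f"{path}: empty hypnogram file")
        if [c.strip().lower() for c in header[:2]] != ["epoch_index", "label"]:
            raise FormatError(
                f"{path}: expected header 'epoch_index,label', got {header}"
            )
        for row in reader:
            if not row:
                continue
            idx = int(row[0])
            if idx in rows:
                raise IntegrityError(f"{path}: duplicate epoch index {idx}")
            rows[idx] = canonical_label(row[1])
    if not rows:
        raise FormatError(f"{path}: hypnogram contains no labels")
    if sorted(rows) != list(range(len(rows))):
        raise IntegrityError(f"{path}: epoch indices are not contiguous from 0")
    labels = np.array([rows[i] for i in range(len(rows))], dtype=object)
    return Hypnogram(labels=labels, epoch_length_s=epoch_length_s)


def write_hypnogram(h: Hypnogram, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch_index", "label"])
        for i, lab in enumerate(h.labels):
            writer.writerow([i, lab])


# ---------------------------------------------------------------------------
# Summaries


def dataset_summary(hypnograms: Hypnogram | Iterable[Hypnogram]) -> DatasetSummary:
    """Pooled class counts/percentages over one or more hypnograms."""
    if isinstance(hypnograms, Hypnogram):
        hypnograms = [hypnograms]
    labels: list[str] = []
    for h in hypnograms:
        labels.extend(h.labels)
    if not labels:
        raise ValueError("dataset_summary: empty label sequence")
    counts = {s: 0 for s in STATES}
    arr = np.asarray(labels, dtype=object)
    for s in STATES:
        counts[s] = int(np.sum(arr == s))
    return DatasetSummary(counts=counts, total=len(labels))


def summary_from_counts(counts: Mapping[str, int]) -> DatasetSummary:
    """Build a DatasetSummary directly from per-class epoch counts."""
    full = {s: int(counts.get(s, 0)) for s in STATES}
    return DatasetSummary(counts=full, total=sum(full.values()))
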