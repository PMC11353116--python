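"""Shared fixtures: small synthetic datasets and a minimal EDF writer."""

from __future__ import annotations

import numpy as np
import pytest

from mlsnet import SynthConfig, generate_dataset, prepare_subjects


def write_edf(path, signals: dict[str, np.ndarray], fs: int) -> None:
    """Write a minimal synthetic EDF file (one record per second).

    Covers just enough of the European Data Format for round-trip tests:
    16-bit samples, per-signal physical scaling from the data range.
    """
    names = list(signals)
    ns = len(names)
    n_samples = len(next(iter(signals.values())))
    assert all(len(v) == n_samples for v in signals.values())
    assert n_samples % fs == 0
    n_records = n_samples // fs

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        assert len(b) <= width, (text, width)
        return b + b" " * (width - len(b))

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate 01-JAN-2024 synthetic", 80),
            pad("01.01.24", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + ns)), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),
            pad(str(ns), 4),
        ]
    )
    phys = {}
    for name in names:
        x = np.asarray(signals[name], dtype=float)
        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:
            hi = lo + 1.0
        phys[name] = (lo, hi)
    for field, width in [
        (lambda n: n, 16),  # label
        (lambda n: "synthetic", 80),  # transducer
        (lambda n: "uV", 8),  # physical dimension
        (lambda n: f"{phys[n][0]:.6g}", 8),
        (lambda n: f"{phys[n][1]:.6g}", 8),
        (lambda n: "-32768", 8),
        (lambda n: "32767", 8),
        (lambda n: "", 80),  # prefiltering
        (lambda n: str(fs), 8),  # samples per record
        (lambda n: "", 32),  # reserved
    ]:
        header += b"".join(pad(str(field(n)), width) for n in names)

    with open(path, "wb") as fh:
        fh.write(header)
        digital = {}
        for name in names:
            lo, hi = phys[name]
            x = np.asarray(signals[name], dtype=float)
            d = np.round((x - lo) / (hi - lo) * 65535 - 32768)
            digital[name] = np.clip(d, -32768, 32767).astype("<i2")
        for r in range(n_records):
            for name in names:
                fh.write(digital[name][r * fs : (r + 1) * fs].tobytes())


@pytest.fixture(scope="session")
def tiny_config() -> SynthConfig:
    """3 subjects x 40 min: small enough for fast unit tests, large enough
    that every subject contains all three states."""
    return SynthConfig(n_subjects=3, duration_s=2400, seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    data, manifest = generate_dataset(tiny_config)
    return data


@pytest.fixture(scope="session")
def tiny_subjects(tiny_dataset):
    return prepare_subjects(tiny_dataset)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
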