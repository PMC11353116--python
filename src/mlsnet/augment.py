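"""Run-length rebalancing of the training sequence.

Mouse hypnograms are heavily imbalanced (REM is under 10% of epochs) and
the labels come in long bouts. The balanced training set is built in two
steps: (1) every maximal constant-label run longer than its class's mean
run length is trimmed at the tail to that mean; (2) minority-class runs
are duplicated — whole runs, cycling in original order — until every class
has (within rounding) as many epochs as the largest class.

No signal values are ever synthesized: each output epoch is a copy of an
input epoch, and the provenance map (output position -> source epoch
index) makes that auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .io_poly import STATES, Hypnogram

__all__ = [
    "RunLengthProfile",
    "AugmentationError",
    "run_length_profile",
    "trim_runs",
    "rebalance",
    "rebalance_training_set",
]


class AugmentationError(ValueError):
    """Rebalancing is impossible (e.g. a class is absent)."""


@dataclass(frozen=True)
class RunLengthProfile:
    """Per-class mean run length (epochs) and run counts."""

    mean_length: dict[str, float]
    run_count: dict[str, int]


def _runs(labels: np.ndarray) -> list[tuple[str, int, int]]:
    """Maximal constant-label segments as (label, start, stop) half-open."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((labels[start], start, i))
            start = i
    return out


def run_length_profile(h: Hypnogram) -> RunLengthProfile:
    """Mean run length per class: epochs in class / number of its runs."""
    if len(h) == 0:
        raise ValueError("run_length_profile: empty hypnogram")
    total: dict[str, int] = {s: 0 for s in STATES}
    count: dict[str, int] = {s: 0 for s in STATES}
    for label, start, stop in _runs(h.labels):
        total[label] += stop - start
        count[label] += 1
    mean = {s: (total[s] / count[s] if count[s] else 0.0) for s in STATES}
    return RunLengthProfile(mean_length=mean, run_count=count)


def trim_runs(labels: np.ndarray, profile: RunLengthProfile) -> np.ndarray:
    """Indices of retained epochs after trimming long runs to the class mean.

    A run of class ``c`` keeps at most ``ceil(mean_c)`` epochs from its
    head; the excess tail is removed. Returns source indices (into the
    original sequence), preserving order, so callers can slice features
    and labels alike.
    """
    labels = np.asarray(labels, dtype=object)
    keep: list[int] = []
    for label, start, stop in _runs(labels):
        limit = ceil(profile.mean_length[label]) if profile.mean_length[label] else stop - start
        keep.extend(range(start, min(stop, start + limit)))
    return np.array(keep, dtype=int)


def rebalance(labels: np.ndarray) -> np.ndarray:
    """Provenance indices of the balanced sequence.

    Input labels are assumed already trimmed. Minority-class runs are
    appended (whole runs, cycling in original order) until each class's
    epoch total matches the majority class within ±1; the majority class
    is untouched. Returns source indices into the input sequence; output
    epoch ``k`` is a copy of input epoch ``indices[k]``.
    """
    labels = np.asarray(labels, dtype=object)
    counts = {s: int(np.sum(labels == s)) for s in STATES}
    if min(counts.values()) == 0:
        missing = [s for s in STATES if counts[s] == 0]
        raise AugmentationError(f"cannot rebalance: class(es) absent: {missing}")
    target = max(counts.values())
    out = list(range(len(labels)))
    runs_by_class = {s: [] for s in STATES}
    for label, start, stop in _runs(labels):
        runs_by_class[label].append((start, stop))
    for s in STATES:
        deficit = target - counts[s]
        cycle = 0
        while deficit > 0:
            start, stop = runs_by_class[s][cycle % len(runs_by_class[s])]
            take = min(stop - start, deficit)
            out.extend(range(start, start + take))
            deficit -= take
            cycle += 1
    return np.array(out, dtype=int)


def rebalance_training_set(
    features: np.ndarray, labels: np.ndarray, h_epoch_length_s: float = 4.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trim + rebalance a (features, labels) training pair.

    Returns (balanced_features, balanced_labels, provenance) where
    ``provenance[k]`` is the index into the *original* arrays that output
    epoch ``k`` copies. Apply to training folds only.
    """
    labels = np.asarray(labels, dtype=object)
    profile = run_length_profile(Hypnogram(labels, h_epoch_length_s))
    kept = trim_runs(labels, profile)
    balanced_local = rebalance(labels[kept])
    provenance = kept[balanced_local]
    return np.asarray(features)[provenance], labels[provenance], provenance
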