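"""Leave-one-out cross-validation and the metric suite.

Evaluation is subject-level LOOCV: with k recordings, each serves once as
the held-out test set while the other k-1 train the model (6/7 = 85.7%
training fraction for the seven-mouse design). Per fold we report the
3x3 confusion matrix (rows = true, columns = predicted, order
WAKE/NREM/REM), per-class one-vs-rest precision / recall / F1 / accuracy,
overall accuracy (trace/total), and macro + micro averages; across folds,
the coefficient of variation CV = 100*sigma/mu of fold accuracies.

Everything fit from labels — EM thresholds, feature standardization, the
rebalancing augmentation — uses training subjects only, so no information
leaks into the held-out recording. EM masking (the EM-exclusion ablation)
applies to training and test alike, since it emulates the modality being
unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .augment import rebalance_training_set
from .features import (
    EMThresholds,
    FeatureScaler,
    base_features,
    em_rate_features,
    fit_em_thresholds,
    mask_em_features,
)
from .io_poly import STATES, ConfigurationError, EpochedRecording, Hypnogram
from .model import ModelConfig, build_model, predict, train

__all__ = [
    "ConfusionMatrix",
    "FoldResult",
    "CVSummary",
    "SubjectData",
    "confusion",
    "metrics",
    "coefficient_of_variation",
    "loocv",
    "hypnogram_report",
]

_IDX = {s: i for i, s in enumerate(STATES)}


@dataclass
class ConfusionMatrix:
    """3x3 counts; rows = true class, columns = predicted (WAKE, NREM, REM)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (3, 3) or (c < 0).any():
            raise ValueError("confusion matrix must be 3x3 nonnegative")
        self.counts = c.astype(int)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, state: str) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) for one class against the rest."""
        i = _IDX[state]
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum() - tp)
        fn = int(self.counts[i, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, tn, fp, fn


def confusion(true, pred) -> ConfusionMatrix:
    """Count epochs per (true, predicted) class pair."""
    true = np.asarray(true, dtype=object)
    pred = np.asarray(pred, dtype=object)
    if true.shape != pred.shape:
        raise ValueError(f"length mismatch: {true.shape} vs {pred.shape}")
    counts = np.zeros((3, 3), dtype=int)
    for t, p in zip(true, pred):
        counts[_IDX[t], _IDX[p]] += 1
    return ConfusionMatrix(counts)


@dataclass
class FoldResult:
    """Metrics for one cross-validation fold."""

    fold_id: int
    subject_id: str
    confusion: ConfusionMatrix
    per_class: dict[str, dict[str, float]] = field(init=False)
    overall_accuracy: float = field(init=False)
    macro_precision: float = field(init=False)
    macro_recall: float = field(init=False)
    macro_f1: float = field(init=False)
    micro_precision: float = field(init=False)
    micro_recall: float = field(init=False)
    micro_f1: float = field(init=False)

    def __post_init__(self) -> None:
        m = metrics(self.confusion)
        self.per_class = m["per_class"]
        self.overall_accuracy = m["overall_accuracy"]
        self.macro_precision = m["macro_precision"]
        self.macro_recall = m["macro_recall"]
        self.macro_f1 = m["macro_f1"]
        self.micro_precision = m["micro_precision"]
        self.micro_recall = m["micro_recall"]
        self.micro_f1 = m["micro_f1"]

    def to_dict(self) -> dict:
        return {
            "fold_id": self.fold_id,
            "subject_id": self.subject_id,
            "confusion": self.confusion.counts.tolist(),
            "per_class": self.per_class,
            "overall_accuracy": self.overall_accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
        }


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    """num/den, or (0, flagged=True) on a zero denominator."""
    if den == 0:
        return 0.0, True
    return num / den, False


def metrics(cm: ConfusionMatrix) -> dict:
    """Per-class one-vs-rest metrics plus overall / macro / micro summaries.

    ``overall_accuracy`` is trace/total of the 3-class matrix; the
    TP+TN-based accuracy appears per class as the one-vs-rest accuracy.
    Zero-denominator metrics are reported as 0 with a ``flagged`` marker.
    """
    if cm.total == 0:
        raise ValueError("metrics: empty confusion matrix")
    per_class: dict[str, dict[str, float]] = {}
    tps = fps = fns = 0
    for s in STATES:
        tp, tn, fp, fn = cm.one_vs_rest(s)
        precision, flag_p = _safe_div(tp, tp + fp)
        recall, flag_r = _safe_div(tp, tp + fn)
        f1, flag_f = _safe_div(2 * precision * recall, precision + recall)
        per_class[s] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "accuracy": (tp + tn) / cm.total,
            "flagged": bool(flag_p or flag_r or flag_f),
        }
        tps += tp
        fps += fp
        fns += fn
    macro = {
        k: float(np.mean([per_class[s][k] for s in STATES]))
        for k in ("precision", "recall", "f1")
    }
    micro_p, _ = _safe_div(tps, tps + fps)
    micro_r, _ = _safe_div(tps, tps + fns)
    micro_f, _ = _safe_div(2 * micro_p * micro_r, micro_p + micro_r)
    return {
        "per_class": per_class,
        "overall_accuracy": float(np.trace(cm.counts)) / cm.total,
        "macro_precision": macro["precision"],
        "macro_recall": macro["recall"],
        "macro_f1": macro["f1"],
        "micro_precision": micro_p,
        "micro_recall": micro_r,
        "micro_f1": micro_f,
    }


@dataclass
class CVSummary:
    """Fold accuracies with their mean, population std and CV percent."""

    accuracies: np.ndarray
    mean: float = field(init=False)
    std: float = field(init=False)
    cv_percent: float = field(init=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.accuracies, dtype=float)
        if a.size < 2:
            raise ValueError("coefficient of variation needs >= 2 folds")
        self.accuracies = a
        self.mean = float(a.mean())
        if self.mean == 0:
            raise ValueError("coefficient of variation undefined for mean 0")
        self.std = float(a.std(ddof=0))
        self.cv_percent = 100.0 * self.std / self.mean


def coefficient_of_variation(accuracies) -> CVSummary:
    """CV = 100*sigma/mu over per-fold accuracies (population sigma)."""
    return CVSummary(np.asarray(accuracies, dtype=float))


# ---------------------------------------------------------------------------
# LOOCV orchestration


@dataclass
class SubjectData:
    """One subject's preprocessed, epoched recording with its hypnogram.

    Threshold-independent feature columns (f1–f8) are computed lazily once
    and cached; only the EM event-rate columns depend on the fold.
    """

    epoched: EpochedRecording
    hypnogram: Hypnogram
    _base: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.hypnogram) != self.epoched.n_epochs:
            raise ValueError(
                f"subject {self.epoched.subject_id}: hypnogram length "
                f"{len(self.hypnogram)} != n_epochs {self.epoched.n_epochs}"
            )

    @property
    def subject_id(self) -> str:
        return self.epoched.subject_id

    def base(self) -> np.ndarray:
        if self._base is None:
            self._base = base_features(self.epoched)
        return self._base

    def features(self, thr: EMThresholds | None) -> np.ndarray:
        if self.epoched.has_em:
            if thr is None:
                raise ConfigurationError("EM channel present but no thresholds")
            em = em_rate_features(self.epoched, thr)
        else:
            em = np.zeros((self.epoched.n_epochs, 2))
        return np.hstack([self.base(), em])


def _pooled_thresholds(train_subjects: list[SubjectData]) -> EMThresholds | None:
    with_em = [s for s in train_subjects if s.epoched.has_em]
    if not with_em:
        return None
    em = np.concatenate([s.epoched.em.reshape(-1) for s in with_em])
    labels = np.concatenate([s.hypnogram.labels for s in with_em])
    any_ep = with_em[0].epoched
    pooled = Hypnogram(labels, any_ep.epoch_length_s)
    return fit_em_thresholds(em, pooled, any_ep.sample_rate_hz, any_ep.epoch_length_s)


def loocv(
    subjects: list[SubjectData],
    cfg: ModelConfig,
    mask_em: bool = False,
    rebalance: bool = False,
    iterations: int = 120,
) -> tuple[list[FoldResult], CVSummary]:
    """Subject-level leave-one-out cross-validation.

    Per fold: EM thresholds and the feature scaler are fit on the k-1
    training subjects; the model is reseeded as ``cfg.seed + fold_id``;
    augmentation (``rebalance``) touches training data only, while EM
    masking applies to both partitions.
    """
    k = len(subjects)
    if k < 2:
        raise ConfigurationError("LOOCV needs at least 2 subjects")
    results: list[FoldResult] = []
    for fold_id, test in enumerate(subjects):
        train_subjects = [s for s in subjects if s is not test]
        thr = _pooled_thresholds(train_subjects)
        F_train = np.vstack([s.features(thr) for s in train_subjects])
        y_train = np.concatenate([s.hypnogram.labels for s in train_subjects])
        F_test = test.features(thr)
        y_test = test.hypnogram.labels
        scaler = FeatureScaler().fit(F_train)
        F_train = scaler.transform(F_train)
        F_test = scaler.transform(F_test)
        if mask_em:
            F_train = mask_em_features(F_train)
            F_test = mask_em_features(F_test)
        if rebalance:
            F_train, y_train, _ = rebalance_training_set(
                F_train, y_train, test.epoched.epoch_length_s
            )
        fold_cfg = ModelConfig(**{**vars(cfg), "seed": cfg.seed + fold_id})
        model = build_model(fold_cfg)
        model, _curves = train(model, F_train, y_train, iterations=iterations)
        preds = [p.label for p in predict(model, F_test)]
        results.append(
            FoldResult(fold_id, test.subject_id, confusion(y_test, preds))
        )
    summary = coefficient_of_variation([r.overall_accuracy for r in results])
    return results, summary


def prepare_subjects(
    pairs,
    preprocess_cfg=None,
    epoch_length_s: float = 4.0,
) -> list[SubjectData]:
    """(Recording, Hypnogram) pairs -> preprocessed, epoched SubjectData.

    Runs the full conditioning chain and segmentation; hypnograms longer
    than the epoched recording (or vice versa) are truncated to the common
    length, since segmentation drops a trailing partial epoch.
    """
    from .io_poly import segment_epochs
    from .preprocess import PreprocessConfig, preprocess_recording

    cfg = preprocess_cfg or PreprocessConfig()
    out = []
    for rec, hyp in pairs:
        ep = segment_epochs(preprocess_recording(rec, cfg), epoch_length_s)
        n = min(ep.n_epochs, len(hyp))
        if n < ep.n_epochs:
            ep = EpochedRecording(
                subject_id=ep.subject_id,
                sample_rate_hz=ep.sample_rate_hz,
                epoch_length_s=ep.epoch_length_s,
                eeg=ep.eeg[:n],
                emg=ep.emg[:n],
                em=None if ep.em is None else ep.em[:n],
            )
        hyp_n = Hypnogram(hyp.labels[:n], hyp.epoch_length_s)
        out.append(SubjectData(ep, hyp_n))
    return out


# ---------------------------------------------------------------------------
# Hypnogram comparison report


def hypnogram_report(
    true,
    pred,
    csv_path=None,
    figure_path=None,
    epoch_length_s: float = 4.0,
) -> dict:
    """Serialize a true-vs-predicted hypnogram pair.

    Returns disagreement statistics (count = Hamming distance, plus the
    maximal disagreement segments); optionally writes a CSV
    (epoch_index,true,pred) and a step-plot figure.
    """
    true = np.asarray(true, dtype=object)
    pred = np.asarray(pred, dtype=object)
    if true.shape != pred.shape:
        raise ValueError(f"length mismatch: {true.shape} vs {pred.shape}")
    disagree = true != pred
    segments = []
    start = None
    for i, d in enumerate(disagree):
        if d and start is None:
            start = i
        elif not d and start is not None:
            segments.append((start, i))
            start = None
    if start is not None:
        segments.append((start, len(disagree)))
    if csv_path is not None:
        import csv as _csv

        with open(csv_path, "w", newline="") as fh:
            w = _csv.writer(fh)
            w.writerow(["epoch_index", "true", "pred"])
            for i, (t, p) in enumerate(zip(true, pred)):
                w.writerow([i, t, p])
    if figure_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        t_axis = np.arange(len(true)) * epoch_length_s
        level = {s: i for i, s in enumerate(STATES)}
        fig, ax = plt.subplots(figsize=(10, 2.5))
        ax.step(t_axis, [level[s] for s in true], where="post", label="expert")
        ax.step(
            t_axis, [level[s] for s in pred], where="post", label="model", ls="--"
        )
        ax.set_yticks(range(3), STATES)
        ax.set_xlabel("time (s)")
        ax.legend(loc="upper right")
        fig.tight_layout()
        fig.savefig(figure_path, dpi=120)
        plt.close(fig)
    return {
        "n_epochs": int(len(true)),
        "disagreements": int(disagree.sum()),
        "segments": segments,
    }
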