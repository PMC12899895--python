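"""Loss, trial-level protocol, optimization recipe, and evaluation reports.

The subject-dependent protocol splits each subject-session at the trial
level: for a 15-trial (3-class) session the first 9 trials train and the
last 6 test; for a 24-trial (4-class) session the last 2 trials of each
emotion (in session order) test and the remaining 16 train.  Windows of a
trial never straddle the split.  Training uses minibatch Adam on the
cross-entropy of the modulus-softmax probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import autograd as ag
from .autograd import Adam, Tensor
from .complex_ops import ComplexTensor
from .errors import ProtocolError, ValidationError
from .model import CVEEGNet
from .spectral import EEGSegment, preprocess_segments

__all__ = [
    "SplitPlan", "TrainConfig", "EvalResult", "EvalReport",
    "cross_entropy", "make_split", "split_segments", "train", "evaluate",
    "export_features",
]

LR_SEARCH_RANGE = (0.001, 0.035)
PROB_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def cross_entropy(probs, labels_onehot) -> Tensor:
    """Mean negative log-likelihood, L = -(1/M) sum_i sum_k y_ik log p_ik.

    `probs` rows must already be normalized; probabilities are floored at
    1e-12 before the log.
    """
    probs_t = probs if isinstance(probs, Tensor) else Tensor(probs)
    y = np.asarray(labels_onehot, dtype=probs_t.data.dtype)
    if probs_t.data.shape != y.shape:
        raise ValidationError(f"probs shape {probs_t.data.shape} != labels shape {y.shape}")
    rows = probs_t.data.sum(axis=1)
    if np.any(np.abs(rows - 1.0) > 1e-4) or np.any(probs_t.data < -1e-9):
        raise ValidationError("probs rows must be normalized probability distributions")
    logp = ag.log(ag.maximum_const(probs_t, PROB_FLOOR))
    picked = ag.tsum(ag.mul(logp, y), axis=1)
    return ag.neg(ag.tmean(picked))


def one_hot(labels: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((len(labels), k))
    out[np.arange(len(labels)), labels] = 1.0
    return out


# ---------------------------------------------------------------------------
# protocol
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Trial-level train/test assignment for one subject-session."""

    train_trials: List[int]
    test_trials: List[int]
    dataset_kind: str

    def __post_init__(self):
        overlap = set(self.train_trials) & set(self.test_trials)
        if overlap:
            raise ProtocolError(f"trials on both sides of the split: {sorted(overlap)}")


def make_split(trial_labels: Sequence[int], dataset_kind: str) -> SplitPlan:
    """Deterministic trial-level split per the subject-dependent protocol.

    trial_labels are in session order; trial ids are their 0-based indices.
    """
    n = len(trial_labels)
    if dataset_kind == "SEED":
        if n != 15:
            raise ProtocolError(f"a 3-class session must have 15 trials, got {n}")
        return SplitPlan(list(range(9)), list(range(9, 15)), dataset_kind)
    if dataset_kind == "SEED-IV":
        if n != 24:
            raise ProtocolError(f"a 4-class session must have 24 trials, got {n}")
        test: List[int] = []
        for emotion in sorted(set(trial_labels)):
            idx = [i for i, lab in enumerate(trial_labels) if lab == emotion]
            if len(idx) != 6:
                raise ProtocolError(
                    f"emotion {emotion} has {len(idx)} trials, expected 6"
                )
            test.extend(idx[-2:])  # last two trials of each emotion, session order
        train = [i for i in range(n) if i not in set(test)]
        return SplitPlan(train, sorted(test), dataset_kind)
    raise ProtocolError(f"unknown dataset kind {dataset_kind!r}")


def split_segments(segments: Sequence[EEGSegment], plan: SplitPlan
                   ) -> Tuple[List[EEGSegment], List[EEGSegment]]:
    """Assign whole trials to one side; a window never crosses the split."""
    train_ids, test_ids = set(plan.train_trials), set(plan.test_trials)
    tr = [s for s in segments if s.trial_id in train_ids]
    te = [s for s in segments if s.trial_id in test_ids]
    return tr, te


def trial_split(segments: Sequence[EEGSegment], train_fraction: float = 2 / 3
                ) -> Tuple[List[EEGSegment], List[EEGSegment]]:
    """Generic per-class trial-level split for synthetic sessions: the first
    fraction of each class's trials (by trial id) train, the rest test."""
    by_class: Dict[int, List[int]] = {}
    for s in segments:
        by_class.setdefault(s.label, [])
        if s.trial_id not in by_class[s.label]:
            by_class[s.label].append(s.trial_id)
    train_ids = set()
    for ids in by_class.values():
        ids.sort()
        train_ids.update(ids[: int(round(len(ids) * train_fraction))])
    tr = [s for s in segments if s.trial_id in train_ids]
    te = [s for s in segments if s.trial_id not in train_ids]
    return tr, te


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    batch_size: int = 64
    epochs: int = 120
    learning_rate: float = 0.002
    seed: int = 0
    dtype: str = "float32"
    allow_lr_outside_range: bool = False

    def __post_init__(self):
        lo, hi = LR_SEARCH_RANGE
        if not self.allow_lr_outside_range and not (lo <= self.learning_rate <= hi):
            if self.learning_rate != 0.0:
                raise ValidationError(
                    f"learning_rate {self.learning_rate} outside the searched range "
                    f"[{lo}, {hi}]; set allow_lr_outside_range=True to override"
                )


def train(model: CVEEGNet, segments: Sequence[EEGSegment], cfg: TrainConfig
          ) -> Tuple[CVEEGNet, List[float]]:
    """Minibatch Adam training on the spectral pipeline of `segments`.

    Returns the model (trained in place) and the per-epoch mean loss
    history.  Deterministic given cfg.seed.
    """
    if len(segments) == 0:
        raise ProtocolError("training set is empty")
    dtype = np.dtype(cfg.dtype)
    xr, xi, labels = preprocess_segments(segments, dtype=dtype)
    k = model.config.n_classes
    if labels.max() >= k:
        raise ValidationError(f"label {labels.max()} outside [0, {k})")
    y = one_hot(labels, k).astype(dtype)

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    n = xr.shape[0]
    history: List[float] = []
    model.train()
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses, weights = [], []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if len(idx) < 2:
                continue  # batch statistics undefined on a single sample
            xb = ComplexTensor(xr[idx], xi[idx])
            loss = cross_entropy(model.forward(xb), y[idx])
            if cfg.learning_rate > 0:
                opt.zero_grad()
                loss.backward()
                opt.step()
            losses.append(float(loss.data))
            weights.append(len(idx))
        history.append(float(np.average(losses, weights=weights)))
    model.eval()
    return model, history


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalResult:
    """Segment-level accuracy and raw confusion counts for one test split."""

    accuracy: float              # percent
    confusion_counts: np.ndarray  # (K, K), rows = true class
    n_segments: int


def evaluate(model: CVEEGNet, segments: Sequence[EEGSegment]) -> EvalResult:
    """Segment-level accuracy (%) and confusion counts on a test split."""
    if len(segments) == 0:
        raise ProtocolError("test set is empty")
    xr, xi, labels = preprocess_segments(segments, dtype=model.dtype)
    model.eval()
    probs = model.predict(ComplexTensor(xr, xi))
    pred = probs.argmax(axis=1)
    k = model.config.n_classes
    conf = np.zeros((k, k), dtype=np.int64)
    np.add.at(conf, (labels, pred), 1)
    acc = 100.0 * float((pred == labels).mean())
    return EvalResult(accuracy=acc, confusion_counts=conf, n_segments=len(segments))


@dataclass
class EvalReport:
    """Aggregation across subject-sessions: accuracy table, mean/std, and a
    pooled row-normalized confusion matrix (%)."""

    n_classes: int
    entries: List[dict] = field(default_factory=list)
    _pooled: np.ndarray = None

    def __post_init__(self):
        if self._pooled is None:
            self._pooled = np.zeros((self.n_classes, self.n_classes), dtype=np.int64)

    def add(self, subject: int, session: int, result: EvalResult):
        self.entries.append({
            "subject": subject, "session": session,
            "accuracy": result.accuracy, "n_segments": result.n_segments,
        })
        self._pooled += result.confusion_counts

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["subject", "session",
                                                   "accuracy", "n_segments"])

    def mean_std(self) -> Tuple[float, float]:
        acc = self.table()["accuracy"].to_numpy()
        return float(acc.mean()), float(acc.std(ddof=0))

    def pooled_confusion_percent(self) -> np.ndarray:
        counts = self._pooled.astype(float)
        rows = counts.sum(axis=1, keepdims=True)
        rows[rows == 0] = 1.0
        return 100.0 * counts / rows


def export_features(model: CVEEGNet, segments: Sequence[EEGSegment]) -> pd.DataFrame:
    """Penultimate-layer embedding per segment: real and imaginary parts of
    the hidden representation concatenated (length 2*hidden), plus label."""
    xr, xi, labels = preprocess_segments(segments, dtype=model.dtype)
    model.eval()
    feats = []
    with ag.no_grad():
        for i in range(0, xr.shape[0], 256):
            h = model.penultimate(ComplexTensor(xr[i:i + 256], xi[i:i + 256]))
            feats.append(np.concatenate([h.real.data, h.imag.data], axis=1))
    mat = np.concatenate(feats, axis=0)
    cols = [f"f{i}" for i in range(mat.shape[1])]
    df = pd.DataFrame(mat, columns=cols)
    df["label"] = labels
    return df
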