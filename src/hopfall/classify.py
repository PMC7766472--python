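"""Cosine-similarity template matching and binary fall-detection metrics.

A recalled 25-neuron state is compared against class templates by cosine
similarity; for bipolar vectors of length N this reduces to the Hamming
closed form (N - 2 d_H) / N.  The fall/not-fall decision is made against
the fall template at a confidence threshold (default 0.8), and batches of
decisions are summarized with the standard confusion counts and

    accuracy = (TP + TN) / (TP + FP + TN + FN).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .features import PatternTemplate

__all__ = [
    "DEFAULT_DECISION_THRESHOLD",
    "ClassificationResult",
    "EvaluationReport",
    "cosine_similarity",
    "classify_sample",
    "evaluate",
]

DEFAULT_DECISION_THRESHOLD = 0.8

#: Label of the positive class throughout the package.
FALL_LABEL = "Fall"


@dataclass(frozen=True)
class ClassificationResult:
    similarities: dict[str, float]
    predicted_label: str
    is_fall: bool
    confidence: float
    threshold: float


@dataclass(frozen=True)
class EvaluationReport:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total


def _vec(x) -> np.ndarray:
    arr = np.asarray(x.vector if isinstance(x, PatternTemplate) else x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-D vector, got shape {arr.shape}")
    return arr


def cosine_similarity(a, b) -> float:
    """dot(a, b) / (|a| |b|); for bipolar vectors equals (N - 2 d_H) / N."""
    a, b = _vec(a), _vec(b)
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} != {b.size}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def classify_sample(
    recalled,
    templates: Mapping[str, PatternTemplate] | Sequence[PatternTemplate],
    positive_label: str = FALL_LABEL,
    threshold: float = DEFAULT_DECISION_THRESHOLD,
) -> ClassificationResult:
    """Match a recalled state against class templates.

    The fall decision is positive iff similarity to the fall template is
    >= ``threshold``.  When several class templates are supplied the
    predicted label is the argmax similarity (ties break lexicographically),
    independent of the binary decision.
    """
    if not -1 < threshold <= 1:
        raise ValueError("threshold must lie in (-1, 1]")
    if not isinstance(templates, Mapping):
        templates = {t.class_label or f"class{i}": t for i, t in enumerate(templates)}
    if positive_label not in templates:
        raise ValueError(f"missing template for positive class {positive_label!r}")
    sims = {label: cosine_similarity(recalled, tpl) for label, tpl in templates.items()}
    best = min(sims, key=lambda k: (-sims[k], k))
    confidence = sims[positive_label]
    return ClassificationResult(
        similarities=sims,
        predicted_label=best,
        is_fall=confidence >= threshold,
        confidence=confidence,
        threshold=threshold,
    )


def evaluate(
    decisions: Iterable[tuple[str, bool]],
    positive_label: str = FALL_LABEL,
) -> EvaluationReport:
    """Confusion counts from (true label, positive decision) pairs."""
    tp = fp = tn = fn = 0
    for true_label, positive in decisions:
        actual_fall = true_label == positive_label
        if actual_fall and positive:
            tp += 1
        elif actual_fall:
            fn += 1
        elif positive:
            fp += 1
        else:
            tn += 1
    if tp + fp + tn + fn == 0:
        raise ValueError("at least one decision required")
    return EvaluationReport(tp=tp, fp=fp, tn=tn, fn=fn)
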