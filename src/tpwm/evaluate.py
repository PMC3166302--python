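"""Evaluation metrics: pattern prediction accuracy, best-hit ROC/AUC with
two-fold cross-validation, and information content.

Pattern prediction accuracy Delta is the sum over positions and nucleotides
of the absolute differences between the true (marginal) probabilities and
their estimates; lower is better, with 0 <= Delta <= 2 * width.  Because a
motif can be recovered on either strand, Delta is computed for the estimate
and its reverse complement and the minimum is reported together with the
orientation used.

Motif enrichment is assessed at the sequence level: each sequence's single
best-hit score is the classifier statistic, and the ROC/AUC over positive
versus negative sequences measures how well the model separates them.  The
trapezoidal AUC of this curve equals the Mann-Whitney U statistic (ties
counted one half).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .model_core import PWM, TPWM, marginal_pwm
from .scanner import BackgroundModel, SequenceSet
from .simulate import MotifModel, shuffle_negatives

__all__ = [
    "PatternAccuracy",
    "RocCurve",
    "CrossValResult",
    "pattern_accuracy",
    "roc_auc",
    "crossval_enrichment",
    "information_content",
]


class PatternAccuracy(NamedTuple):
    delta: float
    orientation: str  # "forward" or "reverse_complement"


def _as_marginal(model) -> PWM:
    if isinstance(model, PWM):
        return model
    if isinstance(model, TPWM):
        return marginal_pwm(model)
    if isinstance(model, MotifModel):
        return model.marginal_pwm()
    raise TypeError(f"cannot extract marginals from {type(model).__name__}")


def pattern_accuracy(truth, estimate) -> PatternAccuracy:
    """Delta = sum_i sum_a |p_ia - phat_ia| over marginal probabilities.

    Accepts PWMs, TPWMs or MotifModels on either side; the estimate is also
    compared reverse-complemented and the minimum Delta is reported.
    """
    t = _as_marginal(truth)
    e = _as_marginal(estimate)
    if t.width != e.width:
        raise ValueError(f"width mismatch: {t.width} != {e.width}")
    fwd = float(np.abs(t.probs - e.probs).sum())
    rev = float(np.abs(t.probs - e.reverse_complement().probs).sum())
    if fwd <= rev:
        return PatternAccuracy(fwd, "forward")
    return PatternAccuracy(rev, "reverse_complement")


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(pos_scores, neg_scores) -> RocCurve:
    """Sequence-level ROC from best-hit scores (positives vs negatives)."""
    pos = np.asarray(list(pos_scores), dtype=float)
    neg = np.asarray(list(neg_scores), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative score")
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    s = np.concatenate([pos, neg])
    # -inf best-hit scores (all-skipped sequences) are legal classifier output
    s = np.nan_to_num(s, neginf=np.finfo(float).min, posinf=np.finfo(float).max)
    fpr, tpr, thr = _sk_roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


@dataclass(frozen=True)
class CrossValResult:
    folds: tuple[RocCurve, RocCurve]
    mean_auc: float


def crossval_enrichment(
    pos_seqs,
    trainer: Callable,
    seed=None,
    neg_factory: Callable | None = None,
    background: BackgroundModel | None = None,
    both_strands: bool = True,
) -> CrossValResult:
    """Two-fold cross-validated motif enrichment.

    The positive set is split into two equal halves at random (seeded); each
    half's negatives are made by shuffling that half's positives once.  The
    model returned by ``trainer(train_pos, train_neg)`` is used to score the
    held-out positives and their shuffled negatives; both ROC curves and
    their mean AUC are returned.  ``trainer`` must accept two lists of
    sequences and return a PWM or TPWM.
    """
    seqs = [s[1] if isinstance(s, tuple) else s for s in pos_seqs]
    if len(seqs) < 4:
        raise ValueError("need at least 4 positive sequences for two folds")
    ss = np.random.SeedSequence(seed)
    s_split, s_negA, s_negB = ss.spawn(3)
    order = np.random.default_rng(s_split).permutation(len(seqs))
    half = len(seqs) // 2
    foldA = [seqs[i] for i in order[:half]]
    foldB = [seqs[i] for i in order[half:]]
    factory = neg_factory or shuffle_negatives
    negA = factory(foldA, s_negA)
    negB = factory(foldB, s_negB)
    bg = background or BackgroundModel.uniform()

    curves = []
    for train_pos, train_neg, test_pos, test_neg in (
        (foldA, negA, foldB, negB),
        (foldB, negB, foldA, negA),
    ):
        model = trainer(train_pos, train_neg)
        pos_scores, _, _, _ = SequenceSet(test_pos).best(model, bg, both_strands)
        neg_scores, _, _, _ = SequenceSet(test_neg).best(model, bg, both_strands)
        curves.append(roc_auc(pos_scores, neg_scores))
    return CrossValResult(
        folds=(curves[0], curves[1]),
        mean_auc=(curves[0].auc + curves[1].auc) / 2.0,
    )


def information_content(pwm: PWM) -> float:
    """Total information content in bits: sum_i (2 + sum_a p log2 p), with
    0*log2(0) taken as 0."""
    p = pwm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return float((2.0 + terms.sum(axis=1)).sum())
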