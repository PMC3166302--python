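"""Discriminative TPWM training (TPD).

Given a positive sequence set (expected to be enriched in binding sites), a
negative set (expected to contain none), and an initial PWM, the algorithm
refines a tree-based PWM that best discriminates the two sets:

for each false-positive rate r in a predefined grid:
    model <- initial PWM
    repeat:
        1. scan the negative set with the current model; the cutoff is the
           score at which a fraction r of negative best hits is flagged;
        2. scan every positive sequence (at most one site per sequence) and
           collect the best-hit words scoring >= cutoff into an alignment;
        3. rebuild the TPWM from that alignment;
        4. stop when the symmetrized, position-averaged Kullback-Leibler
           divergence between the marginal PWMs of consecutive models drops
           below ``kld_tol`` (0.001 by default).
finally return the model whose confusion counts on the two sets maximize the
Matthews correlation coefficient (MCC); ties go to the lowest FPR.

Training is deterministic: identical inputs and configuration produce an
identical result.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .model_core import (
    DEFAULT_DEP_THRESHOLD,
    DEFAULT_MIN_LEAF,
    DEFAULT_PSEUDOCOUNT,
    PWM,
    SiteAlignment,
    TPWM,
    marginal_pwm,
)
from .scanner import BackgroundModel, SequenceSet, cutoff_at_fpr

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "TrainConfig",
    "FprTrace",
    "TrainResult",
    "TrainingError",
    "mcc",
    "pwm_kld",
    "tpd_fit_at_fpr",
    "tpd",
]

DEFAULT_FPR_GRID = (0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.3)


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 by convention when any marginal
    total of the confusion table is zero."""
    tp, tn, fp, fn = float(c.tp), float(c.tn), float(c.fp), float(c.fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def pwm_kld(a: PWM, b: PWM) -> float:
    """Symmetrized Kullback-Leibler divergence averaged over positions:

    (1/W) * sum_i sum_a 0.5 * [p ln(p/q) + q ln(q/p)].

    Requires strictly positive cells (use a pseudocount when estimating).
    """
    if a.width != b.width:
        raise ValueError(f"width mismatch: {a.width} != {b.width}")
    p, q = a.probs, b.probs
    if (p <= 0).any() or (q <= 0).any():
        raise ValueError(
            "zero probability cell; estimate the PWMs with a positive pseudocount"
        )
    kl = 0.5 * (p * np.log(p / q) + q * np.log(q / p))
    return float(kl.sum() / a.width)


@dataclass(frozen=True)
class TrainConfig:
    """TPD configuration.

    ``fpr_grid`` is the predefined set of false-positive rates explored;
    ``kld_tol`` the convergence threshold on the marginal-PWM divergence;
    ``max_inner_iter`` a safety bound on the inner loop.  ``seed`` is unused
    by training itself (which is deterministic) and echoed for provenance.
    """

    fpr_grid: tuple[float, ...] = DEFAULT_FPR_GRID
    kld_tol: float = 1e-3
    max_inner_iter: int = 50
    min_leaf: int = DEFAULT_MIN_LEAF
    dep_threshold: float = DEFAULT_DEP_THRESHOLD
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    both_strands: bool = True
    background: BackgroundModel | None = None
    seed: int | None = None

    def __post_init__(self):
        grid = tuple(float(r) for r in self.fpr_grid)
        if not grid:
            raise ValueError("fpr_grid must be non-empty")
        if any(not 0.0 < r < 1.0 for r in grid):
            raise ValueError("fpr_grid values must lie strictly in (0, 1)")
        if list(grid) != sorted(grid):
            raise ValueError("fpr_grid must be sorted ascending")
        if self.kld_tol <= 0:
            raise ValueError("kld_tol must be > 0")
        object.__setattr__(self, "fpr_grid", grid)


@dataclass
class FprTrace:
    fpr: float
    iterations: int
    final_kld: float
    confusion: ConfusionCounts | None
    mcc: float
    n_aligned_sites: int
    cutoff: float
    converged: bool
    failed: bool = False


@dataclass
class TrainResult:
    best_model: TPWM
    best_fpr: float
    best_mcc: float
    cutoff: float
    per_fpr_trace: list[FprTrace] = field(default_factory=list)
    aligned_sites: SiteAlignment | None = None

    @property
    def predicted_tpr(self) -> float:
        c = next(
            t.confusion for t in self.per_fpr_trace if t.fpr == self.best_fpr
        )
        return c.tp / (c.tp + c.fn)


def _floor_marginal(pwm: PWM, eps: float = 1e-9) -> PWM:
    """Clamp zero cells before the convergence KLD (branch probabilities are
    raw fractions, so marginals can contain exact zeros)."""
    p = np.clip(pwm.probs, eps, None)
    return PWM(p / p.sum(axis=1, keepdims=True))


def _as_set(seqs) -> SequenceSet:
    if isinstance(seqs, SequenceSet):
        return seqs
    seqs = list(seqs)
    if seqs and isinstance(seqs[0], tuple):
        return SequenceSet([s for _, s in seqs], ids=[i for i, _ in seqs])
    return SequenceSet(seqs)


def tpd_fit_at_fpr(
    pos_seqs,
    neg_seqs,
    init_pwm: PWM,
    r: float,
    cfg: TrainConfig | None = None,
):
    """Run the TPD inner loop at one false-positive rate.

    Returns ``(model, trace, alignment)``; on failure (no positive sequence
    clears the cutoff at some iteration) the model and alignment are None and
    the trace carries ``failed=True`` with an ``mcc`` of -inf so the FPR is
    excluded from selection without aborting the grid.
    """
    cfg = cfg or TrainConfig()
    pos = _as_set(pos_seqs)
    neg = _as_set(neg_seqs)
    bg = cfg.background or BackgroundModel.uniform()

    current = init_pwm
    prev_marginal = _floor_marginal(init_pwm)
    kld = math.inf
    iterations = 0
    converged = False

    def failed_trace():
        return FprTrace(
            fpr=r, iterations=iterations, final_kld=kld, confusion=None,
            mcc=-math.inf, n_aligned_sites=0, cutoff=math.nan,
            converged=False, failed=True,
        )

    while iterations < cfg.max_inner_iter:
        iterations += 1
        neg_scores, _, _ = neg.hit_words(current, bg, cfg.both_strands)
        cut = cutoff_at_fpr(neg_scores, r).cutoff
        pos_scores, pos_words, pos_valid = pos.hit_words(
            current, bg, cfg.both_strands
        )
        keep = pos_valid & (pos_scores >= cut)
        if not keep.any():
            logger.warning("FPR %.4g: no positive sequence clears the cutoff", r)
            return None, failed_trace(), None
        alignment = SiteAlignment(pos_words[keep])
        model = _build(alignment, cfg)
        marg = _floor_marginal(marginal_pwm(model))
        kld = pwm_kld(marg, prev_marginal)
        prev_marginal = marg
        current = model
        if kld < cfg.kld_tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "FPR %.4g: inner loop hit max_inner_iter=%d (last KLD %.3g); "
            "keeping the last model", r, cfg.max_inner_iter, kld,
        )

    # confusion counts and the final alignment under the final model/cutoff
    neg_scores, _, neg_valid = neg.hit_words(current, bg, cfg.both_strands)
    cutres = cutoff_at_fpr(neg_scores, r)
    pos_scores, pos_words, pos_valid = pos.hit_words(
        current, bg, cfg.both_strands
    )
    keep = pos_valid & (pos_scores >= cutres.cutoff)
    if not keep.any():
        return None, failed_trace(), None
    alignment = SiteAlignment(pos_words[keep])
    tp = int(keep.sum())
    fn = pos.n - tp
    fp = int((neg_valid & (neg_scores >= cutres.cutoff)).sum())
    tn = neg.n - fp
    confusion = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    trace = FprTrace(
        fpr=r,
        iterations=iterations,
        final_kld=kld,
        confusion=confusion,
        mcc=mcc(confusion),
        n_aligned_sites=alignment.count,
        cutoff=cutres.cutoff,
        converged=converged,
    )
    return current, trace, alignment


def _build(alignment: SiteAlignment, cfg: TrainConfig) -> TPWM:
    from .model_core import build_tpwm

    return build_tpwm(
        alignment,
        min_leaf=cfg.min_leaf,
        threshold=cfg.dep_threshold,
        pseudocount=cfg.pseudocount,
    )


def tpd(pos_seqs, neg_seqs, init_pwm: PWM, cfg: TrainConfig | None = None) -> TrainResult:
    """Full TPD run: fit at every grid FPR and keep the MCC-maximal model.

    Ties on MCC go to the lowest FPR.  Raises :class:`TrainingError` when
    every grid entry fails to align any site.
    """
    cfg = cfg or TrainConfig()
    pos = _as_set(pos_seqs)
    neg = _as_set(neg_seqs)
    traces: list[FprTrace] = []
    best = None  # (mcc, model, trace, alignment)
    for r in cfg.fpr_grid:
        model, trace, alignment = tpd_fit_at_fpr(pos, neg, init_pwm, r, cfg)
        traces.append(trace)
        if trace.failed:
            continue
        if best is None or trace.mcc > best[0]:
            best = (trace.mcc, model, trace, alignment)
    if best is None:
        raise TrainingError("no model discriminates the positive set")
    _, model, trace, alignment = best
    return TrainResult(
        best_model=model,
        best_fpr=trace.fpr,
        best_mcc=trace.mcc,
        cutoff=trace.cutoff,
        per_fpr_trace=traces,
        aligned_sites=alignment,
    )


def trace_table(traces) -> "pd.DataFrame":
    """Per-FPR trace as a DataFrame (columns of the trace TSV)."""
    import pandas as pd

    rows = []
    for t in traces:
        c = t.confusion or ConfusionCounts(0, 0, 0, 0)
        rows.append(
            dict(
                fpr=t.fpr, iterations=t.iterations, final_kld=t.final_kld,
                tp=c.tp, fn=c.fn, fp=c.fp, tn=c.tn,
                mcc=t.mcc, n_sites=t.n_aligned_sites,
            )
        )
    return pd.DataFrame(rows)
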