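"""Window scanning, best-hit extraction and FPR-based cutoff calibration.

Sequences are scored with a log-odds statistic in bits:

    score(w) = log2( P(w | model) / prod_i bg(w_i) )

where the model is a plain PWM or a TPWM (composite probability) and the
background is an order-0 nucleotide distribution (uniform by default).  Each
sequence contributes at most one site -- its best-scoring window over all
offsets and, by default, both strands.  Windows containing non-ACGT letters
are skipped.  Score cutoffs are calibrated empirically on a negative set: the
cutoff at false-positive rate r is the floor(r*m)-th largest best-hit score
of the m negative sequences, with classification everywhere using
``score >= cutoff``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import PWM, TPWM, decode, encode

__all__ = [
    "BackgroundModel",
    "ScanHit",
    "CutoffResult",
    "SequenceSet",
    "score_window",
    "best_hit",
    "best_hits",
    "cutoff_at_fpr",
    "write_hits_tsv",
]


@dataclass(frozen=True)
class BackgroundModel:
    """Order-0 nucleotide background for log-odds scoring."""

    probs: np.ndarray = None

    def __post_init__(self):
        p = self.probs
        p = np.full(4, 0.25) if p is None else np.asarray(p, dtype=float)
        if p.shape != (4,):
            raise ValueError("background needs exactly 4 probabilities")
        if (p <= 0).any():
            raise ValueError("background probabilities must all be > 0")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")
        object.__setattr__(self, "probs", p)

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(np.full(4, 0.25))

    @classmethod
    def from_sequences(cls, sequences) -> "BackgroundModel":
        """Empirical order-0 composition of a sequence collection (ACGT only)."""
        counts = np.zeros(4, dtype=np.int64)
        for seq in sequences:
            codes = encode(seq)
            counts += np.bincount(codes[codes >= 0], minlength=4)
        if counts.sum() == 0:
            raise ValueError("no ACGT letters in sequences")
        return cls(counts / counts.sum())

    def log2_probs(self) -> np.ndarray:
        return np.log2(self.probs)


@dataclass(frozen=True)
class ScanHit:
    """Best-scoring window of one sequence.

    ``start`` is the 0-based offset of the window in the forward sequence;
    ``word`` is reverse-complemented into motif orientation when strand is '-'.
    """

    sequence_id: str
    start: int
    strand: str
    score: float
    word: str


@dataclass(frozen=True)
class CutoffResult:
    fpr_requested: float
    cutoff: float
    fpr_empirical: float
    k: int


def _model_width(model) -> int:
    return model.width


def _log2_model(model, X: np.ndarray) -> np.ndarray:
    """log2 P(word | model) for each row of an (N, W) code matrix (codes 0..3)."""
    if isinstance(model, TPWM):
        return model.log2_word_probs(X)
    if isinstance(model, PWM):
        lp = model.log2_probs()
        out = np.zeros(X.shape[0], dtype=float)
        for pos in range(model.width):
            out += lp[pos, X[:, pos]]
        return out
    raise TypeError(f"cannot score with model of type {type(model).__name__}")


def score_window(model, word: str, background: BackgroundModel | None = None) -> float:
    """Log-odds score (bits) of one width-length word."""
    bg = background or BackgroundModel.uniform()
    w = _model_width(model)
    if len(word) != w:
        raise ValueError(f"word length {len(word)} != model width {w}")
    codes = encode(word)
    if (codes < 0).any():
        raise ValueError(f"non-ACGT character in word {word!r}")
    X = codes[None, :]
    with np.errstate(divide="ignore"):
        lp = _log2_model(model, X)[0]
    return float(lp - bg.log2_probs()[codes].sum())


class SequenceSet:
    """A set of sequences with cached, width-specific scan windows.

    Sequences may have different lengths; shorter ones are padded internally
    and padded windows are treated like windows containing non-ACGT letters
    (skipped).  Window matrices are cached per (width, strand) so repeated
    scans with same-width models -- the TPD inner loop -- only pay the
    scoring cost.
    """

    def __init__(self, sequences, ids=None):
        seqs = list(sequences)
        if not seqs:
            raise ValueError("empty sequence set")
        self.ids = list(ids) if ids is not None else [
            f"seq{i}" for i in range(len(seqs))
        ]
        if len(self.ids) != len(seqs):
            raise ValueError("ids and sequences differ in length")
        self.lengths = np.array([len(s) for s in seqs])
        self.n = len(seqs)
        L = int(self.lengths.max())
        mat = np.full((self.n, L), -1, dtype=np.int8)
        for i, s in enumerate(seqs):
            mat[i, : len(s)] = encode(s)
        self._mat = mat
        self._cache: dict[tuple, tuple] = {}

    def _windows(self, width: int):
        key = width
        if key in self._cache:
            return self._cache[key]
        L = self._mat.shape[1]
        if width > L:
            raise ValueError(
                f"model width {width} exceeds longest sequence length {L}"
            )
        nwin = L - width + 1
        Vf = np.lib.stride_tricks.sliding_window_view(self._mat, width, axis=1)
        Xf = np.ascontiguousarray(Vf).reshape(-1, width)
        rc = np.where(self._mat >= 0, 3 - self._mat, np.int8(-1))[:, ::-1]
        Vr = np.lib.stride_tricks.sliding_window_view(rc, width, axis=1)
        # reorder so row (seq, s) is the reverse complement of the forward
        # window starting at s
        Xr = np.ascontiguousarray(Vr[:, ::-1, :]).reshape(-1, width)
        valid = (Xf >= 0).all(axis=1)
        bundle = (Xf, Xr, valid, nwin)
        self._cache[key] = bundle
        return bundle

    def _window_scores(self, model, background: BackgroundModel):
        """Per-window log-odds scores on both strands; invalid windows -inf."""
        width = _model_width(model)
        Xf, Xr, valid, nwin = self._windows(width)
        lbg = background.log2_probs()

        def score_matrix(X):
            Xc = np.where(X < 0, 0, X)
            with np.errstate(divide="ignore", invalid="ignore"):
                s = _log2_model(model, Xc)
                for pos in range(width):
                    s -= lbg[Xc[:, pos]]
            s[~valid] = -np.inf
            return s.reshape(self.n, nwin)

        return score_matrix(Xf), score_matrix(Xr), valid.reshape(self.n, nwin), nwin

    def best(self, model, background: BackgroundModel | None = None,
             both_strands: bool = True):
        """Best window per sequence.

        Returns ``(scores, starts, strands, valid_any)`` arrays; sequences
        whose windows are all skipped get score -inf and valid_any False.
        Ties are broken by smaller start, then the forward strand.
        """
        bg = background or BackgroundModel.uniform()
        sf, sr, valid, nwin = self._window_scores(model, bg)
        if both_strands:
            comb = np.empty((self.n, 2 * nwin))
            comb[:, 0::2] = sf  # index = 2*start + strand: lexicographic ties
            comb[:, 1::2] = sr
            idx = np.argmax(comb, axis=1)
            scores = comb[np.arange(self.n), idx]
            starts = idx // 2
            strands = idx % 2
        else:
            idx = np.argmax(sf, axis=1)
            scores = sf[np.arange(self.n), idx]
            starts = idx
            strands = np.zeros(self.n, dtype=int)
        valid_any = valid.any(axis=1)
        # a -inf best score on a sequence with valid windows means the model
        # assigns zero probability everywhere; report the first valid window
        fix = np.flatnonzero(~np.isfinite(scores) & valid_any)
        for i in fix:
            j = int(np.argmax(valid[i]))
            starts[i] = j
            strands[i] = 0
        return scores, starts, strands, valid_any

    def best_hits(self, model, background: BackgroundModel | None = None,
                  both_strands: bool = True) -> list[ScanHit | None]:
        width = _model_width(model)
        scores, starts, strands, valid_any = self.best(
            model, background, both_strands
        )
        Xf, Xr, _, nwin = self._windows(width)
        hits: list[ScanHit | None] = []
        for i in range(self.n):
            if not valid_any[i]:
                hits.append(None)
                continue
            flat = i * nwin + int(starts[i])
            word = decode(Xf[flat] if strands[i] == 0 else Xr[flat])
            hits.append(
                ScanHit(
                    sequence_id=self.ids[i],
                    start=int(starts[i]),
                    strand="+" if strands[i] == 0 else "-",
                    score=float(scores[i]),
                    word=word,
                )
            )
        return hits

    def hit_words(self, model, background=None, both_strands=True):
        """Best-hit scores plus the matched words as a code matrix.

        Lower-level companion to :meth:`best_hits` used by the training loop;
        rows of the word matrix for skipped sequences are undefined (mask with
        ``valid_any``).
        """
        width = _model_width(model)
        scores, starts, strands, valid_any = self.best(
            model, background, both_strands
        )
        Xf, Xr, _, nwin = self._windows(width)
        flat = np.arange(self.n) * nwin + starts
        words = np.where(strands[:, None] == 0, Xf[flat], Xr[flat])
        return scores, words.astype(np.int8), valid_any


def best_hit(model, sequence: str, background: BackgroundModel | None = None,
             both_strands: bool = True, sequence_id: str = "seq") -> ScanHit | None:
    """Best-scoring window of one sequence, or None if every window is skipped."""
    if len(sequence) < _model_width(model):
        raise ValueError(
            f"sequence length {len(sequence)} < model width {_model_width(model)}"
        )
    return SequenceSet([sequence], ids=[sequence_id]).best_hits(
        model, background, both_strands
    )[0]


def best_hits(model, sequences, background=None, both_strands=True, ids=None):
    """Best-scoring window of every sequence in a collection."""
    return SequenceSet(sequences, ids=ids).best_hits(
        model, background, both_strands
    )


def cutoff_at_fpr(neg_best_scores, r: float) -> CutoffResult:
    """Score cutoff at which a fraction r of negative sequences is flagged.

    k = floor(r*m) of the m negative best-hit scores are allowed at/above the
    cutoff; with k = 0 the cutoff is placed just above the maximum so no
    negative is flagged.  Ties can push the empirical FPR above r; the
    recomputed value is reported, not hidden.
    """
    scores = np.asarray(list(neg_best_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("empty score list")
    if not 0 < r <= 1:
        raise ValueError("false positive rate must lie in (0, 1]")
    m = scores.size
    k = int(np.floor(r * m))
    if k == 0:
        top = scores.max()
        cutoff = top + 1e-9 if np.isfinite(top) else 0.0
    else:
        cutoff = float(np.sort(scores)[::-1][k - 1])
    k_at = int((scores >= cutoff).sum())
    return CutoffResult(
        fpr_requested=float(r),
        cutoff=float(cutoff),
        fpr_empirical=k_at / m,
        k=k_at,
    )


def write_hits_tsv(hits, width: int, path) -> None:
    """Write hits as 6-column BED-like TSV (0-based half-open coordinates)."""
    with open(path, "w") as fh:
        for hit in hits:
            if hit is None:
                continue
            fh.write(
                f"{hit.sequence_id}\t{hit.start}\t{hit.start + width}\t"
                f"{hit.word}\t{hit.score:.6f}\t{hit.strand}\n"
            )
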