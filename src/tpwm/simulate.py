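"""Synthetic benchmark generator: Markov background, motif models with
intra-motif dependency, abundance-controlled implantation and shuffled
negatives.

The generator emulates the standard simulation design for discriminative
motif learning: ``n`` background sequences of fixed length are drawn from an
order-k Markov chain (k = 3 by default, with a user-suppliable transition
table; uniform fallback); a motif site is implanted into each sequence with
probability ``abundance`` (0.8 "abundant", 0.5 "weak") at a uniformly chosen
offset, overwriting the background so lengths stay fixed; and negatives are
produced by an independent per-sequence Fisher-Yates shuffle, which destroys
positional signal while preserving each sequence's exact base composition.

Motif models are either column-independent or carry *correlated blocks*:
ordered subsets of positions governed by a joint probability table over
4^|block| words.  The shipped dependent models (widths 10 and 20 with 2, 4
and 6 correlated positions) are synthetic surrogates built from a two-class
latent mixture; each position couples to the latent class with its own
strength, which fixes the exact pairwise dependency structure in closed form
(for a two-class mixture, D(i,j) = delta_i * delta_j / 4 where
delta_p = sum_a |P(a | class 1) - P(a | class 2)| at position p).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import ALPHABET, PWM, decode, encode

__all__ = [
    "BackgroundSpec",
    "CorrelatedBlock",
    "MotifModel",
    "SimulatedDataset",
    "markov_background",
    "sample_site",
    "implant",
    "shuffle_negatives",
    "make_dataset",
    "read_transitions",
    "load_motif_model",
    "builtin_model",
    "BUILTIN_MODELS",
]


# --------------------------------------------------------------------------
# background


@dataclass(frozen=True)
class BackgroundSpec:
    """Order-k Markov background over ACGT.

    ``transitions`` has shape (4**order, 4): row c is the distribution of the
    next base given the length-k context with base-4 index c (first context
    base most significant).  ``initial`` is the distribution over the 4**order
    possible initial contexts.  Both default to uniform.
    """

    order: int = 3
    transitions: np.ndarray | None = None
    initial: np.ndarray | None = None

    def __post_init__(self):
        if self.order < 0:
            raise ValueError("order must be >= 0")
        nctx = 4 ** self.order
        t = self.transitions
        if t is not None:
            t = np.asarray(t, dtype=float)
            if t.shape != (nctx, 4):
                raise ValueError(
                    f"transition table must have shape ({nctx}, 4) for order "
                    f"{self.order}, got {t.shape}"
                )
            bad = np.flatnonzero(np.abs(t.sum(axis=1) - 1.0) > 1e-6)
            if bad.size:
                ctx = decode(_digits(bad[0], self.order)) if self.order else ""
                raise ValueError(
                    f"transition row for context {ctx!r} does not sum to 1"
                )
            if (t < 0).any():
                raise ValueError("transition probabilities must be >= 0")
            object.__setattr__(self, "transitions", t)
        init = self.initial
        if init is not None:
            init = np.asarray(init, dtype=float)
            if init.shape != (nctx,) or abs(init.sum() - 1.0) > 1e-6:
                raise ValueError(
                    f"initial distribution must be {nctx} probabilities summing to 1"
                )
            object.__setattr__(self, "initial", init)

    @property
    def is_uniform(self) -> bool:
        return self.transitions is None and self.initial is None

    def sample_codes(self, n: int, length: int, rng: np.random.Generator) -> np.ndarray:
        if length < self.order:
            raise ValueError("length must be >= order")
        if self.is_uniform:
            return rng.integers(0, 4, size=(n, length), dtype=np.int8)
        nctx = 4 ** self.order
        out = np.empty((n, length), dtype=np.int8)
        init = self.initial if self.initial is not None else np.full(nctx, 1.0 / nctx)
        ctx = rng.choice(nctx, size=n, p=init)
        for j, pos in enumerate(range(self.order - 1, -1, -1)):
            out[:, j] = (ctx >> (2 * pos)) & 3
        trans = (
            self.transitions
            if self.transitions is not None
            else np.full((nctx, 4), 0.25)
        )
        cum = trans.cumsum(axis=1)
        mask = nctx - 1 if self.order else 0
        for t in range(self.order, length):
            u = rng.random(n)
            nxt = (u[:, None] >= cum[ctx]).sum(axis=1)
            out[:, t] = nxt
            ctx = ((ctx << 2) | nxt) & mask if self.order else ctx
        return out


def _digits(index: int, k: int) -> np.ndarray:
    return np.array([(index >> (2 * p)) & 3 for p in range(k - 1, -1, -1)], dtype=np.int8)


def markov_background(
    n: int,
    length: int,
    order: int = 3,
    transitions: np.ndarray | None = None,
    initial: np.ndarray | None = None,
    seed=None,
) -> list[str]:
    """Draw ``n`` independent order-k Markov sequences of the given length."""
    spec = BackgroundSpec(order=order, transitions=transitions, initial=initial)
    rng = np.random.default_rng(seed)
    return [decode(row) for row in spec.sample_codes(n, length, rng)]


def read_transitions(path, order: int = 3) -> BackgroundSpec:
    """Read a transition table from TSV: 4**order context rows x 4 columns.

    An optional first column may name the context k-mer; rows are otherwise
    taken in base-4 (A<C<G<T) context order.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) == 5:
                parts = parts[1:]
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: expected 4 probabilities")
            rows.append([float(x) for x in parts])
    return BackgroundSpec(order=order, transitions=np.asarray(rows))


# --------------------------------------------------------------------------
# motif models


@dataclass(frozen=True)
class CorrelatedBlock:
    """Joint distribution over an ordered subset of motif positions.

    ``joint`` is a flat array of length 4**k in base-4 word order (first
    listed position most significant).
    """

    positions: tuple[int, ...]
    joint: np.ndarray

    def __post_init__(self):
        pos = tuple(int(p) for p in self.positions)
        if len(pos) < 2 or len(set(pos)) != len(pos):
            raise ValueError("block needs >= 2 distinct positions")
        j = np.asarray(self.joint, dtype=float).ravel()
        if j.shape != (4 ** len(pos),):
            raise ValueError(
                f"joint table must have 4**{len(pos)} entries, got {j.size}"
            )
        if (j < 0).any() or abs(j.sum() - 1.0) > 1e-9:
            raise ValueError("joint table must be a probability distribution")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "joint", j)

    @property
    def size(self) -> int:
        return len(self.positions)

    def marginals(self) -> np.ndarray:
        """Per-position marginals, shape (size, 4)."""
        k = self.size
        grid = self.joint.reshape((4,) * k)
        return np.vstack(
            [grid.sum(axis=tuple(a for a in range(k) if a != i)) for i in range(k)]
        )


@dataclass(frozen=True)
class MotifModel:
    """Fixed-width motif: independent columns plus disjoint correlated blocks.

    ``columns`` has shape (width, 4); rows belonging to a block are ignored
    (the block's joint table governs those positions).  Positions are 1-based.
    """

    width: int
    columns: np.ndarray
    blocks: tuple[CorrelatedBlock, ...] = ()

    def __post_init__(self):
        cols = np.asarray(self.columns, dtype=float)
        if cols.shape != (self.width, 4):
            raise ValueError(f"columns must have shape ({self.width}, 4)")
        object.__setattr__(self, "columns", cols)
        object.__setattr__(self, "blocks", tuple(self.blocks))
        covered: set[int] = set()
        for b in self.blocks:
            for p in b.positions:
                if not 1 <= p <= self.width:
                    raise ValueError(f"block position {p} outside 1..{self.width}")
                if p in covered:
                    raise ValueError(f"position {p} covered by two blocks")
                covered.add(p)
        for p in range(1, self.width + 1):
            if p in covered:
                continue
            row = cols[p - 1]
            if (row < 0).any() or abs(row.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"independent column {p} is not a probability distribution"
                )

    @property
    def block_positions(self) -> set[int]:
        return {p for b in self.blocks for p in b.positions}

    def marginal_pwm(self) -> PWM:
        """Exact position-wise marginals of the model."""
        probs = self.columns.copy()
        for b in self.blocks:
            m = b.marginals()
            for i, p in enumerate(b.positions):
                probs[p - 1] = m[i]
        return PWM(probs)

    def consensus(self) -> str:
        return self.marginal_pwm().consensus()

    def sample_codes(self, m: int, rng: np.random.Generator) -> np.ndarray:
        out = np.empty((m, self.width), dtype=np.int8)
        blocked = self.block_positions
        for p in range(1, self.width + 1):
            if p in blocked:
                continue
            cum = self.columns[p - 1].cumsum()
            out[:, p - 1] = (rng.random(m)[:, None] >= cum).sum(axis=1)
        for b in self.blocks:
            words = rng.choice(b.joint.size, size=m, p=b.joint)
            for i, p in enumerate(b.positions):
                out[:, p - 1] = (words >> (2 * (b.size - 1 - i))) & 3
        return out


def sample_site(model: MotifModel, seed=None) -> str:
    """Draw one site from the motif model."""
    rng = np.random.default_rng(seed)
    return decode(model.sample_codes(1, rng)[0])


# --------------------------------------------------------------------------
# implantation and negatives


def implant(sequences, model: MotifModel, abundance: float, seed=None):
    """Implant one motif site per sequence with probability ``abundance``.

    Sites overwrite the background at a uniformly chosen valid offset so
    sequence lengths are preserved.  Returns ``(sequences, truth)`` where
    truth is a DataFrame with columns sequence_id, has_site, start, end,
    site_word (0-based half-open; start/end are -1 and site_word empty for
    sequences without a site).
    """
    if not 0.0 <= abundance <= 1.0:
        raise ValueError("abundance must lie in [0, 1]")
    seqs = list(sequences)
    W = model.width
    for i, s in enumerate(seqs):
        if len(s) < W:
            raise ValueError(f"sequence {i} shorter than motif width {W}")
    rng = np.random.default_rng(seed)
    has_site = rng.random(len(seqs)) < abundance
    n_sites = int(has_site.sum())
    words = model.sample_codes(n_sites, rng) if n_sites else np.empty((0, W), np.int8)
    out, rows = [], []
    j = 0
    for i, s in enumerate(seqs):
        if has_site[i]:
            start = int(rng.integers(0, len(s) - W + 1))
            word = decode(words[j])
            j += 1
            out.append(s[:start] + word + s[start + W:])
            rows.append((f"seq{i}", True, start, start + W, word))
        else:
            out.append(s)
            rows.append((f"seq{i}", False, -1, -1, ""))
    truth = pd.DataFrame(
        rows, columns=["sequence_id", "has_site", "start", "end", "site_word"]
    )
    return out, truth


def shuffle_negatives(sequences, seed=None) -> list[str]:
    """Independently permute the letters of every sequence (one Fisher-Yates
    pass per sequence), preserving its exact base composition."""
    rng = np.random.default_rng(seed)
    out = []
    for s in sequences:
        arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
        out.append(rng.permutation(arr).tobytes().decode("ascii"))
    return out


# --------------------------------------------------------------------------
# datasets


@dataclass
class SimulatedDataset:
    positives: list[tuple[str, str]]
    negatives: list[tuple[str, str]]
    truth: pd.DataFrame
    model: MotifModel
    abundance: float
    seed: object


def make_dataset(
    model: MotifModel,
    n: int = 3000,
    length: int = 200,
    abundance: float = 0.8,
    background: BackgroundSpec | None = None,
    seed=None,
    out_prefix=None,
) -> SimulatedDataset:
    """Positive set with implanted sites plus per-sequence shuffled negatives.

    Defaults follow the benchmark design this generator emulates: 3000
    sequences of 200 bp, third-order Markov background (uniform transition
    table unless one is supplied), one site per positive sequence with the
    stated abundance.  All randomness derives from ``seed`` through
    independent per-stage streams, so reruns are file-identical.
    """
    bg = background or BackgroundSpec()
    ss = np.random.SeedSequence(seed)
    s_bg, s_implant, s_shuffle = ss.spawn(3)
    raw = [
        decode(row)
        for row in bg.sample_codes(n, length, np.random.default_rng(s_bg))
    ]
    pos, truth = implant(raw, model, abundance, seed=s_implant)
    neg = shuffle_negatives(pos, seed=s_shuffle)
    positives = [(f"seq{i}", s) for i, s in enumerate(pos)]
    negatives = [(f"seq{i}_shuf", s) for i, s in enumerate(neg)]
    ds = SimulatedDataset(positives, negatives, truth, model, abundance, seed)
    if out_prefix is not None:
        from .io_formats import write_fasta

        write_fasta(positives, f"{out_prefix}_pos.fa")
        write_fasta(negatives, f"{out_prefix}_neg.fa")
        truth.to_csv(f"{out_prefix}_truth.tsv", sep="\t", index=False)
    return ds


# --------------------------------------------------------------------------
# shipped motif models (synthetic surrogates)

_CONSENSUS_SOURCE = "TGACGTCATTCGAACGGTAC"


def _independent_columns(width: int, major: float) -> np.ndarray:
    cols = np.full((width, 4), (1.0 - major) / 3.0)
    for p, letter in enumerate(_CONSENSUS_SOURCE[:width]):
        cols[p, ALPHABET.index(letter)] = major
    return cols


def _two_class_joint(positions, class_letters, couplings) -> CorrelatedBlock:
    """Joint table of a two-class latent mixture over a correlated block.

    Class 1 prefers ``class_letters[p][0]`` at position p with probability
    ``couplings[p]`` (remainder spread over the other letters); class 2
    prefers ``class_letters[p][1]``.  Classes are equiprobable.
    """
    dists = {1: [], 2: []}
    for p in positions:
        q = couplings[p]
        for cls in (1, 2):
            d = np.full(4, (1.0 - q) / 3.0)
            d[ALPHABET.index(class_letters[p][cls - 1])] = q
            dists[cls].append(d)
    joint = 0.5 * functools.reduce(np.multiply.outer, dists[1]) + 0.5 * functools.reduce(
        np.multiply.outer, dists[2]
    )
    return CorrelatedBlock(positions=tuple(positions), joint=joint.ravel())


def independent_motif(width: int = 10, strength: str = "strong") -> MotifModel:
    """Column-independent surrogate motif.

    The strong tier puts probability 0.97 on the consensus base of every
    column (~1.76 bits of information per position, a highly conserved
    site); the weak tier uses 0.7 (~0.64 bits per position)."""
    major = {"strong": 0.97, "weak": 0.7}[strength]
    return MotifModel(width=width, columns=_independent_columns(width, major))


def dependent_pair_10bp(strength: str = "strong") -> MotifModel:
    """Width-10 surrogate with two correlated positions (3, 8).

    Synthetic surrogate joint table (two-class mixture); the published joint
    tables for this benchmark design are not redistributable here.
    """
    scale = 1.0 if strength == "strong" else 0.85
    block = _two_class_joint(
        (3, 8),
        {3: ("A", "G"), 8: ("T", "C")},
        {3: 0.85 * scale + 0.25 * (1 - scale), 8: 0.95 * scale + 0.25 * (1 - scale)},
    )
    cols = _independent_columns(10, {"strong": 0.97, "weak": 0.7}[strength])
    return MotifModel(width=10, columns=cols, blocks=(block,))


def dependent_quad_20bp(strength: str = "strong") -> MotifModel:
    """Width-20 surrogate with four correlated positions (5, 6, 14, 15).

    Synthetic surrogate joint table (two-class mixture).
    """
    q = {
        "strong": {5: 0.9, 6: 0.85, 14: 0.8, 15: 0.95},
        "weak": {5: 0.8, 6: 0.75, 14: 0.7, 15: 0.85},
    }[strength]
    block = _two_class_joint(
        (5, 6, 14, 15),
        {5: ("A", "C"), 6: ("G", "T"), 14: ("T", "A"), 15: ("C", "G")},
        q,
    )
    cols = _independent_columns(20, {"strong": 0.97, "weak": 0.7}[strength])
    return MotifModel(width=20, columns=cols, blocks=(block,))


def dependent_hex_20bp(strength: str = "strong") -> MotifModel:
    """Width-20 surrogate with six correlated positions (3, 4, 12, 13, 19, 20).

    Synthetic surrogate joint table: a two-class latent mixture whose
    per-position couplings are strongest at position 20, so position 20 has
    the maximal dependency sum exactly (D(i,j) = delta_i * delta_j / 4 for a
    two-class mixture) and is the expected first split of a dependence tree.
    """
    q = {
        "strong": {3: 0.9, 4: 0.9, 12: 0.8, 13: 0.8, 19: 0.9, 20: 0.97},
        "weak": {3: 0.8, 4: 0.8, 12: 0.72, 13: 0.72, 19: 0.8, 20: 0.9},
    }[strength]
    block = _two_class_joint(
        (3, 4, 12, 13, 19, 20),
        {
            3: ("A", "G"),
            4: ("C", "T"),
            12: ("G", "A"),
            13: ("T", "C"),
            19: ("C", "G"),
            20: ("A", "C"),
        },
        q,
    )
    cols = _independent_columns(20, {"strong": 0.97, "weak": 0.7}[strength])
    return MotifModel(width=20, columns=cols, blocks=(block,))


BUILTIN_MODELS = {
    "strong10": lambda: independent_motif(10, "strong"),
    "weak10": lambda: independent_motif(10, "weak"),
    "strong20": lambda: independent_motif(20, "strong"),
    "weak20": lambda: independent_motif(20, "weak"),
    "dep10-2corr": lambda: dependent_pair_10bp("strong"),
    "dep20-4corr": lambda: dependent_quad_20bp("strong"),
    "dep20-6corr": lambda: dependent_hex_20bp("strong"),
    "dep10-2corr-weak": lambda: dependent_pair_10bp("weak"),
    "dep20-4corr-weak": lambda: dependent_quad_20bp("weak"),
    "dep20-6corr-weak": lambda: dependent_hex_20bp("weak"),
}


def builtin_model(name: str) -> MotifModel:
    try:
        return BUILTIN_MODELS[name]()
    except KeyError:
        raise ValueError(
            f"unknown builtin model {name!r}; available: {sorted(BUILTIN_MODELS)}"
        ) from None


def load_motif_model(path) -> MotifModel:
    """Load a MotifModel from YAML/JSON.

    Schema: ``{width: int, columns: [[pA,pC,pG,pT], ...],
    blocks: [{positions: [..], joint: {"WORD": prob, ...}}]}``; or
    ``{builtin: name}``.
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: motif model document must be a mapping")
    if "builtin" in doc:
        return builtin_model(doc["builtin"])
    try:
        width = int(doc["width"])
        columns = np.asarray(doc["columns"], dtype=float)
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"{path}: invalid motif model: {exc}") from None
    blocks = []
    for bi, b in enumerate(doc.get("blocks", []) or []):
        positions = tuple(int(p) for p in b["positions"])
        k = len(positions)
        joint = np.zeros(4 ** k)
        for word, prob in b["joint"].items():
            if len(word) != k:
                raise ValueError(
                    f"{path}: blocks[{bi}]: word {word!r} length != {k}"
                )
            codes = encode(word)
            if (codes < 0).any():
                raise ValueError(f"{path}: blocks[{bi}]: non-ACGT word {word!r}")
            idx = 0
            for c in codes:
                idx = idx * 4 + int(c)
            joint[idx] = float(prob)
        blocks.append(CorrelatedBlock(positions=positions, joint=joint))
    return MotifModel(width=width, columns=columns, blocks=tuple(blocks))
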