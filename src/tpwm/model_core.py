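"""Position weight matrices, intra-motif dependency statistics and tree-based PWMs.

A classical PWM treats every motif position as an independent multinomial over
the four nucleotides.  Real binding sites frequently violate that assumption:
pairs of positions -- adjacent or long-range -- covary because of the 3-D
geometry of the protein-DNA interface or because the observed motif is a
mixture of binding subclasses.  The tree-based PWM (TPWM) implemented here
models such structure by recursive maximal-dependence subdivision of an
aligned site set:

1. for every pair of positions (i, j) estimate the joint dinucleotide
   distribution and the product of the marginals, and measure their L1
   distance D(i, j) = sum_{a,b} |p_ij(a,b) - p_i(a) p_j(b)|;
2. the dependency sum S_i = sum_{j != i} D(i, j) measures how strongly
   position i interacts with the rest of the motif;
3. the *maximal dependent position* is the position with the largest S_i
   among positions whose strongest pairwise dependency exceeds a threshold;
4. the site set is partitioned into at most four subsets by the nucleotide at
   that position; subsets with at least ``min_leaf`` sites become children and
   the procedure recurses on each, with the split position held fixed.

Leaves store conditional PWMs; internal nodes store the empirical nucleotide
distribution at their split position.  The composite model -- branch
probabilities down a root-to-leaf path times the leaf PWM over the unfixed
positions -- is a proper probability distribution over all 4^W words.
Words routed to a branch that was below ``min_leaf`` at build time fall back
to a PWM fitted on exactly those residual sites, so normalization is exact.

Positions are 1-based throughout the public API, matching the convention used
for motif annotation; the underlying arrays are 0-based.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"

#: Default pseudocount added per matrix cell when estimating leaf PWMs.
DEFAULT_PSEUDOCOUNT = 0.5
#: Default minimum number of sites a subset needs to become a splitting branch.
DEFAULT_MIN_LEAF = 100
#: Default gate on the pairwise L1 dependency statistic.  Null calibration
#: (see docs/methods.md): in best-hit alignments of several hundred or more
#: sites from column-independent motifs the maximum pairwise statistic stays
#: around 0.04-0.06, while genuinely correlated position pairs typically
#: score 0.5-1.5, so 0.1 cleanly separates noise from signal.
DEFAULT_DEP_THRESHOLD = 0.1

_ENC = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _ENC[ord(_c)] = _i
del _i, _c


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes A=0, C=1, G=2, T=3; others become -1."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` for valid codes (0..3)."""
    arr = np.asarray(codes)
    if arr.min(initial=0) < 0 or arr.max(initial=0) > 3:
        raise ValueError("codes outside 0..3 cannot be decoded")
    return "".join(ALPHABET[c] for c in arr)


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


@dataclass(frozen=True)
class PWM:
    """Column-stochastic motif model over {A, C, G, T}.

    ``probs`` has shape (width, 4), one row per motif position in A, C, G, T
    order.  ``counts`` optionally retains the integer nucleotide counts the
    probabilities were derived from, in which case
    ``probs[i, a] == (counts[i, a] + pseudocount) / (n_i + 4 * pseudocount)``.
    """

    probs: np.ndarray
    counts: np.ndarray | None = None
    pseudocount: float = 0.0

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4 or p.shape[0] < 1:
            raise ValueError("probs must have shape (width, 4) with width >= 1")
        if (p < -1e-12).any() or (p > 1 + 1e-12).any():
            raise ValueError("probabilities must lie in [0, 1]")
        if np.abs(p.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("every PWM column must sum to 1 within 1e-9")
        object.__setattr__(self, "probs", p)
        if self.counts is not None:
            c = np.asarray(self.counts)
            if c.shape != p.shape:
                raise ValueError("counts shape must match probs shape")
            if (c < 0).any():
                raise ValueError("counts must be non-negative")
            object.__setattr__(self, "counts", c)
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def log2_probs(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.probs)

    def reverse_complement(self) -> "PWM":
        """The PWM describing the reverse-complement strand of the motif."""
        cnt = None if self.counts is None else self.counts[::-1, ::-1].copy()
        return PWM(self.probs[::-1, ::-1].copy(), cnt, self.pseudocount)

    def consensus(self) -> str:
        return "".join(ALPHABET[a] for a in np.argmax(self.probs, axis=1))


@dataclass(frozen=True)
class SiteAlignment:
    """A set of equal-length aligned candidate binding sites, strictly ACGT.

    Stored as an (n, width) int8 code matrix for fast counting.
    """

    codes: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.codes, dtype=np.int8)
        if c.ndim != 2:
            raise ValueError("codes must be a 2-D (n_sites, width) array")
        if c.shape[0] < 1:
            raise ValueError("no sites")
        if c.shape[1] < 1:
            raise ValueError("width must be >= 1")
        bad = np.argwhere((c < 0) | (c > 3))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"non-ACGT character in site {i} at position {j + 1}"
            )
        object.__setattr__(self, "codes", c)

    @classmethod
    def from_strings(cls, sites: list[str]) -> "SiteAlignment":
        if not sites:
            raise ValueError("no sites")
        widths = {len(s) for s in sites}
        if len(widths) != 1:
            raise ValueError(f"sites have unequal lengths: {sorted(widths)}")
        mat = np.vstack([encode(s) for s in sites])
        bad = np.argwhere(mat < 0)
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"non-ACGT character {sites[i][j]!r} in site {i} at position {j + 1}"
            )
        return cls(mat)

    @property
    def sites(self) -> list[str]:
        return [decode(row) for row in self.codes]

    @property
    def width(self) -> int:
        return self.codes.shape[1]

    @property
    def count(self) -> int:
        return self.codes.shape[0]


def column_frequencies(sites: SiteAlignment) -> np.ndarray:
    """Raw per-position nucleotide frequencies, shape (width, 4)."""
    onehot = np.eye(4)[sites.codes]
    return onehot.mean(axis=0)


def estimate_pwm(sites: SiteAlignment, pseudocount: float = 0.0) -> PWM:
    """Estimate a PWM from aligned sites.

    Column i, letter a gets ``(count_i(a) + pseudocount) / (n + 4*pseudocount)``.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    n, w = sites.codes.shape
    counts = np.zeros((w, 4), dtype=np.int64)
    for j in range(w):
        counts[j] = np.bincount(sites.codes[:, j], minlength=4)
    probs = (counts + pseudocount) / (n + 4.0 * pseudocount)
    return PWM(probs, counts=counts, pseudocount=pseudocount)


@dataclass(frozen=True)
class DependencyMatrix:
    """Pairwise L1 dependency values D(i, j) and their row sums S_i.

    ``d`` is symmetric with a zero diagonal; arrays are 0-indexed but the
    values refer to 1-based motif positions.
    """

    d: np.ndarray
    s: np.ndarray

    @property
    def width(self) -> int:
        return self.d.shape[0]


def pairwise_dependency(sites: SiteAlignment, i: int, j: int) -> float:
    """L1 distance between the empirical joint of positions (i, j) and the
    product of their empirical marginals (1-based positions, no pseudocount)."""
    w = sites.width
    if i == j:
        raise ValueError("positions must differ")
    for p in (i, j):
        if not 1 <= p <= w:
            raise ValueError(f"position {p} outside 1..{w}")
    ci = sites.codes[:, i - 1].astype(np.int64)
    cj = sites.codes[:, j - 1].astype(np.int64)
    n = sites.count
    joint = np.bincount(ci * 4 + cj, minlength=16).reshape(4, 4) / n
    pi = np.bincount(ci, minlength=4) / n
    pj = np.bincount(cj, minlength=4) / n
    return float(np.abs(joint - np.outer(pi, pj)).sum())


def dependency_matrix(sites: SiteAlignment) -> DependencyMatrix:
    """All pairwise dependencies D(i, j) plus the dependency sums S_i."""
    if sites.width < 2:
        raise ValueError("dependency matrix requires width >= 2")
    onehot = np.eye(4)[sites.codes]  # (n, W, 4)
    n = sites.count
    joint = np.einsum("nia,njb->ijab", onehot, onehot) / n
    marg = onehot.mean(axis=0)  # (W, 4)
    prod = np.einsum("ia,jb->ijab", marg, marg)
    d = np.abs(joint - prod).sum(axis=(2, 3))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # symmetrize away float noise
    return DependencyMatrix(d=d, s=d.sum(axis=1))


def maximal_dependent_position(
    dep: DependencyMatrix, threshold: float
) -> int | None:
    """The 1-based position with the largest dependency sum among positions
    whose strongest pairwise dependency strictly exceeds ``threshold``.

    Returns ``None`` when no position passes the gate (the no-dependency
    signal).  Ties are broken by the lowest position index.
    """
    gate = dep.d.max(axis=1) > threshold
    if not gate.any():
        return None
    candidates = np.flatnonzero(gate)
    best = candidates[np.argmax(dep.s[candidates])]  # argmax -> first max
    return int(best) + 1


@dataclass
class TPWMNode:
    """One node of a TPWM.

    Non-leaf nodes carry the 1-based split position, the raw nucleotide
    fractions at that position among the node's sites (``branch_probs``), and
    children keyed by nucleotide code.  Letters whose subset fell below the
    minimum leaf size have no child; the sites routed to them are summarized
    by ``fallback_pwm`` (fitted on exactly those residual sites) with total
    raw mass ``miss_mass``.  Leaves carry a conditional PWM over all width
    positions.  ``fixed`` maps ancestor split positions to the nucleotide
    code on the path to this node.
    """

    node_id: int
    n_sites: int
    fixed: dict[int, int]
    is_leaf: bool = True
    split_position: int | None = None
    branch_probs: np.ndarray | None = None
    children: dict[int, "TPWMNode"] = field(default_factory=dict)
    leaf_pwm: PWM | None = None
    fallback_pwm: PWM | None = None
    miss_mass: float = 0.0


@dataclass
class TPWM:
    """Tree-based PWM: a mixture of conditional PWMs indexed by the nucleotides
    observed at recursively chosen maximal dependent positions."""

    width: int
    root: TPWMNode
    min_leaf: int = DEFAULT_MIN_LEAF
    dep_threshold: float = DEFAULT_DEP_THRESHOLD
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def iter_nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children.values())

    def split_positions(self) -> set[int]:
        return {
            n.split_position for n in self.iter_nodes() if not n.is_leaf
        }

    @property
    def n_split_nodes(self) -> int:
        return sum(1 for n in self.iter_nodes() if not n.is_leaf)

    def height(self) -> int:
        def h(node):
            if node.is_leaf:
                return 0
            return 1 + max(h(c) for c in node.children.values())

        return h(self.root)

    def log2_word_probs(self, X: np.ndarray) -> np.ndarray:
        """log2 composite probability for each row of an (N, width) code matrix."""
        X = np.asarray(X, dtype=np.int8)
        if X.ndim != 2 or X.shape[1] != self.width:
            raise ValueError(f"expected (N, {self.width}) code matrix")
        out = np.zeros(X.shape[0], dtype=float)
        with np.errstate(divide="ignore"):
            self._score(self.root, X, np.arange(X.shape[0]), out)
        return out

    def _score(self, node: TPWMNode, X: np.ndarray, idx: np.ndarray, out: np.ndarray):
        if idx.size == 0:
            return
        if node.is_leaf:
            lp = node.leaf_pwm.log2_probs()
            for pos in range(self.width):
                if (pos + 1) in node.fixed:
                    continue
                out[idx] += lp[pos, X[idx, pos]]
            return
        sp = node.split_position - 1
        letters = X[idx, sp]
        routed = np.zeros(idx.size, dtype=bool)
        lbp = np.log2(node.branch_probs)
        for a, child in node.children.items():
            sel = letters == a
            routed |= sel
            sub = idx[sel]
            out[sub] += lbp[a]
            self._score(child, X, sub, out)
        miss = idx[~routed]
        if miss.size == 0:
            return
        if node.miss_mass <= 0.0 or node.fallback_pwm is None:
            out[miss] = -np.inf
            return
        out[miss] += np.log2(node.miss_mass)
        fb = node.fallback_pwm.log2_probs()
        fbp = node.fallback_pwm.probs
        # renormalize the fallback split-position column over the absent letters
        absent = np.setdiff1d(np.arange(4), list(node.children))
        denom = fbp[sp, absent].sum()
        out[miss] += np.log2(fbp[sp, X[miss, sp]] / denom)
        for pos in range(self.width):
            if (pos + 1) in node.fixed or pos == sp:
                continue
            out[miss] += fb[pos, X[miss, pos]]

    def composite_probability(self, word: str) -> float:
        """Probability of ``word`` under the composite (mixture) model."""
        if len(word) != self.width:
            raise ValueError(f"word length {len(word)} != width {self.width}")
        codes = encode(word)
        if (codes < 0).any():
            raise ValueError(f"non-ACGT character in word {word!r}")
        lp = self.log2_word_probs(codes[None, :])[0]
        return float(2.0 ** lp) if np.isfinite(lp) else 0.0


def build_tpwm(
    sites: SiteAlignment,
    min_leaf: int = DEFAULT_MIN_LEAF,
    threshold: float = DEFAULT_DEP_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> TPWM:
    """Build a TPWM by recursive maximal-dependence subdivision.

    At every node the dependency matrix is computed over the positions not yet
    fixed by ancestor splits.  If no position passes the dependency gate, or
    no nucleotide subset reaches ``min_leaf`` sites, the node becomes a leaf
    and stores ``estimate_pwm(its sites, pseudocount)``.  Construction is
    fully deterministic.
    """
    if min_leaf < 1:
        raise ValueError("min_leaf must be >= 1")
    width = sites.width
    counter = itertools.count()

    def grow(codes: np.ndarray, fixed: dict[int, int]) -> TPWMNode:
        n = codes.shape[0]
        node = TPWMNode(node_id=next(counter), n_sites=n, fixed=dict(fixed))
        free = [p for p in range(1, width + 1) if p not in fixed]
        sp = None
        if len(free) >= 2:
            sub = SiteAlignment(codes[:, [p - 1 for p in free]])
            k = maximal_dependent_position(dependency_matrix(sub), threshold)
            if k is not None:
                sp = free[k - 1]
        if sp is not None:
            col = codes[:, sp - 1]
            cnts = np.bincount(col, minlength=4)
            keep = [a for a in range(4) if cnts[a] >= min_leaf]
            if keep:
                node.is_leaf = False
                node.split_position = sp
                node.branch_probs = cnts / n
                for a in keep:  # ascending code = A < C < G < T
                    node.children[a] = grow(
                        codes[col == a], {**fixed, sp: a}
                    )
                miss = ~np.isin(col, keep)
                if miss.any():
                    node.miss_mass = float(miss.mean())
                    node.fallback_pwm = estimate_pwm(
                        SiteAlignment(codes[miss]), pseudocount
                    )
        if node.is_leaf:
            node.leaf_pwm = estimate_pwm(SiteAlignment(codes), pseudocount)
        return node

    root = grow(sites.codes, {})
    return TPWM(
        width=width,
        root=root,
        min_leaf=min_leaf,
        dep_threshold=threshold,
        pseudocount=pseudocount,
    )


def marginal_pwm(model: TPWM) -> PWM:
    """Position-wise marginals of the composite distribution.

    Computed by traversing root-to-leaf paths with their branch-probability
    weights (no word enumeration), including the residual mass routed to
    absent branches.
    """
    W = model.width
    M = np.zeros((W, 4), dtype=float)

    def visit(node: TPWMNode, weight: float, fixed: dict[int, int]):
        if weight <= 0.0:
            return
        if node.is_leaf:
            for pos in range(W):
                if (pos + 1) in fixed:
                    M[pos, fixed[pos + 1]] += weight
                else:
                    M[pos] += weight * node.leaf_pwm.probs[pos]
            return
        sp = node.split_position - 1
        for a, child in node.children.items():
            visit(child, weight * node.branch_probs[a], {**fixed, sp + 1: a})
        if node.miss_mass > 0.0 and node.fallback_pwm is not None:
            w2 = weight * node.miss_mass
            fbp = node.fallback_pwm.probs
            absent = np.setdiff1d(np.arange(4), list(node.children))
            col = np.zeros(4)
            col[absent] = fbp[sp, absent] / fbp[sp, absent].sum()
            for pos in range(W):
                if (pos + 1) in fixed:
                    M[pos, fixed[pos + 1]] += w2
                elif pos == sp:
                    M[pos] += w2 * col
                else:
                    M[pos] += w2 * fbp[pos]

    visit(model.root, 1.0, {})
    # exact up to float accumulation; renormalize the residual drift
    M /= M.sum(axis=1, keepdims=True)
    return PWM(M)
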