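"""Unit and property tests for PWMs, dependency statistics and TPWMs."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tpwm.model_core import (
    PWM,
    SiteAlignment,
    DependencyMatrix,
    build_tpwm,
    column_frequencies,
    dependency_matrix,
    estimate_pwm,
    marginal_pwm,
    maximal_dependent_position,
    pairwise_dependency,
)

from .conftest import random_alignment, random_tree


def enumerate_words(width):
    return np.array(
        list(itertools.product(range(4), repeat=width)), dtype=np.int8
    )


# ---------------------------------------------------------------------------
# PWM estimation


@pytest.mark.parametrize(
    "sites,pc,expected",
    [
        (["AC", "AC", "AC", "AC"], 0.0,
         [[1, 0, 0, 0], [0, 1, 0, 0]]),
        (["AA", "CC"], 0.0,
         [[0.5, 0.5, 0, 0], [0.5, 0.5, 0, 0]]),
        (["AA", "AC", "CA", "CC"], 1.0,
         [[3 / 8, 3 / 8, 1 / 8, 1 / 8]] * 2),
    ],
)
def test_estimate_pwm_examples(sites, pc, expected):
    pwm = estimate_pwm(SiteAlignment.from_strings(sites), pc)
    np.testing.assert_allclose(pwm.probs, expected)
    assert pwm.counts is not None


def test_estimate_pwm_counts_relation(rng):
    aln = random_alignment(rng, n=50, width=5)
    pwm = estimate_pwm(aln, pseudocount=0.7)
    np.testing.assert_allclose(
        pwm.probs, (pwm.counts + 0.7) / (50 + 4 * 0.7), atol=1e-12
    )


def test_empty_alignment_rejected():
    with pytest.raises(ValueError, match="no sites"):
        SiteAlignment.from_strings([])


def test_non_acgt_rejected_with_location():
    with pytest.raises(ValueError, match="site 1 at position 3"):
        SiteAlignment.from_strings(["ACGT", "ACNT"])


def test_pwm_column_sum_validated():
    with pytest.raises(ValueError, match="sum to 1"):
        PWM(np.array([[0.5, 0.5, 0.5, 0.0]]))


# ---------------------------------------------------------------------------
# dependency statistic


@pytest.mark.parametrize(
    "sites,expected",
    [
        (["AC", "AC"], 0.0),
        (["AA", "AA", "CC", "CC"], 1.0),
        (["AA", "CC", "GG", "TT"], 1.5),
    ],
)
def test_pairwise_dependency_hand_cases(sites, expected):
    aln = SiteAlignment.from_strings(sites)
    assert pairwise_dependency(aln, 1, 2) == pytest.approx(expected, abs=1e-12)
    assert pairwise_dependency(aln, 2, 1) == pytest.approx(expected, abs=1e-12)


def test_pairwise_dependency_same_position_rejected():
    aln = SiteAlignment.from_strings(["AC", "GT"])
    with pytest.raises(ValueError, match="differ"):
        pairwise_dependency(aln, 1, 1)


def test_dependency_matrix_constant_columns_is_zero():
    aln = SiteAlignment.from_strings(["ACG"] * 10)
    dep = dependency_matrix(aln)
    assert dep.d.max() == 0.0
    assert dep.s.max() == 0.0


def test_dependency_matrix_matches_pairwise(rng):
    aln = random_alignment(rng, n=80, width=5)
    dep = dependency_matrix(aln)
    for i in range(1, 6):
        for j in range(i + 1, 6):
            assert dep.d[i - 1, j - 1] == pytest.approx(
                pairwise_dependency(aln, i, j), abs=1e-12
            )
    np.testing.assert_allclose(dep.s, dep.d.sum(axis=1), atol=1e-12)
    np.testing.assert_allclose(dep.d, dep.d.T, atol=0)


def test_dependency_matrix_needs_width_two():
    with pytest.raises(ValueError, match="width"):
        dependency_matrix(SiteAlignment.from_strings(["A", "C"]))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_dependency_bounded_by_three_halves(seed):
    rng = np.random.default_rng(seed)
    aln = random_alignment(
        rng, n=int(rng.integers(2, 40)), width=int(rng.integers(2, 7))
    )
    dep = dependency_matrix(aln)
    assert dep.d.max() <= 1.5 + 1e-12
    assert dep.d.min() >= 0.0


def test_maximal_dependent_position_gate_and_ties():
    zero = DependencyMatrix(d=np.zeros((3, 3)), s=np.zeros(3))
    assert maximal_dependent_position(zero, 0.1) is None

    d2 = np.array([[0.0, 1.0], [1.0, 0.0]])
    tie = DependencyMatrix(d=d2, s=d2.sum(axis=1))
    assert maximal_dependent_position(tie, 0.1) == 1  # lowest index wins

    d3 = np.array([[0, 0.3, 0.0], [0.3, 0, 0.4], [0.0, 0.4, 0]])
    dep3 = DependencyMatrix(d=d3, s=d3.sum(axis=1))
    assert list(dep3.s) == pytest.approx([0.3, 0.7, 0.4])
    assert maximal_dependent_position(dep3, 0.1) == 2
    # a high threshold gates everything out
    assert maximal_dependent_position(dep3, 0.5) is None


# ---------------------------------------------------------------------------
# tree construction


def paired_alignment(rng, n=400):
    """Positions 1,2 jointly AA/CC; positions 3,4 uniform independent."""
    z = rng.random(n) < 0.5
    codes = np.zeros((n, 4), np.int8)
    codes[:, 0] = np.where(z, 0, 1)
    codes[:, 1] = np.where(z, 0, 1)
    codes[:, 2] = rng.integers(0, 4, n)
    codes[:, 3] = rng.integers(0, 4, n)
    return SiteAlignment(codes)


def test_build_splits_correlated_pair(rng):
    aln = paired_alignment(rng)
    # gate above the null level of uniform columns at ~200 sites (~0.2) but
    # far below the perfect pair dependency D(1,2)=1
    tree = build_tpwm(aln, min_leaf=50, threshold=0.3, pseudocount=0.5)
    assert tree.root.split_position == 1
    assert sorted(tree.root.children) == [0, 1]  # A and C branches only
    assert all(c.is_leaf for c in tree.root.children.values())
    assert tree.root.children[0].fixed == {1: 0}


def test_build_independent_sites_single_leaf():
    from tpwm.simulate import independent_motif

    model = independent_motif(6, "strong")
    sample_rng = np.random.default_rng(7)
    aln = SiteAlignment(model.sample_codes(1000, sample_rng))
    tree = build_tpwm(aln, min_leaf=100, threshold=0.1)
    assert tree.root.is_leaf
    assert tree.n_split_nodes == 0


def test_build_respects_min_leaf(rng):
    aln = paired_alignment(rng, n=80)
    tree = build_tpwm(aln, min_leaf=81, threshold=0.1)
    assert tree.root.is_leaf  # no subset can reach min_leaf


def test_build_deterministic(rng):
    from tpwm.io_formats import tpwm_to_json

    aln = random_alignment(rng, n=300, width=5)
    t1 = build_tpwm(aln, min_leaf=40, threshold=0.05)
    t2 = build_tpwm(aln, min_leaf=40, threshold=0.05)
    assert tpwm_to_json(t1) == tpwm_to_json(t2)


def test_raising_threshold_only_prunes_root_split(rng):
    aln = paired_alignment(rng)
    low = build_tpwm(aln, min_leaf=50, threshold=0.05)
    high = build_tpwm(aln, min_leaf=50, threshold=0.5)
    hi_split = set() if high.root.is_leaf else {high.root.split_position}
    lo_split = set() if low.root.is_leaf else {low.root.split_position}
    assert hi_split <= lo_split


def test_paths_have_distinct_split_positions_and_bounded_height(rng):
    for _ in range(10):
        tree, _ = random_tree(rng)
        assert tree.height() <= tree.width

        def walk(node, seen):
            if node.is_leaf:
                return
            assert node.split_position not in seen
            assert node.split_position not in node.fixed
            assert 1 <= len(node.children) <= 4
            assert sum(c.n_sites for c in node.children.values()) <= node.n_sites
            for child in node.children.values():
                assert child.n_sites >= 40
                walk(child, seen | {node.split_position})

        walk(tree.root, set())


# ---------------------------------------------------------------------------
# composite model and marginals


def test_single_leaf_composite_is_column_product(rng):
    aln = random_alignment(rng, n=60, width=4, correlated=False)
    tree = build_tpwm(aln, min_leaf=1000, threshold=99.0, pseudocount=0.5)
    assert tree.root.is_leaf
    pwm = tree.root.leaf_pwm
    for word in ("ACGT", "TTTT", "GACC"):
        expected = np.prod(
            [pwm.probs[i, "ACGT".index(c)] for i, c in enumerate(word)]
        )
        assert tree.composite_probability(word) == pytest.approx(expected, rel=1e-12)


def test_composite_rejects_bad_words(rng):
    tree, _ = random_tree(rng, width=4)
    with pytest.raises(ValueError, match="length"):
        tree.composite_probability("ACG")
    with pytest.raises(ValueError, match="non-ACGT"):
        tree.composite_probability("ACGN")


def test_composite_normalization_and_marginals_by_enumeration(rng):
    for _ in range(8):
        tree, _ = random_tree(rng)
        words = enumerate_words(tree.width)
        probs = np.exp2(tree.log2_word_probs(words))
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)
        brute = np.zeros((tree.width, 4))
        for w, q in zip(words, probs):
            for pos in range(tree.width):
                brute[pos, w[pos]] += q
        np.testing.assert_allclose(marginal_pwm(tree).probs, brute, atol=1e-9)


def test_marginal_of_pc0_tree_recovers_raw_frequencies(rng):
    aln = paired_alignment(rng)
    tree = build_tpwm(aln, min_leaf=50, threshold=0.05, pseudocount=0.0)
    np.testing.assert_allclose(
        marginal_pwm(tree).probs, column_frequencies(aln), atol=1e-9
    )


def test_marginal_of_single_leaf_is_leaf_pwm(rng):
    aln = random_alignment(rng, n=50, width=3, correlated=False)
    tree = build_tpwm(aln, min_leaf=1000, threshold=99.0, pseudocount=0.5)
    np.testing.assert_allclose(
        marginal_pwm(tree).probs, tree.root.leaf_pwm.probs, atol=1e-12
    )
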