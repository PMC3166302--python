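"""Generator tests: Markov background, motif sampling, implantation, shuffling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tpwm.model_core import SiteAlignment, dependency_matrix, encode
from tpwm.simulate import (
    BackgroundSpec,
    CorrelatedBlock,
    MotifModel,
    builtin_model,
    dependent_hex_20bp,
    implant,
    independent_motif,
    make_dataset,
    markov_background,
    sample_site,
    shuffle_negatives,
)


# ---------------------------------------------------------------------------
# Markov background


def test_order0_uniform_base_frequencies():
    seqs = markov_background(1000, 200, order=0, seed=5)
    counts = np.zeros(4)
    for s in seqs:
        counts += np.bincount(encode(s), minlength=4)
    freqs = counts / counts.sum()
    se = np.sqrt(0.25 * 0.75 / counts.sum())
    assert np.abs(freqs - 0.25).max() < 3 * se


def test_degenerate_chain_repeats_initial_base():
    # order-1 chain forcing next base == previous base, started at A
    transitions = np.eye(4)
    initial = np.array([1.0, 0, 0, 0])
    seqs = markov_background(
        3, 50, order=1, transitions=transitions, initial=initial, seed=0
    )
    assert all(s == "A" * 50 for s in seqs)


def test_order1_transition_frequencies_match_table():
    t = np.array(
        [[0.7, 0.1, 0.1, 0.1],
         [0.1, 0.7, 0.1, 0.1],
         [0.25, 0.25, 0.25, 0.25],
         [0.4, 0.4, 0.1, 0.1]]
    )
    seqs = markov_background(200, 300, order=1, transitions=t, seed=9)
    pair_counts = np.zeros((4, 4))
    for s in seqs:
        codes = encode(s)
        np.add.at(pair_counts, (codes[:-1], codes[1:]), 1)
    emp = pair_counts / pair_counts.sum(axis=1, keepdims=True)
    n = pair_counts.sum(axis=1, keepdims=True)
    assert (np.abs(emp - t) < 3 * np.sqrt(t * (1 - t) / n) + 1e-9).all()


def test_markov_determinism():
    a = markov_background(5, 100, order=3, seed=77)
    b = markov_background(5, 100, order=3, seed=77)
    assert a == b


def test_malformed_transition_table_names_context():
    bad = np.full((4, 4), 0.25)
    bad[2] = [0.5, 0.5, 0.5, 0.5]
    with pytest.raises(ValueError, match="'G'"):
        BackgroundSpec(order=1, transitions=bad)


# ---------------------------------------------------------------------------
# motif sampling


def test_probability_one_columns_always_consensus():
    probs = np.zeros((4, 4))
    for i, c in enumerate("GATC"):
        probs[i, "ACGT".index(c)] = 1.0
    model = MotifModel(width=4, columns=probs)
    assert all(sample_site(model, seed=s) == "GATC" for s in range(5))


def test_block_support_respected():
    joint = np.zeros(16)
    joint[0] = 0.5   # AA
    joint[5] = 0.5   # CC
    model = MotifModel(
        width=3,
        columns=np.full((3, 4), 0.25),
        blocks=(CorrelatedBlock(positions=(1, 3), joint=joint),),
    )
    rng = np.random.default_rng(3)
    draws = model.sample_codes(200, rng)
    pairs = {(a, b) for a, b in zip(draws[:, 0], draws[:, 2])}
    assert pairs <= {(0, 0), (1, 1)}


def test_block_word_frequencies_match_table():
    from tpwm.simulate import dependent_pair_10bp

    rng = np.random.default_rng(11)
    model = dependent_pair_10bp()
    block = model.blocks[0]
    draws = model.sample_codes(10_000, rng)
    idx = np.zeros(10_000, dtype=np.int64)
    for p in block.positions:
        idx = idx * 4 + draws[:, p - 1]
    emp = np.bincount(idx, minlength=block.joint.size) / 10_000
    # normal-approximation bound on the well-populated cells, aggregate L1
    # bound on the sparse remainder (3 sigma per cell is meaningless there)
    big = block.joint >= 0.005
    se = np.sqrt(block.joint * (1 - block.joint) / 10_000)
    assert (np.abs(emp - block.joint)[big] <= 3 * se[big]).all()
    assert np.abs(emp - block.joint).sum() < 0.05


def test_blocks_must_be_disjoint():
    j = np.full(16, 1 / 16)
    with pytest.raises(ValueError, match="two blocks"):
        MotifModel(
            width=4,
            columns=np.full((4, 4), 0.25),
            blocks=(
                CorrelatedBlock(positions=(1, 2), joint=j),
                CorrelatedBlock(positions=(2, 3), joint=j),
            ),
        )


def test_hex_surrogate_maximal_dependency_at_position_20():
    """The shipped 6-correlated surrogate must place its strongest dependency
    sum at position 20, the documented first split."""
    model = dependent_hex_20bp()
    rng = np.random.default_rng(21)
    aln = SiteAlignment(model.sample_codes(4000, rng))
    dep = dependency_matrix(aln)
    assert int(np.argmax(dep.s)) + 1 == 20
    corr = {3, 4, 12, 13, 19, 20}
    strong_pairs = {
        (i + 1, j + 1)
        for i in range(20) for j in range(20)
        if dep.d[i, j] > 0.3
    }
    assert all(i in corr and j in corr for i, j in strong_pairs)


# ---------------------------------------------------------------------------
# implantation


def test_implant_extremes():
    seqs = ["ACGTACGTACGT"] * 50
    model = independent_motif(4, "strong")
    out, truth = implant(seqs, model, 1.0, seed=1)
    assert truth.has_site.all()
    out0, truth0 = implant(seqs, model, 0.0, seed=1)
    assert out0 == seqs and not truth0.has_site.any()


def test_implant_site_count_binomial_bound():
    seqs = markov_background(3000, 200, order=0, seed=13)
    _, truth = implant(seqs, independent_motif(10, "strong"), 0.8, seed=14)
    n_sites = int(truth.has_site.sum())
    assert abs(n_sites - 2400) <= 3 * np.sqrt(3000 * 0.8 * 0.2)


def test_implant_truth_records_are_consistent():
    seqs = markov_background(200, 60, order=0, seed=15)
    out, truth = implant(seqs, independent_motif(10, "strong"), 0.5, seed=16)
    for row, seq in zip(truth.itertuples(), out):
        assert len(seq) == 60
        if row.has_site:
            assert seq[row.start : row.end] == row.site_word
            assert 0 <= row.start <= 60 - 10
        else:
            assert row.start == -1 and row.site_word == ""


def test_implant_rejects_short_sequences():
    with pytest.raises(ValueError, match="shorter"):
        implant(["ACGT"], independent_motif(10, "strong"), 0.5, seed=0)


# ---------------------------------------------------------------------------
# shuffled negatives


def test_shuffle_single_letter_unchanged():
    assert shuffle_negatives(["A"], seed=0) == ["A"]


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=1, max_size=80), st.integers(0, 1000))
def test_shuffle_preserves_composition(seq, seed):
    (out,) = shuffle_negatives([seq], seed=seed)
    assert sorted(out) == sorted(seq)


def test_shuffle_displaces_planted_word():
    rng = np.random.default_rng(31)
    base = "".join("ACGT"[c] for c in rng.integers(0, 4, 200))
    seq = base[:90] + "TTGACATTGA" + base[100:]
    displaced = 0
    for seed in range(10):
        (shuf,) = shuffle_negatives([seq], seed=seed)
        if shuf[90:100] != "TTGACATTGA":
            displaced += 1
    assert displaced >= 9


# ---------------------------------------------------------------------------
# dataset assembly


def test_make_dataset_counts_and_determinism(tmp_path):
    model = builtin_model("strong10")
    ds = make_dataset(model, n=50, length=80, abundance=0.8, seed=99)
    assert len(ds.positives) == 50 and len(ds.negatives) == 50
    assert len(ds.truth) == 50

    p1, p2 = tmp_path / "a", tmp_path / "b"
    make_dataset(model, n=20, length=60, abundance=0.8, seed=7, out_prefix=p1)
    make_dataset(model, n=20, length=60, abundance=0.8, seed=7, out_prefix=p2)
    for suffix in ("_pos.fa", "_neg.fa", "_truth.tsv"):
        assert (tmp_path / f"a{suffix}").read_bytes() == (
            tmp_path / f"b{suffix}"
        ).read_bytes()


def test_negatives_score_below_positives():
    from tpwm.scanner import SequenceSet

    model = builtin_model("strong10")
    pwm = model.marginal_pwm()
    worse = 0
    for seed in range(10):
        ds = make_dataset(model, n=60, length=150, abundance=0.8, seed=600 + seed)
        ps, _, _, _ = SequenceSet([s for _, s in ds.positives]).best(pwm)
        ns, _, _, _ = SequenceSet([s for _, s in ds.negatives]).best(pwm)
        if ns.mean() < ps.mean():
            worse += 1
    assert worse == 10
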