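"""Alignment records, dialect parsing, and the seeded gapless aligner."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sexchrom.align import (AlignmentBlock, aligned_fraction, anchor_align,
                            chain_colinear, merge_intervals, read_alignments,
                            revcomp, write_alignments)


def _random_blocks(rng, n=50):
    blocks = []
    for i in range(n):
        qs = int(rng.integers(0, 500))
        qlen = int(rng.integers(50, 400))
        ts = int(rng.integers(0, 500))
        blocks.append(AlignmentBlock(
            query_id=f"q{i % 5}", target_id=f"t{i % 3}",
            query_start=qs, query_end=qs + qlen,
            target_start=ts, target_end=ts + qlen,
            strand="+" if rng.random() < 0.5 else "-",
            matches=int(rng.integers(qlen // 2, qlen + 1)), align_len=qlen))
    return blocks


@pytest.mark.parametrize("dialect", ["paf", "coords"])
def test_round_trip_write_read(tmp_path, rng, dialect):
    blocks = _random_blocks(rng)
    path = tmp_path / f"aln.{dialect}"
    write_alignments(blocks, path, dialect)
    back = read_alignments(path, dialect)
    assert back == blocks


def test_coords_convention_shift(tmp_path):
    # 1-based inclusive (1, 100) becomes 0-based half-open (0, 100)
    path = tmp_path / "x.coords"
    path.write_text("1\t100\t1\t100\t100\t100\t98.000000\tref\tqry\n")
    (b,) = read_alignments(path, "coords")
    assert (b.target_start, b.target_end) == (0, 100)
    assert (b.query_start, b.query_end) == (0, 100)
    assert b.strand == "+"
    # reversed query coordinates signal the minus strand
    path.write_text("1\t100\t100\t1\t100\t100\t98.000000\tref\tqry\n")
    (b,) = read_alignments(path, "coords")
    assert b.strand == "-"
    assert (b.query_start, b.query_end) == (0, 100)


def test_paf_is_zero_based(tmp_path):
    path = tmp_path / "x.paf"
    path.write_text("q\t150\t0\t100\t+\tt\t500\t30\t130\t95\t100\t60\n")
    (b,) = read_alignments(path, "paf")
    assert (b.query_start, b.query_end) == (0, 100)
    assert b.matches == 95


def test_malformed_line_names_line_number(tmp_path):
    path = tmp_path / "bad.paf"
    path.write_text("q\t150\t0\t100\t+\tt\t500\t30\n")
    with pytest.raises(ValueError, match="line 1"):
        read_alignments(path, "paf")
    with pytest.raises(ValueError, match="dialect"):
        read_alignments(path, "nonsense")


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_self_alignment_full_identity(rng):
    seq = _random_dna(rng, 500)
    blocks = anchor_align(seq, seq, k=11, min_block=100)
    best = blocks[0]
    assert (best.query_start, best.query_end) == (0, 500)
    assert best.identity == 1.0 and best.strand == "+"


def test_reverse_complement_hits_minus_strand(rng):
    seq = _random_dna(rng, 400)
    blocks = anchor_align(revcomp(seq), seq, k=11, min_block=100)
    best = blocks[0]
    assert best.strand == "-"
    assert best.identity == 1.0
    assert (best.target_start, best.target_end) == (0, 400)


def test_planted_substitutions_identity_window(rng):
    target = _random_dna(rng, 2000)
    q = list(target)
    pos = rng.choice(2000, size=40, replace=False)  # 2% divergence
    for p in pos:
        q[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[p]]
    blocks = anchor_align("".join(q), target, k=11, min_block=500)
    best = blocks[0]
    assert 0.97 <= best.identity <= 0.99


def _best_gapless_oracle(query, target, min_block):
    """Exhaustive best gapless segment under +1/-1 scoring, via per-diagonal
    prefix sums over every (start, end) pair."""
    lq, lt = len(query), len(target)
    best = (-1, None)  # (score, identity)
    for strand, q in (("+", query), ("-", revcomp(query))):
        qa = np.frombuffer(q.encode(), np.uint8)
        ta = np.frombuffer(target.encode(), np.uint8)
        for d in range(-lq + 1, lt):
            qs, qe = max(0, -d), min(lq, lt - d)
            if qe - qs < min_block:
                continue
            m = (qa[qs:qe] == ta[qs + d:qe + d]).astype(int)
            score = np.concatenate([[0], np.cumsum(2 * m - 1)])
            matches = np.concatenate([[0], np.cumsum(m)])
            n = len(m)
            for i in range(n - min_block + 1):
                for j in range(i + min_block, n + 1):
                    s = score[j] - score[i]
                    if s > best[0]:
                        ident = (matches[j] - matches[i]) / (j - i)
                        best = (s, ident)
    return best


def test_matches_exhaustive_gapless_oracle(rng):
    """On short sequences the aligner's best block equals the exhaustive
    best gapless segment (same score, same identity)."""
    for _ in range(5):
        target = _random_dna(rng, 150)
        core = list(target[40:120])
        for p in rng.choice(len(core), size=4, replace=False):
            core[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[core[p]]
        query = _random_dna(rng, 30) + "".join(core) + _random_dna(rng, 30)
        blocks = anchor_align(query, target, k=8, min_block=20)
        assert blocks
        got = max(2 * b.matches - b.align_len for b in blocks)
        arg = max(blocks, key=lambda b: 2 * b.matches - b.align_len)
        score, ident = _best_gapless_oracle(query, target, 20)
        assert got == score
        assert arg.identity == pytest.approx(ident, abs=1e-12)


def test_aligned_fraction_union_semantics():
    mk = lambda qs, qe: AlignmentBlock("q", "t", qs, qe, qs, qe, "+", qe - qs, qe - qs)
    assert aligned_fraction([mk(0, 25)], 100) == 0.25
    # two identical overlapping blocks still cover 25 bp
    assert aligned_fraction([mk(0, 25), mk(0, 25)], 100) == 0.25
    with pytest.raises(ValueError):
        aligned_fraction([mk(0, 25)], 0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 195), st.integers(1, 60)), max_size=15),
       st.integers(1, 200))
def test_aligned_fraction_matches_per_base_marking(ivs, qlen):
    blocks = []
    marked = np.zeros(qlen, bool)
    for s, ln in ivs:
        e = min(s + ln, qlen)
        if e <= s or s >= qlen:
            continue
        blocks.append(AlignmentBlock("q", "t", s, e, s, e, "+", e - s, e - s))
        marked[s:e] = True
    assert aligned_fraction(blocks, qlen) == pytest.approx(marked.mean())


def test_merge_intervals_union():
    assert merge_intervals([(5, 10), (0, 6), (12, 15)]) == [(0, 10), (12, 15)]


def test_chain_discounts_gap_span_but_bounds_the_rest():
    a = AlignmentBlock("q", "t", 0, 1000, 0, 1000, "+", 1000, 1000)
    b = AlignmentBlock("q", "t", 1000, 2000, 3000, 4000, "+", 1000, 1000)
    # a 2 kb target skip breaks the chain unless 1 kb of it is an N-gap
    assert len(chain_colinear([a, b], max_indel=1000)) == 1
    assert len(chain_colinear([a, b], max_indel=1000,
                              waive_intervals=[(1500, 2500)])) == 2
    # a distant block does not chain merely because a gap lies in between
    far = AlignmentBlock("q", "t", 1000, 2000, 60_000, 61_000, "+", 1000, 1000)
    assert len(chain_colinear([a, far], max_indel=1000,
                              waive_intervals=[(1500, 2500)])) == 1
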