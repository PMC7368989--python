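"""BAC classification rules, merging, and the concordance summary."""

import numpy as np
import pytest

from sexchrom.align import anchor_align
from sexchrom.bac import (GapInterval, classify_all, classify_bac,
                          concordance_summary, find_gaps, merge_bacs)


def _dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture()
def toy_scaffold(rng):
    """Two 30 kb contigs around a 5 kb N-gap; the true inter-contig
    sequence is 7 kb, so a spanning BAC adds 2 kb net."""
    left = _dna(rng, 30_000)
    hidden = _dna(rng, 7_000)
    right = _dna(rng, 30_000)
    scaffold = left + "N" * 5000 + right
    truth = left + hidden + right
    return scaffold, truth, len(left), len(hidden)


def _classify(seq, scaffold, **kw):
    gaps = find_gaps(scaffold)
    blocks = anchor_align(seq, scaffold, k=15, min_block=200, query_id="bac",
                          target_id="s")
    return classify_bac("bac", len(seq), blocks, gaps, **kw), gaps


def test_exact_substring_is_concordant(toy_scaffold):
    scaffold, truth, left_len, _ = toy_scaffold
    bac = scaffold[5000:20_000]
    cls, _ = _classify(bac, scaffold)
    assert cls.verdict == "concordant"
    assert cls.end_slack == (0, 0)
    assert cls.identity == 1.0
    assert cls.length_delta == 0


def test_gap_spanning_bac(toy_scaffold):
    scaffold, truth, left_len, hidden_len = toy_scaffold
    bac = truth[left_len - 4000:left_len + hidden_len + 4000]
    cls, _ = _classify(bac, scaffold)
    assert cls.verdict == "spans_gap"
    assert cls.gap_ids == ["gap00"]


def test_extends_into_gap(toy_scaffold):
    scaffold, truth, left_len, hidden_len = toy_scaffold
    bac = truth[left_len - 5000:left_len + 2500]  # 2.5 kb into the gap
    cls, _ = _classify(bac, scaffold)
    assert cls.verdict == "extends_into_gap"
    assert cls.gap_ids == ["gap00"]


def test_planted_inversion_is_discordant(toy_scaffold, rng):
    from sexchrom.align import revcomp
    scaffold, truth, *_ = toy_scaffold
    bac = scaffold[4000:18_000]
    mid = len(bac) // 2
    bac = bac[:mid - 2000] + revcomp(bac[mid - 2000:mid + 2000]) + bac[mid + 2000:]
    cls, _ = _classify(bac, scaffold)
    assert cls.verdict == "discordant"


def test_planted_large_deletion_is_discordant(toy_scaffold):
    scaffold, truth, *_ = toy_scaffold
    bac = scaffold[4000:20_000]
    mid = len(bac) // 2
    bac = bac[:mid - 2500] + bac[mid + 2500:]  # 5 kb deletion
    cls, _ = _classify(bac, scaffold)
    assert cls.verdict == "discordant"


def test_no_alignment_is_discordant(rng):
    cls = classify_bac("bac", 10_000, [], [])
    assert cls.verdict == "discordant"
    assert cls.reason == "no alignment"


def test_low_identity_fails_every_rule(toy_scaffold, rng):
    scaffold, truth, *_ = toy_scaffold
    bac = list(scaffold[5000:15_000])
    for p in rng.choice(len(bac), size=len(bac) // 50, replace=False):  # 2%
        bac[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[bac[p]]
    cls, _ = _classify("".join(bac), scaffold)
    assert cls.verdict == "discordant"
    assert cls.identity < 0.99


def test_merge_spanning_bac_fills_gap_and_adds_net_length(toy_scaffold):
    scaffold, truth, left_len, hidden_len = toy_scaffold
    bac = truth[left_len - 4000:left_len + hidden_len + 4000]
    cls, gaps = _classify(bac, scaffold)
    merged, report, liftover = merge_bacs(scaffold, [cls], {"bac": bac})
    assert merged.count("N") == 0
    assert len(merged) - len(scaffold) == hidden_len - 5000  # +2 kb net
    assert merged == truth
    # applied BAC re-classifies concordant against the merged scaffold
    blocks = anchor_align(bac, merged, k=15, min_block=200, query_id="bac",
                          target_id="m")
    recls = classify_bac("bac", len(bac), blocks, find_gaps(merged))
    assert recls.verdict == "concordant"


def test_merge_prefers_highest_identity_then_longest(toy_scaffold, rng):
    scaffold, truth, left_len, hidden_len = toy_scaffold
    good = truth[left_len - 4000:left_len + hidden_len + 4000]
    worse = list(truth[left_len - 3000:left_len + hidden_len + 3000])
    for p in rng.choice(len(worse), size=len(worse) // 200, replace=False):
        worse[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[worse[p]]
    worse = "".join(worse)  # identity ~0.995, still >= 0.99
    cls_good, _ = _classify(good, scaffold)
    cls_bad, _ = _classify(worse, scaffold)
    cls_bad.bac_id = "worse"
    assert cls_good.identity > cls_bad.identity
    merged, report, _ = merge_bacs(scaffold, [cls_bad, cls_good],
                                   {"bac": good, "worse": worse})
    assert report[0]["bac_id"] == "bac"


def test_merge_never_decreases_non_n_length(sim, bacs):
    from sexchrom.pipeline import bac_truth_recovery
    res = bac_truth_recovery(sim, bacs)
    merged, report, _ = merge_bacs(sim.scaffold,
                                   list(res["classifications"].values()), bacs)
    before = len(sim.scaffold) - sim.scaffold.count("N")
    after = len(merged) - merged.count("N")
    assert after >= before
    assert report  # something was merged


def test_concordance_summary_counts_and_fraction():
    assert concordance_summary([], 10)["counts"]["concordant"] == 0
    from sexchrom.bac import BacClassification
    cls = [BacClassification("a", "spans_gap", gap_ids=["g1"]),
           BacClassification("b", "spans_gap", gap_ids=["g1", "g2"]),
           BacClassification("c", "spans_gap", gap_ids=["g3"]),
           BacClassification("d", "concordant"),
           BacClassification("e", "discordant")]
    s = concordance_summary(cls, 10)
    assert s["counts"]["spans_gap"] == 3
    assert s["gaps_spanned"] == 3
    assert s["fraction_gaps_spanned"] == pytest.approx(0.30)
    assert concordance_summary(cls, 0)["fraction_gaps_spanned"] is None


def test_classification_order_independent(toy_scaffold, rng):
    scaffold, truth, left_len, hidden_len = toy_scaffold
    bac = truth[left_len - 4000:left_len + hidden_len + 4000]
    gaps = find_gaps(scaffold)
    blocks = anchor_align(bac, scaffold, k=15, min_block=200, query_id="bac",
                          target_id="s")
    shuffled = list(blocks)
    rng.shuffle(shuffled)
    a = classify_bac("bac", len(bac), blocks, gaps)
    b = classify_bac("bac", len(bac), shuffled, gaps)
    assert (a.verdict, a.footprint, a.identity) == (b.verdict, b.footprint, b.identity)
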