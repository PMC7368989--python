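"""NG86 divergence against a brute-force oracle, strata, and dating."""

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from sexchrom.divergence import (DivergenceEstimate, StratumModel, assign_stratum,
                                 best_gametolog, calibrate_age, gene_loss_rate,
                                 mann_whitney, ng86_divergence, stratum_summary)

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon):
    return None if codon in STOPS else str(Seq(codon).translate())


def _oracle_sites(codon):
    """Independent enumeration of synonymous site fractions."""
    total = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in STOPS:
                continue
            valid += 1
            if _aa(alt) == _aa(codon):
                syn += 1
        if valid:
            total += syn / valid
    return total


def _oracle_pathways(c1, c2):
    diff = [i for i in range(3) if c1[i] != c2[i]]
    clean, blocked = [], []
    for order in itertools.permutations(diff):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOPS or cur in STOPS:
                ok = False
            if cur not in STOPS and nxt not in STOPS and _aa(cur) == _aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (clean if ok else blocked).append((sd, nd))
    use = clean or blocked
    return (sum(x[0] for x in use) / len(use), sum(x[1] for x in use) / len(use))


def _oracle_ng86(sx, sy):
    S = N = Sd = Nd = 0.0
    for i in range(0, len(sx), 3):
        c1, c2 = sx[i:i + 3], sy[i:i + 3]
        if c1 in STOPS or c2 in STOPS:
            continue
        s = (_oracle_sites(c1) + _oracle_sites(c2)) / 2
        S += s
        N += 3 - s
        sd, nd = _oracle_pathways(c1, c2)
        Sd += sd
        Nd += nd
    ps, pn = Sd / S, Nd / N
    if ps >= 0.75 or pn >= 0.75:
        return None
    jc = lambda p: -0.75 * math.log(1 - 4 * p / 3)
    return jc(ps), jc(pn)


def _random_pair(rng, n_codons, rate):
    sense = [c for c in ("".join(t) for t in itertools.product(BASES, repeat=3))
             if c not in STOPS]
    sx = "".join(rng.choice(sense) for _ in range(n_codons))
    sy = list(sx)
    for i in range(len(sy)):
        if rng.random() < rate:
            sy[i] = rng.choice([b for b in BASES if b != sy[i]])
    return sx, "".join(sy)


def test_identical_sequences_have_zero_divergence():
    seq = "ATGGCTAAGCTTGGGACTTGGCCTAAGCTTGGGACTTGGCCTTGGCCTAAGCTTGGGACTTGGCCTAAGCTTGGGACTTGGCCTTGGCCA"
    est = ng86_divergence(seq, seq)
    assert est.dS == 0.0 and est.dN == 0.0 and est.dn_ds is None


def test_single_synonymous_change_matches_oracle():
    sx = "AAA" * 10
    sy = "AAG" + "AAA" * 9  # Lys -> Lys, third-position transition
    est = ng86_divergence(sx, sy)
    ds, dn = _oracle_ng86(sx, sy)
    assert est.dN == 0.0
    assert est.dS == pytest.approx(ds, abs=1e-12)
    assert dn == 0.0


def test_random_pairs_match_bruteforce_oracle():
    rng = np.random.default_rng(42)
    checked = 0
    for _ in range(200):
        n = int(rng.integers(10, 61))
        rate = float(rng.uniform(0.0, 0.25))
        sx, sy = _random_pair(rng, n, rate)
        est = ng86_divergence(sx, sy)
        oracle = _oracle_ng86(sx, sy)
        if oracle is None:
            assert est.saturated
            continue
        assert not est.saturated
        assert est.dS == pytest.approx(oracle[0], abs=1e-9)
        assert est.dN == pytest.approx(oracle[1], abs=1e-9)
        checked += 1
    assert checked >= 150


def test_ng86_is_symmetric():
    rng = np.random.default_rng(3)
    for _ in range(20):
        sx, sy = _random_pair(rng, 40, 0.1)
        a, b = ng86_divergence(sx, sy), ng86_divergence(sy, sx)
        assert a.dS == pytest.approx(b.dS, abs=1e-12)
        assert a.dN == pytest.approx(b.dN, abs=1e-12)


def test_divergence_monotone_in_substitution_count_on_average():
    rng = np.random.default_rng(9)
    rates = [0.01, 0.05, 0.10, 0.20]
    means = []
    for rate in rates:
        vals = []
        for _ in range(25):
            sx, sy = _random_pair(rng, 60, rate)
            est = ng86_divergence(sx, sy)
            if est.usable:
                vals.append(est.dS + est.dN)
        means.append(np.mean(vals))
    assert means == sorted(means)


def test_gapped_and_stop_columns_are_dropped():
    sx = "ATG" + "TAA" + "AAA"
    sy = "ATG" + "AAA" + "AAA"
    est = ng86_divergence(sx, sy)
    assert est.n_codons == 2  # the stop-containing column is excluded
    est = ng86_divergence("ATG---AAA", "ATGAAAAAA")
    assert est.n_codons == 2


def test_best_gametolog_filters_then_takes_lowest_ds():
    mk = lambda ds, pos: DivergenceEstimate(dS=ds, dN=0.01, dn_ds=None,
                                            S_sites=50, N_sites=100,
                                            y_position=pos)
    assert best_gametolog([mk(0.04, 5), mk(0.31, 9)]).dS == 0.04
    assert best_gametolog([mk(2.5, 5)]) is None  # saturated-range candidate
    tie = best_gametolog([mk(0.04, 900), mk(0.04, 100)])
    assert tie.y_position == 100
    with pytest.raises(ValueError):
        best_gametolog([])


def test_stratum_assignment_follows_breakpoints():
    model = StratumModel()
    assert assign_stratum(1.0e6, "X", model) == 0    # PAR below 2.5 Mb
    assert assign_stratum(13.0e6, "X", model) == 1   # above the 12.5 Mb S3/S1 break
    assert assign_stratum(3.0e6, "X", model) == 2
    assert assign_stratum(7.0e6, "X", model) == 3
    assert assign_stratum(0.2e6, "Y", model) == 0
    assert assign_stratum(1.0e6, "Y", model) == 1
    assert assign_stratum(5.0e6, "Y", model) == 2    # past the 4.67 Mb S1/S2 break
    assert assign_stratum(10.0e6, "Y", model) == 3
    with pytest.raises(ValueError):
        assign_stratum(-1, "Y", model)
    with pytest.raises(ValueError):
        StratumModel(y_breakpoints=(5e6, 1e6, 9e6))


def _mwu_permutation_oracle(a, b):
    """Exact one-sided (greater) P by enumerating all group relabelings."""
    pooled = list(a) + list(b)
    n1 = len(a)

    def u_stat(x, y):
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)

    observed = u_stat(a, b)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        if u_stat(xs, ys) >= observed - 1e-12:
            count += 1
        total += 1
    return count / total


def test_mann_whitney_matches_rank_permutation_oracle():
    rng = np.random.default_rng(11)
    cases = [([1, 2, 3], [4, 5, 6])]
    for _ in range(5):
        cases.append((list(rng.normal(size=5)), list(rng.normal(0.5, 1, size=4))))
    for a, b in cases:
        res = mann_whitney(a, b, alternative="greater")
        assert res.pvalue == pytest.approx(_mwu_permutation_oracle(a, b), abs=1e-12)


def test_identical_value_multisets_give_p_one():
    ests, strata = [], []
    for s in (1, 2):
        for v in (0.1, 0.2, 0.3, 0.4):
            ests.append(DivergenceEstimate(dS=v, dN=v / 2, dn_ds=0.5,
                                           S_sites=10, N_sites=20))
            strata.append(s)
    medians, tests = stratum_summary(ests, strata)
    assert medians.loc[1, "dS"] == medians.loc[2, "dS"]
    for (metric, *_), p in tests.items():
        assert p == pytest.approx(1.0)


def test_calibration_reproduces_published_ages():
    assert calibrate_age(0.155, 0.184, 26) == 21.9
    assert calibrate_age(0.042, 0.184, 26) == 5.9
    assert calibrate_age(0.033, 0.184, 26) == 4.7
    assert calibrate_age(0.0, 0.184, 26) == 0.0
    with pytest.raises(ValueError):
        calibrate_age(-0.1, 0.184, 26)
    with pytest.raises(ValueError):
        calibrate_age(0.1, 0.0, 26)


def test_gene_loss_rate_arithmetic():
    assert gene_loss_rate(0.82, 21.9) == 3.7
    assert gene_loss_rate(0.0, 10) == 0.0
    assert gene_loss_rate(1.0, 10) == 10.0
    with pytest.raises(ValueError):
        gene_loss_rate(0.5, 0)
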