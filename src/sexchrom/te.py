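"""Transposable-element density and the autosomal-window permutation test.

TE density is the proportion of nucleotides of a window covered by TE
annotations (overlapping annotations merged first).  Whether a focal
region's density (for example the pseudoautosomal region's) exceeds what
recombining sequence ordinarily carries is tested against a null of
equal-size windows drawn uniformly from the autosomes.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .align import merge_intervals


def te_fraction(intervals: Sequence[tuple[int, int]],
                window: tuple[int, int]) -> float:
    """Proportion of the window covered by the union of TE intervals."""
    ws, we = window
    if we <= ws:
        raise ValueError("window must have positive length")
    covered = 0
    for s, e in merge_intervals(intervals):
        covered += max(0, min(e, we) - max(s, ws))
    return covered / (we - ws)


def _coverage_arrays(intervals):
    merged = merge_intervals(intervals)
    starts = np.array([s for s, _ in merged], dtype=float)
    ends = np.array([e for _, e in merged], dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(ends - starts)])
    return starts, ends, cum


def permutation_test(observed_fraction: float,
                     te_by_chrom: Mapping[str, Sequence[tuple[int, int]]],
                     chrom_lengths: Mapping[str, int],
                     window_size: int = 2_500_000,
                     n_perm: int = 10_000,
                     seed: int = 0) -> dict:
    """One-sided (enrichment) permutation P for a focal TE density.

    Null windows of ``window_size`` are drawn with replacement from the
    autosomes: the chromosome with probability proportional to its number
    of valid start positions, the start uniformly within them.
    P = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    chroms = [c for c in sorted(chrom_lengths)
              if chrom_lengths[c] >= window_size]
    if not chroms:
        raise ValueError("no autosome is at least window_size long")
    rng = np.random.default_rng(seed)
    weights = np.array([chrom_lengths[c] - window_size + 1 for c in chroms], float)
    probs = weights / weights.sum()
    cov = {c: _coverage_arrays(te_by_chrom.get(c, [])) for c in chroms}
    choice = rng.choice(len(chroms), size=n_perm, p=probs)
    null = np.empty(n_perm)
    for i, ci in enumerate(choice):
        c = chroms[ci]
        start = int(rng.integers(0, chrom_lengths[c] - window_size + 1))
        starts, ends, cum = cov[c]
        null[i] = (_interval_coverage(start, start + window_size, starts, ends, cum)
                   / window_size)
    p = (1.0 + int(np.sum(null >= observed_fraction))) / (n_perm + 1.0)
    return {"observed": float(observed_fraction), "n_perm": int(n_perm),
            "seed": int(seed), "p_value": float(p),
            "null_mean": float(null.mean()), "null_sd": float(null.std())}


def _interval_coverage(ws, we, starts, ends, cum):
    """TE bases overlapping [ws, we) from merged interval arrays."""
    if len(starts) == 0:
        return 0.0
    lo = np.searchsorted(ends, ws, side="right")
    hi = np.searchsorted(starts, we, side="left")
    total = 0.0
    for i in range(lo, hi):
        total += max(0.0, min(ends[i], we) - max(starts[i], ws))
    return total
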