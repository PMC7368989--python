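"""Gametolog divergence estimation, strata assignment, and dating.

Synonymous and nonsynonymous divergence between gametolog coding sequences
is estimated with the Nei–Gojobori (1986) counting method: potential
synonymous/nonsynonymous sites are averaged over the two sequences,
multi-position codon differences are averaged over all equally weighted
mutational pathways, and the resulting proportions are Jukes–Cantor
corrected.  Mutations to or through stop codons are excluded.  Saturated
pairs (JC undefined, or dS above 2) are filtered out downstream, exactly
as pairs returned by ML estimators with sentinel values would be.

Strata are assigned by position against ordered breakpoints on the X and Y
(the X carries the strata in the order PAR, S2, S3, S1 because of the
inversions; the Y in the order PAR, S1, S2, S3), and strata ages follow
from a molecular-clock calibration against a known outgroup divergence.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)
_AA = dict(_TABLE.forward_table)
_BASES = "ACGT"


def translate_codon(codon: str) -> str | None:
    """Amino acid for a codon, or None for a stop codon."""
    if codon in _STOPS:
        return None
    return _AA[codon]


@dataclass
class DivergenceEstimate:
    dS: float
    dN: float
    dn_ds: float | None
    S_sites: float
    N_sites: float
    saturated: bool = False
    n_codons: int = 0
    y_position: int | None = None
    gene_id: str | None = None

    @property
    def usable(self) -> bool:
        return not self.saturated and self.dS <= 2.0


def _synonymous_fraction(codon: str) -> float:
    """Fraction of the three possible changes at each position that are
    synonymous, summed over positions; stop-codon targets are excluded
    from the denominator."""
    aa = translate_codon(codon)
    total = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            alt_aa = translate_codon(alt)
            if alt_aa is None:
                continue
            valid += 1
            if alt_aa == aa:
                syn += 1
        if valid:
            total += syn / valid
    return total


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts over all
    mutational pathways between two codons, skipping pathways that pass
    through a stop codon (falling back to all pathways if none avoid one)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    blocked = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            a1, a2 = translate_codon(cur), translate_codon(nxt)
            if a2 is None or a1 is None:
                ok = False
            if a1 is not None and a2 is not None and a1 == a2:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (results if ok else blocked).append((sd, nd))
    use = results or blocked
    sd = sum(r[0] for r in use) / len(use)
    nd = sum(r[1] for r in use) / len(use)
    return sd, nd


def _jc(p: float) -> float:
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_divergence(seq_x: str, seq_y: str, **meta) -> DivergenceEstimate:
    """NG86 dS/dN with Jukes–Cantor correction for one codon alignment.

    Sequences must be equal length multiples of three; codon columns
    containing a gap, an ambiguous base, or a stop codon in either
    sequence are dropped.  Identical inputs give dS = dN = 0; proportions
    at or beyond 0.75 are flagged saturated (JC undefined).
    """
    if len(seq_x) != len(seq_y):
        raise ValueError("aligned sequences must have equal length")
    if len(seq_x) % 3:
        raise ValueError("alignment length must be a multiple of three")
    seq_x, seq_y = seq_x.upper(), seq_y.upper()
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(seq_x), 3):
        c1, c2 = seq_x[i:i + 3], seq_y[i:i + 3]
        if any(ch not in _BASES for ch in c1 + c2):
            continue
        if c1 in _STOPS or c2 in _STOPS:
            continue
        n_codons += 1
        s1, s2 = _synonymous_fraction(c1), _synonymous_fraction(c2)
        S += (s1 + s2) / 2.0
        N += 3.0 - (s1 + s2) / 2.0
        sd, nd = _pathway_counts(c1, c2)
        Sd += sd
        Nd += nd
    if n_codons == 0:
        raise ValueError("no usable codon columns")
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    saturated = ps >= 0.75 or pn >= 0.75
    dS = _jc(ps) if not saturated else float("inf")
    dN = _jc(pn) if not saturated else float("inf")
    dn_ds = None if (saturated or dS == 0.0) else dN / dS
    return DivergenceEstimate(dS=dS, dN=dN, dn_ds=dn_ds, S_sites=S, N_sites=N,
                              saturated=saturated, n_codons=n_codons, **meta)


def best_gametolog(candidates: Sequence[DivergenceEstimate]):
    """Keep the lowest-dS candidate after removing saturated / dS > 2 hits;
    returns None when nothing survives (the gene is lost from the Y).
    Ties break to the leftmost Y position."""
    if not candidates:
        raise ValueError("at least one candidate required")
    usable = [c for c in candidates if c.usable]
    if not usable:
        return None
    return min(usable, key=lambda c: (c.dS, c.y_position if c.y_position is not None else 0))


# ---------------------------------------------------------------------------
# Strata
# ---------------------------------------------------------------------------

MB = 1_000_000


@dataclass
class StratumModel:
    """Ordered strata breakpoints (bp).  Defaults reproduce the three-strata
    model of the stickleback Y: on the Y the strata run PAR, S1, S2, S3
    with breakpoints at 0.34 / 4.67 / 9.67 Mb; on the X they run PAR, S2,
    S3, S1 with breakpoints at 2.5 / 6.89 / 12.5 Mb."""

    y_breakpoints: tuple[float, float, float] = (0.34 * MB, 4.67 * MB, 9.67 * MB)
    x_breakpoints: tuple[float, float, float] = (2.5 * MB, 6.89 * MB, 12.5 * MB)
    y_order: tuple[int, ...] = (0, 1, 2, 3)   # PAR, S1, S2, S3
    x_order: tuple[int, ...] = (0, 2, 3, 1)   # PAR, S2, S3, S1

    def __post_init__(self) -> None:
        for bp in (self.y_breakpoints, self.x_breakpoints):
            if list(bp) != sorted(bp):
                raise ValueError("breakpoints must be strictly increasing")


def assign_stratum(position: float, chromosome: str,
                   model: StratumModel | None = None) -> int:
    """Stratum index (0 = PAR) for a position by half-open interval lookup."""
    model = model or StratumModel()
    if position < 0:
        raise ValueError("position must be nonnegative")
    if chromosome == "X":
        breaks, order = model.x_breakpoints, model.x_order
    elif chromosome == "Y":
        breaks, order = model.y_breakpoints, model.y_order
    else:
        raise ValueError(f"chromosome must be X or Y, got {chromosome!r}")
    idx = int(np.searchsorted(np.asarray(breaks), position, side="right"))
    return order[idx]


def mann_whitney(a: Sequence[float], b: Sequence[float],
                 alternative: str = "two-sided"):
    """Mann-Whitney U: exact null for small tie-free samples, otherwise a
    tie-corrected normal approximation."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    return stats.mannwhitneyu(a, b, alternative=alternative, method=method)


def stratum_summary(estimates: Sequence[DivergenceEstimate],
                    strata: Sequence[int]):
    """Per-stratum medians and pairwise Mann-Whitney results.

    Returns ``(medians, tests)`` where medians is a DataFrame indexed by
    stratum with columns dS/dN/dn_ds and n, and tests maps
    (metric, stratum_a, stratum_b) -> p-value.
    """
    import pandas as pd
    rows = [{"stratum": s, "dS": e.dS, "dN": e.dN, "dn_ds": e.dn_ds}
            for e, s in zip(estimates, strata) if e.usable]
    df = pd.DataFrame(rows)
    present = sorted(df["stratum"].unique()) if len(df) else []
    med_rows = []
    for s in present:
        sub = df[df["stratum"] == s]
        med_rows.append({
            "stratum": s, "n": len(sub),
            "dS": sub["dS"].median(), "dN": sub["dN"].median(),
            "dn_ds": sub["dn_ds"].dropna().median()})
    medians = pd.DataFrame(med_rows).set_index("stratum") if med_rows else pd.DataFrame()
    tests = {}
    for metric in ("dS", "dN", "dn_ds"):
        for sa, sb in itertools.combinations(present, 2):
            va = df[df["stratum"] == sa][metric].dropna()
            vb = df[df["stratum"] == sb][metric].dropna()
            if len(va) >= 2 and len(vb) >= 2:
                tests[(metric, sa, sb)] = float(
                    mann_whitney(va, vb, "two-sided").pvalue)
    return medians, tests


# ---------------------------------------------------------------------------
# Dating
# ---------------------------------------------------------------------------

def calibrate_age(median_ds: float, reference_ds: float = 0.184,
                  reference_time_my: float = 26.0) -> float:
    """Stratum age in million years from a linear molecular-clock scaling
    of the stratum's median dS against a dated outgroup divergence."""
    if median_ds < 0 or reference_time_my < 0:
        raise ValueError("divergence and time must be nonnegative")
    if reference_ds <= 0:
        raise ValueError("reference_ds must be positive")
    return round(median_ds / reference_ds * reference_time_my, 1)


def gene_loss_rate(fraction_lost: float, age_my: float) -> float:
    """Percent of ancestral genes lost per million years (= generations
    for an annual species)."""
    if not 0.0 <= fraction_lost <= 1.0:
        raise ValueError("fraction_lost must be in [0, 1]")
    if age_my <= 0:
        raise ValueError("age_my must be positive")
    return round(100.0 * fraction_lost / age_my, 1)
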