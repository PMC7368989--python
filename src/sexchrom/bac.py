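"""BAC-insert concordance checking and gap merging.

Sanger-sequenced BAC inserts are an independent oracle for assembly
accuracy: a BAC whose alignment footprint reproduces its own length,
reaches both of its ends, and matches at high identity is concordant with
the scaffold.  BACs whose footprints bridge N-gaps validate contig order
and donate the missing sequence, which can be merged into the assembly.

Classification applies three rule sets in order (concordant, spans-gap,
extends-into-gap); anything failing all three is discordant.  Split
alignments are first chained into a single footprint; chaining refuses
indels larger than ``max_indel`` so large planted structural differences
(inversions, multi-kb indels) surface as discordance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .align import AlignmentBlock, chain_colinear, revcomp


@dataclass
class GapInterval:
    scaffold_id: str
    start: int
    end: int
    gap_id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("gap end must exceed start")


@dataclass
class BacClassification:
    bac_id: str
    verdict: str  # concordant | spans_gap | extends_into_gap | discordant
    gap_ids: list[str] = field(default_factory=list)
    identity: float = 0.0
    end_slack: tuple[int, int] = (0, 0)
    length_delta: int = 0
    reason: str = ""
    footprint: tuple[int, int] | None = None  # scaffold coords of the chain
    query_footprint: tuple[int, int] | None = None
    strand: str = "+"


def find_gaps(scaffold: str, scaffold_id: str = "scaffold",
              min_run: int = 10) -> list[GapInterval]:
    """N-runs of at least ``min_run`` bases, as sorted GapIntervals."""
    gaps = []
    i, n = 0, len(scaffold)
    idx = 0
    while i < n:
        if scaffold[i] == "N":
            j = i
            while j < n and scaffold[j] == "N":
                j += 1
            if j - i >= min_run:
                gaps.append(GapInterval(scaffold_id, i, j, f"gap{idx:02d}"))
                idx += 1
            i = j
        else:
            i += 1
    return gaps


def _contig_edges(gaps: Sequence[GapInterval]) -> set[int]:
    """Scaffold positions where a contig abuts a gap."""
    edges = set()
    for g in gaps:
        edges.add(g.start)  # right end of the left-flanking contig
        edges.add(g.end)    # left end of the right-flanking contig
    return edges


def classify_bac(bac_id: str, bac_len: int, blocks: Sequence[AlignmentBlock],
                 gaps: Sequence[GapInterval], end_tol: int = 1000,
                 len_tol: int = 10_000, min_identity: float = 0.99,
                 max_indel: int = 1000,
                 min_block_identity: float = 0.95) -> BacClassification:
    """Apply the concordant / spans-gap / extends-into-gap rules in order.

    Concordant: both footprint ends within ``end_tol`` of the BAC ends, the
    footprint span within ``len_tol`` of the BAC length, identity at least
    ``min_identity``, and the footprint touching no gap.  Spans-gap: ends
    within ``end_tol``, total aligned length not exceeding the BAC length,
    identity at least ``min_identity``, and at least one gap contained
    entirely in the footprint.  Extends-into-gap: one alignment end
    coinciding exactly with a contig end adjacent to a gap, the opposite
    footprint end within ``end_tol`` of the corresponding BAC end, and
    identity at least ``min_identity``.
    """
    if not blocks:
        return BacClassification(bac_id, "discordant", reason="no alignment")
    # repeat-induced low-identity blocks can only dilute a footprint that
    # must reach min_identity anyway, so drop them before chaining
    blocks = [b for b in blocks if b.identity >= min_block_identity]
    if not blocks:
        return BacClassification(bac_id, "discordant", reason="no alignment")
    chain = chain_colinear(blocks, max_indel=max_indel,
                           waive_intervals=[(g.start, g.end) for g in gaps])
    if not chain:
        return BacClassification(bac_id, "discordant", reason="no chain")
    strand = chain[0].strand
    qmin = min(b.query_start for b in chain)
    qmax = max(b.query_end for b in chain)
    tmin = min(b.target_start for b in chain)
    tmax = max(b.target_end for b in chain)
    matches = sum(b.matches for b in chain)
    cols = sum(b.align_len for b in chain)
    identity = matches / cols
    slack = (qmin, bac_len - qmax)
    length_delta = (tmax - tmin) - bac_len
    contained = [g for g in gaps if tmin <= g.start and g.end <= tmax]
    overlapping = [g for g in gaps if g.start < tmax and tmin < g.end]

    result = BacClassification(
        bac_id, "discordant", identity=identity, end_slack=slack,
        length_delta=length_delta, footprint=(tmin, tmax),
        query_footprint=(qmin, qmax), strand=strand)

    ends_ok = slack[0] <= end_tol and slack[1] <= end_tol
    if identity >= min_identity:
        if ends_ok and abs(length_delta) <= len_tol and not overlapping:
            result.verdict = "concordant"
            return result
        if ends_ok and cols <= bac_len and contained:
            result.verdict = "spans_gap"
            result.gap_ids = [g.gap_id for g in contained]
            return result
        # extends into a gap: the inner alignment end sits exactly on a
        # contig end, the outer BAC end is reached within tolerance
        for g in gaps:
            left_reach = tmax == g.start and slack[0] <= end_tol
            right_reach = tmin == g.end and slack[1] <= end_tol
            if strand == "-":
                left_reach = tmax == g.start and slack[1] <= end_tol
                right_reach = tmin == g.end and slack[0] <= end_tol
            if left_reach or right_reach:
                result.verdict = "extends_into_gap"
                result.gap_ids = [g.gap_id]
                return result
    result.reason = "failed all rule sets"
    return result


def classify_all(bacs: dict[str, str], scaffold: str,
                 gaps: Sequence[GapInterval] | None = None,
                 aligner_kwargs: dict | None = None,
                 **rule_kwargs) -> dict[str, BacClassification]:
    """Align every BAC to the scaffold and classify it."""
    from .align import anchor_align
    if gaps is None:
        gaps = find_gaps(scaffold, min_run=10)
    kwargs = {"k": 15, "min_block": 200}
    kwargs.update(aligner_kwargs or {})
    out = {}
    for bac_id in sorted(bacs):
        seq = bacs[bac_id]
        blocks = anchor_align(seq, scaffold, query_id=bac_id,
                              target_id="scaffold", **kwargs)
        out[bac_id] = classify_bac(bac_id, len(seq), blocks, gaps, **rule_kwargs)
    return out


def merge_bacs(scaffold: str, classifications: Iterable[BacClassification],
               bac_sequences: dict[str, str]):
    """Merge gap-spanning/extending BAC sequence into the scaffold.

    For each gap at most one BAC is applied: the highest identity wins,
    ties go to the longer BAC.  A spanning BAC replaces its footprint
    (gap Ns plus flanking aligned overlap) with its own sequence; an
    extending BAC replaces only the reached-into prefix or suffix of the
    gap with its unaligned overhang.  Returns ``(merged, report, liftover)``
    where liftover rows are (old_start, old_end, new_start) for the
    unchanged segments between edits.
    """
    gaps = find_gaps(scaffold)
    by_gap: dict[str, list[BacClassification]] = {}
    for c in classifications:
        if c.verdict in ("spans_gap", "extends_into_gap"):
            for gid in c.gap_ids:
                by_gap.setdefault(gid, []).append(c)
    chosen: list[tuple[GapInterval, BacClassification]] = []
    used_ids = set()
    for g in gaps:
        cands = by_gap.get(g.gap_id)
        if not cands:
            continue
        cands.sort(key=lambda c: (-c.identity, -len(bac_sequences[c.bac_id]), c.bac_id))
        pick = cands[0]
        if pick.bac_id not in bac_sequences:
            raise KeyError(f"BAC sequence missing for {pick.bac_id}")
        chosen.append((g, pick))
        used_ids.add(pick.bac_id)
    # reject overlapping edits (later gap whose chosen BAC footprint
    # reaches into an already-claimed region)
    edits = []  # (start, end, replacement, bac_id, gap_id)
    claimed: list[tuple[int, int]] = []
    report = []
    for g, c in sorted(chosen, key=lambda gc: gc[0].start):
        seq = bac_sequences[c.bac_id]
        if c.strand == "-":
            seq = revcomp(seq)
            qfp = (len(seq) - c.query_footprint[1], len(seq) - c.query_footprint[0])
        else:
            qfp = c.query_footprint
        if c.verdict == "spans_gap":
            start, end = c.footprint
            replacement = seq[qfp[0]:qfp[1]]
        else:  # extends into the gap
            if c.footprint[1] == g.start:  # extends rightward
                over = seq[qfp[1]:]
                consumed = min(len(over), g.end - g.start)
                start, end = g.start, g.start + consumed
                replacement = over
            else:  # extends leftward
                over = seq[:qfp[0]]
                consumed = min(len(over), g.end - g.start)
                start, end = g.end - consumed, g.end
                replacement = over
        if any(s < end and start < e for s, e in claimed):
            warnings.warn(f"overlapping merge for {c.bac_id} at gap {g.gap_id} rejected")
            continue
        claimed.append((start, end))
        edits.append((start, end, replacement, c.bac_id, g.gap_id))
        report.append({"gap_id": g.gap_id, "bac_id": c.bac_id,
                       "verdict": c.verdict, "identity": c.identity,
                       "old_span": end - start, "new_span": len(replacement)})
    merged_parts = []
    liftover = []
    pos = 0
    new_pos = 0
    for start, end, replacement, _, _ in sorted(edits):
        merged_parts.append(scaffold[pos:start])
        liftover.append((pos, start, new_pos))
        new_pos += start - pos
        merged_parts.append(replacement)
        new_pos += len(replacement)
        pos = end
    merged_parts.append(scaffold[pos:])
    liftover.append((pos, len(scaffold), new_pos))
    merged = "".join(merged_parts)
    return merged, report, liftover


def concordance_summary(classifications: Iterable[BacClassification],
                        n_gaps_total: int) -> dict:
    """Verdict counts, distinct gaps resolved, and the fraction of gaps
    spanned (None when the assembly has no gaps)."""
    counts = {"concordant": 0, "spans_gap": 0, "extends_into_gap": 0,
              "discordant": 0}
    spanned = set()
    for c in classifications:
        counts[c.verdict] += 1
        if c.verdict == "spans_gap":
            spanned.update(c.gap_ids)
    fraction = len(spanned) / n_gaps_total if n_gaps_total > 0 else None
    return {"counts": counts, "gaps_spanned": len(spanned),
            "fraction_gaps_spanned": fraction}
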