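"""Pairwise alignment primitives.

Provides the :class:`AlignmentBlock` record used throughout the package,
parsers/writers for two common tabular alignment dialects (minimap2-style
PAF and MUMmer ``show-coords -T``), and a small exact-seeded gapless
aligner adequate for desk-scale sequences so that no external aligner is
needed for testing.  Real-data users are expected to supply PAF or coords
files produced by minimap2/nucmer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """Byte view of a sequence for vectorized comparison."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


@dataclass
class AlignmentBlock:
    """One gapless (or chained) local alignment between a query and a target.

    Coordinates are 0-based half-open on both sequences; query coordinates
    always refer to the original (forward) query strand.
    """

    query_id: str
    target_id: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str
    matches: int
    align_len: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0 <= self.query_start < self.query_end):
            raise ValueError("query interval must satisfy 0 <= start < end")
        if not (0 <= self.target_start < self.target_end):
            raise ValueError("target interval must satisfy 0 <= start < end")
        if self.matches > self.align_len:
            raise ValueError("matches cannot exceed align_len")

    @property
    def identity(self) -> float:
        return self.matches / self.align_len

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start


# ---------------------------------------------------------------------------
# Dialect parsing
# ---------------------------------------------------------------------------

def read_alignments(path, dialect: str) -> list[AlignmentBlock]:
    """Read alignment records, normalizing coordinates to 0-based half-open.

    ``paf`` is the 12+ column minimap2 format (already 0-based half-open);
    ``coords`` is the tab-separated ``show-coords -T`` output of MUMmer
    (1-based inclusive, reference columns first), which is shifted on read.
    """
    if dialect not in ("paf", "coords"):
        raise ValueError(f"unknown dialect {dialect!r}")
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "paf":
                    blocks.append(_parse_paf(fields))
                else:
                    parsed = _parse_coords(fields)
                    if parsed is not None:
                        blocks.append(parsed)
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed {dialect} line {lineno}: {exc}") from exc
    return blocks


def _parse_paf(f: Sequence[str]) -> AlignmentBlock:
    return AlignmentBlock(
        query_id=f[0],
        query_start=int(f[2]),
        query_end=int(f[3]),
        strand=f[4],
        target_id=f[5],
        target_start=int(f[7]),
        target_end=int(f[8]),
        matches=int(f[9]),
        align_len=int(f[10]),
    )


def _parse_coords(f: Sequence[str]):
    # show-coords -T header lines contain non-numeric first fields; skip them.
    try:
        s1 = int(f[0])
    except ValueError:
        return None
    e1, s2, e2 = int(f[1]), int(f[2]), int(f[3])
    len1, len2, idy = int(f[4]), int(f[5]), float(f[6])
    target_id, query_id = f[7], f[8]
    if s2 <= e2:
        strand, qs, qe = "+", s2 - 1, e2
    else:
        strand, qs, qe = "-", e2 - 1, s2
    align_len = max(len1, len2)
    matches = int(round(idy / 100.0 * align_len))
    return AlignmentBlock(
        query_id=query_id,
        target_id=target_id,
        query_start=qs,
        query_end=qe,
        target_start=s1 - 1,
        target_end=e1,
        strand=strand,
        matches=matches,
        align_len=align_len,
    )


def write_alignments(blocks: Iterable[AlignmentBlock], path, dialect: str,
                     query_lengths: dict[str, int] | None = None,
                     target_lengths: dict[str, int] | None = None) -> None:
    """Write blocks in the named dialect (inverse of :func:`read_alignments`)."""
    if dialect not in ("paf", "coords"):
        raise ValueError(f"unknown dialect {dialect!r}")
    qlen = query_lengths or {}
    tlen = target_lengths or {}
    with open(path, "w") as fh:
        for b in blocks:
            if dialect == "paf":
                fh.write("\t".join(map(str, [
                    b.query_id, qlen.get(b.query_id, b.query_end), b.query_start,
                    b.query_end, b.strand, b.target_id,
                    tlen.get(b.target_id, b.target_end), b.target_start,
                    b.target_end, b.matches, b.align_len, 255,
                ])) + "\n")
            else:
                if b.strand == "+":
                    s2, e2 = b.query_start + 1, b.query_end
                else:
                    s2, e2 = b.query_end, b.query_start + 1
                idy = 100.0 * b.matches / b.align_len
                fh.write("\t".join(map(str, [
                    b.target_start + 1, b.target_end, s2, e2,
                    b.target_span, b.query_span, f"{idy:.6f}",
                    b.target_id, b.query_id,
                ])) + "\n")


# ---------------------------------------------------------------------------
# Seeded gapless alignment
# ---------------------------------------------------------------------------

def _kmer_index(arr: np.ndarray, k: int, max_hits: int) -> dict[bytes, list[int]]:
    index: dict[bytes, list[int]] = {}
    data = arr.tobytes()
    n = len(data)
    for i in range(n - k + 1):
        word = data[i:i + k]
        if b"N" in word:
            continue
        hits = index.setdefault(word, [])
        if len(hits) <= max_hits:
            hits.append(i)
    return index


def _segments_on_diagonal(match: np.ndarray, match_score: int, mismatch_cost: int,
                          min_block: int) -> list[tuple[int, int, int]]:
    """Maximal positive-scoring runs (start, end, matches) along one diagonal.

    Linear scan in the Kadane style: the running score resets below zero,
    splitting the diagonal into candidate segments; within each stretch the
    segment ends at the running-score maximum.  The globally best segment it
    returns equals the exhaustive best gapless segment under the same
    +match/-mismatch scoring.
    """
    score = np.where(match, match_score, -mismatch_cost).tolist()
    segments: list[tuple[int, int]] = []
    run = 0
    start = -1
    best = 0
    best_end = -1
    for i, s in enumerate(score):
        if start < 0:
            if s <= 0:
                continue
            start, run, best, best_end = i, 0, 0, -1
        run += s
        if run > best:
            best, best_end = run, i
        if run < 0:
            segments.append((start, best_end + 1))
            start = -1
    if start >= 0:
        segments.append((start, best_end + 1))
    out = []
    for s, e in segments:
        if e - s >= min_block:
            out.append((s, e, int(match[s:e].sum())))
    return out


def anchor_align(query: str, target: str, k: int = 15, min_block: int = 100,
                 *, match_score: int = 1, mismatch_cost: int = 1,
                 max_kmer_hits: int = 100, query_id: str = "query",
                 target_id: str = "target") -> list[AlignmentBlock]:
    """Exact k-mer seeded, gapless alignment of ``query`` against ``target``.

    Shared k-mers anchor candidate diagonals; each anchored diagonal is
    scanned for maximal positive-scoring gapless segments (+match_score /
    -mismatch_cost), and segments of at least ``min_block`` bases are
    reported on both strands.  Identity is matches over the extended span.
    """
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    if k < 8:
        raise ValueError("k must be >= 8")
    tarr = seq_to_array(target.upper())
    index = _kmer_index(tarr, k, max_kmer_hits)
    blocks: list[AlignmentBlock] = []
    lq, lt = len(query), len(target)
    for strand in "+-":
        q = query.upper() if strand == "+" else revcomp(query.upper())
        qarr = seq_to_array(q)
        qbytes = qarr.tobytes()
        diagonals: set[int] = set()
        for i in range(lq - k + 1):
            word = qbytes[i:i + k]
            hits = index.get(word)
            if not hits or len(hits) > max_kmer_hits:
                continue
            for t in hits:
                diagonals.add(t - i)
        n_mask = np.uint8(ord("N"))
        for d in sorted(diagonals):
            qs = max(0, -d)
            qe = min(lq, lt - d)
            if qe - qs < min_block:
                continue
            a = qarr[qs:qe]
            b = tarr[qs + d:qe + d]
            match = (a == b) & (a != n_mask) & (b != n_mask)
            for s, e, m in _segments_on_diagonal(match, match_score,
                                                 mismatch_cost, min_block):
                q0, q1 = qs + s, qs + e
                t0, t1 = q0 + d, q1 + d
                if strand == "-":
                    q0, q1 = lq - q1, lq - q0
                blocks.append(AlignmentBlock(
                    query_id=query_id, target_id=target_id,
                    query_start=q0, query_end=q1,
                    target_start=t0, target_end=t1,
                    strand=strand, matches=m, align_len=e - s))
    # deterministic order: best first, then leftmost on target
    blocks.sort(key=lambda b: (-b.matches, b.target_start, b.query_start, b.strand))
    return blocks


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted, non-overlapping list."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def aligned_fraction(blocks: Sequence[AlignmentBlock], query_len: int) -> float:
    """Fraction of the query covered by the union of block query intervals."""
    if query_len <= 0:
        raise ValueError("query_len must be positive")
    ids = {b.query_id for b in blocks}
    if len(ids) > 1:
        raise ValueError(f"blocks span multiple queries: {sorted(ids)}")
    covered = sum(e - s for s, e in
                  merge_intervals((b.query_start, b.query_end) for b in blocks))
    return covered / query_len


def chain_colinear(blocks: Sequence[AlignmentBlock], max_indel: int = 1000,
                   max_overlap: int = 50,
                   waive_intervals: Sequence[tuple[int, int]] | None = None
                   ) -> list[AlignmentBlock]:
    """Best-scoring colinear chain of same-strand blocks.

    Blocks chain when query and target order agree (accounting for strand),
    small overlaps are tolerated, and the implied indel between consecutive
    blocks (difference of query gap and target gap) is at most ``max_indel``.
    Large structural differences therefore break the chain.  A chain step
    whose target-side skip overlaps one of ``waive_intervals`` (assembly
    N-gaps, whose true length is unknown) is exempt from the indel bound.
    Returns the chain maximizing total matches; ties go to the leftmost
    target start.
    """
    waive = list(waive_intervals or [])
    candidates: list[tuple[int, int, list[AlignmentBlock]]] = []
    for strand in "+-":
        sub = [b for b in blocks if b.strand == strand]
        if not sub:
            continue
        if strand == "+":
            sub.sort(key=lambda b: (b.query_start, b.target_start))
        else:
            # with query coords on the forward strand, a reverse-strand chain
            # walks the target forward while the query walks backward
            sub.sort(key=lambda b: (b.target_start, -b.query_start))
        n = len(sub)
        score = [b.matches for b in sub]
        parent = [-1] * n
        for j in range(n):
            for i in range(j):
                a, b = sub[i], sub[j]
                if strand == "+":
                    qgap = b.query_start - a.query_end
                    tgap = b.target_start - a.target_end
                else:
                    qgap = a.query_start - b.query_end
                    tgap = b.target_start - a.target_end
                if qgap < -max_overlap or tgap < -max_overlap:
                    continue
                t_lo, t_hi = a.target_end, b.target_start
                gap_span = sum(max(0, min(e, t_hi) - max(s, t_lo))
                               for s, e in waive)
                if gap_span > 0:
                    # only the N-gap itself has unknown length; the rest of
                    # the target skip is still held to the indel bound
                    if tgap - gap_span > max_indel:
                        continue
                elif abs(tgap - qgap) > max_indel:
                    continue
                cand = score[i] + b.matches
                if cand > score[j]:
                    score[j] = cand
                    parent[j] = i
        j = int(np.argmax(score))
        total = score[j]
        chain = []
        while j != -1:
            chain.append(sub[j])
            j = parent[j]
        chain.reverse()
        candidates.append((total, min(b.target_start for b in chain), chain))
    if not candidates:
        return []
    candidates.sort(key=lambda c: (-c[0], c[1]))
    return candidates[0][2]
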