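"""Classification of assembly contigs into X-linked and Y-candidate sets.

A long-read male assembly mixes X- and Y-derived contigs (plus allelic
haplotigs of the autosomes).  Contigs are partitioned by their aggregate
identity to the reference X chromosome: high-identity contigs are X-linked,
lower-identity ones are Y candidates, and contigs with little or no
alignment are retained as putative Y-unique sequence.  The identity
threshold is chosen by sweeping candidate values and picking the one whose
X-linked set best matches the known X chromosome length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentBlock, merge_intervals


@dataclass
class ContigRecord:
    contig_id: str
    length: int
    contig_class: str  # x_linked | y_candidate | partial | unaligned
    best_identity: float | None
    aligned_fraction: float


def collapse_haplotigs(blocks: Iterable[AlignmentBlock],
                       contig_lengths: dict[str, int],
                       min_len: int = 1000,
                       min_identity: float = 0.98) -> set[str]:
    """Mark redundant haplotigs from all-vs-all contig self-alignments.

    For every alignment of at least ``min_len`` bases and ``min_identity``
    identity between two distinct contigs, the shorter contig is marked
    redundant.  Marking is greedy from the longest contig down, so a contig
    that is itself redundant never absorbs others (transitive-safe).
    """
    partners: dict[str, set[str]] = {}
    for b in blocks:
        if b.query_id == b.target_id:
            warnings.warn(f"self-hit for {b.query_id} skipped")
            continue
        if b.align_len < min_len or b.identity < min_identity:
            continue
        partners.setdefault(b.query_id, set()).add(b.target_id)
        partners.setdefault(b.target_id, set()).add(b.query_id)
    order = sorted(partners, key=lambda c: (-contig_lengths[c], c))
    redundant: set[str] = set()
    for contig in order:
        if contig in redundant:
            continue
        for other in partners[contig]:
            if other in redundant:
                continue
            pair = sorted([contig, other], key=lambda c: (-contig_lengths[c], c))
            if pair[1] != contig:  # the shorter of the pair is dropped
                redundant.add(pair[1])
    return redundant


def classify_contigs(blocks: Sequence[AlignmentBlock],
                     contig_lengths: dict[str, int],
                     identity_threshold: float = 0.96,
                     min_fraction: float = 0.25) -> list[ContigRecord]:
    """Partition contigs by alignment to the reference X chromosome.

    A contig with at least ``min_fraction`` of its length aligned is
    X-linked when its alignment-length-weighted mean identity exceeds the
    threshold and a Y candidate otherwise (the boundary value goes to the
    Y).  Contigs with some but less than ``min_fraction`` coverage are
    ``partial`` and unaligned contigs ``unaligned``; the downstream Y set
    is the union of y_candidate, partial, and unaligned.
    """
    by_query: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        if b.query_id not in contig_lengths:
            raise KeyError(f"no length recorded for contig {b.query_id}")
        by_query.setdefault(b.query_id, []).append(b)
    records = []
    for contig_id in sorted(contig_lengths):
        length = contig_lengths[contig_id]
        sub = by_query.get(contig_id, [])
        if not sub:
            records.append(ContigRecord(contig_id, length, "unaligned", None, 0.0))
            continue
        covered = sum(e - s for s, e in merge_intervals(
            (b.query_start, b.query_end) for b in sub))
        fraction = covered / length
        identity = sum(b.matches for b in sub) / sum(b.align_len for b in sub)
        if fraction >= min_fraction:
            cls = "x_linked" if identity > identity_threshold else "y_candidate"
        else:
            cls = "partial"
        records.append(ContigRecord(contig_id, length, cls, identity, fraction))
    return records


def y_set(records: Sequence[ContigRecord]) -> set[str]:
    """The putative Y-linked set: candidates plus partial plus unaligned."""
    return {r.contig_id for r in records
            if r.contig_class in ("y_candidate", "partial", "unaligned")}


def sweep_identity_threshold(blocks: Sequence[AlignmentBlock],
                             contig_lengths: dict[str, int],
                             reference_x_len: int,
                             thresholds: Sequence[float] | None = None,
                             min_fraction: float = 0.25):
    """Choose the identity threshold whose X-linked set total length is
    closest to the reference X chromosome length (ties toward the lower
    threshold).  Returns ``(chosen_threshold, table)``."""
    if not blocks:
        raise ValueError("no alignment blocks supplied")
    if thresholds is None:
        thresholds = np.round(np.arange(0.92, 0.9801, 0.01), 4)
    thresholds = list(thresholds)
    if len(thresholds) < 2:
        raise ValueError("need at least two thresholds to sweep")
    rows = []
    for t in thresholds:
        records = classify_contigs(blocks, contig_lengths, identity_threshold=t,
                                   min_fraction=min_fraction)
        total = sum(r.length for r in records if r.contig_class == "x_linked")
        rows.append({"threshold": float(t), "x_linked_total": total,
                     "abs_diff": abs(total - reference_x_len)})
    table = pd.DataFrame(rows)
    best = table.sort_values(["abs_diff", "threshold"]).iloc[0]
    return float(best["threshold"]), table
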