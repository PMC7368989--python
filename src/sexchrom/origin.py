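"""Origin and copy-number classification of Y-linked genes.

Each Y gene is placed into one of six categories: {X-ancestral, autosomal,
unknown origin} x {single copy, duplicated}.  An X hit takes precedence
over autosomal paralogs; an autosomal paralog only counts as the origin
when its dS falls below the stratum-one median (0.101), which guards
against assigning ancient paralogs as the source of a recent translocation.
Hits to unplaced contigs (ChrUn) are ignored.  Translocated copies are
additionally screened for retrogene signatures (complete intron loss
relative to the autosomal paralog).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

STRATUM_ONE_MEDIAN_DS = 0.101


@dataclass
class Hit:
    target_class: str  # "X" | "autosome" | "Y" | "ChrUn"
    target_pos: int
    dS: float


@dataclass
class ParalogSet:
    gene_id: str
    origin: str            # x_ancestral | autosomal | unknown
    copy_class: str        # single | duplicated
    n_y_copies: int = 1
    x_hit: Hit | None = None
    autosome_hit: Hit | None = None
    stratum: int | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def category(self) -> str:
        return f"{self.origin}_{self.copy_class}"


def classify_origin(gene_id: str, hits: Sequence[Hit], n_y_copies: int = 1,
                    ds_cutoff: float = STRATUM_ONE_MEDIAN_DS) -> ParalogSet:
    """Assign origin and copy class from precomputed per-hit dS values.

    An X hit (lowest dS retained) makes the gene X-ancestral regardless of
    autosomal paralogs; otherwise an autosomal hit below ``ds_cutoff``
    makes it autosome-derived; anything else is of unknown origin.
    """
    hits = [h for h in hits if h.target_class != "ChrUn"]
    x_hits = sorted((h for h in hits if h.target_class == "X"),
                    key=lambda h: (h.dS, h.target_pos))
    a_hits = sorted((h for h in hits if h.target_class == "autosome"),
                    key=lambda h: (h.dS, h.target_pos))
    flags = []
    if x_hits:
        origin = "x_ancestral"
    elif a_hits and a_hits[0].dS < ds_cutoff:
        origin = "autosomal"
    else:
        origin = "unknown"
        if not hits:
            flags.append("no_hits")
    copy_class = "duplicated" if n_y_copies >= 2 else "single"
    return ParalogSet(gene_id=gene_id, origin=origin, copy_class=copy_class,
                      n_y_copies=n_y_copies,
                      x_hit=x_hits[0] if x_hits else None,
                      autosome_hit=a_hits[0] if a_hits else None,
                      flags=flags)


def retrogene_check(y_intron_count: int, autosomal_intron_count: int) -> str:
    """RNA- vs DNA-based translocation signature from intron retention.

    A multi-intron autosomal paralog whose Y copy lost every intron is an
    RNA-mediated (retrogene) candidate; any retained intron indicates a
    DNA-based translocation; paralogs with fewer than two introns are
    uninformative.
    """
    if y_intron_count < 0 or autosomal_intron_count < 0:
        raise ValueError("intron counts must be nonnegative")
    if autosomal_intron_count <= 1:
        return "uninformative"
    if y_intron_count == 0:
        return "rna_based_candidate"
    return "dna_based"


CATEGORIES = [
    "x_ancestral_single", "x_ancestral_duplicated",
    "autosomal_single", "autosomal_duplicated",
    "unknown_single", "unknown_duplicated",
]


def origin_table(paralog_sets: Sequence[ParalogSet],
                 strata: Sequence[int] | None = None) -> pd.DataFrame:
    """Category x stratum counts with row totals and percentages.

    Returns a DataFrame indexed by stratum (plus a ``total`` row) with one
    count column per category, a ``total`` column, and matching
    ``pct_<category>`` columns rounded to one decimal.
    """
    if strata is None:
        strata = [p.stratum for p in paralog_sets]
    rows = pd.DataFrame({
        "category": [p.category for p in paralog_sets],
        "stratum": list(strata)})
    strata_present = sorted(s for s in set(rows["stratum"]) if s is not None) \
        if len(rows) else []
    out = []
    for s in strata_present + ["total"]:
        sub = rows if s == "total" else rows[rows["stratum"] == s]
        counts = {cat: int((sub["category"] == cat).sum()) for cat in CATEGORIES}
        total = sum(counts.values())
        row = {"stratum": s, **counts, "total": total}
        for cat in CATEGORIES:
            row[f"pct_{cat}"] = round(100.0 * counts[cat] / total, 1) if total else 0.0
        out.append(row)
    if not out:
        out = [{"stratum": "total", **{c: 0 for c in CATEGORIES}, "total": 0,
                **{f"pct_{c}": 0.0 for c in CATEGORIES}}]
    return pd.DataFrame(out).set_index("stratum")
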