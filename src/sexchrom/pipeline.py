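"""End-to-end stages over a simulated genome, scored against its truth.

These functions wire the individual modules together the way the analysis
runs on real data — align, sweep, classify, estimate — and report how well
each stage recovers the generator's ground truth.  They are shared by the
test suite and the acceptance script.
"""

from __future__ import annotations


import numpy as np
import pandas as pd

from . import bac as bacmod
from . import dosage, origin, partition
from .align import anchor_align
from .centromere import chip_enrichment
from .divergence import ng86_divergence
from .simulate import GenomeSimulation, TracksAndCounts, gametolog_cds_pairs


def partition_truth_recovery(sim: GenomeSimulation, k: int = 15,
                             min_block: int = 200) -> dict:
    """Align X/Y contigs to the reference X, sweep the identity threshold,
    classify at the chosen threshold, and score against expected labels.

    Anchoring uses target-unique k-mers (MUM-style), which suppresses
    cross-repeat hits the same way a unique-match anchor aligner does.
    """
    truth = sim.truth
    ref = sim.reference["refX"]
    contigs = {cid: seq for cid, seq in sim.contigs.items()
               if truth.contig_labels[cid] in ("X", "Y")}
    lengths = {cid: len(seq) for cid, seq in contigs.items()}
    blocks = []
    for cid in sorted(contigs):
        blocks.extend(anchor_align(contigs[cid], ref, k=k, min_block=min_block,
                                   max_kmer_hits=1, query_id=cid,
                                   target_id="refX"))
    threshold, table = partition.sweep_identity_threshold(
        blocks, lengths, reference_x_len=len(ref))
    records = partition.classify_contigs(blocks, lengths,
                                         identity_threshold=threshold)
    predicted = {r.contig_id: ("x" if r.contig_class == "x_linked" else "y")
                 for r in records}
    expected = {cid: truth.contig_expected[cid] for cid in contigs}
    correct = sum(predicted[cid] == expected[cid] for cid in contigs)
    return {"threshold": threshold, "sweep_table": table, "records": records,
            "accuracy": correct / len(contigs), "n_contigs": len(contigs),
            "predicted": predicted, "expected": expected}


def bac_truth_recovery(sim: GenomeSimulation, bacs: dict[str, str],
                       **rule_kwargs) -> dict:
    """Classify simulated BACs against the gapped scaffold and compare
    verdicts with the planted truth classes."""
    gaps = [bacmod.GapInterval(g["scaffold_id"], g["start"], g["end"], g["gap_id"])
            for g in sim.truth.gaps]
    classifications = bacmod.classify_all(
        bacs, sim.scaffold, gaps=gaps,
        aligner_kwargs={"k": 15, "min_block": 200, "max_kmer_hits": 1},
        **rule_kwargs)
    mismatches = {}
    for bid, c in classifications.items():
        want = sim.truth.bac_truth[bid]["class"]
        if c.verdict != want:
            mismatches[bid] = (want, c.verdict)
    return {"classifications": classifications, "mismatches": mismatches,
            "accuracy": 1.0 - len(mismatches) / max(len(bacs), 1),
            "summary": bacmod.concordance_summary(
                classifications.values(), n_gaps_total=len(gaps))}


def gametolog_divergence(sim: GenomeSimulation) -> pd.DataFrame:
    """NG86 estimates for every retained gametolog pair, with the X-side
    stratum of each gene."""
    rows = []
    for xid, (cds_x, cds_y) in gametolog_cds_pairs(sim).items():
        g = sim.truth.genes[xid]
        stratum = next(s for a, b, s in sim.truth.strata_intervals["chrX"]
                       if a <= g.start < b)
        est = ng86_divergence(cds_x, cds_y, gene_id=xid)
        rows.append({"gene": xid, "stratum": stratum, "dS": est.dS,
                     "dN": est.dN, "usable": est.usable})
    return pd.DataFrame(rows)


def _cds_collections(sim: GenomeSimulation):
    truth = sim.truth
    x_cds, a_cds, y_cds = {}, {}, {}
    for gid, g in truth.genes.items():
        cds = g.cds(sim.sequences[g.chrom])
        if g.chrom == "chrX":
            x_cds[gid] = cds
        elif g.chrom == "chrY":
            y_cds[gid] = cds
        else:
            a_cds[gid] = cds
    return x_cds, a_cds, y_cds


def _kmer_candidates(query_cds: dict[str, str], target_cds: dict[str, str],
                     k: int = 12, min_shared: int = 10):
    """Pairs of (query gene, target gene) sharing at least ``min_shared``
    exact k-mers — a cheap prefilter before codon-level comparison."""
    index: dict[str, set[str]] = {}
    for tid, seq in target_cds.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i:i + k], set()).add(tid)
    pairs = {}
    for qid, seq in query_cds.items():
        counts: dict[str, int] = {}
        for i in range(len(seq) - k + 1):
            for tid in index.get(seq[i:i + k], ()):
                counts[tid] = counts.get(tid, 0) + 1
        pairs[qid] = sorted(t for t, c in counts.items() if c >= min_shared)
    return pairs


def gene_origin_truth_recovery(sim: GenomeSimulation) -> dict:
    """Discover X/autosome/Y paralogs of every Y gene by k-mer prefilter +
    NG86, classify origins, and compare with the generator's truth."""
    truth = sim.truth
    x_cds, a_cds, y_cds = _cds_collections(sim)
    x_cand = _kmer_candidates(y_cds, x_cds)
    a_cand = _kmer_candidates(y_cds, a_cds)
    y_cand = _kmer_candidates(y_cds, y_cds)

    def _ds(seq1, seq2):
        if len(seq1) != len(seq2):
            return None
        est = ng86_divergence(seq1, seq2)
        return est.dS if est.usable else None

    # Y copy families: connected components of mutual k-mer sharing
    comp: dict[str, int] = {}
    for gid in y_cds:
        comp.setdefault(gid, len(comp))
    for gid, partners in y_cand.items():
        for pid in partners:
            a, b = comp[gid], comp[pid]
            if a != b:
                for key, v in comp.items():
                    if v == b:
                        comp[key] = a
    copies: dict[int, list[str]] = {}
    for gid, c in comp.items():
        copies.setdefault(c, []).append(gid)

    results = {}
    strata_iv = truth.strata_intervals["chrY"]
    for c, members in copies.items():
        members.sort(key=lambda gid: truth.genes[gid].start)
        first = members[0]
        hits = []
        for tid in x_cand.get(first, []):
            ds = _ds(y_cds[first], x_cds[tid])
            if ds is not None:
                hits.append(origin.Hit("X", truth.genes[tid].start, ds))
        for tid in a_cand.get(first, []):
            ds = _ds(y_cds[first], a_cds[tid])
            if ds is not None:
                hits.append(origin.Hit("autosome", truth.genes[tid].start, ds))
        pset = origin.classify_origin(first, hits, n_y_copies=len(members))
        pset.stratum = next(s for a, b, s in strata_iv
                            if a <= truth.genes[first].start < b)
        results[truth.genes[first].family] = pset

    mismatches = {}
    for family, info in truth.gene_origins.items():
        pset = results.get(family)
        got = (pset.origin, pset.copy_class) if pset else None
        want = (info["origin"], info["copy_class"])
        if got != want:
            mismatches[family] = (want, got)
    table = origin.origin_table(list(results.values()))
    return {"paralog_sets": results, "mismatches": mismatches,
            "accuracy": 1.0 - len(mismatches) / max(len(truth.gene_origins), 1),
            "table": table}


def chip_peak_recovery(sim: GenomeSimulation, tracks: TracksAndCounts,
                       window: int = 1000, peak_fold: float = 4.0) -> dict:
    """Locate the ChIP enrichment peak and measure its overlap with the
    planted centromere interval (fraction of the truth interval covered)."""
    track, peak = chip_enrichment(tracks.chip_ip, tracks.chip_input,
                                  window=window, peak_fold=peak_fold)
    cs, ce = sim.truth.centromere_interval
    overlap = 0.0
    if peak is not None:
        ov = max(0, min(peak[1], ce) - max(peak[0], cs))
        overlap = ov / (ce - cs)
    return {"track": track, "peak": peak, "truth": (cs, ce), "overlap": overlap}


def coverage_ratio_check(sim: GenomeSimulation, tracks: TracksAndCounts) -> dict:
    """Per-sex relative depth of X/Y/autosomes vs the expected pattern."""
    chrom_class = {c: ("X" if c == "chrX" else "Y" if c == "chrY" else "autosome")
                   for c in sim.sequences}
    out = {}
    for sex in ("male", "female"):
        ratios = dosage.coverage_ratio(tracks.depth[sex], chrom_class)
        out[sex] = {k: float(v) for k, v in ratios.items()}
    return out


def expression_bias_check(sim: GenomeSimulation, tracks: TracksAndCounts,
                          group_b: str = "liver") -> dict:
    """Autosome-anchored TMM + testis log2FC per gene class."""
    counts = tracks.counts
    auto = (tracks.gene_meta["compartment"] == "autosome").to_numpy()
    factors = dosage.tmm_factors_autosomal(counts, auto)
    lfc = dosage.y_log2fc(counts, factors, tracks.sample_groups,
                          "testis", group_b, auto)
    y_mask = tracks.gene_meta["compartment"] == "Y"
    tests = dosage.class_bias_tests(
        lfc[y_mask.to_numpy()],
        tracks.gene_meta.loc[y_mask, "expr_class"].to_dict())
    return {"factors": factors, "log2fc": lfc, "class_tests": tests}


def mean_pairwise_difference(seq_a: str, seq_b: str) -> float:
    """Raw per-site mismatch fraction between equal-length sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    a = np.frombuffer(seq_a.encode(), np.uint8)
    b = np.frombuffer(seq_b.encode(), np.uint8)
    return float(np.mean(a != b))


def stratum_raw_divergence(sim: GenomeSimulation) -> dict[int, float]:
    """Mean raw gametolog CDS difference per stratum (direct counting)."""
    pairs = gametolog_cds_pairs(sim)
    strata_iv = sim.truth.strata_intervals["chrX"]
    sums: dict[int, list[float]] = {}
    for xid, (cx, cy) in pairs.items():
        g = sim.truth.genes[xid]
        stratum = next(s for a, b, s in strata_iv if a <= g.start < b)
        sums.setdefault(stratum, []).append(mean_pairwise_difference(cx, cy))
    return {s: float(np.mean(v)) for s, v in sorted(sums.items())}
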