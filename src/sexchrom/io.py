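"""Small readers/writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython; BED is 0-based half-open; GFF is written
1-based inclusive.  Coverage and count tables are plain TSV handled with
pandas.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(seqs: Mapping[str, str], path, width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(intervals: Iterable[tuple], path) -> None:
    """Rows of (chrom, start, end[, name]) as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path) -> list[tuple]:
    rows = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                continue
            rows.append((f[0], int(f[1]), int(f[2]), *f[3:]))
    return rows


def write_gff(genes, path) -> None:
    """Write gene models (``GeneModel`` objects) as GFF3, 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write("\t".join(map(str, [
                g.chrom, "sexchrom", "gene", g.start + 1, g.end, ".", "+", ".",
                f"ID={g.gene_id};family={g.family}"])) + "\n")
            for i, (es, ee) in enumerate(g.exons, start=1):
                fh.write("\t".join(map(str, [
                    g.chrom, "sexchrom", "exon", es + 1, ee, ".", "+", ".",
                    f"ID={g.gene_id}.e{i};Parent={g.gene_id}"])) + "\n")


def write_coverage(depth_by_chrom: Mapping[str, "list | object"], path) -> None:
    """Per-base coverage as TSV of (chrom, pos0, depth)."""
    with open(path, "w") as fh:
        for chrom, depth in depth_by_chrom.items():
            for pos, d in enumerate(depth):
                fh.write(f"{chrom}\t{pos}\t{int(d)}\n")


def read_coverage(path) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "depth"])
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        out[chrom] = sub["depth"].to_list()
    return out
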