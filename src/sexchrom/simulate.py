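"""Synthetic diploid genome generator with known truth.

Emulates the structure of a fish sex-chromosome system at desk scale: a
handful of autosomes, an X, and a Y derived from the X through three
evolutionary strata of decreasing divergence plus an identical
pseudoautosomal region (PAR).  The Y additionally carries gene losses,
within-Y duplications, DNA-based translocations from the autosomes (introns
retained), an elevated density of transposable elements, and a tandem
centromeric monomer array organized like an alpha-satellite.  Downstream
fixtures — a gapped scaffold, BAC-sized inserts of four truth classes,
ChIP IP/input coverage with a centromeric peak, sex-specific read-depth
tracks, and tissue count matrices with a testis-biased class — are all
derived from the same truth so every pipeline stage can be scored.

All coordinates are 0-based half-open.  Identical seeds give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import seq_to_array

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# transition partner (A<->G, C<->T) and the two transversion choices per base
_TS = {65: 71, 71: 65, 67: 84, 84: 67}
_TV = {65: (67, 84), 71: (67, 84), 67: (65, 71), 84: (65, 71)}
_TS_MAP = np.zeros(256, dtype=np.uint8)
_TV1_MAP = np.zeros(256, dtype=np.uint8)
_TV2_MAP = np.zeros(256, dtype=np.uint8)
for b, t in _TS.items():
    _TS_MAP[b] = t
for b, (v1, v2) in _TV.items():
    _TV1_MAP[b] = v1
    _TV2_MAP[b] = v2

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = ["".join((a, b, c)) for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE_CODONS = [c for c in _CODONS if c not in _STOPS]


def random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply per-site substitutions with a 2:1 transition bias."""
    if rate <= 0:
        return seq
    arr = seq_to_array(seq).copy()
    pos = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(pos) == 0:
        return seq
    r = rng.random(len(pos))
    cur = arr[pos]
    out = np.where(r < 0.5, _TS_MAP[cur], np.where(r < 0.75, _TV1_MAP[cur], _TV2_MAP[cur]))
    arr[pos] = out
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Configuration and truth
# ---------------------------------------------------------------------------

_RATE_FIELDS = (
    "strata_divergence", "loss_fractions", "translocation_divergence",
    "duplication_divergence", "te_density_y", "te_density_auto",
    "te_density_par", "te_divergence", "monomer_mutation_rate",
    "discordant_bac_fraction", "reference_divergence",
)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome.

    Per-stratum divergences default to the observed gametolog divergence
    levels of the three strata (0.15 / 0.04 / 0.03 per site), loss fractions
    to the observed per-stratum gene-loss proportions, and gene counts per
    stratum to the observed relative stratum sizes, scaled to desk scale.
    """

    seed: int = 0
    n_autosomes: int = 3
    autosome_len: int = 150_000
    x_len: int = 220_000
    par_len: int = 20_000
    strata_fractions: tuple[float, float, float] = (0.40, 0.35, 0.25)
    strata_divergence: tuple[float, float, float] = (0.15, 0.04, 0.03)
    loss_fractions: tuple[float, float, float] = (0.82, 0.24, 0.31)
    genes_per_stratum: tuple[int, int, int] = (62, 24, 34)
    genes_per_autosome: int = 20
    cds_codons: int = 200
    n_introns: int = 2
    intron_len: int = 90
    n_translocations: int = 6
    n_translocation_duplicated: int = 4
    n_duplications: int = 5
    n_unknown_genes: int = 4
    n_unknown_duplicated: int = 1
    translocation_divergence: float = 0.02
    duplication_divergence: float = 0.01
    te_density_y: float = 0.12
    te_density_auto: float = 0.03
    te_density_par: float = 0.05
    te_len: int = 500
    te_divergence: float = 0.05
    monomer_len: int = 187
    n_monomers: int = 60
    monomer_mutation_rate: float = 0.10
    reference_divergence: float = 0.005
    n_gaps: int = 6
    gap_hidden_range: tuple[int, int] = (2500, 4000)
    gap_n_len: int = 300
    n_bacs: int = 20
    bac_len_mean: int = 8000
    bac_len_sd: int = 1000
    discordant_bac_fraction: float = 0.10
    read_depth_mean: float = 20.0
    chip_enrichment_fold: float = 8.0
    testis_bias_fold: float = 8.0
    counts_dispersion: float = 0.3

    def validate(self) -> None:
        if abs(sum(self.strata_fractions) - 1.0) > 1e-9:
            raise ValueError("strata_fractions must sum to 1")
        if not self.par_len < self.x_len:
            raise ValueError("par_len must be smaller than x_len")
        for name in _RATE_FIELDS:
            value = getattr(self, name)
            vals = value if isinstance(value, tuple) else (value,)
            for v in vals:
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name} must be within [0, 1], got {v}")
        if self.counts_dispersion < 0:
            raise ValueError("counts_dispersion must be nonnegative")
        for name in ("n_autosomes", "autosome_len", "x_len", "monomer_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GeneModel:
    gene_id: str
    family: str
    chrom: str
    start: int
    end: int
    exons: list[tuple[int, int]]

    def cds(self, seq: str) -> str:
        return "".join(seq[s:e] for s, e in self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1


@dataclass
class TruthSet:
    """Ground truth of the simulated genome; everything downstream is scored
    against these tables.  Intervals are 0-based half-open."""

    contig_labels: dict[str, str] = field(default_factory=dict)
    contig_expected: dict[str, str] = field(default_factory=dict)
    strata_intervals: dict[str, list[tuple[int, int, int]]] = field(default_factory=dict)
    gene_origins: dict[str, dict] = field(default_factory=dict)
    gametologs: dict[str, str | None] = field(default_factory=dict)
    te_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    centromere_interval: tuple[int, int] | None = None
    bac_truth: dict[str, dict] = field(default_factory=dict)
    depth_truth: dict[str, dict[str, float]] = field(default_factory=dict)
    gaps: list[dict] = field(default_factory=list)
    genes: dict[str, GeneModel] = field(default_factory=dict)
    monomer_consensus: str = ""

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["genes"] = {k: dataclasses.asdict(v) for k, v in self.genes.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            payload = json.load(fh)
        payload["genes"] = {
            k: GeneModel(**{**v, "exons": [tuple(e) for e in v["exons"]]})
            for k, v in payload["genes"].items()}
        payload["centromere_interval"] = (
            tuple(payload["centromere_interval"])
            if payload["centromere_interval"] else None)
        payload["strata_intervals"] = {
            c: [tuple(iv) for iv in ivs]
            for c, ivs in payload["strata_intervals"].items()}
        payload["te_intervals"] = {
            c: [tuple(iv) for iv in ivs] for c, ivs in payload["te_intervals"].items()}
        return cls(**payload)


@dataclass
class GenomeSimulation:
    config: SimulationConfig
    sequences: dict[str, str]
    reference: dict[str, str]
    contigs: dict[str, str]
    scaffold: str
    truth: TruthSet


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def _make_gene(rng, gene_id, family, chrom, cds_codons, n_introns, intron_len):
    """An intact ORF (ATG ... TAA, no internal stops) split across introns.

    Lengths are jittered per gene (CDS +/- 30%, introns +/- 33%) so that
    no two genes share a length; size-quantized indels would otherwise
    make unrelated regions fall on recurring alignment diagonals.
    """
    cds_codons = int(rng.integers(int(cds_codons * 0.7), int(cds_codons * 1.3) + 1))
    body = rng.choice(len(_SENSE_CODONS), size=cds_codons - 2)
    cds = "ATG" + "".join(_SENSE_CODONS[i] for i in body) + "TAA"
    cds_len = len(cds)
    cuts = sorted(rng.choice(np.arange(30, cds_len - 30), size=n_introns, replace=False)) \
        if n_introns else []
    pieces, prev = [], 0
    for c in cuts:
        pieces.append(cds[prev:c])
        prev = c
    pieces.append(cds[prev:])
    seq_parts, exons, pos = [], [], 0
    for i, piece in enumerate(pieces):
        if i:
            ilen = int(rng.integers(int(intron_len * 2 / 3), int(intron_len * 4 / 3) + 1))
            seq_parts.append(random_seq(rng, ilen))
            pos += ilen
        seq_parts.append(piece)
        exons.append((pos, pos + len(piece)))
        pos += len(piece)
    seq = "".join(seq_parts)
    model = GeneModel(gene_id, family, chrom, 0, len(seq), exons)
    return model, seq


def _place_region(rng, region_len, genes):
    """Lay genes with random intergenic spacers across a region.

    ``genes`` is a list of (model, seq); returns (sequence, placed models)
    with model coordinates relative to the region start.
    """
    total_gene = sum(len(s) for _, s in genes)
    slack = region_len - total_gene
    if slack < (len(genes) + 1) * 20:
        raise ValueError("region too small for requested genes")
    cuts = np.sort(rng.random(len(genes) + 1))
    spacers = np.maximum((cuts / cuts.sum() * slack).astype(int), 20)
    parts, placed, pos = [], [], 0
    for (model, seq), spacer in zip(genes, spacers):
        parts.append(random_seq(rng, int(spacer)))
        pos += int(spacer)
        model = dataclasses.replace(
            model, start=pos, end=pos + len(seq),
            exons=[(pos + s, pos + e) for s, e in model.exons])
        parts.append(seq)
        placed.append(model)
        pos += len(seq)
    if region_len - pos > 0:
        parts.append(random_seq(rng, region_len - pos))
    return "".join(parts)[:region_len], placed


def _scatter_tes(rng, seq, occupied, density, te_consensus, te_divergence, offset=0):
    """Overwrite intergenic slots with diverged TE copies; returns new seq and
    the TE intervals (in region coordinates)."""
    te_len = len(te_consensus)
    n_copies = int(round(density * len(seq) / te_len))
    free = _free_intervals(len(seq), occupied, te_len + 10)
    arr = bytearray(seq.encode())
    placed = []
    attempts = 0
    while n_copies > 0 and free and attempts < 500:
        attempts += 1
        idx = int(rng.integers(len(free)))
        s, e = free[idx]
        start = int(rng.integers(s, e - te_len + 1))
        copy = mutate(te_consensus, te_divergence, rng)
        arr[start:start + te_len] = copy.encode()
        placed.append((start, start + te_len))
        # split the free interval
        free.pop(idx)
        if start - s >= te_len + 10:
            free.append((s, start))
        if e - (start + te_len) >= te_len + 10:
            free.append((start + te_len, e))
        n_copies -= 1
    placed.sort()
    return arr.decode(), placed


def _free_intervals(length, occupied, min_len):
    occ = sorted(occupied)
    free, pos = [], 0
    for s, e in occ:
        if s - pos >= min_len:
            free.append((pos, s))
        pos = max(pos, e)
    if length - pos >= min_len:
        free.append((pos, length))
    return free


def simulate_genome(config: SimulationConfig):
    """Build the diploid genome and its truth tables.

    Returns ``(GenomeSimulation, TruthSet)`` (the truth is also attached to
    the simulation object).  The Y is derived from the X by applying the
    three per-stratum substitution rates outside the PAR, deleting lost
    gametologs, inserting TEs, translocated autosomal genes (introns
    retained), within-Y duplicates, de novo genes of unknown origin, and a
    tandem centromeric monomer array.  The PAR is copied identically.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = TruthSet()
    sequences: dict[str, str] = {}
    te_consensus = random_seq(rng, config.te_len)

    # --- autosomes -------------------------------------------------------
    auto_genes: list[GeneModel] = []
    for a in range(1, config.n_autosomes + 1):
        chrom = f"chrA{a}"
        genes = [
            _make_gene(rng, f"gA{a}_{j:03d}", f"gA{a}_{j:03d}", chrom,
                       config.cds_codons, config.n_introns, config.intron_len)
            for j in range(config.genes_per_autosome)]
        seq, placed = _place_region(rng, config.autosome_len, genes)
        seq, tes = _scatter_tes(
            rng, seq, [(g.start, g.end) for g in placed],
            config.te_density_auto, te_consensus, config.te_divergence)
        sequences[chrom] = seq
        truth.te_intervals[chrom] = tes
        for g in placed:
            truth.genes[g.gene_id] = g
            auto_genes.append(g)

    # --- X chromosome ----------------------------------------------------
    non_par = config.x_len - config.par_len
    stratum_lens = [int(round(f * non_par)) for f in config.strata_fractions]
    stratum_lens[-1] = non_par - sum(stratum_lens[:-1])
    par_seq = random_seq(rng, config.par_len)
    x_parts = [par_seq]
    x_strata = [(0, config.par_len, 0)]
    x_genes_by_stratum: list[list[GeneModel]] = []
    offset = config.par_len
    for s in range(3):
        genes = [
            _make_gene(rng, f"gX_s{s + 1}_{j:03d}", f"gX_s{s + 1}_{j:03d}", "chrX",
                       config.cds_codons, config.n_introns, config.intron_len)
            for j in range(config.genes_per_stratum[s])]
        seq, placed = _place_region(rng, stratum_lens[s], genes)
        seq, tes = _scatter_tes(
            rng, seq, [(g.start, g.end) for g in placed],
            config.te_density_auto, te_consensus, config.te_divergence)
        placed = [dataclasses.replace(
            g, start=g.start + offset, end=g.end + offset,
            exons=[(a + offset, b + offset) for a, b in g.exons]) for g in placed]
        truth.te_intervals.setdefault("chrX", []).extend(
            (a + offset, b + offset) for a, b in tes)
        x_parts.append(seq)
        x_strata.append((offset, offset + stratum_lens[s], s + 1))
        x_genes_by_stratum.append(placed)
        for g in placed:
            truth.genes[g.gene_id] = g
        offset += stratum_lens[s]
    # PAR TEs
    par_with_te, par_tes = _scatter_tes(
        rng, par_seq, [], config.te_density_par, te_consensus, config.te_divergence)
    x_parts[0] = par_with_te
    truth.te_intervals["chrX"] = sorted(par_tes + truth.te_intervals.get("chrX", []))
    x_seq = "".join(x_parts)
    sequences["chrX"] = x_seq
    truth.strata_intervals["chrX"] = x_strata

    # --- choose Y events -------------------------------------------------
    lost: set[str] = set()
    retained_by_stratum: list[list[GeneModel]] = []
    for s in range(3):
        genes = x_genes_by_stratum[s]
        n_lost = int(round(config.loss_fractions[s] * len(genes)))
        lost_ids = rng.choice([g.gene_id for g in genes], size=n_lost, replace=False)
        lost.update(lost_ids)
        retained_by_stratum.append([g for g in genes if g.gene_id not in lost_ids])
    for s, genes in enumerate(x_genes_by_stratum):
        for g in genes:
            truth.gametologs[g.gene_id] = None if g.gene_id in lost else g.gene_id + "_Y"

    # --- Y backbone per stratum -----------------------------------------
    monomer = random_seq(rng, config.monomer_len)
    truth.monomer_consensus = monomer
    y_strata_chunks: list[list[tuple]] = []
    mutated_gene_seq: dict[str, str] = {}
    for s in range(3):
        region_start, region_end, _ = x_strata[s + 1]
        rate = config.strata_divergence[s]
        features: list[tuple] = [("gene", g) for g in x_genes_by_stratum[s]]
        features += [("te", iv) for iv in truth.te_intervals.get("chrX", [])
                     if region_start <= iv[0] and iv[1] <= region_end]
        features.sort(key=lambda f: f[1].start if f[0] == "gene" else f[1][0])
        chunks: list[tuple] = []
        pos = region_start
        for kind, obj in features:
            fs, fe = (obj.start, obj.end) if kind == "gene" else obj
            if fs > pos:
                chunks.append(("seq", mutate(x_seq[pos:fs], rate, rng)))
            if kind == "gene":
                if obj.gene_id in lost:
                    pass  # deleted from the Y
                else:
                    gseq = mutate(x_seq[fs:fe], rate, rng)
                    mutated_gene_seq[obj.gene_id] = gseq
                    chunks.append(("gene", obj, gseq))
            else:
                chunks.append(("te", mutate(x_seq[fs:fe], rate, rng)))
            pos = fe
        if region_end > pos:
            chunks.append(("seq", mutate(x_seq[pos:region_end], rate, rng)))
        y_strata_chunks.append(chunks)

    # --- insertion items -------------------------------------------------
    insertions: list[list[tuple]] = [[], [], []]

    def _queue(stratum, kind, model, seq):
        insertions[stratum].append((kind, model, seq))

    # within-Y duplications of retained gametologs
    retained_all = [g for genes in retained_by_stratum for g in genes]
    dup_sources = list(rng.choice(
        [g.gene_id for g in retained_all],
        size=min(config.n_duplications, len(retained_all)), replace=False))
    for gid in dup_sources:
        src = truth.genes[gid]
        seq = mutate(mutated_gene_seq[gid], config.duplication_divergence, rng)
        model = GeneModel(gid + "_Yd", gid, "chrY", 0, len(seq),
                          [(a - src.start, b - src.start) for a, b in src.exons])
        _queue(int(rng.integers(3)), "gene", model, seq)
    # autosomal translocations (DNA-based: introns retained)
    trans_sources = list(rng.choice(
        [g.gene_id for g in auto_genes],
        size=min(config.n_translocations, len(auto_genes)), replace=False))
    trans_dup = set(trans_sources[:config.n_translocation_duplicated])
    for gid in trans_sources:
        src = truth.genes[gid]
        src_seq = sequences[src.chrom][src.start:src.end]
        n_copies = 2 if gid in trans_dup else 1
        for c in range(n_copies):
            seq = mutate(src_seq, config.translocation_divergence, rng)
            model = GeneModel(f"{gid}_Yt{c + 1}", gid, "chrY", 0, len(seq),
                              [(a - src.start, b - src.start) for a, b in src.exons])
            _queue(int(rng.integers(3)), "gene", model, seq)
    # genes of unknown origin
    for j in range(config.n_unknown_genes):
        model, seq = _make_gene(rng, f"gU{j:02d}_Y1", f"gU{j:02d}", "chrY",
                                config.cds_codons, config.n_introns, config.intron_len)
        _queue(int(rng.integers(3)), "gene", model, seq)
        if j < config.n_unknown_duplicated:
            seq2 = mutate(seq, config.duplication_divergence, rng)
            model2 = dataclasses.replace(model, gene_id=f"gU{j:02d}_Y2")
            _queue(int(rng.integers(3)), "gene", model2, seq2)
    # extra Y TEs to reach the elevated density
    backbone_len = sum(
        len(c[-1]) if c[0] != "gene" else len(c[2])
        for chunks in y_strata_chunks for c in chunks)
    n_extra_te = max(0, int(round(
        (config.te_density_y - config.te_density_auto) * backbone_len / config.te_len)))
    for _ in range(n_extra_te):
        _queue(int(rng.integers(3)), "te", None,
               mutate(te_consensus, config.te_divergence, rng))
    # centromeric array in stratum two
    if config.n_monomers > 0:
        array = "".join(
            mutate(monomer, config.monomer_mutation_rate, rng)
            for _ in range(config.n_monomers))
        insertions[1].append(("centromere", None, array))

    # --- assemble the Y --------------------------------------------------
    y_parts = [x_seq[:config.par_len]]  # PAR identical between X and Y
    y_offset = config.par_len
    y_strata = [(0, config.par_len, 0)]
    y_tes: list[tuple[int, int]] = []
    y_genes: list[GeneModel] = []
    centromere = None
    for s in range(3):
        chunks = list(y_strata_chunks[s])
        ins = insertions[s]
        if ins:
            # insertion points between chunks, never inside a gene
            slots = sorted(rng.integers(0, len(chunks) + 1, size=len(ins)))[::-1]
            for slot, item in zip(slots, sorted(ins, key=lambda i: str(i[1] and i[1].gene_id))):
                chunks.insert(int(slot), item)
        stratum_start = y_offset
        for chunk in chunks:
            kind = chunk[0]
            if kind == "seq":
                y_parts.append(chunk[1])
                y_offset += len(chunk[1])
            elif kind == "te":
                seq = chunk[-1]
                y_tes.append((y_offset, y_offset + len(seq)))
                y_parts.append(seq)
                y_offset += len(seq)
            elif kind == "centromere":
                seq = chunk[2]
                centromere = (y_offset, y_offset + len(seq))
                y_parts.append(seq)
                y_offset += len(seq)
            else:  # gene
                _, model, seq = chunk
                if model.chrom == "chrY":  # inserted copy with relative exons
                    placed = dataclasses.replace(
                        model, start=y_offset, end=y_offset + len(seq),
                        exons=[(a + y_offset, b + y_offset) for a, b in model.exons])
                else:  # retained gametolog: exon layout mirrors the X gene
                    placed = GeneModel(
                        model.gene_id + "_Y", model.gene_id, "chrY",
                        y_offset, y_offset + len(seq),
                        [(a - model.start + y_offset, b - model.start + y_offset)
                         for a, b in model.exons])
                y_genes.append(placed)
                truth.genes[placed.gene_id] = placed
                y_parts.append(seq)
                y_offset += len(seq)
        y_strata.append((stratum_start, y_offset, s + 1))
    y_seq = "".join(y_parts)
    sequences["chrY"] = y_seq
    truth.strata_intervals["chrY"] = y_strata
    truth.te_intervals["chrY"] = sorted(y_tes)
    truth.centromere_interval = centromere

    # --- Table-2 style origin truth --------------------------------------
    families: dict[str, list[GeneModel]] = {}
    for g in y_genes:
        families.setdefault(g.family, []).append(g)
    y_strata_iv = truth.strata_intervals["chrY"]
    for family, copies in families.items():
        first = min(copies, key=lambda g: g.start)
        stratum = next(idx for a, b, idx in y_strata_iv if a <= first.start < b)
        if family.startswith("gX"):
            origin = "x_ancestral"
        elif family.startswith("gA"):
            origin = "autosomal"
        else:
            origin = "unknown"
        # a retained gametolog plus a _Yd copy counts as duplicated
        copy_class = "duplicated" if len(copies) > 1 else "single"
        truth.gene_origins[family] = {
            "origin": origin, "copy_class": copy_class, "stratum": stratum,
            "copies": sorted(g.gene_id for g in copies)}

    truth.depth_truth = {
        "male": {"autosome": 1.0, "X": 0.5, "Y": 0.5},
        "female": {"autosome": 1.0, "X": 1.0, "Y": 0.0},
    }

    # --- reference genome (diverged female assembly) ----------------------
    reference = {"refX": mutate(x_seq, config.reference_divergence, rng)}
    for a in range(1, config.n_autosomes + 1):
        reference[f"refA{a}"] = mutate(
            sequences[f"chrA{a}"], config.reference_divergence, rng)

    # --- scaffold with N-gaps + contigs ----------------------------------
    scaffold, gaps = _build_scaffold(rng, y_seq, config, centromere)
    truth.gaps = gaps
    contigs = _split_contigs(rng, sequences, scaffold, config, truth)

    sim = GenomeSimulation(config=config, sequences=sequences, reference=reference,
                           contigs=contigs, scaffold=scaffold, truth=truth)
    return sim, truth


def _build_scaffold(rng, y_seq, config, centromere):
    """Mask hidden intervals of the Y with N-runs, recording both the
    scaffold-coordinate gap and the hidden source interval.

    Hidden intervals are spaced at least 8 kb apart so that a BAC-sized
    insert never straddles two of them, and the centromeric array stays
    intact.  One gap sits at the PAR boundary so the PAR forms its own
    contig, mirroring an assembly that did not target the PAR into the Y."""
    if config.n_gaps == 0:
        return y_seq, []
    hidden: list[tuple[int, int]] = [(config.par_len, config.par_len + 2500)]
    lo, hi = config.gap_hidden_range
    spacing = max(12_000, config.bac_len_mean + 4000)
    tries = 0
    while len(hidden) < config.n_gaps and tries < 1000:
        tries += 1
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(config.par_len + spacing,
                                 len(y_seq) - length - spacing))
        iv = (start, start + length)
        ok = all(iv[1] + spacing < s or e + spacing < iv[0] for s, e in hidden)
        if ok and centromere is not None:
            cs, ce = centromere
            ok = iv[1] + 2000 < cs or ce + 2000 < iv[0]
        if ok:
            hidden.append(iv)
    hidden.sort()
    parts, gaps, pos, out_pos = [], [], 0, 0
    for i, (s, e) in enumerate(hidden):
        parts.append(y_seq[pos:s])
        out_pos += s - pos
        parts.append("N" * config.gap_n_len)
        gaps.append({"gap_id": f"gap{i:02d}", "scaffold_id": "scaffoldY",
                     "start": out_pos, "end": out_pos + config.gap_n_len,
                     "hidden_start": s, "hidden_end": e})
        out_pos += config.gap_n_len
        pos = e
    parts.append(y_seq[pos:])
    return "".join(parts), gaps


def _split_contigs(rng, sequences, scaffold, config, truth):
    contigs: dict[str, str] = {}

    def _chop(seq, chrom, n_pieces, label, expected):
        bounds = [0] + sorted(
            int(b) for b in rng.integers(10_000, len(seq) - 10_000, size=n_pieces - 1)
        ) + [len(seq)]
        for i in range(len(bounds) - 1):
            s, e = bounds[i], bounds[i + 1]
            if e - s < 1000:
                continue
            cid = f"ctg_{chrom}_{i:02d}"
            contigs[cid] = seq[s:e]
            truth.contig_labels[cid] = label
            truth.contig_expected[cid] = expected

    for a in range(1, config.n_autosomes + 1):
        _chop(sequences[f"chrA{a}"], f"chrA{a}", 4, "autosome", "autosome")
    _chop(sequences["chrX"], "chrX", 6, "X", "x")
    # Y contigs follow the scaffold's non-N runs; the PAR piece is expected
    # to classify as X-linked (it is sequence-identical to the X)
    runs, pos = [], 0
    arr = np.frombuffer(scaffold.encode(), dtype=np.uint8)
    is_n = arr == ord("N")
    boundaries = np.flatnonzero(np.diff(is_n.astype(np.int8)) != 0) + 1
    edges = [0] + boundaries.tolist() + [len(scaffold)]
    idx = 0
    for i in range(len(edges) - 1):
        s, e = edges[i], edges[i + 1]
        if is_n[s]:
            continue
        if e - s < 1000:
            continue
        cid = f"ctg_chrY_{idx:02d}"
        contigs[cid] = scaffold[s:e]
        truth.contig_labels[cid] = "Y"
        par_overlap = max(0, min(e, config.par_len) - s)
        truth.contig_expected[cid] = "x" if par_overlap > 0.5 * (e - s) else "y"
        idx += 1
    return contigs


# ---------------------------------------------------------------------------
# BACs
# ---------------------------------------------------------------------------

def simulate_bacs(sim: GenomeSimulation, config: SimulationConfig | None = None,
                  rng: np.random.Generator | None = None):
    """Cut BAC-sized inserts from the true Y sequence in four truth classes:
    fully within a contig, gap-spanning, gap-extending, and discordant (a
    planted inversion or deletion).  Updates ``sim.truth.bac_truth``."""
    config = config or sim.config
    rng = rng or np.random.default_rng(config.seed + 1)
    y_seq = sim.sequences["chrY"]
    gaps = sim.truth.gaps
    if config.bac_len_mean >= len(y_seq):
        raise ValueError("bac_len_mean exceeds chromosome length")
    bacs: dict[str, str] = {}
    n_disc = int(round(config.discordant_bac_fraction * config.n_bacs))
    n_rest = config.n_bacs - n_disc
    n_span = min(len(gaps), max(1, n_rest // 3)) if gaps else 0
    n_ext = min(len(gaps), max(1, n_rest // 5)) if gaps else 0
    n_within = n_rest - n_span - n_ext

    def _bac_len():
        return int(np.clip(rng.normal(config.bac_len_mean, config.bac_len_sd),
                           4000, config.bac_len_mean + 2000))

    def _contig_interval(length):
        """An interval of the Y clear of hidden gap intervals and of the
        centromeric array (whose repeats would leave BAC ends unanchored)."""
        cen = sim.truth.centromere_interval
        for _ in range(200):
            start = int(rng.integers(0, len(y_seq) - length))
            iv = (start, start + length)
            ok = all(g["hidden_end"] + 200 < iv[0] or iv[1] + 200 < g["hidden_start"]
                     for g in gaps)
            if ok and cen is not None:
                ok = iv[1] + 500 < cen[0] or cen[1] + 500 < iv[0]
            if ok:
                return iv
        raise RuntimeError("could not place BAC clear of gaps")

    idx = 0
    for _ in range(n_within):
        s, e = _contig_interval(_bac_len())
        bid = f"bac{idx:03d}"
        bacs[bid] = y_seq[s:e]
        sim.truth.bac_truth[bid] = {"class": "concordant", "gap_ids": [],
                                    "y_interval": (s, e)}
        idx += 1
    span_gaps = list(rng.choice(len(gaps), size=n_span, replace=False)) if n_span else []
    for gi in span_gaps:
        g = gaps[int(gi)]
        length = max(_bac_len(), g["hidden_end"] - g["hidden_start"] + 4000)
        margin = (length - (g["hidden_end"] - g["hidden_start"]))
        left = int(rng.integers(1500, min(max(1600, margin - 1500), 4000)))
        s = max(0, g["hidden_start"] - left)
        e = min(len(y_seq), s + length)
        bid = f"bac{idx:03d}"
        bacs[bid] = y_seq[s:e]
        sim.truth.bac_truth[bid] = {"class": "spans_gap", "gap_ids": [g["gap_id"]],
                                    "y_interval": (s, e)}
        idx += 1
    ext_choice = list(rng.choice(len(gaps), size=n_ext, replace=False)) if n_ext else []
    for g in (gaps[int(i)] for i in ext_choice):
        length = _bac_len()
        # overhang beyond the contig end must exceed the end tolerance
        # (otherwise the BAC is simply concordant) but stay short of the
        # hidden span (otherwise it would bridge the gap)
        hidden_len = g["hidden_end"] - g["hidden_start"]
        overhang = int(rng.integers(1200, max(1300, hidden_len - 800)))
        e = g["hidden_start"] + overhang
        s = max(0, e - length)
        bid = f"bac{idx:03d}"
        bacs[bid] = y_seq[s:e]
        sim.truth.bac_truth[bid] = {"class": "extends_into_gap",
                                    "gap_ids": [g["gap_id"]], "y_interval": (s, e)}
        idx += 1
    for d in range(n_disc):
        s, e = _contig_interval(_bac_len())
        seq = y_seq[s:e]
        mid = len(seq) // 2
        if d % 2 == 0:  # planted inversion
            from .align import revcomp
            seq = seq[:mid - 1000] + revcomp(seq[mid - 1000:mid + 1000]) + seq[mid + 1000:]
            reason = "inversion"
        else:  # planted deletion larger than the chaining indel tolerance
            seq = seq[:mid - 1000] + seq[mid + 1000:]
            reason = "deletion"
        bid = f"bac{idx:03d}"
        bacs[bid] = seq
        sim.truth.bac_truth[bid] = {"class": "discordant", "gap_ids": [],
                                    "y_interval": (s, e), "reason": reason}
        idx += 1
    return bacs, sim.truth


# ---------------------------------------------------------------------------
# Tracks and counts
# ---------------------------------------------------------------------------

@dataclass
class TracksAndCounts:
    chip_ip: np.ndarray
    chip_input: np.ndarray
    depth: dict[str, dict[str, np.ndarray]]  # sex -> chrom -> per-base depth
    counts: pd.DataFrame                     # genes x samples
    sample_groups: dict[str, str]
    gene_meta: pd.DataFrame                  # compartment + expression class


def simulate_tracks_and_counts(sim: GenomeSimulation,
                               config: SimulationConfig | None = None,
                               rng: np.random.Generator | None = None) -> TracksAndCounts:
    """ChIP IP/input coverage over the Y, male/female depth tracks, and a
    tissue count matrix with a testis-biased class of Y genes."""
    config = config or sim.config
    rng = rng or np.random.default_rng(config.seed + 2)
    truth = sim.truth
    if truth.centromere_interval is None:
        raise ValueError("centromere_interval undefined; simulate with n_monomers > 0")
    y_len = len(sim.sequences["chrY"])
    lam = config.read_depth_mean
    fold = np.ones(y_len)
    cs, ce = truth.centromere_interval
    fold[cs:ce] = config.chip_enrichment_fold
    chip_input = rng.poisson(lam, size=y_len).astype(float)
    chip_ip = rng.poisson(lam * fold).astype(float)

    depth: dict[str, dict[str, np.ndarray]] = {"male": {}, "female": {}}
    for chrom, seq in sim.sequences.items():
        if chrom == "chrX":
            m_f, f_f = 0.5, 1.0
        elif chrom == "chrY":
            m_f, f_f = 0.5, 0.0
        else:
            m_f, f_f = 1.0, 1.0
        depth["male"][chrom] = rng.poisson(lam * m_f, size=len(seq)).astype(float)
        depth["female"][chrom] = (
            rng.poisson(lam * f_f, size=len(seq)).astype(float)
            if f_f > 0 else np.zeros(len(seq)))

    # --- counts -----------------------------------------------------------
    tissues = [("testis", 6), ("liver", 6), ("brain", 3), ("larvae", 2)]
    samples, groups = [], {}
    for tissue, n in tissues:
        for i in range(1, n + 1):
            name = f"{tissue}_{i}"
            samples.append(name)
            groups[name] = tissue
    genes, compartment, expr_class = [], [], []
    for fam, info in truth.gene_origins.items():
        for gid in info["copies"]:
            genes.append(gid)
            compartment.append("Y")
            if info["origin"] == "x_ancestral" and info["copy_class"] == "single":
                expr_class.append("sex_ancestral_single")
            elif info["origin"] == "x_ancestral":
                expr_class.append("duplicated")
            elif info["origin"] == "autosomal":
                expr_class.append("translocated")
            else:
                expr_class.append("unknown")
    for gid, g in truth.genes.items():
        if g.chrom.startswith("chrA"):
            genes.append(gid)
            compartment.append("autosome")
            expr_class.append("autosomal_background")
    meta = pd.DataFrame({"compartment": compartment, "expr_class": expr_class},
                        index=pd.Index(genes, name="gene"))
    base = np.exp(rng.normal(np.log(100.0), 0.6, size=len(genes)))
    lib_factor = np.exp(rng.normal(0.0, 0.2, size=len(samples)))
    biased = meta["expr_class"].isin(["duplicated", "translocated"]).to_numpy()
    disp = config.counts_dispersion
    mat = np.zeros((len(genes), len(samples)), dtype=int)
    for j, sample in enumerate(samples):
        mu = base * lib_factor[j]
        if groups[sample] == "testis":
            mu = np.where(biased, mu * config.testis_bias_fold, mu)
        if disp > 0:
            n_param = 1.0 / disp
            p_param = n_param / (n_param + mu)
            mat[:, j] = rng.negative_binomial(n_param, p_param)
        else:
            mat[:, j] = rng.poisson(mu)
    counts = pd.DataFrame(mat, index=meta.index, columns=samples)
    return TracksAndCounts(chip_ip=chip_ip, chip_input=chip_input, depth=depth,
                           counts=counts, sample_groups=groups, gene_meta=meta)


# ---------------------------------------------------------------------------
# Output writing
# ---------------------------------------------------------------------------

def write_outputs(sim: GenomeSimulation, outdir,
                  bacs: dict[str, str] | None = None,
                  tracks: TracksAndCounts | None = None) -> None:
    """Dump FASTA/BED/GFF/TSV/JSON fixtures for the simulation."""
    import os

    from . import io as sio
    os.makedirs(outdir, exist_ok=True)
    p = lambda name: os.path.join(outdir, name)
    sio.write_fasta(sim.sequences, p("genome.fa"))
    sio.write_fasta(sim.reference, p("reference.fa"))
    sio.write_fasta(sim.contigs, p("contigs.fa"))
    sio.write_fasta({"scaffoldY": sim.scaffold}, p("scaffold.fa"))
    truth = sim.truth
    sio.write_bed([(c, s, e) for c, ivs in truth.te_intervals.items()
                   for s, e in ivs], p("te.bed"))
    sio.write_bed([(c, s, e, f"stratum{idx}" if idx else "PAR")
                   for c, ivs in truth.strata_intervals.items()
                   for s, e, idx in ivs], p("strata.bed"))
    sio.write_bed([("scaffoldY", g["start"], g["end"], g["gap_id"])
                   for g in truth.gaps], p("gaps.bed"))
    if truth.centromere_interval:
        sio.write_bed([("chrY", *truth.centromere_interval, "centromere")],
                      p("centromere.bed"))
    sio.write_gff(sorted(truth.genes.values(), key=lambda g: (g.chrom, g.start)),
                  p("genes.gff"))
    truth.to_json(p("truth.json"))
    with open(p("config.json"), "w") as fh:
        json.dump(dataclasses.asdict(sim.config), fh, indent=1, sort_keys=True)
    if bacs is not None:
        sio.write_fasta(bacs, p("bacs.fa"))
    if tracks is not None:
        sio.write_coverage({"chrY_ip": tracks.chip_ip,
                            "chrY_input": tracks.chip_input}, p("chip.tsv"))
        tracks.counts.to_csv(p("counts.tsv"), sep="\t")
        pd.Series(tracks.sample_groups, name="tissue").rename_axis("sample") \
            .to_csv(p("samples.tsv"), sep="\t")


def gametolog_cds_pairs(sim: GenomeSimulation) -> dict[str, tuple[str, str]]:
    """X/Y CDS pairs for every retained gametolog, keyed by the X gene id."""
    pairs = {}
    for xid, yid in sim.truth.gametologs.items():
        if yid is None:
            continue
        xg = sim.truth.genes[xid]
        yg = sim.truth.genes[yid]
        pairs[xid] = (xg.cds(sim.sequences["chrX"]), yg.cds(sim.sequences["chrY"]))
    return pairs
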