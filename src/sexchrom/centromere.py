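"""Centromeric repeat detection and ChIP-based centromere localization.

The centromere of the assembled Y is found two ways that must agree: a
tandem array of an alpha-satellite-like monomer (~187 bp) detected against
a consensus, and a fold-enrichment peak of CENP-A ChIP reads over input.
Monomer hits are length-filtered (consensus length +/- a tolerance),
consensus sequences are rebuilt by per-column majority vote, and identity
summaries are computed over global pairwise alignments (gap columns count
as mismatches).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .align import anchor_align


@dataclass
class RepeatMonomer:
    start: int
    end: int
    strand: str
    identity: float
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


def find_monomers(target: str, consensus: str, len_tol: int = 10,
                  k: int = 8, min_identity: float = 0.6) -> list[RepeatMonomer]:
    """Monomer copies of ``consensus`` in ``target`` (both strands).

    Local gapless hits are kept when their length is within ``len_tol`` of
    the consensus length; overlapping hits resolve to the higher identity
    (then leftmost).  Truncated copies fall outside the length window and
    are excluded.
    """
    if len(consensus) < 50:
        raise ValueError("consensus must be at least 50 bp")
    if not target:
        return []
    blocks = anchor_align(consensus, target, k=k,
                          min_block=len(consensus) - len_tol,
                          mismatch_cost=2, query_id="consensus",
                          target_id="target")
    hits = []
    for b in blocks:
        if abs(b.align_len - len(consensus)) > len_tol:
            continue
        if b.identity < min_identity:
            continue
        hits.append(RepeatMonomer(b.target_start, b.target_end, b.strand,
                                  b.identity, target[b.target_start:b.target_end]))
    hits.sort(key=lambda m: (-m.identity, m.start))
    kept: list[RepeatMonomer] = []
    for m in hits:
        if all(m.end <= o.start or o.end <= m.start for o in kept):
            kept.append(m)
    kept.sort(key=lambda m: m.start)
    return kept


def majority_consensus(monomers: list[RepeatMonomer] | list[str]) -> str:
    """Per-column majority base over equal-length monomers (the modal
    length is used; off-length copies are dropped).  Ties break in the
    fixed base order A < C < G < T."""
    seqs = [m.sequence if isinstance(m, RepeatMonomer) else m for m in monomers]
    if len(seqs) < 1:
        raise ValueError("at least one monomer required")
    lengths = pd.Series([len(s) for s in seqs])
    modal = int(lengths.mode().iloc[0])
    seqs = [s for s in seqs if len(s) == modal]
    arr = np.array([list(s) for s in seqs])
    out = []
    for col in arr.T:
        bases, counts = np.unique(col, return_counts=True)
        order = np.lexsort((bases, -counts))  # max count, then A<C<G<T
        out.append(bases[order[0]])
    return "".join(out)


def _global_identity(a: str, b: str) -> float:
    """Needleman-Wunsch identity with internal gap columns as mismatches."""
    res = edlib.align(a, b, mode="NW", task="distance")
    align_cols = max(len(a), len(b))  # lower bound on columns; edit distance
    # counts each gap column once, so identity over max length is exact for
    # substitutions-plus-indels
    return 1.0 - res["editDistance"] / align_cols


def pairwise_identity(monomers_a, monomers_b=None) -> float:
    """Mean pairwise global identity: within one set (unordered pairs,
    no self-pairs) or across two sets (all cross pairs)."""
    seqs_a = [m.sequence if isinstance(m, RepeatMonomer) else m for m in monomers_a]
    if monomers_b is None:
        if len(seqs_a) < 2:
            raise ValueError("need at least two monomers")
        vals = [_global_identity(seqs_a[i], seqs_a[j])
                for i in range(len(seqs_a)) for j in range(i + 1, len(seqs_a))]
    else:
        seqs_b = [m.sequence if isinstance(m, RepeatMonomer) else m for m in monomers_b]
        if not seqs_a or not seqs_b:
            raise ValueError("need at least one monomer per set")
        vals = [_global_identity(a, b) for a in seqs_a for b in seqs_b]
    return float(np.mean(vals))


def windowed_identity_profile(region: str, consensus: str,
                              window: int = 100) -> pd.DataFrame:
    """Identity of each non-overlapping window against its best alignment
    to the consensus (infix mode); the series renders higher-order repeat
    structure as a heat strip.

    Windows are matched against the doubled consensus so that windows
    straddling a monomer junction (rotations of the consensus) still score
    as array sequence."""
    if len(region) < window:
        raise ValueError("region shorter than window")
    target = consensus * 2 if window <= len(consensus) else consensus * (
        2 * (window // len(consensus) + 1))
    rows = []
    for start in range(0, len(region) - window + 1, window):
        chunk = region[start:start + window]
        res = edlib.align(chunk, target, mode="HW", task="distance")
        rows.append({"start": start, "end": start + window,
                     "identity": 1.0 - res["editDistance"] / window})
    return pd.DataFrame(rows)


def chip_enrichment(ip: np.ndarray, input_: np.ndarray,
                    ip_libsize: float | None = None,
                    input_libsize: float | None = None,
                    window: int = 1000, peak_fold: float = 4.0):
    """Library-normalized IP/input fold enrichment in windows, plus the
    peak interval.

    Per-position fold is (ip/ip_libsize)/(input/input_libsize) with
    zero-input positions masked; windows average the per-position folds.
    The peak is the longest contiguous run of windows above ``peak_fold``
    times the track median (ties to the higher mean); None when no window
    clears the threshold.
    """
    ip = np.asarray(ip, float)
    input_ = np.asarray(input_, float)
    if ip.shape != input_.shape:
        raise ValueError("tracks must cover the same span")
    if not np.any(input_ > 0):
        raise ValueError("input track is all zero")
    ip_libsize = float(ip.sum()) if ip_libsize is None else float(ip_libsize)
    input_libsize = float(input_.sum()) if input_libsize is None else float(input_libsize)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = (ip / ip_libsize) / (input_ / input_libsize)
    fold[input_ == 0] = np.nan
    n_windows = len(fold) // window
    rows = []
    for w in range(n_windows):
        chunk = fold[w * window:(w + 1) * window]
        rows.append({"window_start": w * window,
                     "fold_enrichment": float(np.nanmean(chunk))})
    track = pd.DataFrame(rows)
    folds = track["fold_enrichment"].to_numpy()
    threshold = peak_fold * float(np.nanmedian(folds))
    above = folds > threshold
    peak = None
    best = (0, -np.inf)  # (run length, mean)
    i = 0
    while i < len(above):
        if not above[i]:
            i += 1
            continue
        j = i
        while j < len(above) and above[j]:
            j += 1
        run = (j - i, float(np.nanmean(folds[i:j])))
        if run > best:
            best = run
            peak = (i * window, j * window)
        i = j
    return track, peak


@dataclass
class DebrisPiece:
    parent_contig: str
    side: str  # "left" | "right"
    sequence: str


def rejoin_debris(scaffold: str, contig_intervals: dict[str, tuple[int, int]],
                  debris: list[DebrisPiece]):
    """Re-attach debris fragments to the recorded side of their parent
    contig (the side trimmed away during scaffold editing), growing the
    assembly by the debris length.  Returns ``(extended, liftover)``."""
    for piece in debris:
        if piece.parent_contig not in contig_intervals:
            raise KeyError(f"unknown parent contig {piece.parent_contig}")
        if piece.side not in ("left", "right"):
            raise ValueError(f"invalid side {piece.side!r}")
    edits = []
    for piece in debris:
        s, e = contig_intervals[piece.parent_contig]
        pos = s if piece.side == "left" else e
        edits.append((pos, piece.sequence))
    edits.sort(key=lambda x: -x[0])
    out = scaffold
    for pos, seq in edits:
        out = out[:pos] + seq + out[pos:]
    liftover = []
    shift = 0
    for pos, seq in sorted(edits):
        liftover.append((pos, shift))
        shift += len(seq)
    liftover.append((len(scaffold), shift))
    return out, liftover
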