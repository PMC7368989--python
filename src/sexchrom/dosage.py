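"""Dosage and expression-bias statistics for Y-linked genes.

Between-sample scaling uses trimmed-mean-of-M-values (TMM) factors
computed on autosomal transcripts only, so that a male-biased Y gene
complement cannot distort the normalization; Y genes are then scaled with
the autosomal factors.  Expression contrasts are pseudocounted log2 fold
changes between tissue groups, compared across gene-origin classes with
Mann-Whitney tests.  Haploinsufficiency-score contrasts and sex-specific
read-depth ratio checks round out the module.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .divergence import mann_whitney


def tmm_factors_autosomal(counts: pd.DataFrame, autosomal: Sequence[bool] | pd.Series,
                          logratio_trim: float = 0.3, sum_trim: float = 0.05,
                          weighting: bool = True) -> pd.Series:
    """TMM scaling factors computed on autosomal genes only.

    Follows the standard TMM recipe: the reference sample is the one whose
    upper-quartile (of counts scaled by library size) is closest to the
    mean upper quartile; per-sample factors are the weighted trimmed mean
    of the M-values (30% on M, 5% on A) against the reference, normalized
    so the factors have geometric mean one.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    auto = counts.loc[np.asarray(autosomal, bool)]
    auto = auto.loc[(auto.sum(axis=1) > 0)]
    lib = auto.sum(axis=0).astype(float)
    if (lib == 0).any():
        bad = lib.index[lib == 0].tolist()
        raise ValueError(f"samples with zero autosomal counts: {bad}")
    f75 = (auto / lib).quantile(0.75)
    ref = (f75 - f75.mean()).abs().idxmin()
    ref_counts = auto[ref].to_numpy(float)
    ref_lib = float(lib[ref])
    factors = {}
    for sample in auto.columns:
        obs = auto[sample].to_numpy(float)
        obs_lib = float(lib[sample])
        with np.errstate(divide="ignore", invalid="ignore"):
            logR = np.log2((obs / obs_lib) / (ref_counts / ref_lib))
            absE = 0.5 * np.log2((obs / obs_lib) * (ref_counts / ref_lib))
            v = ((obs_lib - obs) / (obs_lib * obs)
                 + (ref_lib - ref_counts) / (ref_lib * ref_counts))
        keep = np.isfinite(logR) & np.isfinite(absE)
        logR, absE, v = logR[keep], absE[keep], v[keep]
        n = len(logR)
        if n == 0:
            factors[sample] = 1.0
            continue
        lo_l = np.floor(n * logratio_trim) + 1
        hi_l = n + 1 - lo_l
        lo_s = np.floor(n * sum_trim) + 1
        hi_s = n + 1 - lo_s
        rank_l = pd.Series(logR).rank().to_numpy()
        rank_s = pd.Series(absE).rank().to_numpy()
        keep = (rank_l >= lo_l) & (rank_l <= hi_l) & (rank_s >= lo_s) & (rank_s <= hi_s)
        if not keep.any():
            factors[sample] = 1.0
            continue
        if weighting:
            f = np.sum(logR[keep] / v[keep]) / np.sum(1.0 / v[keep])
        else:
            f = np.mean(logR[keep])
        factors[sample] = 1.0 if not np.isfinite(f) or abs(f) < 1e-6 else 2.0 ** f
    out = pd.Series(factors, name="tmm_factor")
    return out / np.exp(np.mean(np.log(out)))


def normalized_cpm(counts: pd.DataFrame, factors: pd.Series,
                   autosomal: Sequence[bool] | pd.Series) -> pd.DataFrame:
    """Counts per million over effective (autosomal) library sizes."""
    lib = counts.loc[np.asarray(autosomal, bool)].sum(axis=0).astype(float)
    eff = lib * factors
    return counts / eff * 1e6


def y_log2fc(counts: pd.DataFrame, factors: pd.Series,
             sample_groups: Mapping[str, str], group_a: str, group_b: str,
             autosomal: Sequence[bool] | pd.Series,
             pseudocount: float = 0.5) -> pd.Series:
    """Per-gene log2 fold change of mean normalized expression, group_a
    over group_b, with a pseudocount on both means."""
    samples_a = [s for s in counts.columns if sample_groups.get(s) == group_a]
    samples_b = [s for s in counts.columns if sample_groups.get(s) == group_b]
    if not samples_a or not samples_b:
        raise ValueError(f"empty sample group among ({group_a!r}, {group_b!r})")
    cpm = normalized_cpm(counts, factors, autosomal)
    mean_a = cpm[samples_a].mean(axis=1)
    mean_b = cpm[samples_b].mean(axis=1)
    return np.log2((mean_a + pseudocount) / (mean_b + pseudocount)).rename(
        f"log2fc_{group_a}_vs_{group_b}")


def class_bias_tests(log2fc: pd.Series, gene_classes: Mapping[str, str],
                     reference_class: str = "sex_ancestral_single") -> pd.DataFrame:
    """Mann-Whitney comparison of each gene class's log2FC distribution
    against the reference class; medians reported per class."""
    cls = pd.Series({g: gene_classes.get(g) for g in log2fc.index})
    ref_vals = log2fc[cls == reference_class].dropna()
    rows = []
    for c in sorted(set(cls.dropna())):
        vals = log2fc[cls == c].dropna()
        row = {"gene_class": c, "n": len(vals), "median_log2fc": vals.median()}
        if c != reference_class and len(vals) >= 2 and len(ref_vals) >= 2:
            row["p_vs_reference"] = float(mann_whitney(vals, ref_vals).pvalue)
        else:
            row["p_vs_reference"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_class")


def haploinsufficiency_contrast(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum one-sided Mann-Whitney test of haploinsufficiency
    scores: retained-on-Y < lost-from-Y.

    ``scores`` needs columns gene, score, retained (bool), stratum.
    Strata with an empty group report NA.
    """
    rows = []
    for stratum, sub in scores.groupby("stratum"):
        kept = sub.loc[sub["retained"], "score"].dropna()
        lost = sub.loc[~sub["retained"], "score"].dropna()
        row = {"stratum": stratum, "n_retained": len(kept), "n_lost": len(lost),
               "median_retained": kept.median() if len(kept) else np.nan,
               "median_lost": lost.median() if len(lost) else np.nan}
        if len(kept) >= 1 and len(lost) >= 1:
            row["p_value"] = float(mann_whitney(kept, lost, alternative="less").pvalue)
        else:
            row["p_value"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("stratum")


def coverage_ratio(depth_by_chrom: Mapping[str, np.ndarray],
                   chrom_class: Mapping[str, str],
                   window: int = 1000) -> pd.Series:
    """Median relative read depth per chromosome class.

    Depth is summarized as the median of per-window medians; each
    chromosome class's value is divided by the autosomal one (expected
    0.5/0.5/1.0/0.0 for male X/Y and female X/Y).
    """
    window_medians: dict[str, list[float]] = {}
    for chrom, depth in depth_by_chrom.items():
        depth = np.asarray(depth, float)
        n = len(depth) // window
        meds = [float(np.median(depth[i * window:(i + 1) * window]))
                for i in range(max(n, 1))]
        window_medians.setdefault(chrom_class[chrom], []).extend(meds)
    if "autosome" not in window_medians:
        raise ValueError("no autosomal depth provided")
    auto_med = float(np.median(window_medians["autosome"]))
    if auto_med == 0:
        raise ValueError("autosomal median depth is zero")
    return pd.Series({cls: float(np.median(vals)) / auto_med
                      for cls, vals in window_medians.items()},
                     name="relative_depth")
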