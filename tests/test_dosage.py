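"""TMM normalization, expression bias, haploinsufficiency, coverage ratios."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from sexchrom.dosage import (class_bias_tests, coverage_ratio,
                             haploinsufficiency_contrast, normalized_cpm,
                             tmm_factors_autosomal, y_log2fc)


def _nb_counts(rng, n_genes, factors, dispersion=0.2, mean_log=np.log(80)):
    mu = np.exp(rng.normal(mean_log, 1.0, size=n_genes))
    mat = np.zeros((n_genes, len(factors)), int)
    for j, f in enumerate(factors):
        m = mu * f
        n = 1 / dispersion
        mat[:, j] = rng.negative_binomial(n, n / (n + m))
    return pd.DataFrame(mat, columns=[f"s{j}" for j in range(len(factors))])


def test_identical_samples_give_unit_factors():
    counts = pd.DataFrame({"a": [10, 20, 30, 5], "b": [10, 20, 30, 5]})
    f = tmm_factors_autosomal(counts, [True] * 4)
    assert np.allclose(f, 1.0)


def test_factors_recover_constructed_library_scaling(rng):
    counts = _nb_counts(rng, 400, [1.0, 1.0])
    doubled = counts.copy()
    doubled["s1"] = 2 * counts["s0"]
    doubled["s0"] = counts["s0"]
    f = tmm_factors_autosomal(doubled, [True] * 400)
    cpm = normalized_cpm(doubled, f, [True] * 400)
    # after normalization the two samples agree gene by gene
    assert np.allclose(cpm["s0"], cpm["s1"], rtol=1e-6)


def test_factor_geometric_mean_is_one(rng):
    counts = _nb_counts(rng, 300, [1.0, 1.7, 0.6, 1.2])
    f = tmm_factors_autosomal(counts, [True] * 300)
    assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)


def test_factors_invariant_to_gene_order(rng):
    counts = _nb_counts(rng, 300, [1.0, 1.5, 0.8])
    f1 = tmm_factors_autosomal(counts, [True] * 300)
    perm = rng.permutation(300)
    f2 = tmm_factors_autosomal(counts.iloc[perm], [True] * 300)
    assert np.allclose(f1, f2)


def test_tmm_matches_edger_oracle(rng, tmp_path):
    """Independent cross-check of the TMM recipe against edgeR."""
    counts = _nb_counts(rng, 300, [1.0, 2.0, 0.7, 1.3, 0.9, 1.1])
    path = tmp_path / "counts.tsv"
    counts.to_csv(path, sep="\t", index=False)
    script = tmp_path / "tmm.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(edgeR))
        x <- as.matrix(read.delim("{path}"))
        cat(sprintf("%.10f", calcNormFactors(x, method="TMM")), sep="\\n")
    """))
    out = subprocess.run(["Rscript", str(script)], capture_output=True,
                         text=True, check=True)
    edger = np.array([float(v) for v in out.stdout.split()])
    ours = tmm_factors_autosomal(counts, [True] * 300).to_numpy()
    assert np.allclose(ours, edger, atol=1e-8)


def test_zero_autosomal_counts_raise():
    counts = pd.DataFrame({"a": [0, 0], "b": [5, 5]})
    with pytest.raises(ValueError, match="zero autosomal"):
        tmm_factors_autosomal(counts, [True, True])


def _simple_setup(rng, bias=1.0):
    factors = [1.0] * 4
    counts = _nb_counts(rng, 200, factors)
    counts.columns = ["t1", "t2", "l1", "l2"]
    counts.loc[:19, ["t1", "t2"]] = (counts.loc[:19, ["t1", "t2"]] * bias).astype(int)
    groups = {"t1": "testis", "t2": "testis", "l1": "liver", "l2": "liver"}
    return counts, groups


def test_log2fc_zero_for_identical_groups(rng):
    counts = _nb_counts(rng, 100, [1.0, 1.0])
    counts.columns = ["a1", "b1"]
    counts["a1"] = counts["b1"]
    groups = {"a1": "A", "b1": "B"}
    f = tmm_factors_autosomal(counts, [True] * 100)
    lfc = y_log2fc(counts, f, groups, "A", "B", [True] * 100)
    assert np.allclose(lfc, 0.0)


def test_log2fc_antisymmetric_under_group_swap(rng):
    counts, groups = _simple_setup(rng, bias=4)
    f = tmm_factors_autosomal(counts, [True] * 200)
    ab = y_log2fc(counts, f, groups, "testis", "liver", [True] * 200)
    ba = y_log2fc(counts, f, groups, "liver", "testis", [True] * 200)
    assert np.allclose(ab, -ba)


def test_unknown_group_raises(rng):
    counts, groups = _simple_setup(rng)
    f = tmm_factors_autosomal(counts, [True] * 200)
    with pytest.raises(ValueError):
        y_log2fc(counts, f, groups, "testis", "kidney", [True] * 200)


def test_planted_testis_bias_recovered(sim, tracks):
    from sexchrom.pipeline import expression_bias_check
    res = expression_bias_check(sim, tracks)
    tests = res["class_tests"]
    # the duplicated and translocated classes carry a planted 8x testis bias
    for cls in ("duplicated", "translocated"):
        assert tests.loc[cls, "median_log2fc"] == pytest.approx(3.0, abs=1.0)
        assert tests.loc[cls, "p_vs_reference"] < 0.01
    assert abs(tests.loc["sex_ancestral_single", "median_log2fc"]) < 0.5


def test_haploinsufficiency_identical_distributions_not_significant(rng):
    scores = pd.DataFrame({
        "gene": [f"g{i}" for i in range(40)],
        "score": list(rng.normal(size=20)) * 2,
        "retained": [True] * 20 + [False] * 20,
        "stratum": 1})
    res = haploinsufficiency_contrast(scores)
    assert res.loc[1, "p_value"] >= 0.4


def test_haploinsufficiency_shift_detected_across_seeds():
    hits = 0
    n_seeds = 40
    for seed in range(n_seeds):
        r = np.random.default_rng(seed)
        scores = pd.DataFrame({
            "gene": [f"g{i}" for i in range(100)],
            "score": np.concatenate([r.normal(-1.0, 1.0, 50),
                                     r.normal(0.0, 1.0, 50)]),
            "retained": [True] * 50 + [False] * 50,
            "stratum": 1})
        if haploinsufficiency_contrast(scores).loc[1, "p_value"] < 0.01:
            hits += 1
    assert hits >= 0.95 * n_seeds


def test_haploinsufficiency_empty_group_reports_na():
    scores = pd.DataFrame({"gene": ["a", "b"], "score": [0.1, 0.2],
                           "retained": [True, True], "stratum": 2})
    assert np.isnan(haploinsufficiency_contrast(scores).loc[2, "p_value"])


def test_coverage_ratio_uniform_and_scaled():
    rng = np.random.default_rng(2)
    tracks = {"a1": rng.poisson(30, 20_000).astype(float),
              "x": rng.poisson(30, 20_000).astype(float)}
    classes = {"a1": "autosome", "x": "X"}
    r = coverage_ratio(tracks, classes)
    assert r["X"] == pytest.approx(1.0, abs=0.05)
    r2 = coverage_ratio({c: 5 * d for c, d in tracks.items()}, classes)
    assert r2["X"] == r["X"]  # scale invariance


def test_coverage_ratio_zero_autosomal_raises():
    with pytest.raises(ValueError):
        coverage_ratio({"a": np.zeros(2000)}, {"a": "autosome"})


def test_class_bias_reference_has_no_self_test(rng):
    vals = pd.Series(rng.normal(size=30), index=[f"g{i}" for i in range(30)])
    classes = {f"g{i}": ("sex_ancestral_single" if i < 20 else "duplicated")
               for i in range(30)}
    table = class_bias_tests(vals, classes)
    assert np.isnan(table.loc["sex_ancestral_single", "p_vs_reference"])
    assert not np.isnan(table.loc["duplicated", "p_vs_reference"])
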