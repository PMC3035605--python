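"""Normalization, allelic partition, zygotic fraction, F13 imputation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ezdc.containers import AllelicCounts, ExpressionData
from ezdc.partition import (
    impute_f13,
    male_x_paternal_violations,
    normalize_autosomal,
    partition_rpkm,
    zygotic_fraction,
)
from ezdc.simulate import SimConfig, simulate_timecourse


def _two_sample_expr(rpkm_rows):
    rpkm = pd.DataFrame(rpkm_rows, index=["g1", "g2"], columns=["s1", "s2"])
    genes = pd.DataFrame({"chrom": ["2L", "3R"], "length": [1000, 1000]}, index=rpkm.index)
    samples = pd.DataFrame(
        {"sex": ["F", "F"], "stage": ["C10", "C11"], "replicate": [1, 1]},
        index=rpkm.columns,
    )
    return ExpressionData(rpkm, genes, samples)


def test_normalization_equalizes_autosomal_totals():
    expr = _two_sample_expr([[60.0, 150.0], [40.0, 50.0]])  # totals 100 and 200
    out = normalize_autosomal(expr)
    totals = out.rpkm.sum(axis=0)
    assert np.allclose(totals, 150.0)  # mean of 100 and 200
    # scalars 1.5 and 0.75
    assert np.allclose(out.rpkm["s1"], [90.0, 60.0])


def test_normalization_is_identity_on_equal_totals():
    expr = _two_sample_expr([[60.0, 60.0], [40.0, 40.0]])
    out = normalize_autosomal(expr)
    pd.testing.assert_frame_equal(out.rpkm, expr.rpkm)


def test_normalization_rejects_zero_autosomal_sample():
    expr = _two_sample_expr([[60.0, 0.0], [40.0, 0.0]])
    with pytest.raises(ValueError, match="zero autosomal total"):
        normalize_autosomal(expr)


def test_x_genes_scaled_by_same_sample_scalar():
    rpkm = pd.DataFrame(
        [[60.0, 150.0], [40.0, 50.0], [10.0, 10.0]],
        index=["g1", "g2", "gx"], columns=["s1", "s2"],
    )
    genes = pd.DataFrame({"chrom": ["2L", "3R", "X"], "length": 1000}, index=rpkm.index)
    samples = pd.DataFrame(
        {"sex": ["F", "F"], "stage": ["C10", "C11"], "replicate": [1, 1]}, index=rpkm.columns
    )
    out = normalize_autosomal(ExpressionData(rpkm, genes, samples))
    assert np.isclose(out.rpkm.loc["gx", "s1"], 10.0 * 1.5)
    # X genes excluded from the totals being equalized
    assert np.allclose(out.rpkm.loc[["g1", "g2"]].sum(axis=0), 150.0)


def test_autosomal_totals_equal_after_normalizing_random_matrix(default_run):
    expr_n = default_run["expr_n"]
    auto = expr_n.genes["chrom"] != "X"
    totals = expr_n.rpkm.loc[auto].sum(axis=0)
    assert np.allclose(totals, totals.mean(), rtol=1e-9, atol=0)


# ---------------------------------------------------------------------------

def _counts(m_rows, p_rows, like):
    return AllelicCounts(
        maternal=pd.DataFrame(m_rows, index=like.rpkm.index, columns=like.rpkm.columns),
        paternal=pd.DataFrame(p_rows, index=like.rpkm.index, columns=like.rpkm.columns),
    )


def test_partition_in_read_proportion():
    expr = _two_sample_expr([[30.0, 12.0], [10.0, 8.0]])
    counts = _counts([[20, 0], [0, 4]], [[10, 8], [0, 0]], expr)
    part = partition_rpkm(expr, counts)
    assert np.isclose(part.maternal.loc["g1", "s1"], 20.0)
    assert np.isclose(part.paternal.loc["g1", "s1"], 10.0)
    # m=0, p=8: fully paternal
    assert np.isclose(part.maternal.loc["g1", "s2"], 0.0)
    assert np.isclose(part.paternal.loc["g1", "s2"], 12.0)
    # m+p=0: undefined
    assert np.isnan(part.maternal.loc["g2", "s1"])
    assert part.defined.loc["g2", "s2"]


def test_partition_conserves_total_where_defined(default_run):
    part, expr = default_run["part"], default_run["expr_n"]
    defined = part.defined.to_numpy()
    total = (part.maternal + part.paternal).to_numpy()
    assert np.allclose(total[defined], expr.rpkm.to_numpy()[defined], atol=1e-9, rtol=0)
    # undefined exactly where no informative reads
    assert (default_run["counts"].total.to_numpy()[~defined] == 0).all()


def test_partition_rejects_misaligned_counts():
    expr = _two_sample_expr([[30.0, 12.0], [10.0, 8.0]])
    counts = AllelicCounts(
        maternal=pd.DataFrame([[1]], index=["g1"], columns=["s1"]),
        paternal=pd.DataFrame([[1]], index=["g1"], columns=["s1"]),
    )
    with pytest.raises(ValueError, match="aligned"):
        partition_rpkm(expr, counts)


def test_negative_counts_rejected():
    expr = _two_sample_expr([[30.0, 12.0], [10.0, 8.0]])
    with pytest.raises(ValueError, match="negative"):
        _counts([[-1, 0], [0, 0]], [[0, 0], [0, 0]], expr)


# ---------------------------------------------------------------------------

def test_zygotic_fraction_closed_forms():
    expr = _two_sample_expr([[30.0, 12.0], [10.0, 8.0]])
    counts = _counts([[10, 20], [0, 0]], [[10, 0], [0, 0]], expr)
    zf = zygotic_fraction(counts, expr)
    assert zf.loc["g1", "s1"] == 1.0   # m=10, p=10 -> biallelic, fully zygotic
    assert zf.loc["g1", "s2"] == 0.0   # m=20, p=0 -> fully maternal
    assert np.isnan(zf.loc["g2", "s1"])  # no informative reads
    raw = zygotic_fraction(counts, expr, doubling=False)
    assert raw.loc["g1", "s1"] == 0.5


def test_zygotic_fraction_undefined_on_male_x():
    rpkm = pd.DataFrame([[5.0]], index=["gx"], columns=["m1"])
    genes = pd.DataFrame({"chrom": ["X"], "length": [1000]}, index=["gx"])
    samples = pd.DataFrame({"sex": ["M"], "stage": ["14A"], "replicate": [1]}, index=["m1"])
    expr = ExpressionData(rpkm, genes, samples)
    counts = AllelicCounts(
        maternal=pd.DataFrame([[9]], index=["gx"], columns=["m1"]),
        paternal=pd.DataFrame([[0]], index=["gx"], columns=["m1"]),
    )
    assert np.isnan(zygotic_fraction(counts, expr).loc["gx", "m1"])


def test_zygotic_fraction_invariant_to_normalization(default_run):
    zf_raw = zygotic_fraction(default_run["counts"], default_run["expr"])
    zf_norm = zygotic_fraction(default_run["counts"], default_run["expr_n"])
    pd.testing.assert_frame_equal(zf_raw, zf_norm)


def test_generator_fraction_recovered_noise_free():
    # known mixture: expected zygotic fraction z/(m+z) under the doubling rule
    cfg = SimConfig(
        n_genes=400, frac_x=0.0, frac_maternal=0.0, frac_zygotic=0.0,
        frac_mat_zyg=1.0, frac_with_snp=1.0, noise_sd=0.0, depth_mean=200.0, seed=4,
    )
    expr, counts, truth = simulate_timecourse(cfg)
    zf = zygotic_fraction(counts, expr)
    stage = "14A"
    col = "F14A_1"
    expect = (
        truth.zygotic_female[stage] / (truth.maternal_profile[stage] + truth.zygotic_female[stage])
    )
    got = zf[col]
    mask = got.notna()
    assert mask.mean() > 0.95
    diff = (got[mask] - np.minimum(1.0, expect[mask])).abs()
    # exact up to binomial read-sampling noise at the simulated depth
    assert diff.mean() < 0.02
    assert (diff < 0.1).mean() > 0.98


def test_mean_zygotic_fraction_rises_over_stages(default_run):
    expr, counts = default_run["expr"], default_run["counts"]
    zf = zygotic_fraction(counts, expr)
    fem = expr.samples.index[expr.samples["sex"] == "F"]
    means = []
    for stage in ("C10", "C12", "14A", "14D"):
        cols = [c for c in fem if expr.samples.loc[c, "stage"] == stage]
        means.append(np.nanmean(zf[cols].to_numpy()))
    assert means == sorted(means)
    assert means[-1] - means[0] > 0.2


# ---------------------------------------------------------------------------

def test_impute_f13_is_mean_of_neighbors(small_timecourse):
    _, expr, _, _ = small_timecourse
    out = impute_f13(expr)
    mean_c12 = expr.rpkm["FC12"]
    mean_14a = expr.rpkm[["F14A_1", "F14A_2"]].mean(axis=1)
    pd.testing.assert_series_equal(
        out.rpkm["FC13"], (mean_c12 + mean_14a) / 2.0, check_names=False
    )
    assert out.samples.loc["FC13", "imputed"]
    # untouched columns unchanged
    pd.testing.assert_series_equal(out.rpkm["MC13"], expr.rpkm["MC13"])


def test_impute_f13_idempotent_and_optional(small_timecourse):
    _, expr, _, _ = small_timecourse
    once = impute_f13(expr)
    twice = impute_f13(once)
    pd.testing.assert_frame_equal(once.rpkm, twice.rpkm)
    off = impute_f13(expr, enabled=False)
    pd.testing.assert_frame_equal(off.rpkm, expr.rpkm)


def test_impute_f13_requires_neighbors():
    rpkm = pd.DataFrame([[1.0]], index=["g1"], columns=["FC13"])
    genes = pd.DataFrame({"chrom": ["2L"], "length": [1]}, index=["g1"])
    samples = pd.DataFrame({"sex": ["F"], "stage": ["C13"], "replicate": [1]}, index=["FC13"])
    with pytest.raises(ValueError, match="imputation requires"):
        impute_f13(ExpressionData(rpkm, genes, samples))


def test_male_x_violations_empty_on_valid_data(small_timecourse):
    _, expr, counts, _ = small_timecourse
    assert len(male_x_paternal_violations(counts, expr)) == 0


def test_male_x_violations_reported_when_planted(small_timecourse):
    _, expr, counts, truth = small_timecourse
    on_x = truth.genes.index[truth.genes["chrom"] == "X"][:1]
    male = expr.samples.index[expr.samples["sex"] == "M"][:1]
    pat = counts.paternal.copy()
    pat.loc[on_x, male] = 5
    bad = AllelicCounts(maternal=counts.maternal, paternal=pat)
    out = male_x_paternal_violations(bad, expr)
    assert len(out) == 1 and out.iloc[0]["paternal_reads"] == 5
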