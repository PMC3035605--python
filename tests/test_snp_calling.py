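"""Fixed-SNP caller: consensus rule, strain comparison, gene overlap."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ezdc.simulate import SimConfig, simulate_annotation, simulate_strain_pileups
from ezdc.snp import BASES, CallerConfig, call_fixed_snps, genes_with_snp, residual_polymorphism, strain_consensus


# ---------------------------------------------------------------------------
# independent oracle: the calling rule applied literally, row by row
# ---------------------------------------------------------------------------

def oracle_consensus(counts: dict, min_depth=13, min_major_freq=0.95):
    depth = sum(counts.get(b, 0) for b in "ACGT")
    if depth < min_depth:
        return None
    ranked = sorted("ACGT", key=lambda b: counts.get(b, 0), reverse=True)
    top, second = counts.get(ranked[0], 0), counts.get(ranked[1], 0)
    if top == second:
        return None
    if top / depth < min_major_freq:
        return None
    return ranked[0]


def oracle_fixed_snps(rows_a, rows_b, **kw):
    """rows: {(chrom,pos): base-count dict}; returns set of (chrom,pos,a,b)."""
    out = set()
    for key in rows_a.keys() & rows_b.keys():
        ca = oracle_consensus(rows_a[key], **kw)
        cb = oracle_consensus(rows_b[key], **kw)
        if ca is not None and cb is not None and ca != cb:
            out.add((*key, ca, cb))
    return out


def random_pileup(rng, n, chrom="2L"):
    rows = []
    for pos in range(1, n + 1):
        depth = int(rng.integers(0, 41))
        probs = rng.dirichlet([0.6, 0.6, 0.6, 0.6])
        counts = rng.multinomial(depth, probs)
        rows.append((chrom, pos, "A", *counts, int(rng.integers(0, 3))))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "A", "C", "G", "T", "N"])


# ---------------------------------------------------------------------------
# per-strain consensus rule
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "counts, base, reason",
    [
        ({"A": 20}, "A", None),                       # clean monomorphic site
        ({"A": 19, "G": 1}, "A", None),               # 19/20 = 0.95 meets "at least 95%"
        ({"A": 12}, None, "low_depth"),               # 12 < 13
        ({"A": 10, "G": 10}, None, "polymorphic"),    # reported as polymorphic or tie
        ({"A": 19, "G": 1, "N": 5}, "A", None),       # N excluded from denominator
        ({"A": 13, "C": 7}, None, "polymorphic"),
        ({}, None, "low_depth"),
    ],
)
def test_strain_consensus_rule(counts, base, reason):
    call = strain_consensus(counts)
    assert call.base == base
    assert call.reason == reason


def test_consensus_boundary_is_inclusive():
    # depth exactly 13 and frequency exactly 95% are both accepted
    assert strain_consensus({"A": 13}).base == "A"
    assert strain_consensus({"A": 19, "C": 1}).base == "A"
    assert strain_consensus({"A": 18, "C": 1}, CallerConfig(min_depth=20)).reason == "low_depth"


def test_tied_majority_never_called():
    # an exact tie cannot reach 95% so it surfaces as polymorphic
    call = strain_consensus({"A": 10, "G": 10, "C": 1})
    assert call.base is None and call.reason == "polymorphic"


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        strain_consensus({"A": -1})


# ---------------------------------------------------------------------------
# two-strain comparison
# ---------------------------------------------------------------------------

def _pile(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "A", "C", "G", "T", "N"])


def test_fixed_difference_called():
    a = _pile([("2L", 5, "A", 20, 0, 0, 0, 0)])
    b = _pile([("2L", 5, "A", 0, 0, 15, 0, 0)])
    out = call_fixed_snps(a, b)
    assert len(out) == 1
    rec = out.iloc[0]
    assert (rec["allele_a"], rec["allele_b"]) == ("A", "G")
    assert rec["depth_a"] == 20 and rec["depth_b"] == 15


def test_identical_consensus_not_called():
    a = _pile([("2L", 5, "A", 20, 0, 0, 0, 0)])
    b = _pile([("2L", 5, "A", 20, 0, 0, 0, 0)])
    assert len(call_fixed_snps(a, b)) == 0


def test_positions_missing_from_one_strain_skipped():
    a = _pile([("2L", 5, "A", 20, 0, 0, 0, 0), ("2L", 9, "A", 20, 0, 0, 0, 0)])
    b = _pile([("2L", 5, "A", 0, 0, 15, 0, 0)])
    assert len(call_fixed_snps(a, b)) == 1


def test_duplicate_positions_rejected():
    a = _pile([("2L", 5, "A", 20, 0, 0, 0, 0), ("2L", 5, "A", 20, 0, 0, 0, 0)])
    b = _pile([("2L", 5, "A", 0, 0, 15, 0, 0)])
    with pytest.raises(ValueError, match="duplicate"):
        call_fixed_snps(a, b)


def test_caller_matches_oracle_on_random_columns():
    rng = np.random.default_rng(7)
    a, b = random_pileup(rng, 500), random_pileup(rng, 500)
    called = call_fixed_snps(a, b)
    got = set(zip(called["chrom"], called["pos"], called["allele_a"], called["allele_b"]))
    rows_a = {(r.chrom, r.pos): {k: getattr(r, k) for k in "ACGT"} for r in a.itertuples()}
    rows_b = {(r.chrom, r.pos): {k: getattr(r, k) for k in "ACGT"} for r in b.itertuples()}
    assert got == oracle_fixed_snps(rows_a, rows_b)


def test_row_order_does_not_change_output():
    rng = np.random.default_rng(3)
    a, b = random_pileup(rng, 200), random_pileup(rng, 200)
    out1 = call_fixed_snps(a, b)
    out2 = call_fixed_snps(a.sample(frac=1, random_state=0), b.sample(frac=1, random_state=1))
    pd.testing.assert_frame_equal(out1, out2)


@pytest.mark.parametrize("stricter", [CallerConfig(min_depth=20), CallerConfig(min_major_freq=0.99)])
def test_raising_thresholds_only_removes_records(stricter):
    rng = np.random.default_rng(11)
    a, b = random_pileup(rng, 400), random_pileup(rng, 400)
    loose = call_fixed_snps(a, b)
    tight = call_fixed_snps(a, b, stricter)
    loose_keys = set(zip(loose["chrom"], loose["pos"]))
    tight_keys = set(zip(tight["chrom"], tight["pos"]))
    assert tight_keys <= loose_keys


def test_caller_recovers_generator_truth():
    cfg = SimConfig(n_genes=300, seed=9)
    pa, pb, truth = simulate_strain_pileups(cfg)
    called = call_fixed_snps(pa, pb)
    fixed = truth[truth["status"] == "fixed"]
    got = set(zip(called["chrom"], called["pos"]))
    want = set(zip(fixed["chrom"], fixed["pos"]))
    assert got == want
    merged = called.merge(fixed, on=["chrom", "pos"])
    assert (merged["allele_a_x"] == merged["allele_a_y"]).all()
    assert (merged["allele_b_x"] == merged["allele_b_y"]).all()


def test_engineered_failures_present_and_uncalled():
    cfg = SimConfig(n_genes=100, n_positions=90, n_fixed_snps=30, seed=2)
    pa, pb, truth = simulate_strain_pileups(cfg)
    assert set(truth["status"]) == {"fixed", "low_depth", "polymorphic", "identical"}
    low = truth[truth["status"] == "low_depth"]
    merged = pa.merge(pb, on=["chrom", "pos"], suffixes=("_a", "_b"))
    for r in low.itertuples():
        row = merged[(merged["chrom"] == r.chrom) & (merged["pos"] == r.pos)].iloc[0]
        da = row[["A_a", "C_a", "G_a", "T_a"]].sum()
        db = row[["A_b", "C_b", "G_b", "T_b"]].sum()
        assert min(da, db) < 13


def test_residual_polymorphism_reported():
    cfg = SimConfig(n_genes=100, n_positions=90, n_fixed_snps=30, seed=2)
    pa, pb, truth = simulate_strain_pileups(cfg)
    resid = residual_polymorphism(pb)
    want = truth[truth["status"] == "polymorphic"]
    got = set(zip(resid["chrom"], resid["pos"]))
    assert set(zip(want["chrom"], want["pos"])) <= got


# ---------------------------------------------------------------------------
# SNP-in-gene counting
# ---------------------------------------------------------------------------

def _annot(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "exon_starts", "exon_ends", "exonic_length"])
    return df.set_index("gene_id")


def test_exonic_snp_counted_intronic_not():
    annot = _annot([("g1", "2L", "+", (100, 300), (199, 399), 200)])
    snps = pd.DataFrame({"chrom": ["2L", "2L", "2L"], "pos": [150, 250, 399]})
    counts = genes_with_snp(snps, annot)
    assert counts["g1"] == 2  # 150 and 399 are exonic; 250 sits in the intron


def test_whole_span_mode_counts_intron():
    annot = _annot([("g1", "2L", "+", (100, 300), (199, 399), 200)])
    snps = pd.DataFrame({"chrom": ["2L"], "pos": [250]})
    assert genes_with_snp(snps, annot, use_exons=False)["g1"] == 1


def test_zero_snp_genes_listed():
    annot = _annot([("g1", "2L", "+", (100,), (199,), 100), ("g2", "3R", "+", (1,), (50,), 50)])
    snps = pd.DataFrame({"chrom": ["2L"], "pos": [150]})
    counts = genes_with_snp(snps, annot)
    assert counts["g2"] == 0 and set(counts.index) == {"g1", "g2"}


def test_unknown_chromosome_skipped_with_warning(caplog):
    annot = _annot([("g1", "2L", "+", (100,), (199,), 100)])
    snps = pd.DataFrame({"chrom": ["U"], "pos": [150]})
    with caplog.at_level("WARNING"):
        counts = genes_with_snp(snps, annot)
    assert counts["g1"] == 0
    assert any("skipping" in r.message for r in caplog.records)


def test_gene_counts_match_bruteforce_on_random_annotation():
    rng = np.random.default_rng(5)
    cfg = SimConfig(n_genes=150, seed=5)
    annot = simulate_annotation(cfg)
    chroms = annot["chrom"].unique()
    snps = pd.DataFrame(
        {
            "chrom": rng.choice(chroms, size=400),
            "pos": rng.integers(1, 60000, size=400),
        }
    )
    counts = genes_with_snp(snps, annot)
    for gid, g in annot.iterrows():
        brute = sum(
            1
            for r in snps.itertuples()
            if r.chrom == g["chrom"]
            and any(s <= r.pos <= e for s, e in zip(g["exon_starts"], g["exon_ends"]))
        )
        assert counts[gid] == brute
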