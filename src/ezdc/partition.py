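"""Sample normalization and maternal/zygotic partitioning of expression.

Each sample is rescaled so its autosomal RPKM total matches the mean
autosomal total across samples (X-linked genes get the same per-sample
scalar, so X totals are free to differ by sex).  A gene's RPKM in a
sample is then split into maternal- and paternal-allele components in
proportion to its allele-informative read counts, and a zygotic fraction
is inferred: zygotic transcription is biallelic on autosomes and the
female X, so the paternal-allele component represents half of the
zygotic pool and is doubled (configurable off).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import AllelicCounts, ExpressionData, PartitionedExpression
from .stages import is_x

__all__ = [
    "normalize_autosomal",
    "partition_rpkm",
    "zygotic_fraction",
    "impute_f13",
    "male_x_paternal_violations",
]


def normalize_autosomal(expr: ExpressionData) -> ExpressionData:
    """Scale every sample so autosomal RPKM totals are equal.

    The common target is the mean pre-normalization autosomal total, which
    keeps values near the input scale.  A sample with zero autosomal
    signal cannot be normalized and raises.
    """
    auto = ~is_x(expr.genes["chrom"])
    if not auto.any():
        raise ValueError("no autosomal genes; cannot normalize")
    totals = expr.rpkm.loc[auto].sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"zero autosomal total in sample(s) {bad}")
    scalars = totals.mean() / totals
    out = expr.copy()
    out.rpkm = expr.rpkm * scalars
    return out


def partition_rpkm(expr: ExpressionData, counts: AllelicCounts) -> PartitionedExpression:
    """Split each gene's RPKM by parental allele, in read proportion.

    maternal = RPKM * m/(m+p) and paternal = RPKM * p/(m+p) wherever at
    least one informative read exists; both NaN otherwise (genes without
    strain-distinguishing SNPs route to correlation-based classification
    downstream).  Wherever defined the two components sum exactly to the
    input RPKM.
    """
    if not counts.maternal.index.equals(expr.rpkm.index) or not (
        counts.maternal.columns.equals(expr.rpkm.columns)
    ):
        raise ValueError("expression and allelic counts are not aligned")
    m = counts.maternal.to_numpy(dtype=float)
    p = counts.paternal.to_numpy(dtype=float)
    tot = m + p
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_m = np.where(tot >= 1, m / tot, np.nan)
    rpkm = expr.rpkm.to_numpy()
    idx, cols = expr.rpkm.index, expr.rpkm.columns
    return PartitionedExpression(
        maternal=pd.DataFrame(rpkm * frac_m, index=idx, columns=cols),
        paternal=pd.DataFrame(rpkm * (1.0 - frac_m), index=idx, columns=cols),
    )


def zygotic_fraction(
    counts: AllelicCounts,
    expr: ExpressionData,
    doubling: bool = True,
) -> pd.DataFrame:
    """Per gene x sample inferred zygotic fraction from allele counts.

    With biallelic zygotic transcription the paternal allele carries half
    the zygotic reads, so fraction = min(1, 2p/(m+p)); ``doubling=False``
    yields the raw paternal share p/(m+p).  Undefined (NaN) when a
    gene/sample has no informative reads, and for X-linked genes in male
    samples, which have no paternal allele to observe.
    """
    m = counts.maternal.to_numpy(dtype=float)
    p = counts.paternal.to_numpy(dtype=float)
    tot = m + p
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(tot >= 1, p / tot, np.nan)
    frac = np.minimum(1.0, 2.0 * share) if doubling else share
    male = (expr.samples["sex"] == "M").to_numpy()
    on_x = is_x(expr.genes["chrom"])
    frac[np.ix_(on_x, male)] = np.nan
    return pd.DataFrame(frac, index=counts.maternal.index, columns=counts.maternal.columns)


def impute_f13(expr: ExpressionData, enabled: bool = True) -> ExpressionData:
    """Replace the female cycle-13 sample by the mean of female C12 and 14A.

    Used when the C13 female is suspect (e.g. a possible sexing error);
    every female C13 column is replaced by the arithmetic mean of all
    female C12 and female 14A columns and flagged ``imputed`` in the
    sample metadata.  Idempotent; ``enabled=False`` is the identity.
    """
    out = expr.copy()
    if "imputed" not in out.samples.columns:
        out.samples["imputed"] = False
    if not enabled:
        return out
    meta = expr.samples
    f13 = meta.index[(meta["sex"] == "F") & (meta["stage"] == "C13")]
    donors = meta.index[(meta["sex"] == "F") & meta["stage"].isin(["C12", "14A"])]
    if len(f13) == 0 or not {"C12", "14A"} <= set(meta.loc[donors, "stage"]):
        raise ValueError("imputation requires female C13, C12 and 14A samples")
    mean_c12 = expr.rpkm[meta.index[(meta["sex"] == "F") & (meta["stage"] == "C12")]].mean(axis=1)
    mean_14a = expr.rpkm[meta.index[(meta["sex"] == "F") & (meta["stage"] == "14A")]].mean(axis=1)
    imputed = (mean_c12 + mean_14a) / 2.0
    for col in f13:
        out.rpkm[col] = imputed
    out.samples.loc[f13, "imputed"] = True
    return out


def male_x_paternal_violations(counts: AllelicCounts, expr: ExpressionData) -> pd.DataFrame:
    """Report paternal-allele reads on the male X (a sexing/genotyping flag).

    Males carry no paternal X, so any paternal-allele read for an
    X-linked gene in a male sample indicates mis-sexing, genotyping error
    or mismapping.  Returns a long table (gene_id, sample_id,
    paternal_reads) of violations; empty on valid inputs.
    """
    male = expr.samples.index[expr.samples["sex"] == "M"]
    on_x = expr.genes.index[is_x(expr.genes["chrom"])]
    block = counts.paternal.loc[on_x, male]
    stacked = block.stack()
    bad = stacked[stacked > 0]
    out = bad.rename("paternal_reads").reset_index()
    out.columns = ["gene_id", "sample_id", "paternal_reads"]
    return out
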