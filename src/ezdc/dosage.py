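"""Female:male expression statistics and dosage-compensation scoring.

For zygotically transcribed genes the package computes, per stage and
chromosome group, female:male RPKM ratios (filtered to genes where both
sexes reach a floor of 2 RPKM), a per-gene compensation score — the
through-origin least-squares slope of female on male replicate-averaged
stage levels, so 1.0 means fully compensated and 2.0 an uncompensated
X — binned ratio summaries, and chromosome-level parental-origin
aggregates of the partitioned expression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionData, PartitionedExpression
from .stages import CYCLE14_STAGES, STAGES, is_x

__all__ = [
    "stage_means_by_sex",
    "fm_ratio",
    "compensation_score",
    "score_table",
    "score_summary",
    "ratio_bins",
    "chrom_aggregate",
    "DEFAULT_BIN_EDGES",
]

#: F:M-axis bin edges; outer bins are open (<1/2 and >2).
DEFAULT_BIN_EDGES: tuple[float, ...] = (
    1 / 2, 1 / 1.75, 1 / 1.5, 1 / 1.25, 1.0, 1.25, 1.5, 1.75, 2.0,
)


def stage_means_by_sex(expr: ExpressionData) -> dict[str, pd.DataFrame]:
    """Replicate-averaged genes x 8-stage RPKM matrices, one per sex."""
    meta = expr.samples
    out: dict[str, pd.DataFrame] = {}
    for sex in ("F", "M"):
        cols = {}
        for stage in STAGES:
            sel = meta.index[(meta["sex"] == sex) & (meta["stage"] == stage)]
            if len(sel) == 0:
                raise ValueError(f"no {sex} sample at stage {stage}")
            cols[stage] = expr.rpkm[sel].mean(axis=1)
        out[sex] = pd.DataFrame(cols)[list(STAGES)]
    return out


def _zygotic_index(classes: pd.DataFrame) -> pd.Index:
    return classes.index[classes["class"] == "zygotic"]


def fm_ratio(
    expr: ExpressionData,
    classes: pd.DataFrame,
    min_rpkm: float = 2.0,
    stages: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-gene, per-stage female:male RPKM ratio for zygotic genes.

    Replicates are averaged per (sex, stage) first.  The ratio is
    defined only where *both* sexes have at least ``min_rpkm`` (a noise
    floor); elsewhere NaN.  ``stages`` restricts the output columns
    (default: all 8 stages).
    """
    means = stage_means_by_sex(expr)
    zyg = _zygotic_index(classes)
    use = list(stages) if stages is not None else list(STAGES)
    f = means["F"].loc[zyg, use]
    m = means["M"].loc[zyg, use]
    ok = (f >= min_rpkm) & (m >= min_rpkm)
    return (f / m).where(ok)


def compensation_score(female_levels, male_levels) -> float:
    """Through-origin least-squares slope of female on male stage levels.

    slope = sum(f*m) / sum(m^2); a pure ratio estimator, so equal
    expression gives exactly 1.0 and scaling the female levels by a
    scales the score by a.  NaN when the male levels are all zero.
    """
    f = np.asarray(female_levels, dtype=float)
    m = np.asarray(male_levels, dtype=float)
    if f.shape != m.shape:
        raise ValueError(f"length mismatch: {f.shape} vs {m.shape}")
    denom = float((m * m).sum())
    if denom == 0.0:
        return float("nan")
    return float((f * m).sum() / denom)


def score_table(
    expr: ExpressionData,
    classes: pd.DataFrame,
    min_max_rpkm: float = 3.0,
    log_scale: bool = False,
) -> pd.DataFrame:
    """Compensation scores for zygotic genes with appreciable expression.

    One row per zygotic gene whose maximum normalized RPKM over all
    samples is strictly greater than ``min_max_rpkm``; the score is the
    through-origin slope of the 8 female on the 8 male replicate-averaged
    stage levels (``log_scale=True`` fits on log2(x+1) levels instead).
    Columns: chrom, score, max_rpkm, n_stages.
    """
    means = stage_means_by_sex(expr)
    zyg = _zygotic_index(classes)
    max_rpkm = expr.rpkm.loc[zyg].max(axis=1)
    keep = zyg[(max_rpkm > min_max_rpkm).to_numpy()]
    f = means["F"].loc[keep].to_numpy()
    m = means["M"].loc[keep].to_numpy()
    if log_scale:
        f, m = np.log2(f + 1.0), np.log2(m + 1.0)
    denom = (m * m).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(denom > 0, (f * m).sum(axis=1) / np.maximum(denom, 1e-300), np.nan)
    return pd.DataFrame(
        {
            "chrom": expr.genes.loc[keep, "chrom"],
            "score": scores,
            "max_rpkm": max_rpkm.loc[keep],
            "n_stages": len(STAGES),
        },
        index=keep,
    )


def score_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-arm counts of scored genes exceeding 1.0 and 1.5."""
    rows = []
    for arm, grp in scores.groupby("chrom"):
        s = grp["score"].dropna()
        rows.append((arm, len(s), int((s > 1.0).sum()), int((s > 1.5).sum()), s.median()))
    return pd.DataFrame(
        rows, columns=["chrom", "n_genes", "n_gt_1.0", "n_gt_1.5", "median_score"]
    ).set_index("chrom")


def ratio_bins(
    ratios: pd.DataFrame,
    genes: pd.DataFrame,
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Per-stage, per-chromosome-group proportions of genes by F:M bin.

    ``ratios`` comes from :func:`fm_ratio` (NaN = filtered out).  Genes
    are split into the groups X and autosomes; for each stage column the
    defined ratios are histogrammed over ``bin_edges`` with open outer
    bins, and proportions sum to 1 over the defined genes.  Output is
    long format: group, stage, bin, proportion, n_genes.
    """
    edges = np.concatenate([[-np.inf], np.asarray(bin_edges, dtype=float), [np.inf]])
    labels = (
        [f"<{bin_edges[0]:.3g}"]
        + [f"{lo:.3g}-{hi:.3g}" for lo, hi in zip(bin_edges[:-1], bin_edges[1:])]
        + [f">{bin_edges[-1]:.3g}"]
    )
    groups = {
        "X": ratios.index[is_x(genes.loc[ratios.index, "chrom"])],
        "autosomes": ratios.index[~is_x(genes.loc[ratios.index, "chrom"])],
    }
    rows = []
    for gname, idx in groups.items():
        for stage in ratios.columns:
            vals = ratios.loc[idx, stage].dropna().to_numpy()
            n = len(vals)
            hist, _ = np.histogram(vals, bins=edges)
            props = hist / n if n else np.zeros(len(labels))
            for lab, p in zip(labels, props):
                rows.append((gname, stage, lab, p, n))
    return pd.DataFrame(rows, columns=["group", "stage", "bin", "proportion", "n_genes"])


def chrom_aggregate(
    part: PartitionedExpression,
    expr: ExpressionData,
    classes: pd.DataFrame,
) -> pd.DataFrame:
    """Parental-origin expression totals for zygotic genes.

    For each (chromosome arm, sex, stage) the replicate-averaged
    maternal-allele, paternal-allele and total components are summed
    over zygotic genes with a defined allele split in that stage's
    samples, so maternal + paternal = total by construction.  On an
    uncompensated X (F:M = 2) the male-X total matches each single
    female-X parental total.  Long format: chrom, sex, stage, origin,
    value, n_genes.
    """
    zyg = _zygotic_index(classes)
    meta = expr.samples
    rows = []
    for arm, arm_genes in expr.genes.loc[zyg].groupby("chrom"):
        gidx = arm_genes.index
        for sex in ("F", "M"):
            for stage in STAGES:
                cols = meta.index[(meta["sex"] == sex) & (meta["stage"] == stage)]
                mat = part.maternal.loc[gidx, cols].mean(axis=1)
                pat = part.paternal.loc[gidx, cols].mean(axis=1)
                defined = mat.notna() & pat.notna()
                m_sum = float(mat[defined].sum())
                p_sum = float(pat[defined].sum())
                rows.append((arm, sex, stage, "maternal", m_sum, int(defined.sum())))
                rows.append((arm, sex, stage, "paternal", p_sum, int(defined.sum())))
                rows.append((arm, sex, stage, "total", m_sum + p_sum, int(defined.sum())))
    return pd.DataFrame(rows, columns=["chrom", "sex", "stage", "origin", "value", "n_genes"])
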