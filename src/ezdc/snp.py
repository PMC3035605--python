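"""Fixed-SNP calling between two parental strains from base-count pileups.

The caller implements a deliberately simple consensus rule designed for
lab strains harboring residual polymorphism: a position is a fixed SNP
if, in *each* strain, at least ``min_depth`` reads cover the base
(default 13) and the most common base accounts for at least
``min_major_freq`` of them (default 95%), and the two strains' consensus
bases differ.  Ambiguous (N) reads are excluded from the frequency
denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "CallerConfig",
    "ConsensusCall",
    "strain_consensus",
    "call_fixed_snps",
    "residual_polymorphism",
    "genes_with_snp",
]

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class CallerConfig:
    min_depth: int = 13
    min_major_freq: float = 0.95

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0.5 < self.min_major_freq <= 1.0:
            raise ValueError("min_major_freq must lie in (0.5, 1]")


class ConsensusCall(NamedTuple):
    """Outcome of the per-strain consensus rule at one position."""

    base: str | None
    reason: str | None  # None when called; else low_depth | polymorphic | tie
    depth: int
    major_freq: float


def strain_consensus(counts: Mapping[str, int], cfg: CallerConfig = CallerConfig()) -> ConsensusCall:
    """Apply the consensus rule to one strain's base counts at one position.

    ``counts`` maps base -> read count; missing bases count as 0 and any
    ``N`` entry is ignored (excluded from the depth/frequency
    denominator).  Returns the consensus base, or a no-call with reason
    ``low_depth`` (depth < min_depth), ``tie`` (two bases share the
    maximum) or ``polymorphic`` (major fraction below min_major_freq).
    """
    c = np.array([counts.get(b, 0) for b in BASES], dtype=float)
    if (c < 0).any():
        raise ValueError("negative base counts")
    depth = int(c.sum())
    if depth < cfg.min_depth:
        return ConsensusCall(None, "low_depth", depth, float("nan"))
    top = c.max()
    freq = top / depth
    if freq < cfg.min_major_freq:
        return ConsensusCall(None, "polymorphic", depth, freq)
    if (c == top).sum() > 1:
        # unreachable while min_major_freq > 0.5; defined for safety
        return ConsensusCall(None, "tie", depth, freq)
    return ConsensusCall(BASES[int(c.argmax())], None, depth, freq)


def _consensus_arrays(pile: pd.DataFrame, cfg: CallerConfig):
    """Vectorized consensus over a whole pileup table.

    Returns (called mask, consensus base array, depth, major freq).
    """
    c = pile[list(BASES)].to_numpy(dtype=float)
    if (c < 0).any():
        raise ValueError("negative base counts in pileup")
    depth = c.sum(axis=1)
    top = c.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(depth > 0, top / np.maximum(depth, 1), 0.0)
    tie = (c == top[:, None]).sum(axis=1) > 1
    ok = (depth >= cfg.min_depth) & ~tie & (freq >= cfg.min_major_freq)
    base = np.array(BASES)[c.argmax(axis=1)]
    return ok, base, depth.astype(int), freq


def _check_pileup(pile: pd.DataFrame, name: str) -> pd.DataFrame:
    dup = pile.duplicated(subset=["chrom", "pos"])
    if dup.any():
        where = pile.loc[dup, ["chrom", "pos"]].iloc[0]
        raise ValueError(
            f"duplicate (chrom, pos) in strain {name} pileup at {where['chrom']}:{where['pos']}"
        )
    return pile


def call_fixed_snps(
    pile_a: pd.DataFrame,
    pile_b: pd.DataFrame,
    cfg: CallerConfig = CallerConfig(),
) -> pd.DataFrame:
    """Call fixed differences between two strains.

    Input pileups are TSV-dialect tables ``chrom pos ref A C G T N``
    (1-based positions).  Positions present in only one pileup are
    skipped.  The output SNP table has one row per position where both
    strains pass the consensus rule and the consensus bases differ:
    ``chrom pos ref allele_a allele_b depth_a depth_b freq_a freq_b``,
    sorted by (chrom, pos); row order of the inputs is irrelevant.
    """
    _check_pileup(pile_a, "A")
    _check_pileup(pile_b, "B")
    merged = pile_a.merge(
        pile_b, on=["chrom", "pos"], suffixes=("_a", "_b"), how="inner", validate="one_to_one"
    )
    a_cols = merged[["chrom", "pos"]].assign(
        ref=merged.get("ref_a", merged.get("ref")),
        **{b: merged[f"{b}_a"] for b in BASES},
    )
    b_cols = merged[["chrom", "pos"]].assign(**{b: merged[f"{b}_b"] for b in BASES})
    ok_a, base_a, depth_a, freq_a = _consensus_arrays(a_cols, cfg)
    ok_b, base_b, depth_b, freq_b = _consensus_arrays(b_cols, cfg)
    keep = ok_a & ok_b & (base_a != base_b)
    out = pd.DataFrame(
        {
            "chrom": merged["chrom"],
            "pos": merged["pos"],
            "ref": a_cols["ref"],
            "allele_a": base_a,
            "allele_b": base_b,
            "depth_a": depth_a,
            "depth_b": depth_b,
            "freq_a": freq_a,
            "freq_b": freq_b,
        }
    )[keep]
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def residual_polymorphism(pile: pd.DataFrame, cfg: CallerConfig = CallerConfig()) -> pd.DataFrame:
    """Sites with adequate depth that fail the major-allele frequency rule.

    Reporting-only diagnostic of residual within-strain polymorphism in
    nominally inbred stocks; no downstream analysis consumes it.
    """
    _check_pileup(pile, "?")
    c = pile[list(BASES)].to_numpy(dtype=float)
    depth = c.sum(axis=1)
    top = c.max(axis=1)
    freq = np.where(depth > 0, top / np.maximum(depth, 1), 0.0)
    mask = (depth >= cfg.min_depth) & (freq < cfg.min_major_freq)
    out = pile.loc[mask, ["chrom", "pos"]].copy()
    out["depth"] = depth[mask].astype(int)
    out["major_freq"] = freq[mask]
    return out.reset_index(drop=True)


def genes_with_snp(
    snps: pd.DataFrame,
    annotation: pd.DataFrame,
    use_exons: bool = True,
) -> pd.Series:
    """Count fixed SNPs overlapping each gene.

    ``annotation`` is indexed by gene_id with columns ``chrom``,
    ``exon_starts``, ``exon_ends`` (tuples of 1-based inclusive
    coordinates).  By default only exonic positions count (RNA-seq reads
    span exons); ``use_exons=False`` counts any SNP within the gene's
    genomic span.  Genes with zero SNPs appear explicitly.  SNPs on
    chromosomes absent from the annotation are skipped with a warning.
    """
    known = set(annotation["chrom"])
    missing = snps[~snps["chrom"].isin(known)]
    if len(missing):
        logger.warning(
            "skipping %d SNP(s) on chromosome(s) %s absent from annotation",
            len(missing),
            sorted(set(missing["chrom"])),
        )
    by_chrom = {
        chrom: np.sort(grp["pos"].to_numpy()) for chrom, grp in snps.groupby("chrom")
    }
    counts = pd.Series(0, index=annotation.index, name="n_snps", dtype=int)
    for gid, g in annotation.iterrows():
        pos = by_chrom.get(g["chrom"])
        if pos is None:
            continue
        starts, ends = g["exon_starts"], g["exon_ends"]
        if not use_exons:
            starts, ends = (min(starts),), (max(ends),)
        total = 0
        for s, e in zip(starts, ends):
            total += int(np.searchsorted(pos, e, side="right") - np.searchsorted(pos, s, side="left"))
        counts.loc[gid] = total
    return counts
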