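"""In-memory containers shared across the pipeline.

Everything is a thin, validated wrapper around pandas objects so that the
tabular TSV dialects in :mod:`ezdc.io` round-trip losslessly:

* expression: genes x samples RPKM matrix plus gene and sample metadata,
* allelic counts: paired genes x samples integer matrices of
  maternal-allele and paternal-allele informative reads,
* partitioned expression: maternal/paternal RPKM components (NaN where no
  informative reads exist for that gene/sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stages import STAGES


@dataclass
class ExpressionData:
    """Genes x samples RPKM with gene and sample metadata.

    Attributes
    ----------
    rpkm : DataFrame, genes x samples, nonnegative RPKM.
    genes : DataFrame indexed by gene_id with at least columns
        ``chrom`` (arm name) and ``length`` (exonic length, bp).
    samples : DataFrame indexed by sample_id with columns
        ``sex`` in {F, M}, ``stage`` in the 8-stage axis, ``replicate``.
    """

    rpkm: pd.DataFrame
    genes: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.rpkm.to_numpy() < 0).any():
            raise ValueError("RPKM matrix contains negative entries")
        if self.rpkm.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        if not self.rpkm.index.equals(self.genes.index):
            self.genes = self.genes.loc[self.rpkm.index]
        if not self.rpkm.columns.equals(self.samples.index):
            self.samples = self.samples.loc[self.rpkm.columns]
        bad = set(self.samples["stage"]) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")
        key = self.samples[["sex", "stage", "replicate"]]
        if key.duplicated().any():
            raise ValueError("(sex, stage, replicate) not unique in sample metadata")

    def copy(self) -> "ExpressionData":
        return ExpressionData(self.rpkm.copy(), self.genes.copy(), self.samples.copy())


@dataclass
class AllelicCounts:
    """Informative-read counts per gene x sample, split by parental allele."""

    maternal: pd.DataFrame
    paternal: pd.DataFrame

    def __post_init__(self) -> None:
        for name, df in (("maternal", self.maternal), ("paternal", self.paternal)):
            arr = df.to_numpy()
            if (arr < 0).any():
                raise ValueError(f"negative {name} read counts")
            if not np.allclose(arr, np.round(arr)):
                raise ValueError(f"{name} read counts must be integers")
        if not self.maternal.index.equals(self.paternal.index) or not (
            self.maternal.columns.equals(self.paternal.columns)
        ):
            raise ValueError("maternal/paternal count matrices are not aligned")

    @property
    def total(self) -> pd.DataFrame:
        return self.maternal + self.paternal


@dataclass
class PartitionedExpression:
    """RPKM split into maternal- and paternal-allele components.

    Components are NaN wherever a gene/sample has zero informative reads;
    wherever defined, maternal + paternal equals the input RPKM.
    """

    maternal: pd.DataFrame
    paternal: pd.DataFrame

    @property
    def total(self) -> pd.DataFrame:
        return self.maternal + self.paternal

    @property
    def defined(self) -> pd.DataFrame:
        return self.maternal.notna()


@dataclass
class GroundTruth:
    """Simulation truth: per-gene labels, kinetics, and expected profiles.

    ``genes`` carries one row per simulated gene: true_class in
    {maternal, zygotic, maternal_zygotic, silent}, chromosome arm,
    compensation (F:M target, 1.0 for autosomes), has_snp flag and the
    kinetic amplitudes.  Expected (noise-free) stage profiles are stored
    per sex, genes x 8 stages.
    """

    genes: pd.DataFrame
    expected_female: pd.DataFrame
    expected_male: pd.DataFrame
    maternal_profile: pd.DataFrame
    zygotic_female: pd.DataFrame
    zygotic_male: pd.DataFrame
    snps: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.genes.index.duplicated().any():
            raise ValueError("duplicate gene ids in ground truth")
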