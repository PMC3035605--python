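"""Synthetic two-strain embryo time-course generator.

Emulates the study design this package analyzes: a cross of two
genetically distinct *D. melanogaster* strains (maternal ``w1``-like,
paternal ``CaS``-like), single-embryo mRNA-seq of 24 staged embryos
(one embryo per sex at mitotic cycles 10-13, two per sex at the four
cellularization substages 14A-14D), and ~35x genomic sequencing of both
parental strains for fixed-SNP discovery.

The generator produces, with full ground truth:

* per-strain base-count pileups containing genuinely fixed differences
  plus positions engineered to fail each criterion of the SNP-calling
  rule (low depth, residual within-strain polymorphism, identical
  consensus);
* a 24-sample RPKM matrix + allele-informative read counts over genes
  drawn from four kinetic classes: purely maternal (exponential decay of
  the deposited pool), purely zygotic (logistic onset, zero at cycle 10),
  maternal+zygotic (sum of both), and silent background;
* 3'UTR sequences with a known number of planted SXL consensus sites.

Maternal transcripts carry only the maternal-strain allele.  Zygotic
transcription is biallelic, so informative reads from zygotic mRNA split
Binomial(n, 1/2) between the parental alleles — except on the male X,
which has no paternal copy.  X-linked zygotic genes carry a per-gene
compensation target c in [1.0, 2.0]: the expected male level is the
female level divided by c, so c = 2 is an uncompensated X (transcription
proportional to chromosome copy number) and c = 1 full compensation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import AllelicCounts, ExpressionData, GroundTruth
from .stages import ARMS, REPLICATES, STAGES

__all__ = [
    "SimConfig",
    "simulate_timecourse",
    "simulate_strain_pileups",
    "simulate_annotation",
    "simulate_utrs",
]

_BASES = np.array(["A", "C", "G", "T"])


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the study design: 14,833 annotated genes of which
    5,598 are maternal, 2,210 zygotic and 1,195 maternal+zygotic (the
    remainder silent in the early embryo), ~70% of genes carrying at
    least one fixed SNP, ~35x strain genome coverage, and per-gene X
    compensation targets uniform on [1.0, 2.0].
    """

    n_genes: int = 14833
    frac_x: float = 0.16
    frac_maternal: float = 5598 / 14833
    frac_zygotic: float = 2210 / 14833
    frac_mat_zyg: float = 1195 / 14833
    frac_with_snp: float = 0.70
    stages: tuple[str, ...] = STAGES
    replicates: tuple[int, ...] = REPLICATES
    #: maternal pool decays as exp(-decay_rate * t) on the stage index.
    decay_rate: float = 0.30
    #: logistic zygotic onset: midpoint stage index and steepness.
    onset_stage: float = 5.0
    onset_steepness: float = 1.5
    #: per-gene F:M target for X-linked zygotic transcription, sampled
    #: uniformly on this closed interval (lo == hi pins the value).
    compensation: tuple[float, float] = (1.0, 2.0)
    #: sd of the gene x sample multiplicative lognormal noise (natural log).
    noise_sd: float = 0.25
    #: informative reads per sample ~ Poisson(depth_mean * RPKM).
    depth_mean: float = 0.5
    #: log-scale location/spread of kinetic amplitudes (median ~e^3=20 RPKM).
    log_level_mu: float = 3.0
    log_level_sd: float = 1.0
    #: constant background of silent genes, and their per-sample dropout.
    silent_level: float = 0.05
    silent_zero_prob: float = 0.9
    # -- strain-genome / pileup parameters ---------------------------------
    #: explicit pileup geometry; when n_fixed_snps is None, fixed SNPs are
    #: instead planted inside exons of the genes flagged as SNP-carrying.
    n_positions: int | None = None
    n_fixed_snps: int | None = None
    coverage: float = 35.0
    seq_error_rate: float = 0.002
    #: mean number of extra fixed SNPs per SNP-carrying gene (coupled mode).
    snps_per_gene: float = 0.5
    # -- 3'UTR parameters --------------------------------------------------
    utr_length: int = 300
    utr_site_rate_x: float = 1.2
    utr_site_rate_auto: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        fr = (self.frac_maternal, self.frac_zygotic, self.frac_mat_zyg)
        if any(f < 0 for f in fr) or sum(fr) > 1 + 1e-12:
            raise ConfigError("class fractions must be nonnegative and sum to <= 1")
        if not 0 <= self.frac_x <= 1 or not 0 <= self.frac_with_snp <= 1:
            raise ConfigError("frac_x and frac_with_snp must lie in [0, 1]")
        if len(self.stages) != 8:
            raise ConfigError("stage axis must have exactly 8 stages")
        if len(self.replicates) != 8 or any(r < 1 for r in self.replicates):
            raise ConfigError("replicates must give a positive count per stage")
        lo, hi = self.compensation
        if not 1.0 <= lo <= hi:
            raise ConfigError("compensation interval must satisfy 1 <= lo <= hi")
        if self.noise_sd < 0 or self.depth_mean < 0 or self.coverage < 0:
            raise ConfigError("noise_sd, depth_mean and coverage must be nonnegative")
        if (self.n_positions is None) != (self.n_fixed_snps is None):
            raise ConfigError("set n_positions and n_fixed_snps together or neither")
        if self.n_fixed_snps is not None and self.n_fixed_snps > self.n_positions:
            raise ConfigError("n_fixed_snps cannot exceed n_positions")


def _children(cfg: SimConfig) -> dict[str, np.random.Generator]:
    """Independent per-stage RNG streams derived from the single seed."""
    names = ("genes", "timecourse", "pileups", "utrs")
    seqs = np.random.SeedSequence(cfg.seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, seqs)}


# ---------------------------------------------------------------------------
# gene table + annotation
# ---------------------------------------------------------------------------

def _simulate_genes(cfg: SimConfig) -> pd.DataFrame:
    """Gene table with class, arm, coordinates, kinetics — the shared truth.

    Deterministic given cfg.seed; both the time-course and the pileup
    generators derive it identically, so planted SNPs, annotation and
    allele counts refer to the same genes.
    """
    cfg.validate()
    rng = _children(cfg)["genes"]
    n = cfg.n_genes
    counts = [int(round(f * n)) for f in (cfg.frac_maternal, cfg.frac_zygotic, cfg.frac_mat_zyg)]
    if sum(counts) > n:  # rounding overflow at extreme fractions
        counts[-1] -= sum(counts) - n
    labels = (
        ["maternal"] * counts[0]
        + ["zygotic"] * counts[1]
        + ["maternal_zygotic"] * counts[2]
        + ["silent"] * (n - sum(counts))
    )
    true_class = np.array(labels)
    rng.shuffle(true_class)

    on_x = rng.random(n) < cfg.frac_x
    arm = np.where(on_x, "X", rng.choice([a for a in ARMS if a != "X"], size=n))
    has_snp = rng.random(n) < cfg.frac_with_snp
    lo, hi = cfg.compensation
    compensation = np.where(on_x, rng.uniform(lo, hi, size=n), 1.0)

    m0 = rng.lognormal(cfg.log_level_mu, cfg.log_level_sd, size=n)
    zmax = rng.lognormal(cfg.log_level_mu, cfg.log_level_sd, size=n)
    m0[~np.isin(true_class, ["maternal", "maternal_zygotic"])] = 0.0
    zmax[~np.isin(true_class, ["zygotic", "maternal_zygotic"])] = 0.0

    genes = pd.DataFrame(
        {
            "chrom": arm,
            "true_class": true_class,
            "has_snp": has_snp,
            "compensation": compensation,
            "m0": m0,
            "zmax": zmax,
        },
        index=pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id"),
    )

    # lay genes sequentially along each arm: 1-3 exons, 500 bp introns
    n_exons = rng.integers(1, 4, size=n)
    starts_list, ends_list, lengths = [], [], np.zeros(n, dtype=int)
    cursor: dict[str, int] = {a: 1 for a in ARMS}
    order = np.argsort(arm, kind="stable")
    tx_start = np.zeros(n, dtype=int)
    for i in order:
        a = arm[i]
        s = cursor[a]
        exon_lens = rng.integers(200, 2001, size=n_exons[i])
        es, ee, pos = [], [], s
        for L in exon_lens:
            es.append(pos)
            ee.append(pos + int(L) - 1)
            pos = ee[-1] + 1 + 500
        starts_list.append((i, tuple(es)))
        ends_list.append((i, tuple(ee)))
        lengths[i] = int(exon_lens.sum())
        tx_start[i] = s
        cursor[a] = ee[-1] + 2000
    exon_starts = [None] * n
    exon_ends = [None] * n
    for i, es in starts_list:
        exon_starts[i] = es
    for i, ee in ends_list:
        exon_ends[i] = ee
    genes["exon_starts"] = exon_starts
    genes["exon_ends"] = exon_ends
    genes["length"] = lengths
    genes["strand"] = rng.choice(["+", "-"], size=n)
    return genes


def simulate_annotation(cfg: SimConfig) -> pd.DataFrame:
    """Gene annotation table (exon intervals, 1-based inclusive)."""
    g = _simulate_genes(cfg)
    return g[["chrom", "strand", "exon_starts", "exon_ends", "length"]].rename(
        columns={"length": "exonic_length"}
    )


# ---------------------------------------------------------------------------
# time course
# ---------------------------------------------------------------------------

def _expected_profiles(cfg: SimConfig, genes: pd.DataFrame):
    """Noise-free stage x sex expectations for every gene (closed form)."""
    t = np.arange(8.0)
    m0 = genes["m0"].to_numpy()[:, None]
    zmax = genes["zmax"].to_numpy()[:, None]
    maternal = m0 * np.exp(-cfg.decay_rate * t)[None, :]

    sig = 1.0 / (1.0 + np.exp(-cfg.onset_steepness * (t - cfg.onset_stage)))
    sig0 = 1.0 / (1.0 + np.exp(cfg.onset_steepness * cfg.onset_stage))
    rise = (sig - sig0) / (sig[-1] - sig0)  # 0 at C10, 1 at 14D
    zyg_f = zmax * rise[None, :]
    comp = genes["compensation"].to_numpy()[:, None]
    zyg_m = np.where((genes["chrom"] == "X").to_numpy()[:, None], zyg_f / comp, zyg_f)

    silent = (genes["true_class"] == "silent").to_numpy()[:, None]
    base = np.where(silent, cfg.silent_level, 0.0)
    exp_f = maternal + zyg_f + base
    exp_m = maternal + zyg_m + base
    cols = list(cfg.stages)
    idx = genes.index
    as_df = lambda a: pd.DataFrame(a, index=idx, columns=cols)
    return as_df(maternal), as_df(zyg_f), as_df(zyg_m), as_df(exp_f), as_df(exp_m)


def sample_sheet(cfg: SimConfig) -> pd.DataFrame:
    """The 24-embryo design: sample metadata in table order (females first)."""
    rows = []
    for sex in ("F", "M"):
        for stage, nrep in zip(cfg.stages, cfg.replicates):
            for r in range(1, nrep + 1):
                sid = f"{sex}{stage}" + (f"_{r}" if nrep > 1 else "")
                rows.append((sid, sex, stage, r))
    df = pd.DataFrame(rows, columns=["sample_id", "sex", "stage", "replicate"])
    return df.set_index("sample_id")


def simulate_timecourse(
    cfg: SimConfig,
) -> tuple[ExpressionData, AllelicCounts, GroundTruth]:
    """Simulate the 24-sample expression matrix and allelic read counts.

    Observed RPKM = expected level x lognormal(0, noise_sd) noise per
    gene x sample (silent genes additionally drop to exactly 0 with
    probability ``silent_zero_prob``, emulating undetected genes).
    Informative read depth is Poisson(depth_mean x RPKM) for genes
    carrying a SNP and 0 otherwise; the paternal share of those reads is
    Binomial with the gene's expected zygotic-biallelic fraction
    (0 on the male X, 1/2 of the zygotic component elsewhere).
    """
    genes = _simulate_genes(cfg)
    rng = _children(cfg)["timecourse"]
    samples = sample_sheet(cfg)
    maternal_p, zyg_f, zyg_m, exp_f, exp_m = _expected_profiles(cfg, genes)

    n_g, n_s = len(genes), len(samples)
    stage_pos = [list(cfg.stages).index(st) for st in samples["stage"]]
    expected = np.empty((n_g, n_s))
    pat_frac = np.empty((n_g, n_s))
    on_x = (genes["chrom"] == "X").to_numpy()
    for j, (sid, meta) in enumerate(samples.iterrows()):
        sp = stage_pos[j]
        if meta["sex"] == "F":
            tot, zyg = exp_f.iloc[:, sp].to_numpy(), zyg_f.iloc[:, sp].to_numpy()
            pf = np.divide(zyg / 2.0, tot, out=np.zeros(n_g), where=tot > 0)
        else:
            tot, zyg = exp_m.iloc[:, sp].to_numpy(), zyg_m.iloc[:, sp].to_numpy()
            pf = np.divide(zyg / 2.0, tot, out=np.zeros(n_g), where=tot > 0)
            pf[on_x] = 0.0  # no paternal X in males
        expected[:, j] = tot
        pat_frac[:, j] = pf

    noise = np.exp(rng.normal(0.0, cfg.noise_sd, size=(n_g, n_s))) if cfg.noise_sd > 0 else 1.0
    rpkm = expected * noise
    silent = (genes["true_class"] == "silent").to_numpy()
    if cfg.silent_zero_prob > 0:
        drop = rng.random((silent.sum(), n_s)) < cfg.silent_zero_prob
        block = rpkm[silent]
        block[drop] = 0.0
        rpkm[silent] = block

    depth_mean = cfg.depth_mean * rpkm
    depth_mean[~genes["has_snp"].to_numpy()] = 0.0
    depth = rng.poisson(depth_mean)
    paternal = rng.binomial(depth, pat_frac)
    maternal_reads = depth - paternal

    idx, cols = genes.index, samples.index
    expr = ExpressionData(
        rpkm=pd.DataFrame(rpkm, index=idx, columns=cols),
        genes=genes[["chrom", "length"]].copy(),
        samples=samples.copy(),
    )
    counts = AllelicCounts(
        maternal=pd.DataFrame(maternal_reads, index=idx, columns=cols),
        paternal=pd.DataFrame(paternal, index=idx, columns=cols),
    )
    truth = GroundTruth(
        genes=genes,
        expected_female=exp_f,
        expected_male=exp_m,
        maternal_profile=maternal_p,
        zygotic_female=zyg_f,
        zygotic_male=zyg_m,
    )
    return expr, counts, truth


# ---------------------------------------------------------------------------
# strain pileups
# ---------------------------------------------------------------------------

def _clean_column(rng, base: str, depth: int, error_rate: float) -> dict[str, int]:
    """Counts for a near-monomorphic site: errors capped below the 5% rule."""
    e = int(min(rng.binomial(depth, error_rate), depth // 20))
    counts = {b: 0 for b in _BASES}
    counts[base] = depth - e
    if e:
        other = rng.choice([b for b in _BASES if b != base])
        counts[other] = e
    return counts


def simulate_strain_pileups(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate per-strain pileups and the truth table of site categories.

    Returns ``(pileup_a, pileup_b, truth)``.  Pileups have columns
    ``chrom pos ref A C G T N``.  The truth table labels every position:

    * ``fixed`` — genuinely fixed difference, guaranteed callable (depth
      >= 13 in both strains, sequencing errors capped below 5%);
    * ``low_depth`` — alleles differ but one strain has < 13 reads;
    * ``polymorphic`` — one strain carries residual within-strain
      polymorphism (60/40 base mix), failing the 95% rule;
    * ``identical`` — both strains share the consensus base.

    By default fixed SNPs are planted inside exons of the genes flagged
    ``has_snp`` in the shared gene table (one + Poisson(snps_per_gene)
    per gene), so SNP calling and gene-overlap counting can be checked
    against the time-course truth.  Setting ``n_positions`` and
    ``n_fixed_snps`` decouples the pileups from the gene table.
    """
    cfg.validate()
    rng = _children(cfg)["pileups"]

    rows = []  # (chrom, pos, status, gene_id)
    if cfg.n_fixed_snps is None:
        genes = _simulate_genes(cfg)
        carriers = genes[genes["has_snp"]]
        for gid, g in carriers.iterrows():
            k = 1 + rng.poisson(cfg.snps_per_gene)
            exon_pos = np.concatenate(
                [np.arange(s, e + 1) for s, e in zip(g["exon_starts"], g["exon_ends"])]
            )
            for p in rng.choice(exon_pos, size=min(k, len(exon_pos)), replace=False):
                rows.append((g["chrom"], int(p), "fixed", gid))
        n_decoy = max(1, len(rows) // 10)
        for status in ("low_depth", "polymorphic", "identical"):
            for _ in range(n_decoy):
                arm = rng.choice(ARMS)
                pos = int(rng.integers(10_000_000, 20_000_000))  # intergenic
                rows.append((arm, pos, status, ""))
    else:
        n_other = cfg.n_positions - cfg.n_fixed_snps
        statuses = ["fixed"] * cfg.n_fixed_snps + [
            ("low_depth", "polymorphic", "identical")[i % 3] for i in range(n_other)
        ]
        pos_pool = rng.choice(
            np.arange(1, max(10 * cfg.n_positions, 1000)), size=cfg.n_positions, replace=False
        )
        rows = [("2L", int(p), s, "") for p, s in zip(np.sort(pos_pool), statuses)]

    # drop duplicate coordinates (possible across genes/decoys)
    seen, uniq = set(), []
    for r in rows:
        if (r[0], r[1]) not in seen:
            seen.add((r[0], r[1]))
            uniq.append(r)
    rows = uniq

    piles = {"A": [], "B": []}
    truth_rows = []
    extra_depth = max(cfg.coverage - 13.0, 0.0)
    for chrom, pos, status, gid in rows:
        base_a = rng.choice(_BASES)
        base_b = rng.choice([b for b in _BASES if b != base_a])
        da = 13 + int(rng.poisson(extra_depth))
        db = 13 + int(rng.poisson(extra_depth))
        if status == "fixed":
            ca = _clean_column(rng, base_a, da, cfg.seq_error_rate)
            cb = _clean_column(rng, base_b, db, cfg.seq_error_rate)
        elif status == "low_depth":
            short = rng.choice(["A", "B"])
            if short == "A":
                da = int(rng.integers(0, 13))
                ca = _clean_column(rng, base_a, da, 0.0)
                cb = _clean_column(rng, base_b, db, cfg.seq_error_rate)
            else:
                db = int(rng.integers(0, 13))
                ca = _clean_column(rng, base_a, da, cfg.seq_error_rate)
                cb = _clean_column(rng, base_b, db, 0.0)
        elif status == "polymorphic":
            ca = _clean_column(rng, base_a, da, cfg.seq_error_rate)
            nb1 = int(round(0.6 * db))
            cb = {b: 0 for b in _BASES}
            cb[base_b] = nb1
            cb[base_a] = db - nb1
        else:  # identical
            base_b = base_a
            ca = _clean_column(rng, base_a, da, cfg.seq_error_rate)
            cb = _clean_column(rng, base_a, db, cfg.seq_error_rate)
        n_amb_a, n_amb_b = int(rng.poisson(0.1)), int(rng.poisson(0.1))
        piles["A"].append((chrom, pos, base_a, ca["A"], ca["C"], ca["G"], ca["T"], n_amb_a))
        piles["B"].append((chrom, pos, base_a, cb["A"], cb["C"], cb["G"], cb["T"], n_amb_b))
        truth_rows.append((chrom, pos, status, base_a, base_b, gid))

    cols = ["chrom", "pos", "ref", "A", "C", "G", "T", "N"]
    pile_a = pd.DataFrame(piles["A"], columns=cols)
    pile_b = pd.DataFrame(piles["B"], columns=cols)
    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "pos", "status", "allele_a", "allele_b", "gene_id"]
    )
    order = np.lexsort((truth["pos"], truth["chrom"]))
    return (
        pile_a.iloc[order].reset_index(drop=True),
        pile_b.iloc[order].reset_index(drop=True),
        truth.iloc[order].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# 3'UTRs with planted SXL sites
# ---------------------------------------------------------------------------

_SITE = "AUUUUUUU"
_RUN_CAP = re.compile("U{6,}")


def simulate_utrs(cfg: SimConfig, n_genes: int | None = None) -> pd.DataFrame:
    """3'UTR sequences with an exactly known number of SXL sites per gene.

    Background sequence has poly-U runs capped at five, so it can never
    contain a site; planted sites (AUUUUUUU or UUUUUUUU, chosen at
    random) are inserted with C flanks so they neither merge nor extend.
    X-linked genes receive Poisson(utr_site_rate_x) sites and autosomal
    genes Poisson(utr_site_rate_auto), emulating the X enrichment of
    predicted SXL targets.  Returns gene_id, arm, sequence, true_sites.
    """
    genes = _simulate_genes(cfg)
    if n_genes is not None:
        genes = genes.iloc[:n_genes]
    rng = _children(cfg)["utrs"]
    on_x = (genes["chrom"] == "X").to_numpy()
    n_sites = rng.poisson(np.where(on_x, cfg.utr_site_rate_x, cfg.utr_site_rate_auto))

    records = []
    for (gid, g), k in zip(genes.iterrows(), n_sites):
        raw = "".join(rng.choice(["A", "C", "G", "U"], size=cfg.utr_length))
        bg = _RUN_CAP.sub("UUUUU", raw)
        if k == 0:
            seq = bg
        else:
            cuts = np.sort(rng.integers(0, len(bg) + 1, size=int(k)))
            parts = []
            prev = 0
            for c in cuts:
                parts.append(bg[prev:c])
                site = _SITE if rng.random() < 0.5 else "UUUUUUUU"
                parts.append("C" + site + "C")
                prev = c
            parts.append(bg[prev:])
            seq = "".join(parts)
        records.append((gid, g["chrom"], seq, int(k)))
    return pd.DataFrame(records, columns=["gene_id", "arm", "sequence", "true_sites"]).set_index(
        "gene_id"
    )
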