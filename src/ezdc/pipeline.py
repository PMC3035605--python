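"""End-to-end orchestration: simulate -> call SNPs -> partition -> classify
-> score -> motif scan, with a reproducibility manifest.

A single global seed deterministically derives per-stage seeds (stable
child-seed derivation through numpy's SeedSequence), so any stage can be
rerun in isolation and two runs with the same configuration are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classify import ClassifyConfig, classify_all
from .containers import AllelicCounts, ExpressionData
from .dosage import chrom_aggregate, fm_ratio, ratio_bins, score_summary, score_table
from .motif import flag_targets
from .partition import impute_f13, male_x_paternal_violations, normalize_autosomal, partition_rpkm
from .simulate import SimConfig, simulate_annotation, simulate_strain_pileups, simulate_timecourse, simulate_utrs
from .snp import CallerConfig, call_fixed_snps, genes_with_snp, residual_polymorphism
from . import io

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every numeric threshold of the analysis, at its study default."""

    sim: SimConfig = field(default_factory=SimConfig)
    caller: CallerConfig = field(default_factory=CallerConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    min_rpkm: float = 2.0       # both-sexes floor for F:M ratios
    min_max_rpkm: float = 3.0   # expression filter for compensation scores
    min_sites: int = 3          # SXL sites to flag a predicted target
    impute_f13: bool = False    # replace female C13 by mean(F C12, F 14A)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (("sim", SimConfig), ("caller", CallerConfig), ("classify", ClassifyConfig)):
            if key in d and isinstance(d[key], dict):
                payload = dict(d[key])
                for tup in ("stages", "replicates", "compensation"):
                    if tup in payload and isinstance(payload[tup], list):
                        payload[tup] = tuple(payload[tup])
                d[key] = sub(**payload)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def child_seeds(seed: int, n: int = 8) -> list[int]:
    """Stable per-stage seeds (< 2^31) derived from one global seed."""
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % 2**31) for s in state]


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"{what} not found: {path}")
    return path


def run_all(cfg: PipelineConfig, outdir, simulate: bool = True, inputs: dict | None = None) -> Path:
    """Execute the full pipeline; returns the output directory.

    With ``simulate=True`` all inputs come from the synthetic generator
    (seeded from cfg.seed).  Otherwise ``inputs`` must name real files:
    ``expr_prefix`` (expression TSV trio), ``counts``, and optionally
    ``pileup_a``/``pileup_b``, ``annotation``, ``utrs``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    seeds = child_seeds(cfg.seed)
    summary: dict = {}

    utrs = None
    snps = truth = None
    if simulate:
        sim_cfg = replace(cfg.sim, seed=seeds[0])
        pile_a, pile_b, snp_truth = simulate_strain_pileups(sim_cfg)
        expr, counts, truth = simulate_timecourse(sim_cfg)
        annotation = simulate_annotation(sim_cfg)
        utrs = simulate_utrs(sim_cfg)
        io.write_pileup(pile_a, out / "strain_a.pileup.tsv")
        io.write_pileup(pile_b, out / "strain_b.pileup.tsv")
        io.write_table(snp_truth, out / "snp_truth.tsv", index=False)
        io.write_table(truth.genes, out / "truth.tsv")
        io.write_expression(expr, out / "timecourse")
        io.write_allelic_counts(counts, out / "allelic_counts.tsv")
        io.write_annotation(annotation, out / "annotation.tsv")
        io.write_utr_fasta(utrs, out / "utrs.fa")
    else:
        inputs = inputs or {}
        prefix = _require(Path(str(inputs["expr_prefix"]) + ".rpkm.tsv"), "expression matrix")
        expr = io.read_expression(inputs["expr_prefix"])
        counts = io.read_allelic_counts(
            _require(Path(inputs["counts"]), "allelic counts"),
            genes=expr.rpkm.index, samples=expr.rpkm.columns,
        )
        pile_a = io.read_pileup(_require(Path(inputs["pileup_a"]), "strain A pileup")) if "pileup_a" in inputs else None
        pile_b = io.read_pileup(_require(Path(inputs["pileup_b"]), "strain B pileup")) if "pileup_b" in inputs else None
        annotation = io.read_annotation(_require(Path(inputs["annotation"]), "annotation")) if "annotation" in inputs else None
        utrs = io.read_utr_fasta(_require(Path(inputs["utrs"]), "3'UTR FASTA")) if "utrs" in inputs else None

    # --- SNP calling ------------------------------------------------------
    if simulate or (pile_a is not None and pile_b is not None):
        snps = call_fixed_snps(pile_a, pile_b, cfg.caller)
        io.write_snps(snps, out / "snps.tsv")
        io.write_snps_vcf(snps, out / "snps.vcf")
        io.write_table(residual_polymorphism(pile_a, cfg.caller), out / "residual_a.tsv", index=False)
        io.write_table(residual_polymorphism(pile_b, cfg.caller), out / "residual_b.tsv", index=False)
        summary["n_fixed_snps"] = int(len(snps))
        if annotation is not None:
            per_gene = genes_with_snp(snps, annotation)
            io.write_table(per_gene.to_frame(), out / "snps_per_gene.tsv")
            summary["n_genes_with_snp"] = int((per_gene > 0).sum())
            summary["n_genes_annotated"] = int(len(per_gene))

    # --- normalization / partition ---------------------------------------
    expr_n = normalize_autosomal(expr)
    if cfg.impute_f13:
        expr_n = impute_f13(expr_n)
    part = partition_rpkm(expr_n, counts)
    io.write_table(part.maternal.rename_axis("gene_id"), out / "maternal_component.tsv")
    io.write_table(part.paternal.rename_axis("gene_id"), out / "paternal_component.tsv")
    violations = male_x_paternal_violations(counts, expr_n)
    io.write_table(violations, out / "male_x_violations.tsv", index=False)
    summary["n_male_x_paternal_violations"] = int(len(violations))

    # --- classification ---------------------------------------------------
    cls_cfg = replace(cfg.classify, seed=seeds[1])
    classes, model = classify_all(part, expr_n, counts, cls_cfg)
    io.write_table(classes, out / "classes.tsv")
    centers = model.centers_log
    import pandas as pd

    dump = pd.DataFrame(centers, columns=[f"m_{i}" for i in range(8)] + [f"p_{i}" for i in range(8)])
    dump.insert(0, "label", model.labels)
    dump.insert(1, "size", model.sizes)
    io.write_table(dump.rename_axis("cluster_id"), out / "cluster_model.tsv")
    summary["class_counts"] = classes["class"].value_counts().to_dict()
    summary["n_clustered"] = int((classes["route"] == "direct").sum())

    # --- dosage compensation ---------------------------------------------
    scores = score_table(expr_n, classes, cfg.min_max_rpkm)
    io.write_table(scores.rename_axis("gene_id"), out / "scores.tsv")
    io.write_table(score_summary(scores), out / "score_summary.tsv")
    ratios = fm_ratio(expr_n, classes, cfg.min_rpkm)
    io.write_table(ratios.rename_axis("gene_id"), out / "ratios.tsv")
    io.write_table(ratio_bins(ratios, expr_n.genes), out / "bins.tsv", index=False)
    io.write_table(chrom_aggregate(part, expr_n, classes), out / "aggregates.tsv", index=False)
    x_scores = scores.loc[scores["chrom"] == "X", "score"].dropna()
    if len(x_scores):
        summary["x_scores"] = {
            "n": int(len(x_scores)),
            "n_gt_1.0": int((x_scores > 1.0).sum()),
            "n_gt_1.5": int((x_scores > 1.5).sum()),
            "median": float(x_scores.median()),
        }

    # --- SXL motif scan ---------------------------------------------------
    if utrs is not None:
        per_gene, tally = flag_targets(utrs, cfg.min_sites)
        io.write_table(per_gene.rename_axis("gene_id"), out / "sxl_targets.tsv")
        io.write_table(tally.to_frame(), out / "sxl_tally.tsv")
        summary["n_sxl_targets"] = int(per_gene["flagged"].sum())
        summary["n_sxl_targets_x"] = int(tally.get("X", 0))

    manifest = {
        "package": "ezdc",
        "version": __version__,
        "seed": cfg.seed,
        "child_seeds": seeds,
        "config": cfg.to_dict(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return out
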