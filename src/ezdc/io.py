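"""Readers and writers for the package's plain-text table dialects.

All tables are tab-separated with a header row:

* pileup:        ``chrom pos ref A C G T N`` (1-based positions)
* SNPs:          caller output columns, plus a minimal sites-only VCF
* annotation:    ``gene_id chrom strand exon_starts exon_ends exonic_length``
                 with 1-based inclusive, comma-separated exon coordinates
* expression:    ``gene_id`` + one column per sample; gene metadata
                 (``gene_id chrom length``) and sample metadata
                 (``sample_id sex stage replicate``) ride in side tables
* allelic counts: long ``gene_id sample_id maternal_reads paternal_reads``
* 3'UTRs:        FASTA with headers ``<gene_id> arm=<arm>``

GTF annotation is read through :mod:`gffutils`; FASTA through Bio.SeqIO.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import AllelicCounts, ExpressionData

PILEUP_COLS = ["chrom", "pos", "ref", "A", "C", "G", "T", "N"]


# -- pileups ---------------------------------------------------------------

def write_pileup(pile: pd.DataFrame, path) -> None:
    pile[PILEUP_COLS].to_csv(path, sep="\t", index=False)


def read_pileup(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PILEUP_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup {path} lacks column(s) {sorted(missing)}")
    return df


# -- SNP tables ------------------------------------------------------------

def write_snps(snps: pd.DataFrame, path) -> None:
    snps.to_csv(path, sep="\t", index=False)


def read_snps(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_snps_vcf(snps: pd.DataFrame, path) -> None:
    """Minimal sites-only VCF: strain alleles in INFO (SA/SB/DPA/DPB)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SA,Number=1,Type=String,Description="Strain A allele">\n')
        fh.write('##INFO=<ID=SB,Number=1,Type=String,Description="Strain B allele">\n')
        fh.write('##INFO=<ID=DPA,Number=1,Type=Integer,Description="Strain A depth">\n')
        fh.write('##INFO=<ID=DPB,Number=1,Type=Integer,Description="Strain B depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in snps.itertuples(index=False):
            ref = row.allele_a
            alt = row.allele_b
            info = f"SA={row.allele_a};SB={row.allele_b};DPA={row.depth_a};DPB={row.depth_b}"
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n")


# -- annotation ------------------------------------------------------------

def _fmt_ints(values) -> str:
    return ",".join(str(int(v)) for v in values)


def write_annotation(annot: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "gene_id": annot.index,
            "chrom": annot["chrom"].to_numpy(),
            "strand": annot["strand"].to_numpy(),
            "exon_starts": [_fmt_ints(v) for v in annot["exon_starts"]],
            "exon_ends": [_fmt_ints(v) for v in annot["exon_ends"]],
            "exonic_length": annot["exonic_length"].to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"exon_starts": str, "exon_ends": str})
    df["exon_starts"] = df["exon_starts"].map(lambda s: tuple(int(x) for x in s.split(",")))
    df["exon_ends"] = df["exon_ends"].map(lambda s: tuple(int(x) for x in s.split(",")))
    return df.set_index("gene_id")


def read_gtf_annotation(path) -> pd.DataFrame:
    """Build the annotation table from a GTF file (exon features).

    Exons are grouped by the ``gene_id`` attribute and overlapping exons
    merged, so exonic_length counts each base once.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    rows: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        gid = exon.attributes["gene_id"][0]
        rec = rows.setdefault(
            gid, {"chrom": exon.seqid, "strand": exon.strand, "ivals": []}
        )
        rec["ivals"].append((exon.start, exon.end))
    out = []
    for gid, rec in rows.items():
        merged: list[list[int]] = []
        for s, e in sorted(rec["ivals"]):
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        starts = tuple(s for s, _ in merged)
        ends = tuple(e for _, e in merged)
        out.append(
            (gid, rec["chrom"], rec["strand"], starts, ends,
             sum(e - s + 1 for s, e in merged))
        )
    return pd.DataFrame(
        out, columns=["gene_id", "chrom", "strand", "exon_starts", "exon_ends", "exonic_length"]
    ).set_index("gene_id")


# -- expression + metadata -------------------------------------------------

def write_expression(expr: ExpressionData, prefix) -> None:
    """Write <prefix>.rpkm.tsv, <prefix>.genes.tsv, <prefix>.samples.tsv."""
    prefix = Path(prefix)
    expr.rpkm.rename_axis("gene_id").to_csv(f"{prefix}.rpkm.tsv", sep="\t")
    expr.genes[["chrom", "length"]].rename_axis("gene_id").to_csv(
        f"{prefix}.genes.tsv", sep="\t"
    )
    expr.samples.rename_axis("sample_id").to_csv(f"{prefix}.samples.tsv", sep="\t")


def read_expression(prefix) -> ExpressionData:
    prefix = Path(prefix)
    rpkm = pd.read_csv(f"{prefix}.rpkm.tsv", sep="\t", index_col="gene_id")
    rpkm.columns.name = "sample_id"
    genes = pd.read_csv(f"{prefix}.genes.tsv", sep="\t", index_col="gene_id")
    samples = pd.read_csv(f"{prefix}.samples.tsv", sep="\t", index_col="sample_id")
    return ExpressionData(rpkm=rpkm, genes=genes, samples=samples)


def write_allelic_counts(counts: AllelicCounts, path) -> None:
    m = counts.maternal.rename_axis("gene_id").stack()
    p = counts.paternal.rename_axis("gene_id").stack()
    long = pd.DataFrame({"maternal_reads": m, "paternal_reads": p}).reset_index()
    long.columns = ["gene_id", "sample_id", "maternal_reads", "paternal_reads"]
    long.to_csv(path, sep="\t", index=False)


def read_allelic_counts(path, genes=None, samples=None) -> AllelicCounts:
    long = pd.read_csv(path, sep="\t")
    m = long.pivot(index="gene_id", columns="sample_id", values="maternal_reads")
    p = long.pivot(index="gene_id", columns="sample_id", values="paternal_reads")
    if genes is not None:
        m, p = m.reindex(genes), p.reindex(genes)
    if samples is not None:
        m, p = m[list(samples)], p[list(samples)]
    return AllelicCounts(maternal=m.fillna(0).astype(int), paternal=p.fillna(0).astype(int))


# -- 3'UTR FASTA -----------------------------------------------------------

def write_utr_fasta(utrs: pd.DataFrame, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(row.sequence), id=str(gid), description=f"arm={row.arm}")
        for gid, row in utrs.iterrows()
    ]
    seqio_write(records, str(path), "fasta")


def read_utr_fasta(path) -> pd.DataFrame:
    """FASTA -> table (gene_id, arm, sequence); arm from an ``arm=`` tag."""
    from Bio import SeqIO

    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        arm = ""
        for token in rec.description.split():
            if token.startswith("arm="):
                arm = token[4:]
        rows.append((rec.id, arm, str(rec.seq)))
    return pd.DataFrame(rows, columns=["gene_id", "arm", "sequence"]).set_index("gene_id")


# -- simple tables ---------------------------------------------------------

def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
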