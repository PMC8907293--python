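"""Readers and writers for the pipeline's text formats.

Genotype dosage TSV (rows = samples, columns = variants, '.' for
missing), sample tables, BED3+ annotation tracks (0-based half-open),
gene-TSS tables, FASTA promoters (via Biopython), variant tables, and a
read-only VCF ingester (GT field to 0/1/2 dosages, via pysam).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from enhscreen.assoc import SampleTable
from enhscreen.qc import GenotypeMatrix, VariantRecord
from enhscreen.regscreen import AnnotationTrack, GeneModel

MISSING = "."

__all__ = [
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_sample_tsv",
    "write_sample_tsv",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_gene_tss",
    "write_gene_tss",
    "read_variant_table",
    "write_variant_table",
    "read_vcf_genotypes",
]


def write_genotype_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(gm.dosages, index=gm.sample_ids, columns=gm.variant_ids)
    out = df.map(lambda v: MISSING if not np.isfinite(v) else str(int(v)))
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    dosages = df.replace(MISSING, np.nan).astype(float).to_numpy()
    return GenotypeMatrix(list(df.index), list(df.columns), dosages)


def write_sample_tsv(samples: SampleTable, path: str | Path) -> None:
    samples.df.to_csv(path, sep="\t", index=False)


def read_sample_tsv(path: str | Path) -> SampleTable:
    return SampleTable(pd.read_csv(path, sep="\t"))


def write_bed(track: AnnotationTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.intervals):
            for start, end in track.intervals[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\t{track.name}\n")


def read_bed(path: str | Path, name: str | None = None) -> AnnotationTrack:
    intervals = []
    track_name = name or Path(path).stem
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            intervals.append((fields[0], int(fields[1]), int(fields[2])))
    if not intervals:
        return AnnotationTrack(track_name, {})
    return AnnotationTrack.from_intervals(track_name, intervals)


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=seq_id, description="") for seq_id, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")  # Biopython wraps at 60 columns


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_gene_tss(genes: list[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.tss_pos, g.strand) for g in genes],
        columns=["gene_id", "chrom", "tss_pos", "strand"],
    ).to_csv(path, sep="\t", index=False)


def read_gene_tss(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    return [
        GeneModel(r.gene_id, str(r.chrom), int(r.tss_pos), r.strand)
        for r in df.itertuples()
    ]


def write_variant_table(variants: list[VariantRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            (v.variant_id, v.chrom, v.pos, v.effect_allele, v.other_allele)
            for v in variants
        ],
        columns=["variant_id", "chrom", "pos", "effect_allele", "other_allele"],
    ).to_csv(path, sep="\t", index=False)


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        VariantRecord(r.variant_id, str(r.chrom), int(r.pos), r.effect_allele, r.other_allele)
        for r in df.itertuples()
    ]


def read_vcf_genotypes(
    path: str | Path,
) -> tuple[GenotypeMatrix, list[VariantRecord]]:
    """Ingest a (plain-text) VCF: GT field to effect-allele dosages.

    The ALT allele is taken as the coded effect allele, so each dosage is
    the ALT-allele count in the GT call; missing calls become NaN. Only
    biallelic records are accepted.
    """
    import pysam

    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_ids = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"{rec.id or rec.pos}: only biallelic records supported")
            vid = rec.id or f"{rec.chrom}:{rec.pos}"
            variants.append(
                VariantRecord(vid, rec.chrom, rec.pos, rec.alts[0], rec.ref)
            )
            col = np.full(len(sample_ids), np.nan)
            for i, sample in enumerate(sample_ids):
                gt = rec.samples[sample].get("GT")
                if gt is None or any(al is None for al in gt):
                    continue
                col[i] = float(sum(gt))
            columns.append(col)
    dosages = (
        np.column_stack(columns) if columns else np.empty((len(sample_ids), 0))
    )
    gm = GenotypeMatrix(sample_ids, [v.variant_id for v in variants], dosages)
    return gm, variants
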