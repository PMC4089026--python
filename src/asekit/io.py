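"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; VCF (1-based) is
converted at the boundary.  All text readers transparently accept gzip.
"""

from __future__ import annotations

import gzip
import io as _stdio
import os
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .table import KEY_COLS, AlleleCountTable
from .types import DNasePeak, GeneModel, GenomicInterval, SampleInfo, VariantSite

__all__ = [
    "read_variants", "write_variants",
    "read_gene_models", "write_gene_models",
    "read_narrowpeak",
    "read_count_table", "write_count_table",
    "read_fasta", "write_fasta",
]


def _open_text(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_variants(
    path,
    annotation_key: str = "ANN",
    gene_key: str = "GENE",
    default_annotation: str = "exonic",
    split_multiallelic: bool = False,
) -> List[VariantSite]:
    """Read biallelic B/D variant sites from a VCF.

    VCF 1-based POS becomes the internal 0-based ``pos``.  The functional
    annotation is taken from INFO key ``annotation_key`` (falling back to
    ``default_annotation``) and the gene assignment from ``gene_key``.
    Multi-allelic records are split into one site per ALT when
    ``split_multiallelic`` is true, and rejected otherwise.
    """
    sites: List[VariantSite] = []
    try:
        vf = pysam.VariantFile(os.fspath(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        for i, rec in enumerate(vf, start=1):
            alts = rec.alts or ()
            if len(alts) == 0:
                continue
            if len(alts) > 1 and not split_multiallelic:
                raise ValueError(
                    f"{path}: multi-allelic record at line ~{i} "
                    f"({rec.chrom}:{rec.pos}); set split_multiallelic=True"
                )
            ann = rec.info.get(annotation_key, default_annotation)
            if isinstance(ann, tuple):
                ann = ann[0]
            gene = rec.info.get(gene_key, None)
            if isinstance(gene, tuple):
                gene = gene[0]
            for alt in alts:
                if alt == rec.ref:
                    raise ValueError(
                        f"{path}: REF==ALT at {rec.chrom}:{rec.pos}"
                    )
                kind = "snp" if len(rec.ref) == 1 and len(alt) == 1 else "indel"
                sites.append(
                    VariantSite(
                        chrom=rec.chrom,
                        pos=rec.start,  # pysam .start is already 0-based
                        b_allele=rec.ref,
                        d_allele=alt,
                        kind=kind,
                        annotation=str(ann),
                        gene_id=gene,
                    )
                )
    return sites


def write_variants(
    sites: List[VariantSite],
    path,
    annotation_key: str = "ANN",
    gene_key: str = "GENE",
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Write variant sites as a minimal VCF (internal 0-based -> POS 1-based)."""
    header = pysam.VariantHeader()
    header.add_line(
        f'##INFO=<ID={annotation_key},Number=1,Type=String,'
        f'Description="Functional annotation">'
    )
    header.add_line(
        f'##INFO=<ID={gene_key},Number=1,Type=String,Description="Gene id">'
    )
    chroms = {}
    for s in sites:
        chroms[s.chrom] = max(chroms.get(s.chrom, 0), s.pos + len(s.b_allele))
    for chrom, minlen in chroms.items():
        length = (contig_lengths or {}).get(chrom, minlen + 1)
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for s in sorted(sites, key=lambda v: (v.chrom, v.pos)):
            rec = out.new_record(
                contig=s.chrom, start=s.pos, stop=s.pos + len(s.b_allele),
                alleles=(s.b_allele, s.d_allele),
            )
            rec.info[annotation_key] = s.annotation
            if s.gene_id is not None:
                rec.info[gene_key] = s.gene_id
            out.write(rec)


# ---------------------------------------------------------------------------
# BED12 gene models
# ---------------------------------------------------------------------------

_BED12_COLS = [
    "chrom", "chromStart", "chromEnd", "name", "score", "strand",
    "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes",
    "blockStarts",
]


def read_gene_models(path) -> List[GeneModel]:
    """Read gene models from BED12.

    Exons are reconstructed from the block fields (0-based half-open
    preserved).  The score column carries the known-isoform count
    (0 is read as 1): BED12 has no native field for it and the
    discordant-exon QC needs one.
    """
    df = pd.read_table(path, header=None, comment="#", dtype=str)
    if df.shape[1] < 12:
        raise ValueError(f"{path}: expected 12 BED columns, got {df.shape[1]}")
    df = df.iloc[:, :12]
    df.columns = _BED12_COLS
    genes: List[GeneModel] = []
    for line_no, row in enumerate(df.itertuples(index=False), start=1):
        start = int(row.chromStart)
        end = int(row.chromEnd)
        n_blocks = int(row.blockCount)
        sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
        offsets = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(offsets) != n_blocks:
            raise ValueError(
                f"{path} line {line_no}: blockCount inconsistent with "
                "blockSizes/blockStarts"
            )
        exons = []
        for off, size in zip(offsets, sizes):
            ex_start = start + off
            ex_end = ex_start + size
            if ex_end > end:
                raise ValueError(
                    f"{path} line {line_no}: block [{ex_start},{ex_end}) "
                    f"extends past chromEnd {end}"
                )
            exons.append(GenomicInterval(row.chrom, ex_start, ex_end, row.strand))
        n_iso = max(1, int(float(row.score)))
        genes.append(
            GeneModel(
                gene_id=row.name, chrom=row.chrom, strand=row.strand,
                exons=exons, n_isoforms=n_iso,
            )
        )
    return genes


def write_gene_models(genes: List[GeneModel], path) -> None:
    rows = []
    for g in genes:
        start = g.exons[0].start
        end = g.exons[-1].end
        sizes = ",".join(str(len(e)) for e in g.exons)
        offs = ",".join(str(e.start - start) for e in g.exons)
        rows.append(
            [g.chrom, start, end, g.gene_id, g.n_isoforms, g.strand,
             start, end, "0", len(g.exons), sizes, offs]
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# narrowPeak
# ---------------------------------------------------------------------------

def read_narrowpeak(path, replicate_id: int = 0) -> List[DNasePeak]:
    """Read ENCODE narrowPeak (10 columns); signal = column 7 (signalValue)."""
    df = pd.read_table(path, header=None, comment="#", dtype=str)
    if df.shape[1] != 10:
        raise ValueError(
            f"{path}: narrowPeak requires 10 columns, got {df.shape[1]}"
        )
    peaks = []
    for line_no, row in enumerate(df.itertuples(index=False), start=1):
        signal = float(row[6])
        if signal < 0:
            raise ValueError(f"{path} line {line_no}: negative signalValue")
        strand = row[5] if row[5] in ("+", "-") else "."
        peaks.append(
            DNasePeak(
                interval=GenomicInterval(row[0], int(row[1]), int(row[2]), strand),
                signal=signal,
                replicate_id=replicate_id,
            )
        )
    return peaks


# ---------------------------------------------------------------------------
# Allele-count TSV
# ---------------------------------------------------------------------------

def write_count_table(counts: AlleleCountTable, path) -> None:
    """Write an allele-count table as TSV with sample metadata header lines."""
    with open(path, "w") as fh:
        for s in counts.samples:
            fh.write(f"#sample\t{s.name}\tcross={s.cross}\tsex={s.sex}\n")
        counts.df.to_csv(fh, sep="\t", index=False)


def read_count_table(path) -> AlleleCountTable:
    samples: List[SampleInfo] = []
    with _open_text(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if line.startswith("#sample\t"):
            _, name, crossf, sexf = line.rstrip("\n").split("\t")
            samples.append(
                SampleInfo(name=name, cross=crossf.split("=", 1)[1],
                           sex=sexf.split("=", 1)[1])
            )
            body_start += 1
        else:
            break
    df = pd.read_table(_stdio.StringIO("".join(lines[body_start:])))
    expected = []
    for s in samples:
        expected += [f"{s.name}.b", f"{s.name}.d", f"{s.name}.other"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: header/sample mismatch, missing {missing}")
    for c in expected + ["pos"]:
        df[c] = df[c].astype(np.int64)
    return AlleleCountTable(df, samples)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> Dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
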