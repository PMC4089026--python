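"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based, half-open ([start, end)), matching the
native convention of BED and narrowPeak.  VCF is the only 1-based surface and
is converted on read/write by :mod:`asekit.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

_BASES = frozenset("ACGT")

VALID_ANNOTATIONS = frozenset(
    {"intronic", "exonic", "utr", "synonymous", "nonsynonymous",
     "stop_gain", "stop_loss"}
)


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name.
    start : int
        0-based inclusive start.
    end : int
        0-based exclusive end; must be > start.
    strand : str
        One of ``+``, ``-``, ``.``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class VariantSite:
    """One biallelic polymorphism between the B (reference) and D strains.

    ``pos`` is 0-based.  For SNPs both alleles are single bases; for indels
    the full REF/ALT strings are kept so that the affected reference span
    ``[pos, pos + len(b_allele))`` can be intersected with peaks.
    """

    chrom: str
    pos: int
    b_allele: str
    d_allele: str
    kind: str = "snp"  # {"snp", "indel"}
    annotation: str = "exonic"
    gene_id: Optional[str] = None

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError("pos must be >= 0")
        if self.b_allele == self.d_allele:
            raise ValueError(
                f"b and d alleles identical at {self.chrom}:{self.pos}"
            )
        if self.kind not in ("snp", "indel"):
            raise ValueError(f"invalid kind {self.kind!r}")
        if self.kind == "snp":
            if self.b_allele not in _BASES or self.d_allele not in _BASES:
                raise ValueError(
                    f"SNP alleles must be single bases in ACGT at "
                    f"{self.chrom}:{self.pos} "
                    f"({self.b_allele!r}/{self.d_allele!r})"
                )
        if self.annotation not in VALID_ANNOTATIONS:
            raise ValueError(f"invalid annotation {self.annotation!r}")

    @property
    def ref_span(self) -> GenomicInterval:
        """Reference interval affected by the variant (length 1 for SNPs)."""
        return GenomicInterval(self.chrom, self.pos, self.pos + len(self.b_allele))


@dataclass
class GeneModel:
    """A gene as an ordered set of non-overlapping exons on one chromosome."""

    gene_id: str
    chrom: str
    strand: str
    exons: list  # of GenomicInterval, sorted, non-overlapping
    n_isoforms: int = 1

    def __post_init__(self):
        if self.n_isoforms < 1:
            raise ValueError("n_isoforms must be >= 1")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(
                    f"exon on {ex.chrom} but gene {self.gene_id} on {self.chrom}"
                )
            if ex.start < prev_end:
                raise ValueError(
                    f"exons of {self.gene_id} overlap or are unsorted"
                )
            prev_end = ex.end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def exon_index_of(self, pos: int) -> Optional[int]:
        """0-based index of the exon containing ``pos``, or None (intronic)."""
        for i, ex in enumerate(self.exons):
            if ex.start <= pos < ex.end:
                return i
        return None


@dataclass(frozen=True)
class DNasePeak:
    """A DNase I hypersensitivity peak with its narrowPeak signalValue."""

    interval: GenomicInterval
    signal: float
    replicate_id: int = 0

    def __post_init__(self):
        if self.signal < 0:
            raise ValueError(
                f"negative signal {self.signal} at "
                f"{self.interval.chrom}:{self.interval.start}"
            )


@dataclass(frozen=True)
class SampleInfo:
    """One sequenced F1 pool: cross direction (maternal strain first) and sex."""

    name: str
    cross: str  # {"BxD", "DxB"}; BxD means the mother is strain B
    sex: str    # {"M", "F"}

    def __post_init__(self):
        if self.cross not in ("BxD", "DxB"):
            raise ValueError(f"invalid cross {self.cross!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"invalid sex {self.sex!r}")

    def maternal_allele(self) -> str:
        """Which strain allele ('B' or 'D') was maternally inherited."""
        return "B" if self.cross == "BxD" else "D"


@dataclass
class CountingPolicy:
    """Read-filtering policy for allele counting.

    mate_mode ``fragment_once`` counts a properly paired fragment once per SNP
    even when both mates cover it (disagreeing mates go to ``other``);
    ``mates_independent`` counts every mate separately.
    """

    min_base_quality: int = 20
    mate_mode: str = "fragment_once"  # or "mates_independent"
    unique_only: bool = True
    max_mismatches: int = 3

    def __post_init__(self):
        if self.min_base_quality < 0:
            raise ValueError("min_base_quality must be >= 0")
        if self.mate_mode not in ("fragment_once", "mates_independent"):
            raise ValueError(f"invalid mate_mode {self.mate_mode!r}")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
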