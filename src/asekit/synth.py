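"""Synthetic F1 reciprocal-cross data with the statistical structure the
analysis assumes.

The generator emulates the study design: four pooled F1 samples (BxD and DxB
crosses, one male and one female pool each) with per-SNP biallelic read
counts.  Counts follow a negative-binomial law (variance mu + alpha*mu^2)
realised as a Poisson-gamma mixture with one gamma factor per
(gene, sample, allele), so that SNP counts within a gene are positively
correlated — as they are in real data, where nearby SNPs share reads — and
gene-level aggregates keep the same dispersion alpha.

Effect classes carried in the truth table:

* a cis effect: a strain log2 fold change (log2 D/B) applied identically in
  every sample (optionally sex-restricted);
* an imprinting effect tied to cross direction: the maternal allele is B in
  BxD and D in DxB (maternal strain named first, flippable);
* genotyping-error genes whose SNPs are not real polymorphisms, so every
  read carries the reference base and the D count is structurally zero;
* a global reference-mapping bias multiplying B-allele means only.

The per-allele means use a symmetric +/- L/2 split so total gene expression
is invariant under allelic imbalance.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .table import AlleleCountTable
from .types import GeneModel, GenomicInterval, SampleInfo, VariantSite

DEFAULT_SAMPLES = (
    ("BxD", "F"), ("DxB", "F"), ("BxD", "M"), ("DxB", "M"),
)


@dataclass
class TruthRecord:
    """Ground truth for one simulated gene."""

    gene_id: str
    ase_log2fc: float = 0.0          # strain effect, log2 D/B; 0 = none
    imprint_effect: str = "none"     # {"none", "maternal", "paternal"}
    imprint_magnitude: float = 0.0   # log2 units
    sex_specificity: str = "both"    # {"both", "male_only", "female_only"}
    is_genotyping_error: bool = False

    def __post_init__(self):
        if self.imprint_effect not in ("none", "maternal", "paternal"):
            raise ValueError(f"invalid imprint_effect {self.imprint_effect!r}")
        if self.sex_specificity not in ("both", "male_only", "female_only"):
            raise ValueError(f"invalid sex_specificity {self.sex_specificity!r}")
        if not (math.isfinite(self.ase_log2fc) and math.isfinite(self.imprint_magnitude)):
            raise ValueError("effect magnitudes must be finite")


@dataclass
class SimulationConfig:
    """Study conditions for the simulator.

    Defaults mirror the real design: 4 F1 pools (2 crosses x 2 sexes), ~10%
    of genes with a cis effect around 1 log2 unit, a small imprinted
    fraction at magnitude 2, a small genotyping-error fraction, NB dispersion
    0.05 and a global B-over-D mapping-bias factor of 1.2 (the order of the
    mapping ratios observed after N-masking).
    """

    seed: int
    n_genes: int = 2000
    snps_per_gene_mean: float = 3.0
    exons_per_gene_mean: float = 3.0
    fraction_cis: float = 0.10
    log2fc_mean: float = 1.0
    log2fc_sd: float = 0.25
    fraction_imprinted: float = 0.02
    imprint_magnitude: float = 2.0
    fraction_sex_specific: float = 0.05   # of cis genes
    fraction_error_snps: float = 0.02     # of genes carrying spurious SNPs
    fraction_stop_gain: float = 0.001     # of SNPs
    fraction_stop_loss: float = 0.00025
    mean_coverage: float = 500.0          # mean total allele-read pairs/gene/sample
    coverage_sigma: float = 0.5           # lognormal shape
    nb_dispersion: float = 0.05
    global_bias: float = 1.2
    samples: Sequence[Tuple[str, str]] = DEFAULT_SAMPLES
    read_length: int = 50
    close_snp_fraction: float = 0.1       # genes with a SNP pair < read_length apart
    multimap_fraction: float = 0.0
    paired: bool = False
    mother_first: bool = True             # cross naming convention

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("fraction_cis", "fraction_imprinted", "fraction_sex_specific",
                     "fraction_error_snps", "fraction_stop_gain",
                     "fraction_stop_loss", "close_snp_fraction",
                     "multimap_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.fraction_cis + self.fraction_imprinted + self.fraction_error_snps > 1:
            raise ValueError("effect fractions sum to > 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.global_bias <= 0:
            raise ValueError("global_bias must be > 0")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be > 0")
        for cross, sex in self.samples:
            SampleInfo(f"{cross}_{sex}", cross, sex)  # validates

    def sample_infos(self) -> List[SampleInfo]:
        return [SampleInfo(f"{cross}_{sex}", cross, sex)
                for cross, sex in self.samples]


@dataclass
class Annotation:
    """Toy genome: reference sequences, gene models and variant sites."""

    reference: Dict[str, str]
    genes: List[GeneModel]
    variants: List[VariantSite]

    def variants_of(self, gene_id: str) -> List[VariantSite]:
        return [v for v in self.variants if v.gene_id == gene_id]


def _rng(cfg: SimulationConfig, stage: int) -> np.random.Generator:
    # independent streams per stage so annotation / truth / counts / reads
    # do not perturb each other's draws
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stage]))


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_EXON_MIN, _EXON_MAX = 200, 400
_INTRON_LEN = 150
_INTERGENIC = 200


def gen_annotation(cfg: SimulationConfig) -> Annotation:
    """Lay genes with exon/intron structure on a toy chromosome and drop
    exonic SNPs into them (every gene gets at least one).

    A fraction ``close_snp_fraction`` of multi-SNP genes get their first two
    SNPs closer than the read length, to exercise double-counting of reads
    spanning two SNPs.
    """
    rng = _rng(cfg, 0)
    chrom = "chr1"
    seq_parts: List[str] = []
    cursor = 0
    genes: List[GeneModel] = []
    variants: List[VariantSite] = []

    for gi in range(cfg.n_genes):
        gene_id = f"gene{gi:05d}"
        n_exons = max(1, rng.poisson(cfg.exons_per_gene_mean - 1) + 1)
        n_snps = max(1, rng.poisson(cfg.snps_per_gene_mean - 1) + 1)
        exons = []
        start = cursor + _INTERGENIC
        pos = start
        for _ in range(n_exons):
            ex_len = int(rng.integers(_EXON_MIN, _EXON_MAX + 1))
            exons.append(GenomicInterval(chrom, pos, pos + ex_len))
            pos += ex_len + _INTRON_LEN
        end = exons[-1].end
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(gene_id, chrom, strand, exons,
                               n_isoforms=int(rng.integers(1, 4))))

        # exonic SNP positions, unique per gene
        exonic_positions = np.concatenate(
            [np.arange(e.start, e.end) for e in exons]
        )
        close = n_snps >= 2 and rng.random() < cfg.close_snp_fraction
        chosen: List[int] = []
        if close:
            # anchor plus one SNP strictly within a read length of it
            anchor_idx = int(rng.integers(0, len(exonic_positions) - 1))
            anchor = int(exonic_positions[anchor_idx])
            near = exonic_positions[
                (np.abs(exonic_positions - anchor) < cfg.read_length)
                & (exonic_positions != anchor)
            ]
            chosen = [anchor, int(rng.choice(near))]
        remaining = n_snps - len(chosen)
        if remaining > 0:
            pool = np.setdiff1d(exonic_positions, np.array(chosen, dtype=int))
            chosen += [int(p) for p in
                       rng.choice(pool, size=min(remaining, len(pool)),
                                  replace=False)]
        # alleles are realised after the sequence exists; keep positions now
        for p in sorted(chosen):
            variants.append((gene_id, p))  # type: ignore[arg-type]
        cursor = end
    total_len = cursor + _INTERGENIC
    if total_len > 10_000_000:
        raise ValueError(f"toy genome too large ({total_len} bp > 10 Mb)")
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq_arr = base_bytes[rng.integers(0, 4, size=total_len)]
    seq = seq_arr.tobytes().decode("ascii")

    # realise alleles: B = reference base, D = a different base
    real_variants: List[VariantSite] = []
    snp_positions = [(g, p) for (g, p) in variants]  # type: ignore[misc]
    n_total = len(snp_positions)
    is_stop_gain = rng.random(n_total) < cfg.fraction_stop_gain
    is_stop_loss = (~is_stop_gain) & (rng.random(n_total) < cfg.fraction_stop_loss)
    for i, (gene_id, p) in enumerate(snp_positions):
        b = seq[p]
        alt_pool = [x for x in "ACGT" if x != b]
        d = alt_pool[int(rng.integers(0, 3))]
        ann = "exonic"
        if is_stop_gain[i]:
            ann = "stop_gain"
        elif is_stop_loss[i]:
            ann = "stop_loss"
        real_variants.append(
            VariantSite(chrom=chrom, pos=int(p), b_allele=b, d_allele=d,
                        kind="snp", annotation=ann, gene_id=gene_id)
        )
    return Annotation(reference={chrom: seq}, genes=genes,
                      variants=real_variants)


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

def gen_truth(cfg: SimulationConfig) -> List[TruthRecord]:
    """Assign effect classes to genes.

    cis and imprinting are drawn independently (they may coexist);
    genotyping-error status is drawn independently and dominates the
    observable counts.  cis effect signs are balanced between B-up and D-up.
    """
    rng = _rng(cfg, 1)
    records = []
    for gi in range(cfg.n_genes):
        gene_id = f"gene{gi:05d}"
        rec = TruthRecord(gene_id=gene_id)
        if rng.random() < cfg.fraction_cis:
            mag = rng.normal(cfg.log2fc_mean, cfg.log2fc_sd)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            rec.ase_log2fc = sign * abs(mag)
            if rng.random() < cfg.fraction_sex_specific:
                rec.sex_specificity = (
                    "male_only" if rng.random() < 0.5 else "female_only"
                )
        if rng.random() < cfg.fraction_imprinted:
            rec.imprint_effect = "maternal" if rng.random() < 0.5 else "paternal"
            rec.imprint_magnitude = cfg.imprint_magnitude
        if rng.random() < cfg.fraction_error_snps:
            rec.is_genotyping_error = True
        records.append(rec)
    return records


def truth_frame(truth: List[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(t) for t in truth])


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _allelic_log2fc(rec: TruthRecord, sample: SampleInfo, mother_first: bool) -> float:
    """Realized log2(D/B) for one gene in one sample."""
    L = 0.0
    if rec.sex_specificity == "both" \
            or (rec.sex_specificity == "male_only" and sample.sex == "M") \
            or (rec.sex_specificity == "female_only" and sample.sex == "F"):
        L += rec.ase_log2fc
    if rec.imprint_effect != "none" and rec.imprint_magnitude != 0.0:
        maternal = sample.maternal_allele() if mother_first else (
            "D" if sample.maternal_allele() == "B" else "B")
        up = maternal if rec.imprint_effect == "maternal" else (
            "D" if maternal == "B" else "B")
        L += rec.imprint_magnitude if up == "D" else -rec.imprint_magnitude
    return L


def gen_counts(annotation: Annotation, truth: List[TruthRecord],
               cfg: SimulationConfig) -> AlleleCountTable:
    """Draw the per-SNP allele-count table.

    For SNP s of gene g in sample j, the expected counts are
    ``mu * bias * 2^(-L/2)`` (B) and ``mu * 2^(+L/2)`` (D) with
    ``mu = C_g / (2 n_snps)`` half the gene's per-SNP coverage share and L
    the realized log2(D/B).  Overdispersion enters through one gamma factor
    per (gene, sample, allele).  Genotyping-error genes emit zero D counts
    and all coverage on B.
    """
    truth_by_gene = {t.gene_id: t for t in truth}
    gene_ids = [g.gene_id for g in annotation.genes]
    if set(gene_ids) != set(truth_by_gene):
        raise ValueError("truth and annotation gene sets differ")
    rng = _rng(cfg, 2)
    samples = cfg.sample_infos()
    coverage = rng.lognormal(
        mean=math.log(cfg.mean_coverage) - cfg.coverage_sigma ** 2 / 2,
        sigma=cfg.coverage_sigma, size=len(gene_ids),
    )
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    variants = sorted(annotation.variants,
                      key=lambda v: (gene_index[v.gene_id], v.pos))
    gidx = np.array([gene_index[v.gene_id] for v in variants])
    n_snps_per_gene = np.bincount(gidx, minlength=len(gene_ids))
    mu_gene = np.divide(coverage, 2.0 * np.maximum(n_snps_per_gene, 1))
    mu_snp = mu_gene[gidx]
    is_error = np.array([truth_by_gene[g].is_genotyping_error
                         for g in gene_ids])
    alpha = cfg.nb_dispersion

    df = pd.DataFrame({
        "chrom": [v.chrom for v in variants],
        "pos": [v.pos for v in variants],
        "gene_id": [v.gene_id for v in variants],
        "annotation": [v.annotation for v in variants],
    })
    for s in samples:
        L_gene = np.array([
            _allelic_log2fc(truth_by_gene[g], s, cfg.mother_first)
            for g in gene_ids
        ])
        if alpha > 0:
            f_b = rng.gamma(1.0 / alpha, alpha, size=len(gene_ids))
            f_d = rng.gamma(1.0 / alpha, alpha, size=len(gene_ids))
        else:
            f_b = f_d = np.ones(len(gene_ids))
        mean_b_gene = np.where(
            is_error, 2.0 * cfg.global_bias * f_b,
            cfg.global_bias * (2.0 ** (-L_gene / 2.0)) * f_b)
        mean_d_gene = np.where(is_error, 0.0, (2.0 ** (L_gene / 2.0)) * f_d)
        b = rng.poisson(mu_snp * mean_b_gene[gidx])
        d = rng.poisson(mu_snp * mean_d_gene[gidx])
        df[f"{s.name}.b"] = b.astype(np.int64)
        df[f"{s.name}.d"] = d.astype(np.int64)
        df[f"{s.name}.other"] = np.zeros(len(variants), dtype=np.int64)
    return AlleleCountTable(df, samples)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def gen_reads(annotation: Annotation, truth: List[TruthRecord],
              cfg: SimulationConfig, sam_path, fasta_path=None):
    """Emit pre-placed alignments (SAM) whose reads carry the correct allele
    at every covered SNP, with the same mean structure as :func:`gen_counts`.

    One read group per sample.  A ``multimap_fraction`` of reads get NH:i:2
    so unique-read filtering can be exercised; unique reads carry NH:i:1.
    Paired mode emits proper pairs as two adjacent non-overlapping mates.
    """
    import pysam

    from . import io as aio

    truth_by_gene = {t.gene_id: t for t in truth}
    if set(g.gene_id for g in annotation.genes) != set(truth_by_gene):
        raise ValueError("truth and annotation gene sets differ")
    rng = _rng(cfg, 3)
    samples = cfg.sample_infos()
    chrom_order = list(annotation.reference)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(annotation.reference[c])}
               for c in chrom_order],
        "RG": [{"ID": s.name, "SM": s.name} for s in samples],
    }
    tid = {c: i for i, c in enumerate(chrom_order)}
    snps_by_gene: Dict[str, List[VariantSite]] = {}
    for v in annotation.variants:
        snps_by_gene.setdefault(v.gene_id, []).append(v)
    coverage = rng.lognormal(
        mean=math.log(cfg.mean_coverage) - cfg.coverage_sigma ** 2 / 2,
        sigma=cfg.coverage_sigma, size=len(annotation.genes),
    )
    rl = cfg.read_length
    frag = 2 * rl if cfg.paired else rl
    alpha = cfg.nb_dispersion
    qual = pysam.qualitystring_to_array("I" * rl)

    with pysam.AlignmentFile(os.fspath(sam_path), "w", header=header) as out:
        serial = 0
        for gidx, gene in enumerate(annotation.genes):
            rec = truth_by_gene[gene.gene_id]
            placeable = [e for e in gene.exons if len(e) >= frag]
            if not placeable:
                raise ValueError(
                    f"read/fragment length {frag} exceeds every exon of "
                    f"{gene.gene_id}"
                )
            weights = np.array([len(e) - frag + 1 for e in placeable], float)
            weights /= weights.sum()
            ref = annotation.reference[gene.chrom]
            gene_snps = {v.pos: v for v in snps_by_gene.get(gene.gene_id, [])}
            for s in samples:
                L = _allelic_log2fc(rec, s, cfg.mother_first)
                for allele in ("B", "D"):
                    if alpha > 0:
                        f = rng.gamma(1.0 / alpha, alpha)
                    else:
                        f = 1.0
                    if rec.is_genotyping_error:
                        mean_n = (coverage[gidx] * cfg.global_bias * f
                                  if allele == "B" else 0.0)
                    elif allele == "B":
                        mean_n = coverage[gidx] / 2.0 * cfg.global_bias \
                            * (2.0 ** (-L / 2.0)) * f
                    else:
                        mean_n = coverage[gidx] / 2.0 * (2.0 ** (L / 2.0)) * f
                    n_reads = rng.poisson(mean_n) if mean_n > 0 else 0
                    for _ in range(int(n_reads)):
                        exon = placeable[int(rng.choice(len(placeable), p=weights))]
                        start = int(rng.integers(exon.start,
                                                 exon.end - frag + 1))
                        multi = rng.random() < cfg.multimap_fraction
                        serial += 1
                        qname = f"r{serial:08d}"
                        mates = ([(start, False), (start + rl, True)]
                                 if cfg.paired else [(start, False)])
                        for mstart, is_read2 in mates:
                            seq = list(ref[mstart:mstart + rl])
                            for off in range(rl):
                                v = gene_snps.get(mstart + off)
                                if v is not None:
                                    # error SNPs are not real: reads carry B
                                    seq[off] = (v.b_allele
                                                if allele == "B"
                                                or rec.is_genotyping_error
                                                else v.d_allele)
                            a = pysam.AlignedSegment()
                            a.query_name = qname
                            a.query_sequence = "".join(seq)
                            a.reference_id = tid[gene.chrom]
                            a.reference_start = mstart
                            a.mapping_quality = 0 if multi else 60
                            a.cigarstring = f"{rl}M"
                            a.query_qualities = qual
                            a.flag = 0
                            if cfg.paired:
                                a.is_paired = True
                                a.is_proper_pair = True
                                a.is_read2 = is_read2
                                a.is_read1 = not is_read2
                                a.next_reference_id = tid[gene.chrom]
                                a.next_reference_start = (
                                    start + rl if not is_read2 else start)
                                a.template_length = frag if not is_read2 else -frag
                            nm = (0 if allele == "B" or rec.is_genotyping_error
                                  else sum(1 for off in range(rl)
                                           if (mstart + off) in gene_snps))
                            a.set_tag("NM", nm)
                            a.set_tag("NH", 2 if multi else 1)
                            a.set_tag("RG", s.name)
                            out.write(a)
    if fasta_path is not None:
        aio.write_fasta(annotation.reference, fasta_path)
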