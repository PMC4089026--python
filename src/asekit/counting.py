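"""Per-SNP, per-sample allele-specific counting from alignments, with
reference-bias mitigation (N-masking) and bias diagnostics."""

from __future__ import annotations

import logging
import os
import warnings
from collections import defaultdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from .table import AlleleCountTable
from .types import CountingPolicy, SampleInfo, VariantSite

logger = logging.getLogger(__name__)

__all__ = ["mask_reference", "mask_fasta", "count_alleles",
           "mapping_ratio", "bias_report"]


# ---------------------------------------------------------------------------
# reference masking
# ---------------------------------------------------------------------------

def mask_reference(sequences: Mapping[str, str],
                   variants: Sequence[VariantSite]) -> Dict[str, str]:
    """Replace every SNP position with N in the reference.

    Only SNPs are masked; indels are skipped with a warning.  Masking is
    idempotent.  A variant position outside its chromosome raises an error
    naming the variant.
    """
    out = {chrom: bytearray(seq, "ascii") for chrom, seq in sequences.items()}
    n_indels = 0
    for v in variants:
        if v.kind != "snp":
            n_indels += 1
            continue
        if v.chrom not in out:
            raise ValueError(f"variant {v.chrom}:{v.pos} on unknown chromosome")
        if not (0 <= v.pos < len(out[v.chrom])):
            raise ValueError(
                f"variant {v.chrom}:{v.pos} ({v.b_allele}/{v.d_allele}) "
                f"outside chromosome of length {len(out[v.chrom])}"
            )
        out[v.chrom][v.pos] = ord("N")
    if n_indels:
        warnings.warn(f"skipped {n_indels} indels during masking (SNPs only)")
    return {chrom: seq.decode("ascii") for chrom, seq in out.items()}


def mask_fasta(fasta_in, variants: Sequence[VariantSite], fasta_out) -> None:
    from . import io as aio

    aio.write_fasta(mask_reference(aio.read_fasta(fasta_in), variants), fasta_out)


# ---------------------------------------------------------------------------
# allele counting
# ---------------------------------------------------------------------------

def _read_passes(read, policy: CountingPolicy) -> bool:
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return False
    if policy.unique_only:
        if read.has_tag("NH") and read.get_tag("NH") > 1:
            return False
        if read.mapping_quality == 0:
            return False
    if read.has_tag("NM") and read.get_tag("NM") > policy.max_mismatches:
        return False
    return True


def count_alleles(sam_path, variants: Sequence[VariantSite],
                  policy: Optional[CountingPolicy] = None,
                  samples: Optional[List[SampleInfo]] = None) -> AlleleCountTable:
    """Count B/D allele support per SNP per sample from a SAM/BAM file.

    Reads are assigned to samples via their RG tag (files without read
    groups count into a single sample).  Under ``fragment_once`` a properly
    paired fragment whose mates both cover a SNP contributes one count
    (disagreeing mates go to ``other``); ``mates_independent`` tallies each
    mate.  Reads failing the uniqueness, mismatch or base-quality filters
    are skipped.  CIGAR-unresolvable positions are skipped and logged.
    """
    policy = policy or CountingPolicy()
    snps = [v for v in variants if v.kind == "snp"]
    by_pos: Dict[Tuple[str, int], List[int]] = defaultdict(list)
    for i, v in enumerate(snps):
        by_pos[(v.chrom, v.pos)].append(i)

    with pysam.AlignmentFile(os.fspath(sam_path), "r") as sam:
        rg_names = [rg["ID"] for rg in sam.header.to_dict().get("RG", [])]
        if samples is None:
            if rg_names:
                samples = [SampleInfo(n, "BxD", "F") for n in rg_names]
            else:
                samples = [SampleInfo("sample1", "BxD", "F")]
        sample_idx = {s.name: j for j, s in enumerate(samples)}
        n_samples = len(samples)
        b = np.zeros((len(snps), n_samples), dtype=np.int64)
        d = np.zeros_like(b)
        other = np.zeros_like(b)
        # fragment_once: defer paired observations until both mates are seen
        pending: Dict[Tuple[str, int, int], str] = {}

        def tally(vi: int, sj: int, base: str) -> None:
            v = snps[vi]
            if base == v.b_allele:
                b[vi, sj] += 1
            elif base == v.d_allele:
                d[vi, sj] += 1
            else:
                other[vi, sj] += 1

        for read in sam:
            if not _read_passes(read, policy):
                continue
            rg = read.get_tag("RG") if read.has_tag("RG") else "sample1"
            if rg not in sample_idx:
                raise ValueError(f"read group {rg!r} not among samples")
            sj = sample_idx[rg]
            seq = read.query_sequence
            quals = read.query_qualities
            try:
                pairs = read.get_aligned_pairs(matches_only=True)
            except ValueError:
                logger.warning("unresolvable CIGAR for %s; skipped",
                               read.query_name)
                continue
            for qpos, rpos in pairs:
                key = (read.reference_name, rpos)
                if key not in by_pos:
                    continue
                if quals is not None and quals[qpos] < policy.min_base_quality:
                    continue
                base = seq[qpos]
                for vi in by_pos[key]:
                    if (policy.mate_mode == "fragment_once"
                            and read.is_paired and read.is_proper_pair):
                        fkey = (read.query_name, vi, sj)
                        if fkey in pending:
                            mate_base = pending.pop(fkey)
                            if mate_base == base:
                                tally(vi, sj, base)
                            else:
                                other[vi, sj] += 1
                        else:
                            pending[fkey] = base
                    else:
                        tally(vi, sj, base)
        # fragments where only one mate covered the SNP
        for (qname, vi, sj), base in pending.items():
            tally(vi, sj, base)

    df = pd.DataFrame({
        "chrom": [v.chrom for v in snps],
        "pos": [v.pos for v in snps],
        "gene_id": [v.gene_id for v in snps],
        "annotation": [v.annotation for v in snps],
    })
    for j, s in enumerate(samples):
        df[f"{s.name}.b"] = b[:, j]
        df[f"{s.name}.d"] = d[:, j]
        df[f"{s.name}.other"] = other[:, j]
    df = df.sort_values(["chrom", "pos", "gene_id"]).reset_index(drop=True)
    return AlleleCountTable(df, samples)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def thin_independent(table: AlleleCountTable, read_length: int) -> pd.Series:
    """Boolean mask of SNPs greedily thinned so consecutive retained SNPs on
    a chromosome are at least ``read_length`` apart (no read can span two
    retained SNPs)."""
    df = table.df.sort_values(["chrom", "pos"])
    keep = pd.Series(False, index=table.df.index)
    last: Dict[str, int] = {}
    seen_pos: Dict[Tuple[str, int], bool] = {}
    for idx, row in df.iterrows():
        key = (row["chrom"], row["pos"])
        if key in seen_pos:
            keep.loc[idx] = seen_pos[key]  # duplicated site (two genes)
            continue
        prev = last.get(row["chrom"])
        ok = prev is None or row["pos"] - prev >= read_length
        if ok:
            last[row["chrom"]] = row["pos"]
        keep.loc[idx] = ok
        seen_pos[key] = ok
    return keep


def mapping_ratio(table: AlleleCountTable, independent_only: bool = False,
                  read_length: int = 50) -> pd.Series:
    """Per-sample B-to-D mapping ratio sum(B)/sum(D).

    With ``independent_only`` the SNP set is first thinned so no read can
    contribute to two retained SNPs.  An undefined ratio (sum(D)=0) is
    reported as NaN.
    """
    if table.n_snps() == 0:
        raise ValueError("empty count table")
    mask = (thin_independent(table, read_length)
            if independent_only else pd.Series(True, index=table.df.index))
    out = {}
    for s in table.sample_names:
        tb = int(table.df.loc[mask, f"{s}.b"].sum())
        td = int(table.df.loc[mask, f"{s}.d"].sum())
        out[s] = (tb / td) if td > 0 else np.nan
    return pd.Series(out, name="b_to_d_ratio")


def bias_report(counts_masked: AlleleCountTable,
                counts_unmasked: AlleleCountTable) -> pd.DataFrame:
    """Per-sample allelic-bias summary for masked vs unmasked counting.

    The truth-free expectation of log2(sum B / sum D) is 0; the report gives
    that excess for both tables and the fold reduction
    |log unmasked| / |log masked| (1.0 when the tables are identical).
    """
    key_m = set(map(tuple, counts_masked.df[["chrom", "pos"]].values))
    key_u = set(map(tuple, counts_unmasked.df[["chrom", "pos"]].values))
    if not (key_m & key_u):
        raise ValueError("masked and unmasked tables share no SNPs")
    if counts_masked.sample_names != counts_unmasked.sample_names:
        raise ValueError("sample sets differ between tables")
    rows = []
    for s in counts_masked.sample_names:
        lm = np.log2(counts_masked.df[f"{s}.b"].sum()
                     / max(counts_masked.df[f"{s}.d"].sum(), 1))
        lu = np.log2(counts_unmasked.df[f"{s}.b"].sum()
                     / max(counts_unmasked.df[f"{s}.d"].sum(), 1))
        if np.isclose(lm, lu):
            fold = 1.0
        elif np.isclose(lm, 0.0):
            fold = np.inf
        else:
            fold = abs(lu) / abs(lm)
        rows.append({"sample": s, "log2_ratio_masked": lm,
                     "log2_ratio_unmasked": lu, "fold_reduction": fold})
    return pd.DataFrame(rows).set_index("sample")
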