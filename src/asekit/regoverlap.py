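"""Downstream concordance analyses: DNase I peak intactness around genes
(the per-gene F ratio) and cis- vs local-eQTL set comparisons."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .types import DNasePeak, GeneModel, GenomicInterval, VariantSite

__all__ = [
    "GeneRegSummary", "EqtlRecord",
    "conserved_peaks", "intact_peaks", "gene_reg_summary", "assign_ase_groups",
    "group_compare", "set_overlap", "venn3_counts", "threshold_sweep",
    "effect_size_compare", "read_eqtl_table",
]


@dataclass
class GeneRegSummary:
    """Per-gene DNase peak summary: intact (non-polymorphic) vs total."""

    gene_id: str
    n_peaks: int
    n_intact_peaks: int
    total_signal: float
    intact_signal: float
    f_ratio: float      # intact_signal / total_signal
    ase_group: str = "NS"  # {"B", "D", "NS"}

    def __post_init__(self):
        if not (0 <= self.n_intact_peaks <= self.n_peaks):
            raise ValueError("intact peak count out of range")
        if self.n_peaks > 0 and not (0.0 <= self.f_ratio <= 1.0 + 1e-12):
            raise ValueError("f_ratio outside [0, 1]")


@dataclass
class EqtlRecord:
    """One gene's local-eQTL status in an external mapping study."""

    gene_id: str
    dataset: str               # {"HMDP", "F2", "other"}
    significant: bool
    effect_size: float         # fold change between homozygous genotypes
    polymorphic_in_d: bool = True

    def __post_init__(self):
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")


def read_eqtl_table(path) -> List[EqtlRecord]:
    """Read a local-eQTL result TSV (gene_id, dataset, significant,
    effect_size, polymorphic_in_d)."""
    df = pd.read_table(path)
    recs = []
    for row in df.itertuples(index=False):
        recs.append(EqtlRecord(
            gene_id=str(row.gene_id), dataset=str(row.dataset),
            significant=bool(row.significant),
            effect_size=float(row.effect_size),
            polymorphic_in_d=bool(getattr(row, "polymorphic_in_d", True)),
        ))
    return recs


# ---------------------------------------------------------------------------
# peak geometry
# ---------------------------------------------------------------------------

def _tree_by_chrom(peaks: Sequence[DNasePeak]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for i, p in enumerate(peaks):
        trees.setdefault(p.interval.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.end, i)
    return trees


def conserved_peaks(rep1: Sequence[DNasePeak],
                    rep2: Sequence[DNasePeak]) -> List[DNasePeak]:
    """Peaks reproducible across replicates.

    Keeps each rep1 interval that overlaps (>= 1 bp) any rep2 interval; the
    signal becomes the mean of the rep1 signal and the best-overlapping rep2
    signal.
    """
    trees = _tree_by_chrom(rep2)
    out: List[DNasePeak] = []
    for p in rep1:
        tree = trees.get(p.interval.chrom)
        if tree is None:
            continue
        hits = tree.overlap(p.interval.start, p.interval.end)
        if not hits:
            continue
        best = max(
            hits,
            key=lambda h: (min(h.end, p.interval.end)
                           - max(h.begin, p.interval.start)),
        )
        out.append(DNasePeak(
            interval=p.interval,
            signal=(p.signal + rep2[best.data].signal) / 2.0,
            replicate_id=p.replicate_id,
        ))
    return out


def intact_peaks(peaks: Sequence[DNasePeak],
                 variants: Sequence[VariantSite]
                 ) -> Tuple[List[DNasePeak], List[DNasePeak]]:
    """Partition peaks into (intact, polymorphic).

    A peak is polymorphic iff any SNP position or any indel reference span
    overlaps it (half-open semantics); the partition is exhaustive and
    disjoint.
    """
    vtrees: Dict[str, IntervalTree] = {}
    for v in variants:
        span = v.ref_span
        vtrees.setdefault(span.chrom, IntervalTree()).addi(span.start, span.end)
    intact, polymorphic = [], []
    for p in peaks:
        tree = vtrees.get(p.interval.chrom)
        if tree is not None and tree.overlap(p.interval.start, p.interval.end):
            polymorphic.append(p)
        else:
            intact.append(p)
    return intact, polymorphic


def gene_reg_summary(genes: Sequence[GeneModel],
                     intact: Sequence[DNasePeak],
                     polymorphic: Sequence[DNasePeak],
                     window_bp: int = 10_000) -> List[GeneRegSummary]:
    """Per-gene peak counts and signal split into intact vs polymorphic.

    A peak is assigned to every gene whose span extended by ``window_bp``
    it overlaps.  Genes with no assigned peak are excluded.  The F ratio is
    the fraction of the gene's DNase signal coming from intact peaks.
    """
    if not (0 <= window_bp <= 10_000):
        raise ValueError("window_bp must be within [0, 10000]")
    itree = _tree_by_chrom(intact)
    ptree = _tree_by_chrom(polymorphic)
    out: List[GeneRegSummary] = []
    for g in genes:
        span = g.span
        lo = max(0, span.start - window_bp)
        hi = span.end + window_bp
        ih = itree.get(g.chrom, IntervalTree()).overlap(lo, hi)
        ph = ptree.get(g.chrom, IntervalTree()).overlap(lo, hi)
        n_i, n_p = len(ih), len(ph)
        if n_i + n_p == 0:
            continue
        sig_i = sum(intact[h.data].signal for h in ih)
        sig_p = sum(polymorphic[h.data].signal for h in ph)
        total = sig_i + sig_p
        out.append(GeneRegSummary(
            gene_id=g.gene_id, n_peaks=n_i + n_p, n_intact_peaks=n_i,
            total_signal=total, intact_signal=sig_i,
            f_ratio=(sig_i / total) if total > 0 else 1.0,
        ))
    return out


def assign_ase_groups(summaries: List[GeneRegSummary],
                      ase_results: pd.DataFrame,
                      alpha: float = 0.05) -> List[GeneRegSummary]:
    """Label each gene B / D / NS from the ASE results (padj and log2fc
    sign, as in the published grouping)."""
    for s in summaries:
        if s.gene_id in ase_results.index:
            row = ase_results.loc[s.gene_id]
            if row["padj"] < alpha:
                s.ase_group = "D" if row["log2fc"] > 0 else "B"
            else:
                s.ase_group = "NS"
        else:
            s.ase_group = "NS"
    return summaries


def group_compare(summaries: Sequence[GeneRegSummary]) -> pd.DataFrame:
    """Pairwise group statistics on the F ratio and intact-peak fractions.

    For each pair among (B, D, NS): a two-sided rank-sum test on the
    per-gene F ratios and a two-proportion z-test on the pooled intact-peak
    fractions.  Empty groups raise an error naming the group.
    """
    frame = pd.DataFrame([vars(s) for s in summaries])
    groups = [g for g in ("B", "D", "NS") if g in set(frame["ase_group"])]
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty groups")
    for g in ("B", "D", "NS"):
        if g in frame["ase_group"].values and \
                (frame["ase_group"] == g).sum() == 0:
            raise ValueError(f"empty group {g}")
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            g1, g2 = groups[i], groups[j]
            f1 = frame.loc[frame["ase_group"] == g1, "f_ratio"]
            f2 = frame.loc[frame["ase_group"] == g2, "f_ratio"]
            if len(f1) == 0 or len(f2) == 0:
                raise ValueError(f"empty group {g1 if len(f1) == 0 else g2}")
            if f1.nunique() == 1 and f2.nunique() == 1 and \
                    f1.iloc[0] == f2.iloc[0]:
                p_rank = 1.0
            else:
                p_rank = float(stats.mannwhitneyu(
                    f1, f2, alternative="two-sided").pvalue)
            sub1 = frame[frame["ase_group"] == g1]
            sub2 = frame[frame["ase_group"] == g2]
            count = np.array([sub1["n_intact_peaks"].sum(),
                              sub2["n_intact_peaks"].sum()])
            nobs = np.array([sub1["n_peaks"].sum(), sub2["n_peaks"].sum()])
            if (count == nobs).all() or (count == 0).all():
                p_prop = 1.0
            else:
                p_prop = float(proportions_ztest(count, nobs)[1])
            rows.append({
                "group_a": g1, "group_b": g2,
                "n_a": len(f1), "n_b": len(f2),
                "median_f_a": float(f1.median()),
                "median_f_b": float(f2.median()),
                "p_ranksum_f_ratio": p_rank,
                "intact_fraction_a": count[0] / max(nobs[0], 1),
                "intact_fraction_b": count[1] / max(nobs[1], 1),
                "p_proportions": p_prop,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# set comparisons
# ---------------------------------------------------------------------------

def set_overlap(set_a: Set, set_b: Set, universe: Set) -> Dict[str, object]:
    """Overlap of two gene sets with a one-sided (upper tail)
    hypergeometric enrichment p-value."""
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be contained in the universe")
    k = len(set_a & set_b)
    n = len(universe)
    p = float(stats.hypergeom.sf(k - 1, n, len(set_a), len(set_b)))
    return {"overlap": k, "n_a": len(set_a), "n_b": len(set_b),
            "n_universe": n, "pvalue": min(p, 1.0)}


def venn3_counts(set_a: Set, set_b: Set, set_c: Set) -> Dict[str, int]:
    """The seven region counts of a three-set Venn diagram."""
    a, b, c = set(set_a), set(set_b), set(set_c)
    abc = a & b & c
    return {
        "a_only": len(a - b - c),
        "b_only": len(b - a - c),
        "c_only": len(c - a - b),
        "ab_only": len((a & b) - c),
        "ac_only": len((a & c) - b),
        "bc_only": len((b & c) - a),
        "abc": len(abc),
    }


def threshold_sweep(pvals_a: pd.Series, pvals_b: pd.Series,
                    cutoffs: Sequence[float],
                    b_cutoff: Optional[float] = None) -> pd.DataFrame:
    """Fraction of A-significant genes that are also B-significant, as the
    A cutoff tightens.

    If lack of power explains a poor overlap, stricter cutoffs should raise
    the overlap fraction.  ``b_cutoff`` fixes B's threshold (defaults to
    each swept cutoff).  Reports a monotonicity flag comparing the
    strictest and loosest cutoffs.
    """
    cutoffs = sorted(cutoffs)
    if len(cutoffs) == 0:
        raise ValueError("empty cutoff grid")
    shared = pvals_a.index.intersection(pvals_b.index)
    pa = pvals_a.loc[shared]
    pb = pvals_b.loc[shared]
    rows = []
    for c in cutoffs:
        bc = b_cutoff if b_cutoff is not None else c
        a_sig = pa < c
        both = a_sig & (pb < bc)
        frac = both.sum() / a_sig.sum() if a_sig.sum() else np.nan
        rows.append({"cutoff": c, "n_a_significant": int(a_sig.sum()),
                     "n_both": int(both.sum()), "overlap_fraction": frac})
    df = pd.DataFrame(rows)
    valid = df["overlap_fraction"].dropna()
    df.attrs["increasing_with_stringency"] = (
        bool(valid.iloc[0] >= valid.iloc[-1]) if len(valid) >= 2 else None)
    return df


def effect_size_compare(ase_results: pd.DataFrame,
                        eqtl_records: Sequence[EqtlRecord],
                        alpha: float = 0.05,
                        exclude_genes: Optional[Set[str]] = None
                        ) -> pd.DataFrame:
    """Effect sizes by overlap category between ASE and a local-eQTL study.

    The ASE effect size is ``2^|log2fc|`` (average allelic fold change);
    genes with exclusive single-allele expression are excluded via
    ``exclude_genes`` since their ratio is unbounded.  Categories are
    "+/+", "+/-", "-/+", "-/-" for (ASE significant / eQTL significant).
    """
    exclude_genes = exclude_genes or set()
    eqtl = pd.DataFrame([vars(r) for r in eqtl_records])
    shared = ase_results.index.intersection(eqtl["gene_id"])
    shared = [g for g in shared if g not in exclude_genes]
    if len(shared) == 0:
        raise ValueError("no shared genes between ASE and eQTL results")
    eqtl = eqtl.set_index("gene_id").loc[shared]
    ase = ase_results.loc[shared]
    ase_sig = ase["padj"] < alpha
    ase_eff = 2.0 ** ase["log2fc"].abs()
    rows = []
    for a_flag, e_flag, label in ((True, True, "+/+"), (True, False, "+/-"),
                                  (False, True, "-/+"), (False, False, "-/-")):
        mask = (ase_sig == a_flag) & (eqtl["significant"] == e_flag)
        sub_a = ase_eff[mask]
        sub_e = eqtl.loc[mask, "effect_size"]
        rows.append({
            "category": label, "n": int(mask.sum()),
            "ase_median": float(sub_a.median()) if mask.sum() else np.nan,
            "ase_iqr": (float(sub_a.quantile(0.75) - sub_a.quantile(0.25))
                        if mask.sum() else np.nan),
            "eqtl_median": float(sub_e.median()) if mask.sum() else np.nan,
            "eqtl_iqr": (float(sub_e.quantile(0.75) - sub_e.quantile(0.25))
                         if mask.sum() else np.nan),
        })
    return pd.DataFrame(rows)
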