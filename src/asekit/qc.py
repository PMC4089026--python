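"""Internal-consistency error estimators and special-variant analyses.

Biology supplies free negative controls: SNPs in the same exon (and exons in
the same gene, absent isoform-specific regulation) must agree in direction,
so significant-but-discordant pairs bound the empirical error rate.  Genes
where only one allele is ever observed flag candidate genotyping errors, and
premature-stop variants let one ask how often nonsense-mediated decay
actually suppresses the impaired allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .table import AlleleCountTable
from .types import GeneModel, VariantSite

__all__ = ["DiscordanceReport", "discordant_pairs", "snp_parent_map",
           "exon_parent_map", "exclusive_report", "stop_codon_ase",
           "ase_concordance"]


@dataclass
class DiscordanceReport:
    level: str                       # {"snp_in_exon", "exon_in_gene"}
    n_units_tested: int
    n_pairs_tested: int
    n_significant_pairs: int
    n_significant_pairs_discordant: int
    pairs: pd.DataFrame              # offending pairs with directions
    isoform_counts: Optional[pd.Series] = None  # exon level only


def snp_parent_map(results_index: Sequence[str],
                   genes: List[GeneModel]) -> Dict[str, str]:
    """Map SNP unit ids ``chrom:pos:gene`` to their host exon
    ``gene:exonNNN`` (intronic SNPs are unmapped)."""
    gmap = {g.gene_id: g for g in genes}
    out = {}
    for uid in results_index:
        chrom, pos, gene_id = uid.rsplit(":", 2)
        g = gmap.get(gene_id)
        if g is None:
            continue
        idx = g.exon_index_of(int(pos))
        if idx is not None:
            out[uid] = f"{gene_id}:exon{idx:03d}"
    return out


def exon_parent_map(results_index: Sequence[str]) -> Dict[str, str]:
    """Map exon unit ids ``gene:exonNNN`` to their gene."""
    return {uid: uid.rsplit(":", 1)[0] for uid in results_index}


def discordant_pairs(results: pd.DataFrame, parent_of: Dict[str, str],
                     alpha: float = 0.05,
                     genes: Optional[List[GeneModel]] = None,
                     level: str = "snp_in_exon") -> DiscordanceReport:
    """Pairs of sibling units that are both significant with opposite
    allelic direction.

    ``parent_of`` maps each unit id to its grouping unit (exon for SNP-level
    results, gene for exon-level).  A unit present in the results but absent
    from the map is an error.  At exon level the per-gene known-isoform
    count is joined so single-isoform discordance (almost surely error) can
    be quantified.
    """
    missing = [u for u in results.index if u not in parent_of]
    if missing:
        raise ValueError(f"units without parent mapping: {missing[:5]} ...")
    groups: Dict[str, List[str]] = {}
    for uid in results.index:
        groups.setdefault(parent_of[uid], []).append(uid)
    sig = results["padj"] < alpha
    n_pairs = 0
    n_sig_pairs = 0
    rows = []
    for parent, members in groups.items():
        for u1, u2 in combinations(members, 2):
            n_pairs += 1
            if sig[u1] and sig[u2]:
                n_sig_pairs += 1
                l1 = results.loc[u1, "log2fc"]
                l2 = results.loc[u2, "log2fc"]
                if l1 * l2 < 0:
                    rows.append({"parent": parent, "unit_a": u1, "unit_b": u2,
                                 "log2fc_a": l1, "log2fc_b": l2})
    pairs = pd.DataFrame(rows, columns=["parent", "unit_a", "unit_b",
                                        "log2fc_a", "log2fc_b"])
    iso = None
    if level == "exon_in_gene" and genes is not None:
        gmap = {g.gene_id: g.n_isoforms for g in genes}
        iso = pd.Series({p: gmap.get(p.rsplit(":", 1)[0] if ":" in p else p, 1)
                         for p in pairs["parent"].unique()},
                        name="n_isoforms", dtype=int)
    return DiscordanceReport(
        level=level,
        n_units_tested=len(results),
        n_pairs_tested=n_pairs,
        n_significant_pairs=n_sig_pairs,
        n_significant_pairs_discordant=len(pairs),
        pairs=pairs,
        isoform_counts=iso,
    )


def exclusive_report(table: AlleleCountTable,
                     min_total: int = 8) -> pd.DataFrame:
    """Genes whose every informative SNP shows the same single allele in
    every sample — the signature of a genotyping error rather than ASE.

    A gene qualifies only with total coverage >= ``min_total`` across
    samples (guards against calling noise).  Returns gene_id, the exclusive
    allele, the number of informative SNPs and the total count.
    """
    b = table.b_counts().sum(axis=1)
    d = table.d_counts().sum(axis=1)
    df = pd.DataFrame({"gene_id": table.df["gene_id"], "b": b, "d": d})
    df = df[(df["b"] + df["d"]) > 0]  # informative SNPs only
    rows = []
    for gene_id, grp in df.groupby("gene_id"):
        total = int(grp["b"].sum() + grp["d"].sum())
        if total < min_total:
            continue
        if (grp["d"] == 0).all() and (grp["b"] > 0).all():
            allele = "B"
        elif (grp["b"] == 0).all() and (grp["d"] > 0).all():
            allele = "D"
        else:
            continue
        rows.append({"gene_id": gene_id, "allele": allele,
                     "n_snps": len(grp), "total_count": total})
    return pd.DataFrame(rows, columns=["gene_id", "allele", "n_snps",
                                       "total_count"])


def stop_codon_ase(results_snp: pd.DataFrame,
                   variants: Sequence[VariantSite],
                   reduction_threshold: float = 0.5) -> Dict[str, object]:
    """Allelic balance at premature-stop variants.

    Stop-gain and stop-loss annotations are D-referenced, so the impaired
    allele is D in both classes and the impaired/intact expression ratio is
    ``2^log2fc`` of the strain-mode SNP result.  A variant shows "marked
    reduction" when that ratio is at or below ``reduction_threshold``
    (default 0.5, i.e. two-fold).  Variants without counts are skipped and
    listed.
    """
    per_variant = []
    skipped = []
    for v in variants:
        if v.annotation not in ("stop_gain", "stop_loss"):
            continue
        uid = f"{v.chrom}:{v.pos}:{v.gene_id}"
        if uid not in results_snp.index:
            skipped.append(uid)
            continue
        l2 = float(results_snp.loc[uid, "log2fc"])
        ratio = 2.0 ** l2  # impaired (D) over intact (B)
        per_variant.append({
            "unit_id": uid, "class": v.annotation,
            "impaired_intact_ratio": ratio,
            "marked_reduction": ratio <= reduction_threshold,
        })
    frame = pd.DataFrame(per_variant,
                         columns=["unit_id", "class",
                                  "impaired_intact_ratio", "marked_reduction"])
    by_class = {}
    for cls, grp in frame.groupby("class"):
        by_class[cls] = {
            "n": int(len(grp)),
            "n_marked": int(grp["marked_reduction"].sum()),
            "marked_fraction": float(grp["marked_reduction"].mean()),
        }
    overall = (float(frame["marked_reduction"].mean())
               if len(frame) else float("nan"))
    return {"per_variant": frame, "by_class": by_class,
            "marked_fraction": overall, "skipped": skipped}


def ase_concordance(results_a: pd.DataFrame, results_b: pd.DataFrame,
                    labels: Optional[pd.Series] = None) -> Dict[str, object]:
    """Fold-change agreement between two result sets (e.g. two tissues).

    Returns R-squared and the regression slope of b on a over shared units,
    plus the merged per-unit frame (with an optional external label column
    for grouping, e.g. eQTL-overlap status).
    """
    shared = results_a.index.intersection(results_b.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared units")
    x = results_a.loc[shared, "log2fc"].to_numpy()
    y = results_b.loc[shared, "log2fc"].to_numpy()
    fit = stats.linregress(x, y)
    frame = pd.DataFrame({"unit_id": shared, "log2fc_a": x, "log2fc_b": y}
                         ).set_index("unit_id")
    if labels is not None:
        frame["label"] = labels.reindex(shared)
    return {"r2": float(fit.rvalue ** 2), "slope": float(fit.slope),
            "pvalue": float(fit.pvalue), "n": int(len(shared)),
            "frame": frame}
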