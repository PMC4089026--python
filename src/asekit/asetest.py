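"""The statistical core: allelic-imbalance testing with replicates.

Allele counts are aggregated to SNP/exon/gene units and reshaped into a
count matrix with one *pseudo-sample* per (mouse sample x allele), i.e. the
two alleles of each sequenced pool are treated as independent replicate
libraries of two conditions.  The contrast is either *strain* (B vs D,
detecting cis effects) or *parent of origin* (maternal vs paternal, derived
from allele strain x cross direction, detecting imprinting).

The test itself is the negative-binomial conditional exact test for two
groups of count libraries: median-of-ratios size factors absorb both depth
and global allelic mapping bias; per-unit dispersions are estimated by
method of moments on normalized counts and shrunk toward a fitted
mean-dispersion curve alpha(mu) = a0 + a1/mu (working dispersion is the
maximum of the empirical and fitted values, a conservative choice); the
p-value sums the probabilities of all splits of the observed total that are
no more probable than the observed split.

A per-SNP Fisher exact baseline (each SNP against the rest of its library)
and Benjamini-Hochberg FDR control round out the module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .table import AlleleCountTable
from .types import GeneModel, SampleInfo

__all__ = [
    "CountMatrix", "ContrastDesign", "DispersionModel",
    "aggregate", "filter_exclusive", "size_factors", "estimate_dispersion",
    "nb_exact_test", "fisher_snp_test", "bh_fdr", "run_contrast",
    "fisher_pipeline", "fisher_calls", "replicate_titration", "compare_sexes",
    "ASEModel", "ASEResults",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """units x pseudo-samples integer counts.

    ``counts`` has unit ids as index and pseudo-sample names
    ``<sample>.<allele>`` as columns; ``meta`` (indexed by column name)
    carries sample, allele, cross and sex for each column.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    level: str  # {"snp", "exon", "gene"}

    def __post_init__(self):
        if self.level not in ("snp", "exon", "gene"):
            raise ValueError(f"invalid level {self.level!r}")
        if list(self.counts.columns) != list(self.meta.index):
            raise ValueError("counts columns and meta index differ")
        per_sample = self.meta.groupby("sample").size()
        if not (per_sample == 2).all():
            raise ValueError("each mouse sample needs exactly 2 columns")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    @property
    def mouse_samples(self) -> List[str]:
        seen = []
        for s in self.meta["sample"]:
            if s not in seen:
                seen.append(s)
        return seen

    def subset_samples(self, names: Iterable[str]) -> "CountMatrix":
        names = list(names)
        cols = [c for c in self.counts.columns
                if self.meta.loc[c, "sample"] in names]
        return CountMatrix(self.counts[cols].copy(),
                           self.meta.loc[cols].copy(), self.level)


@dataclass
class ContrastDesign:
    """Two-level contrast over pseudo-samples.

    ``strain`` labels columns by allele (B vs D); ``parent`` labels them
    maternal vs paternal using the cross direction (the maternal allele is B
    in BxD and D in DxB).  ``sex_filter`` restricts the analysis to one sex.
    """

    mode: str = "strain"        # {"strain", "parent"}
    sex_filter: str = "all"     # {"all", "male", "female"}

    # condition whose mean goes in the numerator of log2fc
    _NUM = {"strain": "D", "parent": "maternal"}
    _DEN = {"strain": "B", "parent": "paternal"}

    def __post_init__(self):
        if self.mode not in ("strain", "parent"):
            raise ValueError(f"invalid mode {self.mode!r}")
        if self.sex_filter not in ("all", "male", "female"):
            raise ValueError(f"invalid sex_filter {self.sex_filter!r}")

    def labels(self, meta: pd.DataFrame) -> pd.Series:
        if self.mode == "strain":
            return meta["allele"]
        maternal = meta.apply(
            lambda r: "B" if r["cross"] == "BxD" else "D", axis=1)
        return pd.Series(
            np.where(meta["allele"] == maternal, "maternal", "paternal"),
            index=meta.index)

    def sex_mask(self, meta: pd.DataFrame) -> pd.Series:
        if self.sex_filter == "all":
            return pd.Series(True, index=meta.index)
        want = "M" if self.sex_filter == "male" else "F"
        return meta["sex"] == want

    @property
    def numerator(self) -> str:
        return self._NUM[self.mode]

    @property
    def denominator(self) -> str:
        return self._DEN[self.mode]

    def direction_labels(self) -> Tuple[str, str]:
        """(positive-log2fc direction, negative-log2fc direction)."""
        return (self.numerator, self.denominator)


@dataclass
class DispersionModel:
    """Per-unit empirical and curve-shrunk NB dispersions."""

    empirical: pd.Series
    fitted: pd.Series
    working: pd.Series
    base_mean: pd.Series
    a0: float
    a1: float


# ---------------------------------------------------------------------------
# aggregation / filtering
# ---------------------------------------------------------------------------

def _snp_unit(row) -> str:
    return f"{row['chrom']}:{row['pos']}:{row['gene_id']}"


def aggregate(table: AlleleCountTable, genes: Optional[List[GeneModel]] = None,
              level: str = "gene", exonic_only: bool = True) -> CountMatrix:
    """Reshape the count table into a units x pseudo-samples matrix.

    Unit counts are sums of member-SNP counts.  ``exonic_only`` drops
    intronic SNPs (tables without an annotation column treat every SNP as
    exonic).  SNP level is a pass-through reshape; exon level maps each SNP
    to its host exon via the gene models (SNPs falling in introns are
    dropped at this level).
    """
    df = table.df.copy()
    if exonic_only and "annotation" in df.columns:
        df = df[df["annotation"] != "intronic"]
    if level == "gene":
        unit = df["gene_id"].astype(str)
    elif level == "snp":
        unit = df.apply(_snp_unit, axis=1)
    elif level == "exon":
        if genes is None:
            raise ValueError("exon-level aggregation requires gene models")
        gmap = {g.gene_id: g for g in genes}
        units = []
        for _, row in df.iterrows():
            g = gmap.get(row["gene_id"])
            idx = g.exon_index_of(int(row["pos"])) if g is not None else None
            units.append(None if idx is None else f"{row['gene_id']}:exon{idx:03d}")
        unit = pd.Series(units, index=df.index)
        df = df[unit.notna()]
        unit = unit.dropna()
    else:
        raise ValueError(f"invalid level {level!r}")

    cols, meta_rows = [], []
    data = {}
    for s in table.samples:
        for allele, suffix in (("B", "b"), ("D", "d")):
            col = f"{s.name}.{allele}"
            cols.append(col)
            meta_rows.append({"column": col, "sample": s.name,
                              "allele": allele, "cross": s.cross, "sex": s.sex})
            data[col] = df[f"{s.name}.{suffix}"].groupby(unit).sum()
    counts = pd.DataFrame(data)[cols]
    if level == "snp":  # preserve input row order
        order = unit[~unit.duplicated()].tolist()
        counts = counts.loc[order]
    meta = pd.DataFrame(meta_rows).set_index("column")
    return CountMatrix(counts, meta, level)


def filter_exclusive(obj, min_total: int = 0):
    """Drop units/SNPs where one allele is zero in every sample.

    Works on a :class:`CountMatrix` or an :class:`AlleleCountTable`.
    Returns ``(filtered, report)`` where the report lists removed rows with
    the absent allele and, for tables, the per-gene count of removed SNPs.
    """
    if isinstance(obj, CountMatrix):
        bcols = [c for c in obj.counts.columns if obj.meta.loc[c, "allele"] == "B"]
        dcols = [c for c in obj.counts.columns if obj.meta.loc[c, "allele"] == "D"]
        bsum = obj.counts[bcols].sum(axis=1)
        dsum = obj.counts[dcols].sum(axis=1)
        total_ok = (bsum + dsum) >= min_total
        b_excl = (dsum == 0) & (bsum > 0) & total_ok
        d_excl = (bsum == 0) & (dsum > 0) & total_ok
        removed = b_excl | d_excl
        report = pd.DataFrame({
            "unit_id": obj.counts.index[removed],
            "absent_allele": np.where(b_excl[removed], "D", "B"),
        })
        filtered = CountMatrix(obj.counts[~removed].copy(), obj.meta.copy(),
                               obj.level)
        return filtered, report
    table: AlleleCountTable = obj
    bsum = table.b_counts().sum(axis=1)
    dsum = table.d_counts().sum(axis=1)
    total_ok = (bsum + dsum) >= min_total
    b_excl = (dsum == 0) & (bsum > 0) & total_ok
    d_excl = (bsum == 0) & (dsum > 0) & total_ok
    removed = (b_excl | d_excl)
    rep = table.df.loc[removed, ["chrom", "pos", "gene_id"]].copy()
    rep["absent_allele"] = np.where(b_excl[removed], "D", "B")
    per_gene = rep.groupby("gene_id").size().rename("n_removed_snps")
    rep = rep.merge(per_gene, on="gene_id", how="left")
    return table.subset_rows(~removed), rep.reset_index(drop=True)


# ---------------------------------------------------------------------------
# size factors & dispersion
# ---------------------------------------------------------------------------

def size_factors(counts, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios library size factors.

    s_j = median over units of k_ij / geometric-mean_i, using units with
    all-positive counts.  With ``pseudo_reference`` the geometric mean
    ignores zeros, a fallback for sparse matrices.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    k = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logk = np.log(k)
    if pseudo_reference:
        finite = np.isfinite(logk)
        with np.errstate(invalid="ignore"):
            logmean = np.where(finite.any(axis=1),
                               np.nansum(np.where(finite, logk, np.nan), axis=1)
                               / np.maximum(finite.sum(axis=1), 1),
                               np.nan)
        usable = finite & np.isfinite(logmean)[:, None]
        sf = np.exp([np.median(logk[usable[:, j], j]
                               - logmean[usable[:, j]]) for j in range(k.shape[1])])
    else:
        allpos = np.isfinite(logk).all(axis=1)
        if not allpos.any():
            raise ValueError(
                "no unit with all-positive counts; retry with "
                "pseudo_reference=True"
            )
        logmean = logk[allpos].mean(axis=1)
        sf = np.exp(np.median(logk[allpos] - logmean[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def estimate_dispersion(matrix: CountMatrix, design: ContrastDesign,
                        factors: pd.Series) -> DispersionModel:
    """Method-of-moments NB dispersion per unit, shrunk toward a fitted
    alpha(mu) = a0 + a1/mu curve.

    The within-condition variance of normalized counts is pooled across the
    two conditions; the shot-noise term subtracted before forming
    alpha = (v - mu*mean(1/s)) / mu^2 accounts for unequal size factors.
    Working dispersion = max(empirical, fitted) (no shrinkage below the
    per-unit value).  Requires >= 2 replicates per condition.
    """
    labels = design.labels(matrix.meta)
    norm = matrix.counts.to_numpy(float) / factors.to_numpy()[None, :]
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError("design must have exactly two condition levels")
    pooled_var = np.zeros(norm.shape[0])
    dof = 0
    for lev in levels:
        cols = np.asarray(labels == lev)
        if cols.sum() < 2:
            raise ValueError(
                f"condition {lev!r} has a single replicate; dispersion "
                "cannot be estimated"
            )
        pooled_var += norm[:, cols].var(axis=1, ddof=1) * (cols.sum() - 1)
        dof += cols.sum() - 1
    pooled_var /= dof
    base_mean = norm.mean(axis=1)
    z = base_mean * np.mean(1.0 / factors.to_numpy())
    with np.errstate(divide="ignore", invalid="ignore"):
        emp = np.where(base_mean > 0,
                       np.maximum(0.0, (pooled_var - z) / base_mean ** 2), 0.0)

    a0, a1 = _fit_dispersion_curve(base_mean, emp)
    with np.errstate(divide="ignore"):
        fitted = np.where(base_mean > 0,
                          np.maximum(0.0, a0 + a1 / base_mean), 0.0)
    working = np.maximum(emp, fitted)
    idx = matrix.counts.index
    return DispersionModel(
        empirical=pd.Series(emp, index=idx),
        fitted=pd.Series(fitted, index=idx),
        working=pd.Series(working, index=idx),
        base_mean=pd.Series(base_mean, index=idx),
        a0=a0, a1=a1,
    )


def _fit_dispersion_curve(base_mean: np.ndarray,
                          emp: np.ndarray) -> Tuple[float, float]:
    """Gamma-family regression of empirical dispersion on 1/mu."""
    use = (emp > 0) & (base_mean > 0)
    if use.sum() < 10:
        med = float(np.median(emp[use])) if use.any() else 0.0
        return med, 0.0
    X = sm.add_constant(1.0 / base_mean[use])
    y = emp[use]
    try:
        import warnings

        with warnings.catch_warnings():
            # identity link on Gamma is intentional (the fitted curve is a
            # mean-dispersion relation, not a response model)
            warnings.simplefilter("ignore")
            model = sm.GLM(y, X, family=sm.families.Gamma(
                link=sm.families.links.Identity()))
            res = model.fit(start_params=[max(np.median(y), 1e-4), 1.0],
                            maxiter=100)
        a0, a1 = res.params
        if not (np.isfinite(a0) and np.isfinite(a1)):
            raise ValueError
    except Exception:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        a0, a1 = coef
    return float(a0), float(a1)


# ---------------------------------------------------------------------------
# exact tests & FDR
# ---------------------------------------------------------------------------

def _nb_split_logpmf(grid: np.ndarray, mean: float, var: float,
                     approximate: bool) -> np.ndarray:
    if approximate:
        return stats.norm.logpdf(grid, loc=mean, scale=math.sqrt(var))
    if var <= mean * (1 + 1e-12):  # Poisson limit
        return stats.poisson.logpmf(grid, mean)
    p = mean / var
    r = mean * mean / (var - mean)
    # nbinom.logpmf via gammaln, avoiding per-call scipy overhead
    return (gammaln(grid + r) - gammaln(r) - gammaln(grid + 1)
            + r * math.log(p) + grid * np.log1p(-p))


def nb_exact_test(counts: np.ndarray, labels: Sequence[str],
                  factors: np.ndarray, dispersion: float,
                  exact_limit: int = 10_000) -> float:
    """NB conditional exact p-value for a two-condition count vector.

    The two condition sums are modelled as NB with moments derived from the
    pooled normalized mean, the working dispersion and the condition
    size-factor sums; the two-sided p-value sums the probabilities of all
    splits a+b of the observed total that are no more probable than the
    observed split.  For totals above ``exact_limit`` the NB split masses
    are replaced by normal densities with the same moments.
    """
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(labels)
    factors = np.asarray(factors, dtype=float)
    if dispersion is None or not np.isfinite(dispersion):
        raise ValueError("working dispersion required")
    levels = sorted(set(labels))
    if len(levels) != 2:
        raise ValueError("exactly two condition levels required")
    in_a = labels == levels[0]
    k_a = counts[in_a].sum()
    k_total = counts.sum()
    if k_total == 0:
        return 1.0
    mu = float(np.mean(counts / factors))
    means, variances = [], []
    for mask in (in_a, ~in_a):
        s = factors[mask]
        m = mu * s.sum()
        v = m + dispersion * mu * mu * np.sum(s * s)
        means.append(m)
        variances.append(v)
    grid = np.arange(int(k_total) + 1, dtype=float)
    approx = k_total > exact_limit
    logp = (_nb_split_logpmf(grid, means[0], variances[0], approx)
            + _nb_split_logpmf(grid[::-1], means[1], variances[1], approx))
    obs = logp[int(k_a)]
    keep = logp <= obs + 1e-10
    p = math.exp(logsumexp(logp[keep]) - logsumexp(logp))
    return min(1.0, max(p, 5e-324))


def fisher_snp_test(b: int, d: int, b_total: int, d_total: int) -> float:
    """Two-sided Fisher exact p for one SNP against the rest of its library.

    The 2x2 table [[b, d], [B_total-b, D_total-d]] conditions on library
    totals, absorbing global allelic bias.  Degenerate (zero-margin) tables
    give p = 1.
    """
    if b > b_total or d > d_total:
        raise ValueError("SNP counts exceed library totals")
    table = np.array([[b, d], [b_total - b, d_total - d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(pvals, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

def run_contrast(matrix: CountMatrix, design: ContrastDesign,
                 alpha: float = 0.05, pseudocount: float = 0.5,
                 exact_limit: int = 10_000,
                 pseudo_reference: bool = False) -> pd.DataFrame:
    """Full per-unit analysis: size factors -> dispersion -> NB exact test
    -> BH FDR, with log2 fold changes from normalized condition means (plus
    a pseudocount) and a direction call for significant units.
    """
    frame, _, _ = _run_contrast_full(matrix, design, alpha, pseudocount,
                                     exact_limit, pseudo_reference)
    return frame


def _run_contrast_full(matrix: CountMatrix, design: ContrastDesign,
                       alpha: float = 0.05, pseudocount: float = 0.5,
                       exact_limit: int = 10_000,
                       pseudo_reference: bool = False):
    if design.sex_filter != "all":
        keep = design.sex_mask(matrix.meta)
        matrix = CountMatrix(matrix.counts.loc[:, keep.values].copy(),
                             matrix.meta.loc[keep.values].copy(), matrix.level)
    factors = size_factors(matrix.counts, pseudo_reference=pseudo_reference)
    disp = estimate_dispersion(matrix, design, factors)
    labels = design.labels(matrix.meta)
    f = factors.to_numpy()
    lab = labels.to_numpy()
    norm = matrix.counts.to_numpy(float) / f[None, :]
    num_mask = lab == design.numerator
    den_mask = lab == design.denominator
    mean_num = norm[:, num_mask].mean(axis=1)
    mean_den = norm[:, den_mask].mean(axis=1)
    log2fc = np.log2((mean_num + pseudocount) / (mean_den + pseudocount))

    raw = matrix.counts.to_numpy()
    working = disp.working.to_numpy()
    pvals = np.array([
        nb_exact_test(raw[i], lab, f, working[i], exact_limit=exact_limit)
        for i in range(raw.shape[0])
    ])
    padj = bh_fdr(pvals)
    significant = padj < alpha
    pos, neg = design.direction_labels()
    direction = np.where(significant,
                         np.where(log2fc > 0, pos, neg), "none")
    res = pd.DataFrame({
        "unit_id": matrix.counts.index,
        "base_mean": disp.base_mean.to_numpy(),
        "log2fc": log2fc,
        "pval": pvals,
        "padj": padj,
        "significant": significant,
        "direction": direction,
    }).set_index("unit_id")
    return res, factors, disp


def fisher_pipeline(table: AlleleCountTable, alpha: float = 0.05,
                    levels: Sequence[str] = ("gene", "snp"),
                    genes: Optional[List[GeneModel]] = None) -> Dict[str, pd.DataFrame]:
    """The per-sample Fisher baseline with intersection of sample calls.

    Each unit is tested against the rest of its library separately in every
    sample; BH correction is applied within sample; a unit is called only
    when significant with a concordant direction in all samples.  Returns
    one frame per requested aggregation level (per-gene and per-SNP call
    sets by default).
    """
    if len(table.samples) < 2:
        raise ValueError("Fisher pipeline needs >= 2 samples")
    out: Dict[str, pd.DataFrame] = {}
    for lev in dict.fromkeys(levels):
        matrix = aggregate(table, genes=genes, level=lev)
        b_cols = [c for c in matrix.counts.columns
                  if matrix.meta.loc[c, "allele"] == "B"]
        d_cols = [c for c in matrix.counts.columns
                  if matrix.meta.loc[c, "allele"] == "D"]
        frame = pd.DataFrame(index=matrix.counts.index)
        for bc, dc in zip(b_cols, d_cols):
            b = matrix.counts[bc].to_numpy()
            d = matrix.counts[dc].to_numpy()
            bt, dt = int(b.sum()), int(d.sum())
            p = np.array([fisher_snp_test(int(bi), int(di), bt, dt)
                          for bi, di in zip(b, d)])
            sample = matrix.meta.loc[bc, "sample"]
            frame[f"padj.{sample}"] = bh_fdr(p)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = (d / max(dt, 1)) - (b / max(bt, 1))
            frame[f"direction.{sample}"] = np.where(ratio > 0, "D", "B")
        out[lev] = fisher_calls(frame, alpha)
    return out


def fisher_calls(frame: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Re-threshold a Fisher-pipeline frame (padj.* / direction.* columns)
    at a new significance level without recomputing the tests."""
    padj_cols = [c for c in frame.columns if c.startswith("padj.")]
    dir_cols = [c for c in frame.columns if c.startswith("direction.")]
    calls = frame[padj_cols] < alpha
    all_sig = calls.all(axis=1)
    concordant = frame[dir_cols].nunique(axis=1) == 1
    called = all_sig & concordant
    out = frame[padj_cols + dir_cols].copy()
    out["called"] = called
    out["direction"] = np.where(called, frame[dir_cols].iloc[:, 0], "none")
    out["n_samples_significant"] = calls.sum(axis=1)
    return out


def replicate_titration(matrix: CountMatrix, design: ContrastDesign,
                        k_values: Sequence[int],
                        alpha: float = 0.05) -> pd.DataFrame:
    """Rerun the contrast on the first k mouse samples for each k.

    Reports the number of significant units and their overlap with the
    full-data calls.  k < 2 is rejected (dispersion needs replicates).
    """
    mice = matrix.mouse_samples
    full = run_contrast(matrix, design, alpha=alpha)
    full_sig = set(full.index[full["significant"]])
    rows = []
    for k in k_values:
        if k < 2:
            raise ValueError("k must be >= 2 (dispersion needs replicates)")
        if k > len(mice):
            raise ValueError(f"k={k} exceeds available samples ({len(mice)})")
        sub = matrix.subset_samples(mice[:k])
        res = run_contrast(sub, design, alpha=alpha)
        sig = set(res.index[res["significant"]])
        rows.append({"k": k, "n_significant": len(sig),
                     "overlap_with_full": len(sig & full_sig)})
    return pd.DataFrame(rows)


def compare_sexes(results_male: pd.DataFrame,
                  results_female: pd.DataFrame) -> Dict[str, object]:
    """Concordance of allelic fold changes between sex-restricted analyses."""
    shared = results_male.index.intersection(results_female.index)
    if len(shared) == 0:
        raise ValueError("no shared units between the two result sets")
    m = results_male.loc[shared]
    f = results_female.loc[shared]
    if len(shared) >= 2 and m["log2fc"].std() > 0 and f["log2fc"].std() > 0:
        r2 = float(np.corrcoef(m["log2fc"], f["log2fc"])[0, 1] ** 2)
    else:
        r2 = float("nan")
    sig_m = set(results_male.index[results_male["significant"]])
    sig_f = set(results_female.index[results_female["significant"]])
    return {
        "r2": r2,
        "n_shared": int(len(shared)),
        "n_significant_male": len(sig_m),
        "n_significant_female": len(sig_f),
        "n_both": len(sig_m & sig_f),
        "n_either": len(sig_m | sig_f),
        "male_specific": sorted(sig_m - sig_f),
        "female_specific": sorted(sig_f - sig_m),
    }


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class ASEModel:
    """Allelic-imbalance model for a pseudo-sample count matrix.

    Parameters
    ----------
    matrix : CountMatrix
        Aggregated units x (sample x allele) counts.
    design : ContrastDesign
        Strain or parent-of-origin contrast, optionally sex-restricted.

    Examples
    --------
    >>> model = ASEModel.from_count_table(table, genes, mode="strain")
    >>> results = model.fit()
    >>> results.frame.head()
    """

    def __init__(self, matrix: CountMatrix, design: Optional[ContrastDesign] = None):
        self.matrix = matrix
        self.design = design or ContrastDesign()

    @classmethod
    def from_count_table(cls, table: AlleleCountTable,
                         genes: Optional[List[GeneModel]] = None,
                         level: str = "gene", mode: str = "strain",
                         sex_filter: str = "all", exonic_only: bool = True,
                         drop_exclusive: bool = False) -> "ASEModel":
        matrix = aggregate(table, genes=genes, level=level,
                           exonic_only=exonic_only)
        if drop_exclusive:
            matrix, _ = filter_exclusive(matrix)
        return cls(matrix, ContrastDesign(mode=mode, sex_filter=sex_filter))

    def fit(self, alpha: float = 0.05, pseudocount: float = 0.5,
            exact_limit: int = 10_000,
            pseudo_reference: bool = False) -> "ASEResults":
        frame, factors, disp = _run_contrast_full(
            self.matrix, self.design, alpha=alpha, pseudocount=pseudocount,
            exact_limit=exact_limit, pseudo_reference=pseudo_reference)
        return ASEResults(self, frame, alpha, factors, disp)


class ASEResults:
    """Fitted allelic-imbalance results.

    Attributes
    ----------
    frame : pandas.DataFrame
        Per-unit base_mean, log2fc, pval, padj, significant, direction.
    size_factors : pandas.Series
    dispersion : DispersionModel
    """

    def __init__(self, model: ASEModel, frame: pd.DataFrame, alpha: float,
                 size_factors: pd.Series, dispersion: DispersionModel):
        self.model = model
        self.frame = frame
        self.alpha = alpha
        self.size_factors = size_factors
        self.dispersion = dispersion

    @property
    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame["significant"]]

    def summary(self) -> str:
        d = self.frame
        mode = self.model.design.mode
        pos, neg = self.model.design.direction_labels()
        lines = [
            "Allelic imbalance results",
            "=" * 64,
            f"contrast:            {mode}"
            f" ({pos} vs {neg}, log2fc = log2 {pos}/{neg})",
            f"aggregation level:   {self.model.matrix.level}",
            f"units tested:        {len(d)}",
            f"pseudo-samples:      {self.model.matrix.counts.shape[1]}",
            f"FDR threshold:       {self.alpha}",
            f"significant units:   {int(d['significant'].sum())}"
            f"  ({pos}-up: {(d['direction'] == pos).sum()},"
            f" {neg}-up: {(d['direction'] == neg).sum()})",
            f"dispersion curve:    alpha(mu) = {self.dispersion.a0:.4g}"
            f" + {self.dispersion.a1:.4g}/mu",
            f"size factors:        "
            + ", ".join(f"{k}={v:.3f}" for k, v in self.size_factors.items()),
            "=" * 64,
        ]
        top = d.nsmallest(min(10, len(d)), "padj")[
            ["base_mean", "log2fc", "pval", "padj", "direction"]]
        lines.append("top units by FDR:")
        lines.append(top.to_string(float_format=lambda x: f"{x:.3g}"))
        return "\n".join(lines)

    def plot_ma(self, ax=None, highlight: bool = True):
        """MA-style plot: allelic log2 fold change vs mean expression."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        d = self.frame
        ax.scatter(d["base_mean"], d["log2fc"], s=4, c="0.6", label="NS")
        if highlight:
            sig = d[d["significant"]]
            ax.scatter(sig["base_mean"], sig["log2fc"], s=6, c="crimson",
                       label=f"padj < {self.alpha}")
        ax.set_xscale("log")
        ax.set_xlabel("mean normalized count")
        pos, neg = self.model.design.direction_labels()
        ax.set_ylabel(f"log2({pos}/{neg})")
        ax.axhline(0.0, lw=0.5, c="k")
        ax.legend(frameon=False, fontsize=8)
        return ax
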