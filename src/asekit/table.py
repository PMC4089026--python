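"""The central per-SNP allele-count container.

An :class:`AlleleCountTable` holds, for every informative SNP, the number of
reads supporting the B allele, the D allele, and any third base, in each
sequenced sample.  Rows are keyed by ``(chrom, pos, gene_id)``; per-sample
counts live in columns ``<sample>.b`` / ``<sample>.d`` / ``<sample>.other``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np
import pandas as pd

from .types import SampleInfo

KEY_COLS = ["chrom", "pos", "gene_id"]


@dataclass
class AlleleCountTable:
    df: pd.DataFrame
    samples: List[SampleInfo]

    def __post_init__(self):
        missing = [c for c in KEY_COLS if c not in self.df.columns]
        if missing:
            raise ValueError(f"count table missing key columns {missing}")
        for s in self.samples:
            for a in ("b", "d", "other"):
                col = f"{s.name}.{a}"
                if col not in self.df.columns:
                    raise ValueError(f"count table missing column {col}")
                vals = self.df[col]
                if (vals < 0).any():
                    raise ValueError(f"negative counts in {col}")
        self.df = self.df.reset_index(drop=True)

    # -- convenience accessors -------------------------------------------
    @property
    def sample_names(self) -> List[str]:
        return [s.name for s in self.samples]

    def b_counts(self) -> pd.DataFrame:
        """SNP x sample matrix of B-allele counts."""
        return self.df[[f"{n}.b" for n in self.sample_names]].set_axis(
            self.sample_names, axis=1
        )

    def d_counts(self) -> pd.DataFrame:
        return self.df[[f"{n}.d" for n in self.sample_names]].set_axis(
            self.sample_names, axis=1
        )

    def n_snps(self) -> int:
        return len(self.df)

    def subset_rows(self, mask) -> "AlleleCountTable":
        return AlleleCountTable(
            self.df.loc[mask].reset_index(drop=True).copy(), list(self.samples)
        )

    def equals(self, other: "AlleleCountTable") -> bool:
        if [s for s in self.samples] != [s for s in other.samples]:
            return False
        a = self.df.reset_index(drop=True)
        b = other.df.reset_index(drop=True)
        if list(a.columns) != list(b.columns):
            return False
        return a.equals(b)


def empty_table(samples: List[SampleInfo], with_annotation: bool = True) -> AlleleCountTable:
    cols = list(KEY_COLS)
    if with_annotation:
        cols.append("annotation")
    for s in samples:
        cols += [f"{s.name}.b", f"{s.name}.d", f"{s.name}.other"]
    df = pd.DataFrame({c: pd.Series(dtype=(np.int64 if "." in c or c == "pos" else object))
                       for c in cols})
    return AlleleCountTable(df, samples)
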