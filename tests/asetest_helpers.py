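"""Shared builders for count-matrix tests."""

import numpy as np
import pandas as pd

from asekit.asetest import CountMatrix


def make_matrix(rows, labels_by_allele=True, level="gene"):
    """Build a CountMatrix from a units x 8 array laid out as
    [m1.B, m2.B, m3.B..., m1.D, m2.D, ...] halves or a units x n array with
    alternating columns — here: first half B columns, second half D."""
    arr = np.asarray(rows)
    n_cols = arr.shape[1]
    n_mice = n_cols // 2
    cols = [f"m{i}.B" for i in range(n_mice)] + \
           [f"m{i}.D" for i in range(n_mice)]
    counts = pd.DataFrame(arr, columns=cols,
                          index=[f"u{i}" for i in range(arr.shape[0])])
    crosses = ["BxD" if i % 2 == 0 else "DxB" for i in range(n_mice)]
    meta = pd.DataFrame({
        "sample": [c.split(".")[0] for c in cols],
        "allele": [c.split(".")[1] for c in cols],
        "cross": crosses * 2,
        "sex": (["F", "M"] * n_mice)[:n_mice] * 2,
    }, index=cols)
    return CountMatrix(counts, meta, level)
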