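import numpy as np
import pandas as pd
import pytest

from asekit import synth
from asekit.table import AlleleCountTable
from asekit.types import SampleInfo


@pytest.fixture(scope="session")
def small_cfg():
    return synth.SimulationConfig(seed=101, n_genes=60, mean_coverage=300)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """A compact simulated study shared by read-only tests."""
    ann = synth.gen_annotation(small_cfg)
    truth = synth.gen_truth(small_cfg)
    table = synth.gen_counts(ann, truth, small_cfg)
    return small_cfg, ann, truth, table


@pytest.fixture
def four_samples():
    return [
        SampleInfo("BxD_F", "BxD", "F"),
        SampleInfo("DxB_F", "DxB", "F"),
        SampleInfo("BxD_M", "BxD", "M"),
        SampleInfo("DxB_M", "DxB", "M"),
    ]


def make_table(rows, samples):
    """Build an AlleleCountTable from (chrom, pos, gene, [(b, d), ...]) rows."""
    data = {"chrom": [], "pos": [], "gene_id": [], "annotation": []}
    for s in samples:
        for a in ("b", "d", "other"):
            data[f"{s.name}.{a}"] = []
    for chrom, pos, gene, counts, *rest in rows:
        ann = rest[0] if rest else "exonic"
        data["chrom"].append(chrom)
        data["pos"].append(pos)
        data["gene_id"].append(gene)
        data["annotation"].append(ann)
        for s, (b, d) in zip(samples, counts):
            data[f"{s.name}.b"].append(b)
            data[f"{s.name}.d"].append(d)
            data[f"{s.name}.other"].append(0)
    return AlleleCountTable(pd.DataFrame(data), samples)


@pytest.fixture
def make_count_table(four_samples):
    def _make(rows):
        return make_table(rows, four_samples)

    return _make
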