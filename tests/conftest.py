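import numpy as np
import pandas as pd
import pytest

import tempodeg as td


@pytest.fixture(scope="session")
def benchmark():
    """Default synthetic benchmark, simulated once per session."""
    return td.simulate_panel(seed=7)


@pytest.fixture(scope="session")
def benchmark_analysis(benchmark):
    """Full standard analysis of the session benchmark."""
    return td.analyze_counts(benchmark.count_table, benchmark.samples)


def make_count_table(endo, hk=None, pos=None, neg=None, sample_ids=None):
    """Small hand-built CountTable from {gene: [counts...]} dicts per class."""
    blocks, classes = [], []
    for block, cc in (
        (endo, "Endogenous"),
        (hk or {}, "Housekeeping"),
        (pos or {}, "Positive"),
        (neg or {}, "Negative"),
    ):
        for gene, row in block.items():
            blocks.append((gene, row))
            classes.append(cc)
    genes = [g for g, _ in blocks]
    mat = np.array([r for _, r in blocks])
    cols = sample_ids or [f"s{i + 1}" for i in range(mat.shape[1])]
    counts = pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"), columns=cols)
    return td.CountTable(counts=counts, code_class=pd.Series(classes, index=counts.index))


@pytest.fixture
def tiny_table():
    return make_count_table(
        endo={"C3": [3, 40, 7], "Gfap": [10, 22, 30], "Vim": [50, 60, 55]},
        hk={"Hk1": [100, 100, 100], "Hk2": [200, 210, 190]},
        pos={"Pos1": [5000, 5100, 4900]},
        neg={"Neg1": [4, 5, 6], "Neg2": [6, 7, 8], "Neg3": [8, 6, 7]},
    )
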