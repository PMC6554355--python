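import numpy as np
import pandas as pd
import pytest

from compartmentseq import SimConfig, simulate_experiment
from compartmentseq.containers import CountMatrix, GeneAnnotation


@pytest.fixture(scope="session")
def small_experiment():
    """A 300-gene default-bias experiment shared by read-only tests."""
    cfg = SimConfig(n_genes=300, seed=7)
    return simulate_experiment(cfg)


def make_metadata(methods, cell_types, sexes=None, prefix="s"):
    n = len(methods)
    sexes = sexes or ["M"] * n
    return pd.DataFrame(
        {"method": methods, "cell_type": cell_types, "sex": sexes},
        index=[f"{prefix}{i}" for i in range(n)],
    )


@pytest.fixture
def toy_counts():
    """3 genes x 2 samples with hand-chosen totals 2e6 and 5e5."""
    meta = make_metadata(["nuclear", "nuclear"], ["D1", "D2"])
    counts = pd.DataFrame(
        {"s0": [1_000_000, 600_000, 400_000], "s1": [100_000, 250_000, 150_000]},
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
    )
    return CountMatrix(counts, meta)


@pytest.fixture
def toy_annotation():
    table = pd.DataFrame(
        {
            "length_bp": [1000, 2000, 500],
            "biotype": ["protein_coding", "lincRNA", "protein_coding"],
            "chrom": ["1", "2", "3"],
            "start": [100, 200, 300],
            "stop": [5000, 9000, 2500],
        },
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
    )
    return GeneAnnotation(table)
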