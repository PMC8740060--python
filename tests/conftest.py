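import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import cistrans as ct
from cistrans.ase import CLASSES

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

EQUAL_TOTALS = {c: 1.0 for c in CLASSES}


@pytest.fixture(scope="session")
def benchmark_run():
    """Classifier output on the packaged seed-42 benchmark, with truth."""
    config = ct.benchmark_config(42)
    counts, truth = ct.simulate_regulatory_counts(config)
    adjusted = ct.adjust_depth(counts, EQUAL_TOTALS)
    tests, calls = ct.classify_regulatory_divergence(adjusted, alpha=0.005)
    truth_df = pd.DataFrame(
        [(t.gene_id, t.true_category, t.c, t.t) for t in truth],
        columns=["gene_id", "true_category", "c", "t"],
    )
    return counts, truth_df, tests, calls.merge(truth_df, on="gene_id")


@pytest.fixture(scope="session")
def null_run():
    """All-conserved simulation (1000 genes, seed 7) through the classifier."""
    config = ct.SimulationConfig(
        n_genes=1000,
        category_proportions={"conserved": 1.0},
        base_mean_range=(500.0, 500.0),
        seed=7,
    )
    counts, truth = ct.simulate_regulatory_counts(config)
    adjusted = ct.adjust_depth(counts, EQUAL_TOTALS)
    _, calls = ct.classify_regulatory_divergence(adjusted, alpha=0.005)
    return calls
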