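import numpy as np
import pytest

from termread.coverage import mean_coverage, smooth_and_bin
from termread.diffexpr import DifferentialExpression
from termread.simulate import (
    MINUS_AUXIN,
    PLUS_AUXIN,
    SimulationConfig,
    simulate_dataset,
)


def condition_coverage(cfg, table, observed):
    """Replicate-pooled CPM coverage per condition, as the pipeline builds it."""
    out = {}
    for cond in cfg.conditions:
        pooled = mean_coverage([observed[s] for s in table.condition_samples(cond)])
        out[cond] = smooth_and_bin(pooled, cfg.bin_size, 2 * cfg.bin_size)
    return out


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded mid-size simulation shared across read-only tests."""
    cfg = SimulationConfig(n_genes=300, seed=11)
    annotation, expected, table, observed = simulate_dataset(cfg)
    cond_cov = condition_coverage(cfg, table, observed)
    de = DifferentialExpression(table, treated=PLUS_AUXIN, control=MINUS_AUXIN).fit()
    return {
        "config": cfg,
        "annotation": annotation,
        "expected": expected,
        "table": table,
        "observed": observed,
        "cond_cov": cond_cov,
        "de": de,
    }
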