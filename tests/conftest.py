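import numpy as np
import pandas as pd
import pytest

from parallex import synthetic_data as syn


@pytest.fixture(scope="session")
def small_expression_study():
    """One-stage synthetic study with 40% affected genes (seed-fixed)."""
    cfg = syn.ExpressionSimConfig(
        n_genes=1_200,
        samples_per_group=6,
        class_fractions={
            "null": 0.6,
            "parallel_up": 0.1,
            "parallel_down": 0.1,
            "snail_only": 0.05,
            "scale_only": 0.1,
            "opposite": 0.05,
        },
        stages=("8-10dpf",),
        seed=11,
    )
    counts, samples, truth = syn.simulate_expression_study(cfg)
    return cfg, counts, samples, truth


@pytest.fixture
def two_group_counts():
    """Poisson counts with a null two-group design (10 vs 10)."""
    rng = np.random.default_rng(42)
    mu = rng.lognormal(4.0, 1.0, 500)
    y = rng.poisson(mu[:, None], (500, 20))
    counts = pd.DataFrame(
        y, index=[f"g{i}" for i in range(500)], columns=[f"s{j}" for j in range(20)]
    )
    samples = pd.DataFrame(
        {
            "sample_id": counts.columns,
            "species": ["generalist"] * 10 + ["snail_eater"] * 10,
            "lake": "crescent_pond",
            "stage": "8-10dpf",
            "generation": "F2",
        }
    )
    return counts, samples
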