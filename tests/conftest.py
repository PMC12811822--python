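import warnings

import numpy as np
import pandas as pd
import pytest

from thermoplast.synth import (
    SynthExprConfig,
    SynthGenomeConfig,
    SynthThermalConfig,
    gen_expression_dataset,
    gen_genome_fixture,
    gen_thermal_dataset,
)

warnings.filterwarnings("ignore", message="ArviZ")


@pytest.fixture(scope="session")
def thermal_small():
    cfg = SynthThermalConfig(n_individuals_per_group=6, seed=7)
    table, truth = gen_thermal_dataset(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def expr_bundle():
    cfg = SynthExprConfig(seed=3)
    counts, samples, truth = gen_expression_dataset(cfg)
    return cfg, counts, samples, truth


@pytest.fixture(scope="session")
def genome_bundle():
    cfg = SynthGenomeConfig(seed=2)
    return cfg, gen_genome_fixture(cfg)


def hub_expression(seed: int, n_samp: int = 30, sizes=(150, 80, 40, 20, 10), n_bg: int = 150):
    """Latent expression with hub structure (heterogeneous loadings and
    module sizes) whose connectivity spectrum is approximately scale-free."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in sizes:
        f = rng.standard_normal(n_samp)
        for _ in range(s):
            load = rng.uniform(0.4, 0.95)
            rows.append(load * f + np.sqrt(1 - load * load) * rng.standard_normal(n_samp))
    for _ in range(n_bg):
        rows.append(rng.standard_normal(n_samp))
    X = np.asarray(rows)
    return pd.DataFrame(
        X, index=[f"g{i:04d}" for i in range(len(rows))], columns=[f"s{j}" for j in range(n_samp)]
    )


@pytest.fixture(scope="session")
def hub_expr():
    return hub_expression(seed=0)
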