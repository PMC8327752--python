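import numpy as np
import pandas as pd
import pytest

from hepanet.io_formats import ExpressionMatrix, SampleInfo
from hepanet.synthetic_data import SimulationConfig, simulate_expression


@pytest.fixture(scope="session")
def planted():
    """Default planted-structure dataset: 54 pairs, 3 modules of 50 at rho=0.9."""
    cfg = SimulationConfig(seed=11)
    expr, samples, truth = simulate_expression(cfg)
    return cfg, expr, samples, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_expr(values, genes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def paired_samples(n_subjects):
    out = []
    for i in range(n_subjects):
        sid = f"S{i:03d}"
        out.append(SampleInfo(f"{sid}T", sid, "tumor"))
        out.append(SampleInfo(f"{sid}N", sid, "normal"))
    return out
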