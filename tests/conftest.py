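"""Shared fixtures: one small and one full-size simulated study."""
import numpy as np
import pandas as pd
import pytest

from erynet import simulate
from erynet.core import ExpressionMatrix


@pytest.fixture(scope="session")
def small_config():
    """A 300-gene variant of the study design for fast unit tests.

    Plants only 30 differential genes so that differential expression stays
    a small fraction of this reduced genome (as in the full design).
    """
    de = tuple(
        simulate.DEEffect(gene=f"G{100 + i:04d}", time="t2", strain="HP",
                          delta=2.0 if i < 20 else -2.0)
        for i in range(30)
    )
    return simulate.default_config(n_genes=300, seed=7, de_effects=de)


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate.simulate_expression(small_config)


@pytest.fixture(scope="session")
def default_config():
    return simulate.default_config()


@pytest.fixture(scope="session")
def default_sim(default_config):
    """The full 2000-gene study at the default seed."""
    return simulate.simulate_expression(default_config)


@pytest.fixture(scope="session")
def clean_matrix(default_sim, default_config):
    """Expression matrix with the two outlier arrays removed."""
    expr, _ = default_sim
    keep = [s for s in expr.sample_ids if s not in default_config.outlier_samples]
    return expr.subset_samples(keep)


def toy_matrix(values, strains, times, replicates=None):
    """Build a small ExpressionMatrix from a values array and group labels."""
    replicates = replicates or list(range(1, len(strains) + 1))
    ids = [f"{s}_{t}_r{r}" for s, t, r in zip(strains, times, replicates)]
    samples = pd.DataFrame(
        {"strain": strains, "time": times, "replicate": replicates},
        index=pd.Index(ids, name="sample"),
    )
    genes = pd.Index([f"g{i}" for i in range(np.asarray(values).shape[0])], name="gene")
    vals = pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=ids)
    return ExpressionMatrix(values=vals, samples=samples)
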