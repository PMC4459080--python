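import dataclasses
import logging

import numpy as np
import pandas as pd
import pytest

from profcorr import simulate as sim
from profcorr import diffexpr as de

logging.getLogger("profcorr").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_experiment():
    """One coupled synthetic experiment at the default design shape."""
    cfg = sim.SimulationConfig(seed=11)
    return sim.generate_experiment(cfg)


@pytest.fixture(scope="session")
def default_fc(default_experiment):
    """Fold-change tables (both layers) for the default experiment."""
    mrna, protein, _ = default_experiment
    return de.compute_fold_changes(mrna), de.compute_fold_changes(protein)


@pytest.fixture(scope="session")
def strong_experiment():
    """Strong, tightly coupled experiment: flags should recover the truth."""
    cfg = sim.SimulationConfig(coupling=0.95, effect_sd=1.5, replicate_sd=0.15, seed=23)
    return sim.generate_experiment(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def make_dataset(values: dict[str, list[float]], meta_rows: list[dict], layer: str = "mrna"):
    """Small hand-built ExpressionDataset: values maps sample id -> column."""
    from profcorr.datamodel import ExpressionDataset

    features = [f"g{i}" for i in range(len(next(iter(values.values()))))]
    mat = pd.DataFrame(values, index=pd.Index(features, name="feature"), dtype=float)
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    return ExpressionDataset(layer=layer, values=mat, samples=samples)
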