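import numpy as np
import pandas as pd
import pytest

from somportraits import preprocess, som, synthetic


@pytest.fixture(scope="session")
def small_study():
    """Synthetic study small enough for every module test: 600 genes, 6 conditions,
    2 planted modules of 40 genes, 3 replicates."""
    truth = synthetic.SyntheticTruth(n_modules=2, module_size=40, n_groups=2, seed=11)
    raw, conditions, pc, truth = synthetic.generate(truth, 600, 6)
    return {"raw": raw, "conditions": conditions, "pc": pc, "truth": truth}


@pytest.fixture(scope="session")
def preprocessed(small_study):
    delta, log_expr = preprocess.preprocess(small_study["raw"], small_study["conditions"])
    return {"delta": delta, "log_expr": log_expr, **small_study}


@pytest.fixture(scope="session")
def trained(preprocessed):
    delta = preprocessed["delta"]
    grid = som.linear_initialize(delta, (8, 8))
    grid = som.train(delta, grid, som.TrainingSchedule(n_presentations=4000, seed=5))
    assignment = som.map_genes(delta, grid)
    return {"grid": grid, "assignment": assignment, **preprocessed}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_delta():
    """Tiny deterministic matrix for hand-checkable operations."""
    return pd.DataFrame(
        [[-1.0, 0.0, 1.0], [0.5, -0.25, -0.25], [2.0, -1.0, -1.0], [0.0, 0.0, 0.0]],
        index=["gA", "gB", "gC", "gD"],
        columns=["s1", "s2", "s3"],
    )
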