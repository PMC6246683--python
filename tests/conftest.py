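import numpy as np
import pandas as pd
import pytest

from estuarynet.dissimilarity import DistanceMatrix
from estuarynet.synthetic import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def scenario():
    """One default synthetic transect shared by read-only tests."""
    env, otus, func, tree, truth = generate_scenario(ScenarioConfig(seed=42))
    return {"env": env, "otus": otus, "func": func, "tree": tree,
            "truth": truth}


@pytest.fixture()
def toy_distance():
    """6-sample two-cluster distance matrix with known structure."""
    rng = np.random.default_rng(17)
    x = rng.standard_normal((6, 3))
    x[3:] += 4.0
    from scipy.spatial.distance import pdist, squareform

    ids = [f"s{i}" for i in range(6)]
    d = pd.DataFrame(squareform(pdist(x)), index=ids, columns=ids)
    groups = pd.Series(["a"] * 3 + ["b"] * 3, index=ids)
    return DistanceMatrix(d), groups
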