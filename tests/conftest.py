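import matplotlib
import numpy as np
import pandas as pd
import pytest

matplotlib.use("Agg")

from rpslogit.model import CrashDataset, ModelSpec
from rpslogit.simulate import GeneratorConfig, generate
from rpslogit.spatial import chain_network


@pytest.fixture(scope="session")
def chain3():
    return chain_network(3)


@pytest.fixture(scope="session")
def small_synth():
    """A small synthetic dataset (N=400, M=20) at the reference truth."""
    return generate(GeneratorConfig(N=400, M=20, seed=11))


@pytest.fixture()
def toy_dataset():
    """Three hand-written crashes on a two-section chain."""
    net = chain_network(2)
    ds = CrashDataset(
        outcome=np.array([1, 0, 0]),
        covariates=pd.DataFrame(
            {
                "ems_response_time": [30.0, 10.0, 5.0],
                "truck": [1, 0, 1],
                "grade": [1.2, 0.3, 0.0],
            }
        ),
        section_id=np.array(["S1", "S2", "S1"], dtype=object),
    )
    return ds, net


@pytest.fixture()
def toy_spec():
    return ModelSpec(
        family="logistic",
        covariates=("ems_response_time", "truck", "grade"),
        random_set=frozenset(),
    )
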