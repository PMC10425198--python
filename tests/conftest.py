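import numpy as np
import pandas as pd
import pytest

from picoda import FeatureTable, Namespace, SampleMetadata
from picoda.synthetic import SimulationConfig, simulate_profile

FIXTURE_SEEDS = (1, 2, 3)


def make_table(values, feature_ids=None, sample_ids=None, namespace=Namespace.KO):
    values = np.asarray(values, dtype=float)
    feature_ids = feature_ids or [f"K{i + 1:05d}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{j + 1}" for j in range(values.shape[1])]
    return FeatureTable(
        feature_ids=feature_ids, sample_ids=sample_ids, values=values,
        namespace=namespace,
    )


def make_meta(sample_ids, groups, reference=None):
    groups = list(groups)
    return SampleMetadata(
        sample_ids=list(sample_ids),
        group=pd.Series(groups, index=list(sample_ids)),
        reference_group=reference or sorted(set(groups))[0],
    )


@pytest.fixture
def tiny_table():
    return make_table(
        [[10, 20, 5, 8], [1, 2, 3, 4], [100, 80, 120, 90]],
        sample_ids=["S1", "S2", "S3", "S4"],
    )


@pytest.fixture
def tiny_meta(tiny_table):
    return make_meta(tiny_table.sample_ids, ["A", "A", "B", "B"])


@pytest.fixture(scope="session")
def spiked_sims():
    """The spiked study fixture: 10% of 500 KOs at log2 effect 2, n=20/group."""
    return [simulate_profile(SimulationConfig(seed=s)) for s in FIXTURE_SEEDS]


@pytest.fixture(scope="session")
def null_sims():
    """Null fixtures (no spiked features) at the same size, three seeds."""
    return [
        simulate_profile(SimulationConfig(seed=s, prop_da=0.0, effect_log2=0.0))
        for s in FIXTURE_SEEDS
    ]
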