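import numpy as np
import pytest

from uromet.io import CONTROL, STUDY, BucketTable
from uromet.synthetic import SyntheticDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def default_design():
    """The generator's default study conditions (seeded)."""
    return SyntheticDesign(seed=7)


@pytest.fixture
def null_design():
    """Same conditions with no group effect at any week."""
    return SyntheticDesign(
        effect_trajectory={1: 1.0, 3: 1.0, 5: 1.0, 7: 1.0}, seed=7
    )


def make_table(values, groups, weeks=None, bucket_ids=None, normalized=False):
    """Small helper to assemble a BucketTable from raw pieces."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    return BucketTable(
        sample_ids=[f"s{i}" for i in range(n)],
        groups=list(groups),
        weeks=list(weeks) if weeks is not None else [1] * n,
        bucket_ids=list(bucket_ids) if bucket_ids is not None
        else [f"b{j}" for j in range(k)],
        values=values,
        normalized=normalized,
    )


@pytest.fixture
def table_factory():
    return make_table
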