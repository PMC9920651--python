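import numpy as np
import pytest

from ecgtcn import HeartbeatDataset, TCNSpec, generate_dataset


@pytest.fixture(scope="session")
def tiny_spec() -> TCNSpec:
    """Two-block, three-filter network on short sequences; fast to probe."""
    return TCNSpec.build(2, 3, (2, 3), dropout=0.0, num_classes=3,
                         input_length=16)


@pytest.fixture(scope="session")
def synthetic_1k() -> HeartbeatDataset:
    """1000 synthetic beats with the archive's class mix (default noise)."""
    return generate_dataset(1000, seed=123)


@pytest.fixture()
def toy_dataset() -> HeartbeatDataset:
    """Deterministic 12-beat, 3-class dataset of 8-sample ramps."""
    rng = np.random.default_rng(7)
    X = np.tile(np.linspace(-1, 1, 8), (12, 1)) + rng.normal(0, 0.01, (12, 8))
    y = np.array([1, 1, 1, 1, 2, 2, 2, 2, 3, 3, 3, 3])
    return HeartbeatDataset(X, y)
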