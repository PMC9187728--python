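import numpy as np
import pytest

import qgarbf as q


@pytest.fixture(scope="session")
def default_clean_split():
    """Full-scale pipeline input: default factorial design, cleaned and split."""
    records = q.generate_dataset(q.ExperimentDesign(), q.GroundTruthParams(seed=1))
    result = q.clean(records)
    return q.split(result.groups, 0.8, seed=1)


@pytest.fixture(scope="session")
def small_split():
    """Reduced factorial design (3 x 6 x 3 conditions) for fast optimizer tests."""
    design = q.ExperimentDesign(
        temperatures=(18.0, 24.0, 30.0),
        ppfd_levels=(1600.0, 800.0, 400.0, 100.0, 20.0, 0.0),
        blue_ratios=(0.2, 0.5, 0.8),
        replicates=3,
    )
    records = q.generate_dataset(design, q.GroundTruthParams(seed=3))
    result = q.clean(records)
    return q.split(result.groups, 0.8, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
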