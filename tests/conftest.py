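import numpy as np
import pandas as pd
import pytest

from voxelrel.synthetic import (
    VarianceComponents,
    generate_parcel_voxels,
    generate_predictor_panel,
)


@pytest.fixture(scope="session")
def pred_panel_30x10():
    """Unit between/within SD predictor for the default study design."""
    return generate_predictor_panel(1.0, 1.0, 30, 10, seed=101)


@pytest.fixture(scope="session")
def cell_means_null():
    """Null outcome per participant-session, random-intercept share 0.2."""
    rng = np.random.default_rng(7)
    n, s = 30, 10
    lam = rng.normal(0, np.sqrt(0.2), n)
    idx = pd.MultiIndex.from_product(
        [range(1, n + 1), range(1, s + 1)], names=["participant", "session"]
    )
    vals = lam[np.repeat(np.arange(n), s)] + rng.normal(0, np.sqrt(0.8), n * s)
    return pd.DataFrame({"value": vals}, index=idx).reset_index()


@pytest.fixture(scope="session")
def three_level_panel():
    """Balanced voxel panel with known components (1, 1, 2)."""
    vc = VarianceComponents(0.0, tuple(np.zeros(10)), 1.0, 1.0, 2.0)
    return generate_parcel_voxels(vc, 50, 10, 50, seed=2)
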