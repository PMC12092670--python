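import numpy as np
import pandas as pd
import pytest

from floralnoise import BudTable, StudyConfig


@pytest.fixture
def config():
    return StudyConfig()


@pytest.fixture
def fast_config():
    """Config with shallow resampling for quick pipeline runs."""
    return StudyConfig(n_permutations=999, n_bootstrap=200, seed=0)


def build_bud(
    x, y, z=None, bud_id="b1", stage="2c", treatment="none", **channels
) -> BudTable:
    """Construct a BudTable from coordinate/signal arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.zeros_like(x) if z is None else np.asarray(z, dtype=float)
    frame = pd.DataFrame({"x_um": x, "y_um": y, "z_um": z})
    for name, values in channels.items():
        frame[name] = np.asarray(values, dtype=float)
    return BudTable(
        bud_id=bud_id,
        stage=stage,
        treatment=treatment,
        data=frame,
        channels=tuple(channels),
    )


@pytest.fixture
def build_bud_fixture():
    return build_bud
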