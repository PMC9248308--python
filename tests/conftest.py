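import numpy as np
import pytest

from icedmri import SyntheticSpec, VarianceComponents, simulate_roi_dataset
from icedmri.design import default_mpm_design


@pytest.fixture(scope="session")
def design():
    return default_mpm_design()


@pytest.fixture(scope="session")
def mixed_components():
    """All four compartments clearly positive (away from the bound)."""
    return VarianceComponents(0.5, 0.15, 0.1, 0.25)


@pytest.fixture(scope="session")
def mixed_dataset(design, mixed_components):
    """Medium-size dataset with all compartments present."""
    spec = SyntheticSpec(60, design, [1.0] * 4, mixed_components, seed=11)
    return simulate_roi_dataset(spec)


@pytest.fixture(scope="session")
def small_dataset(design):
    """Tiny 5-person dataset for oracle comparisons."""
    rng = np.random.default_rng(42)
    from icedmri import ReliabilityDataset

    return ReliabilityDataset(rng.normal(1.0, 0.4, (5, design.k)), design)
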