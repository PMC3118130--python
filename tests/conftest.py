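import numpy as np
import pytest

from aimpanel import FrequencyPanel, GenotypeTable, SimulationConfig, simulate_panel


@pytest.fixture
def small_panel() -> FrequencyPanel:
    """3 populations x 4 loci with hand-chosen frequencies."""
    freq = np.array([
        [0.2, 0.4, 0.0, 0.9],
        [0.5, 0.4, 1.0, 0.8],
        [0.8, 0.4, 0.5, 0.1],
    ])
    return FrequencyPanel(["popA", "popB", "popC"],
                          ["L1", "L2", "L3", "L4"], freq, [10, 12, 8])


@pytest.fixture
def two_pop_fixed_panel() -> FrequencyPanel:
    """Two populations fixed for opposite alleles at every locus."""
    freq = np.array([[1.0, 1.0, 1.0],
                     [0.0, 0.0, 0.0]])
    return FrequencyPanel(["A", "B"], ["L1", "L2", "L3"], freq, [20, 20])


@pytest.fixture
def tiny_gt() -> GenotypeTable:
    dosage = np.array([
        [2.0, 1.0, 0.0, 2.0],
        [1.0, 1.0, 1.0, np.nan],
        [0.0, 2.0, 2.0, 0.0],
    ])
    return GenotypeTable(["i1", "i2", "i3"], ["L1", "L2", "L3", "L4"],
                         dosage, ["popA", "popA", "popB"])


@pytest.fixture(scope="session")
def standard_sim():
    """The workhorse simulation: 8 equally diverged breeds, F = 0.10."""
    cfg = SimulationConfig(n_breeds=8, n_loci=2000, breed_fst=[0.1] * 8,
                           sample_sizes=[30] * 8, seed=1)
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def study_sim():
    """17 heterogeneous breeds shaped like a real breed survey."""
    return simulate_panel(SimulationConfig.study_like(seed=1))
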