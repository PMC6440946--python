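import pytest

from bcrnet.reference import get_default_reference
from bcrnet.simulate import SimulationConfig, simulate_repertoire


@pytest.fixture(scope="session")
def reference():
    return get_default_reference()


@pytest.fixture(scope="session")
def noiseless_sample():
    """Small sample with no SHM, no sequencing error, unique UMIs."""
    config = SimulationConfig(
        seed=11,
        dominant_fractions=(0.6, 0.3),
        n_background_clones=5,
        n_molecules=400,
        shm_rate=0.0,
        seq_error=0.0,
        unique_umis=True,
        pcr_mean_depth=3.0,
    )
    return simulate_repertoire(config)


@pytest.fixture(scope="session")
def noisy_sample():
    """Sample at the standard study conditions (SHM + sequencing error)."""
    config = SimulationConfig(
        seed=7,
        dominant_fractions=(0.9,),
        n_molecules=3000,
        shm_rate=0.005,
        seq_error=0.003,
    )
    return simulate_repertoire(config)
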