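import numpy as np
import pytest

from gconnect.synth import BatterySpec, NetworkSpec, simulate_battery, simulate_connectomes


def equicorrelation(p: int, rho: float) -> np.ndarray:
    R = np.full((p, p), rho)
    np.fill_diagonal(R, 1.0)
    return R


@pytest.fixture(scope="session")
def battery_500():
    """Large two-group one-factor battery, no group shift."""
    return simulate_battery(
        BatterySpec(n_per_group=500, loadings=np.full(11, 0.7), group_shift=0.0, seed=11)
    )


@pytest.fixture(scope="session")
def shifted_battery():
    """Battery with the default patient deficit on the latent factor."""
    return simulate_battery(BatterySpec(n_per_group=120, seed=5))


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject modular connectome cohort with a planted group deficit."""
    spec = NetworkSpec(
        n_nodes=48, module_sizes=[12] * 4, within_corr=0.5, between_corr=0.1,
        subject_noise_sd=0.05, group_delta=0.15, seed=21,
    )
    return spec, simulate_connectomes(spec, 3)
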