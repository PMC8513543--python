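import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ktah_cea as k
from ktah_cea.params import EconomicInputs, ModelParameters
from ktah_cea.registry import monthly_rows_from_events

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def truth():
    """Default synthetic generating process."""
    return k.default_ground_truth()


@pytest.fixture(scope="session")
def recovery_registry(truth):
    """~10,000-patient registry with known ground truth (5 years)."""
    return k.generate_registry(truth, n_years=5, seed=1234)


@pytest.fixture(scope="session")
def recovery_counts(recovery_registry):
    return k.count_annual_transitions(recovery_registry)


@pytest.fixture(scope="session")
def estimated_params(recovery_registry):
    """Full estimation pipeline output on the recovery registry."""
    return k.estimate_parameters(recovery_registry)


def build_two_modality_params(
    horizon: int = 24,
    initial_chd: float = 10_000.0,
    initial_ldkt: float = 10_000.0,
    inflow_chd: float = 50.0,
    chd_to_ldkt_fy: float = 0.02,
) -> ModelParameters:
    """Toy configuration active on CHD and LDKT only; the other four
    modalities are inert. LDKT utility exceeds dialysis utility."""
    monthly = monthly_rows_from_events(
        {
            ("CHD", "first_year"): {"LDKT": chd_to_ldkt_fy, "death": 0.01},
            ("CHD", "subsequent"): {"LDKT": 0.01, "death": 0.012},
            ("LDKT", "first_year"): {"CHD": 0.005, "death": 0.002},
            ("LDKT", "subsequent"): {"CHD": 0.002, "death": 0.001},
        }
    )
    inflow = np.zeros((horizon, 1, 6))
    inflow[:, 0, 0] = inflow_chd
    initial = np.zeros((1, 6, 13))
    initial[0, 0, 12] = initial_chd
    initial[0, 5, 12] = initial_ldkt
    return ModelParameters(
        monthly=monthly,
        inflow=inflow,
        initial=initial,
        econ=k.economic_inputs_from_reference(),
    )


@pytest.fixture()
def toy_params():
    return build_two_modality_params()
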