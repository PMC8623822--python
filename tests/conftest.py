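import numpy as np
import pytest
from hypothesis import settings

from memdiel import CircuitParams, GeneratorConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def control_circuit() -> CircuitParams:
    """Planar-bilayer control condition: 0.79 µF/cm² and 1.42 MΩ·cm²
    over the 8e-5 cm² aperture, Teflon capacitance 56.33 pF, 100 kΩ
    series resistance."""
    return CircuitParams.from_specific(0.79, 1.42e6)


@pytest.fixture
def control_guv() -> dict:
    """GUV control batch conditions: λ_in = 258 µS/cm, Λ = 0.87,
    C̄_m truth 0.44 µF/cm²."""
    return {
        "cm_eff": 0.44,
        "lambda_in_s_m": 258e-4,
        "ratio": 0.87,
    }


@pytest.fixture
def quiet_config() -> GeneratorConfig:
    return GeneratorConfig(seed=7, fcr_noise_cv=0.0, eis_noise_frac=0.0)
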