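import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mesocluster as mc

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rd_params() -> mc.RDParams:
    """Equilibrated reaction-diffusion parameters for a dilute bulk solution.

    Bulk at 0.01 M total keeps the dimer fraction small, the regime in
    which the linearized screened model is the faithful description.
    """
    return mc.RDParams.from_solution(
        k_D=1.147, c_total=0.01, D1=4e-11, D2=3.2e-11, k2=1.25e5
    )


@pytest.fixture(scope="session")
def screen_length() -> float:
    return mc.screening_length(3.2e-11, 1.25e5)


@pytest.fixture(scope="session")
def radial_grid(screen_length) -> np.ndarray:
    return mc.default_grid(screen_length, n_nodes=160)
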