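import numpy as np
import pytest

from thermofit import fit
from thermofit.synthgen import (
    CARROT_ALPHA,
    CARROT_H_REDUCED,
    carrot_chilling_design,
    generate,
)

# standard starting values of the inverse iteration: alpha0 = 1e-7 m^2/s and
# h_H0 = 4 W/m^2/K converted to h' with rho*Cp of the carrot design
STANDARD_INIT = (1e-7, 4.0 / (1003.0 * 3918.0))
MC_NOISE_SD = 0.005
MC_REPLICATES = 200


@pytest.fixture(scope="session")
def carrot_design():
    return carrot_chilling_design()


@pytest.fixture(scope="session")
def mc_fits():
    """200 replicate fits of noisy synthetic curves with known sigma.

    Shared by the coverage-calibration, mean-recovery and correlation-sign
    tests so the Monte-Carlo loop runs once per session.
    """
    results = []
    for seed in range(1, MC_REPLICATES + 1):
        design = carrot_chilling_design(noise_sd=MC_NOISE_SD, seed=seed)
        series = generate(design)
        results.append(fit(series, design.geometry, init=STANDARD_INIT))
    return results


@pytest.fixture(scope="session")
def mc_truth():
    return np.array([CARROT_ALPHA, CARROT_H_REDUCED])
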