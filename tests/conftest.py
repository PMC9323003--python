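import numpy as np
import pytest

from adoptsem import ModelParams

#: UK-Biobank-like group sizes used for the headline power calculations.
UKB_SIZES = {"G1": 1000, "G2": 4000, "G3": 1800, "G4": 300000, "G5": 6000, "G7": 50}


@pytest.fixture(scope="session")
def ukb_sizes():
    return dict(UKB_SIZES)


@pytest.fixture(scope="session")
def scaled_sizes():
    """A tenth of the headline sizes, for replicated simulation studies."""
    return {code: n // 10 for code, n in UKB_SIZES.items()}


@pytest.fixture(scope="session")
def theta_star():
    """A generic interior parameter point with every path nonzero."""
    return ModelParams(
        gamma_m=0.1, beta_m=0.1, beta_p=0.1, beta_o=0.1,
        rho=0.05, phi=1.0, eps1_sq=0.9, eps2_sq=0.95,
    )


def draw_params(rng: np.random.Generator, with_r: bool = False) -> ModelParams:
    """A random parameter point inside the plausible (PD-safe) region."""
    phi = rng.uniform(0.8, 1.25)
    return ModelParams(
        gamma_m=rng.uniform(-0.3, 0.3),
        beta_m=rng.uniform(-0.3, 0.3),
        beta_p=rng.uniform(-0.3, 0.3),
        beta_o=rng.uniform(-0.3, 0.3),
        rho=rng.uniform(-0.1, 0.1) * phi,
        phi=phi,
        eps1_sq=rng.uniform(0.6, 1.3),
        eps2_sq=rng.uniform(0.6, 1.3),
        r=rng.uniform(0.0, 0.4) * phi if with_r else 0.0,
    )
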