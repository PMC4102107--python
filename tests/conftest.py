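import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from gencorr.core_io import TwinTable
from gencorr.twin_ace import AceParams

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# Twin-model point estimates used as generating truth throughout the suite:
# reading A/C/E = 0.66/0.14/0.20, mathematics A/C/E = 0.51/0.21/0.27,
# component correlations rho_A/rho_C/rho_E = 0.64/0.90/0.30.
COHORT_ACE = dict(
    V_A1=0.66, V_C1=0.14, V_E1=0.20,
    V_A2=0.51, V_C2=0.21, V_E2=0.27,
    rho_A=0.64, rho_C=0.90, rho_E=0.30,
)


@pytest.fixture(scope="session")
def cohort_params() -> AceParams:
    return AceParams(**COHORT_ACE)


def make_twin_table(values, zygosity, age=12.0, sex=0) -> TwinTable:
    """Build a TwinTable from an n x 4 array and per-family zygosity labels."""
    values = np.asarray(values, dtype=float)
    zygosity = list(zygosity)
    n = values.shape[0]
    return TwinTable(
        pd.DataFrame(
            {
                "family_id": [f"F{i:05d}" for i in range(n)],
                "zygosity": zygosity,
                "twin1_trait1": values[:, 0],
                "twin1_trait2": values[:, 1],
                "twin2_trait1": values[:, 2],
                "twin2_trait2": values[:, 3],
                "age": age,
                "sex1": sex,
                "sex2": sex,
            }
        )
    )
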