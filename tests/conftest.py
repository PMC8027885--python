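import numpy as np
import pytest

from sebpop import simpop


@pytest.fixture(scope="session")
def two_group_config():
    """Two admixed groups with an X chromosome, desk-scale."""
    q1 = np.array([0.85, 0.13, 0.02])
    q2 = np.array([0.96, 0.03, 0.01])
    return simpop.SimConfig(
        groups=[
            simpop.GroupSpec(
                name="HighKS", n=40, q=q1, drift=0.004, g=30,
                site_fractions=[0.7, 0.3, 0.0],
            ),
            simpop.GroupSpec(
                name="LowKS", n=40, q=q2, drift=0.004, g=40,
                site_fractions=[0.2, 0.8, 0.0],
            ),
        ],
        chroms=simpop.default_chromosomes(n_autosomes=2, include_x=True),
        L=600,
        F_anc=simpop.DEFAULT_F_ANC,
        missing_rate=0.01,
        seed=123,
    )


@pytest.fixture(scope="session")
def two_group_sim(two_group_config):
    return simpop.simulate_genotypes(two_group_config)
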