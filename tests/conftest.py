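import numpy as np
import pandas as pd
import pytest

from thermowire.scaling import GrowthParams, ScalingParams
from thermowire.synthetic import GlomerulusSpec, gen_synapse_table


@pytest.fixture(scope="session")
def fitted_scaling() -> ScalingParams:
    """The study's fitted factors: alpha=0.128, beta=0.133 per °C, T0=25 °C."""
    return ScalingParams(alpha=0.128, beta=0.133, ref_temp=25.0)


@pytest.fixture(scope="session")
def growth_params() -> GrowthParams:
    return GrowthParams(base_rate=0.05, activation_energy=0.822, asymptotic_mass=1.0)


@pytest.fixture()
def toy_synapse_table() -> pd.DataFrame:
    """Hand-checkable allocation input: A->P1:12, B->P1:2, A->P2:5, B->P2:6, A->P3:4."""
    spec = GlomerulusSpec(
        name="DM1",
        pre_type="Or42b",
        connections=[("A", "P1", 12), ("B", "P1", 2), ("A", "P2", 5),
                     ("B", "P2", 6), ("A", "P3", 4)],
        post_classes={"P1": "uPN", "P2": "mPN"},
    )
    return gen_synapse_table([spec], coordinate_spread=0.5, seed=11)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20250115)
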