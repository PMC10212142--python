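import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from llps_assembly.exchange import ExchangeSpec
from llps_assembly.params import AssemblyModelParams, CompartmentParams


@pytest.fixture
def ng_params() -> AssemblyModelParams:
    """Nucleation-and-growth defaults: N=120, n_nuc=3, g_nuc=-4, g_elong=-17."""
    return AssemblyModelParams()


@pytest.fixture
def ng5_params() -> AssemblyModelParams:
    return AssemblyModelParams(n_nuc=5)


@pytest.fixture
def cnt_params() -> AssemblyModelParams:
    """CNT shell defaults: N=120, g_sub=-17 (so sigma*l0 = 8.5)."""
    return AssemblyModelParams(model_kind="CNT", g_sub=-17.0, n_nuc=None)


@pytest.fixture
def make_compartment():
    def _make(K_c=1.0, V_r=1e-3, rho_T=2e-7, mode="fast_equilibrium", k_exch=300.0):
        return CompartmentParams(
            K_c=K_c,
            V_r=V_r,
            rho_T=rho_T,
            exchange=ExchangeSpec(mode=mode, k_exch=k_exch),
        )

    return _make


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230515)
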