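import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from streamdegas import (
    GroundwaterEndMember,
    ModelParams,
    Observation,
    simulate,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fig1_em():
    """The typical acidic, DIC-rich groundwater end-member (1200 umol/L, pH 5.5, 4 C)."""
    return GroundwaterEndMember(dic=1200.0, ph=5.5, d13c_dic=-25.0, temperature=4.0)


@pytest.fixture(scope="session")
def fig1_traj(fig1_em):
    return simulate(fig1_em)


def observation_on_trajectory(
    em: GroundwaterEndMember,
    fraction_lost: float,
    params: ModelParams | None = None,
    **obs_kwargs,
) -> Observation:
    """Noise-free observation taken from the forward model at a given
    fraction of delivered CO2 lost (the parameter-recovery oracle)."""
    traj = simulate(em, params or ModelParams(stop_ratio=1.001))
    t = traj.arrays["time_d"]
    f = traj.arrays["fraction_CO2_lost"]
    tt = float(np.interp(fraction_lost, f, t))
    return Observation(
        dic=float(np.interp(tt, t, traj.arrays["DIC_umol_L"])),
        ph=float(np.interp(tt, t, traj.arrays["pH"])),
        d13c_dic=float(np.interp(tt, t, traj.arrays["d13C_DIC_permil"])),
        temperature=em.temperature,
        **obs_kwargs,
    )


@pytest.fixture(scope="session")
def obs_on_trajectory():
    return observation_on_trajectory
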