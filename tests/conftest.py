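import numpy as np
import pytest

from photoroutes import LeafEnv, c3_defaults, c4_defaults


@pytest.fixture
def c3p():
    return c3_defaults()


@pytest.fixture
def c4p():
    return c4_defaults()


def fig1_env(i_inc: float) -> LeafEnv:
    """Input conditions of the published leaf light-response curves:
    Ca = 400, T_l = 25 degC, n = 2.3, VPD = 2.0 kPa, absorptance 0.85."""
    return LeafEnv(i_inc=i_inc, c_a=400.0, t_l=25.0, vpd=2.0, n_leaf=2.3,
                   absorptance=0.85)


def random_envs(n: int, seed: int, i_max: float = 2000.0):
    """Physiological random leaf environments for solver equivalence."""
    rng = np.random.default_rng(seed)
    envs = []
    for _ in range(n):
        envs.append(LeafEnv(
            i_inc=float(rng.uniform(0.0, i_max)),
            c_a=float(rng.uniform(200.0, 800.0)),
            t_l=float(rng.uniform(10.0, 40.0)),
            vpd=float(rng.uniform(0.3, 3.0)),
            n_leaf=float(rng.uniform(0.5, 3.5)),
        ))
    return envs
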