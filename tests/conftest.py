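import numpy as np
import pytest

import ecochaos as ec


@pytest.fixture(scope="session")
def params():
    return ec.FIG2_PARAMS


@pytest.fixture(scope="session")
def chaotic_traj(params):
    """Post-transient chaotic trajectory (V = 1/3), 5e4 time units."""
    return ec.integrate(params, t_total=5.2e4, t_transient=2000.0)


@pytest.fixture(scope="session")
def limit_cycle_traj(params):
    """Settled long-period limit cycle at V = 1/15 (slow transient)."""
    return ec.integrate(params.with_V(ec.V_LIMIT_CYCLE), t_total=1.5e5, t_transient=7.0e4)


@pytest.fixture(scope="session")
def lyap_chaotic(params):
    """Global Lyapunov spectrum on the chaotic attractor, t = 2e5."""
    return ec.benettin_spectrum(params, t_total=2.0e5, t_transient=2000.0)


@pytest.fixture(scope="session")
def interior_equilibrium(params):
    """Coexistence equilibrium (weakly unstable spiral for V = 1/3)."""
    from scipy.optimize import brentq

    p = params
    x = p.d2 / (p.ya * p.a2 - p.d2 * p.b2)
    c = brentq(
        lambda cc: 2 * p.k2 * p.d1 - 4 * p.k4 * p.d1 * cc * cc
        - p.a1 * p.k1 * x / (1 + p.b1 * cc),
        0.1,
        0.71,
    )
    y = (p.a1 * c / (1 + p.b1 * c) - p.d1) * (1 + p.b2 * x) / p.a2
    st = ec.EcoState(x, y, c)
    assert np.allclose(ec.rhs(st, p), 0.0, atol=1e-12)
    return st
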