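import numpy as np

from ecochaos.simulate import SolverMeta, Trajectory


def make_traj(times, states, params):
    """Hand-built trajectory for constructed-input tests."""
    times = np.asarray(times, float)
    meta = SolverMeta(
        "none", 1e-9, 1e-11, tuple(np.asarray(states, float)[0]), 0.0,
        float(times[1] - times[0]),
    )
    return Trajectory(times, np.asarray(states, float), params, meta)
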