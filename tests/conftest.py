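import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ihfit

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bench_params():
    """The (slow, fast) benchmark parameter pair."""
    return ihfit.benchmark_fixture()


@pytest.fixture(scope="session")
def region(bench_params):
    return ihfit.SearchRegion.around(bench_params, tol=0.8)


@pytest.fixture(scope="session")
def small_protocol():
    """Coarsely sampled protocol for fast unit tests of the fit pipelines."""
    return ihfit.standard_protocol(t_step=3000.0, t_post=800.0, sample_interval=5.0)


@pytest.fixture(scope="session")
def noisy_small_ts(bench_params, small_protocol):
    slow, fast = bench_params
    return ihfit.synthesize(slow, fast, small_protocol, noise_sd=10.0, seed=7)


def euler_gate_current(step, params, constants=None, dt=0.01, n_act=None,
                       n_post=0, sample_every=1):
    """Independent ODE oracle: forward-Euler integration of the activation
    gate dr/dt = (r_inf(V) - r) / tau_r(V) over one voltage step (and
    optionally the return to the pre-step potential), returning the sampled
    current in pA."""
    from ihfit.channel import ChannelConstants, activation, time_constant

    if constants is None:
        constants = ChannelConstants()
    r = activation(step.Vps, params)
    out = []
    for phase, V, n in (("act", step.Vs, n_act), ("post", step.Vps, n_post)):
        if not n:
            continue
        r_inf = activation(V, params)
        tau = time_constant(V, params)
        drive = V - constants.Eh
        for i in range(n):
            if i % sample_every == 0:
                out.append(params.G * r * drive)
            r = r + dt * (r_inf - r) / tau
    return np.array(out)
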