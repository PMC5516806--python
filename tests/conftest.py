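import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tandemtox.models import glutathione as gsh_model
from tandemtox.models import glycogen as glycogen_model
from tandemtox.models import ppp as ppp_model
from tandemtox.synthetic import jitter_params

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def glycogen_params():
    return glycogen_model.GlycogenParams()


@pytest.fixture(scope="session")
def ppp_params():
    return ppp_model.PppParams()


@pytest.fixture(scope="session")
def gsh_params():
    return gsh_model.GshParams()


@pytest.fixture(scope="session")
def glycogen_reference_state(glycogen_params):
    return glycogen_model.reference_steady_state(glycogen_params)


def feasible_jittered(reference, steady_fn, n, cv=0.1, start_seed=0):
    """First `n` jittered parameter sets (seeds ascending from `start_seed`)
    for which the model relaxes to a genuine steady state.

    Feasibility is judged solely by the integrator's convergence flag —
    strong jitter can push a model outside its validity domain (e.g. an
    NADPH supply below the H2O2 load has no steady state), and there is
    nothing for a steady-state comparison to compare there.
    """
    out, seed = [], start_seed
    while len(out) < n and seed < start_seed + 10 * n:
        params = jitter_params(reference, cv, seed)
        ss = steady_fn(params)
        if ss.converged:
            out.append((seed, params, ss))
        seed += 1
    assert len(out) == n, f"only {len(out)} feasible jittered sets found"
    return out


def max_rel_diff(a, b, idx=None, floor=1e-6):
    a, b = np.asarray(a, float), np.asarray(b, float)
    if idx is not None:
        a, b = a[idx], b[idx]
    return float(np.max(np.abs(a - b) / np.maximum(np.abs(b), floor)))
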