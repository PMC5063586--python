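import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

from nadflux import SamplingDesign, build_scenario, quantify, simulate

_hyp_settings.register_profile("repro", derandomize=True, deadline=None)
_hyp_settings.load_profile("repro")

GRID = np.round(np.arange(0.0, 8.01, 0.25), 10)
NOISELESS = SamplingDesign(times=(0.0, 2.0, 4.0, 6.0), n_wells=1, noise_cv=0.0, seed=0)


def make_flux_table(name, axotomized, *, n_wells=1, noise_cv=0.0, seed=0, grid=GRID):
    """Simulate a tracer-at-time-zero scenario and quantify it."""
    scen, params = build_scenario(
        name, {}, axotomized=axotomized, t_axotomy=0.0, tracer_start=0.0, duration=8.0
    )
    traj = simulate(scen, params, grid)
    design = SamplingDesign(
        times=(0.0, 2.0, 4.0, 6.0), n_wells=n_wells, noise_cv=noise_cv, seed=seed
    )
    return traj, quantify(traj, design)


@pytest.fixture(scope="session")
def control_uninjured():
    return make_flux_table("control", False)


@pytest.fixture(scope="session")
def control_axotomy():
    return make_flux_table("control", True)
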