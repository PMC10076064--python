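"""Shared fixtures: models, small equilibrated boxes, helpers.

Expensive MD-based fixtures are session-scoped so the cost is paid once.
"""

import pytest

from aquarigid import models
from aquarigid.engine import RunConfig, initialize_velocities, run
from aquarigid.fixtures import water_lattice


@pytest.fixture(scope="session")
def qtip4pf():
    return models.get_model("q-TIP4P/F")


@pytest.fixture(scope="session")
def qtip4pf_mg(qtip4pf):
    return models.rigidify_mg(qtip4pf)


@pytest.fixture(scope="session")
def tip4p_ice():
    return models.get_model("TIP4P/Ice")


def small_water_box(model, n_side=3, density=0.03):
    """n_side³ molecules on a jittered grid, random orientations."""
    state, topo = water_lattice(n_side**3, model, density=density, seed=11)
    return state, topo


@pytest.fixture(scope="session")
def equilibrated_rigid_box(qtip4pf_mg):
    """27 rigid q-TIP4P/F waters, NVT-equilibrated at 300 K (cutoff 4.5 Å)."""
    state, topo = small_water_box(qtip4pf_mg)
    cfg = RunConfig(timestep=1.0, ensemble="NVT",
                    thermostat="stochastic_rescale", tau_t=100.0,
                    T_target=300.0, cutoff=4.5, tail_correction=False,
                    seed=42, output_every=500)
    initialize_velocities(state, topo, 300.0, seed=42)
    traj = run(state, topo, cfg, 3000)
    return traj.final_state, topo, cfg


@pytest.fixture(scope="session")
def liquid_flexible_traj(qtip4pf):
    """Flexible q-TIP4P/F liquid at ~298 K, 1 bar (reduced size).

    Used by the ensemble-geometry extraction tests: the condensed phase
    stretches the OH bond and closes the HOH angle relative to the gas
    geometry.
    """
    state, topo = small_water_box(qtip4pf, n_side=3, density=0.0334)
    cfg_eq = RunConfig(timestep=0.5, ensemble="NVT",
                       thermostat="stochastic_rescale", tau_t=100.0,
                       T_target=298.0, cutoff=4.4, tail_correction=False,
                       seed=7, output_every=1000)
    initialize_velocities(state, topo, 298.0, seed=7)
    eq = run(state, topo, cfg_eq, 3000)          # 1.5 ps equilibration
    cfg_np = RunConfig(timestep=0.5, ensemble="NPT",
                       thermostat="stochastic_rescale", tau_t=200.0,
                       T_target=298.0, tau_p=2000.0, P_target=1.0,
                       cutoff=4.4, tail_correction=False,
                       seed=8, output_every=40)
    traj = run(eq.final_state, topo, cfg_np, 6000)   # 3 ps production
    return traj
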