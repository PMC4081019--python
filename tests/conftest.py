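import numpy as np
import pytest

from ubscape.dynamics import SimulationConfig, langevin_run, relax
from ubscape.energetics import EnergyModel
from ubscape.model_builder import build_hydrophobic_matrix
from ubscape.synthetic_fixtures import (MiniDimerSpec, make_mini_dimer,
                                        ub_dimer_system, ub_monomer_residues)


@pytest.fixture(scope="session")
def hp_matrix():
    return build_hydrophobic_matrix()


@pytest.fixture(scope="session")
def mini_dimer():
    return make_mini_dimer(MiniDimerSpec(seed=0))


@pytest.fixture(scope="session")
def mini_energy_model(mini_dimer, hp_matrix):
    return EnergyModel(mini_dimer.model, mini_dimer.topology, hp_matrix)


@pytest.fixture(scope="session")
def ub_residues():
    return ub_monomer_residues()


@pytest.fixture(scope="session")
def ub_free_system():
    return ub_dimer_system("free")


@pytest.fixture(scope="session")
def ub_monomer_run():
    """Short folded-monomer trajectory at the working temperature,
    shared by the stability, RMSF and convergence tests."""
    from ubscape.model_builder import (assign_charges, build_topology,
                                       coarse_grain, detect_native_contacts)

    residues = ub_monomer_residues()
    contacts = detect_native_contacts(residues)
    monomer = coarse_grain(residues, "distal")
    model, topo = build_topology(monomer, linkage="free", contacts=contacts)
    assign_charges(model)
    em = EnergyModel(model, topo)
    x0 = relax(em, model.coords(), steps=400)
    cfg = SimulationConfig(temperature=50.0, steps=30000, stride=150)
    traj = langevin_run(em, cfg, x0, seed=42)
    return model, topo, traj
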