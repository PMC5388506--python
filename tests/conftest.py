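"""Shared fixtures: the built stack and a few reusable simulations."""

from __future__ import annotations

import numpy as np
import pytest

import betaroll as br


@pytest.fixture(scope="session")
def stack():
    """(Conformation, BetaRollTopology) of the default two-molecule build."""
    return br.build_ideal_stack()


@pytest.fixture(scope="session")
def topology(stack):
    return stack[1]


@pytest.fixture(scope="session")
def conformation(stack):
    return stack[0]


@pytest.fixture(scope="session")
def forcefield(stack):
    conf, top = stack
    return br.ForceField.from_topology(br.EnergyModel(), top, conf)


@pytest.fixture(scope="session")
def cmd_run(stack, forcefield):
    """Reference conventional-MD run used across tests (seeded)."""
    conf, _ = stack
    return br.run_cmd(forcefield, conf, n_steps=20000, equil_steps=5000,
                      save_interval=20, seed=7)


@pytest.fixture(scope="session")
def boost_params(cmd_run, topology):
    return br.prescribe_parameters(
        cmd_run.v_avg_total, cmd_run.v_avg_dihedral,
        n_res=topology.n_residues, n_atoms=topology.n_residues, n=2.0)


@pytest.fixture(scope="session")
def amd_template_run(stack, boost_params):
    """Accelerated run with the partially-fixed bottom template (n=2)."""
    conf, top = stack
    fixed = br.select_fixed_atoms(top, "partial_template")
    ff = br.ForceField.from_topology(br.EnergyModel(), top, conf,
                                     fixed_atoms=tuple(fixed))
    return br.run_amd(ff, conf, boost_params, n_steps=50000,
                      save_interval=20, seed=9)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
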