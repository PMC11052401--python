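"""Shared fixtures: teacher systems, solvated boxes, an equilibrated
ground-state trajectory and a Lennard-Jones fluid."""

import numpy as np
import pytest

from qmdff.forcefield import ForceFieldParameters, SystemConfiguration
from qmdff.md import (IntegratorSettings, maxwell_velocities, run_md,
                      run_equilibrium_protocol)
from qmdff.teachers import build_teacher_system
from qmdff.topology import Atom, Topology


@pytest.fixture(scope="session")
def cyc_s0():
    teacher, cfg = build_teacher_system("CYC_S0")
    return teacher, cfg


@pytest.fixture(scope="session")
def cyc_s1():
    teacher, cfg = build_teacher_system("CYC_S1")
    return teacher, cfg


@pytest.fixture(scope="session")
def pyr_s1():
    teacher, cfg = build_teacher_system("PYR_S1")
    return teacher, cfg


def make_lj_fluid(n_side=5, density=8.0, mass=39.948, eps=0.998,
                  sigma=0.3405, seed=0):
    """Argon-like LJ fluid on a jittered cubic lattice."""
    n = n_side ** 3
    edge = (n / density) ** (1.0 / 3.0)
    rng = np.random.default_rng(seed)
    grid = (np.stack(np.meshgrid(*[np.arange(n_side)] * 3),
                     axis=-1).reshape(-1, 3) + 0.5) * (edge / n_side)
    grid += rng.uniform(-0.02, 0.02, grid.shape)
    atoms = [Atom("Ar", "Ar", mass, molecule=i, role="solvent")
             for i in range(n)]
    topo = Topology(atoms=atoms)
    ff = ForceFieldParameters(
        state="S0", bond_k=[], bond_r0=[], angle_k=[], angle_theta0=[],
        stiff_k=[], stiff_phi0=[], fourier=np.zeros((0, 1)),
        charges=np.zeros(n), lj_epsilon=np.full(n, eps),
        lj_sigma=np.full(n, sigma))
    vel = maxwell_velocities(topo.masses, 300.0, rng)
    cfg = SystemConfiguration(grid, vel, box=edge)
    return topo, ff, cfg


@pytest.fixture(scope="session")
def lj_fluid():
    return make_lj_fluid()


@pytest.fixture(scope="session")
def solvated_cyc():
    """CYC chromophore in 32 waters with desk-scale run settings."""
    teacher, cfg = build_teacher_system("CYC_S0", "water", 32, seed=11)
    settings = IntegratorSettings(timestep=5e-4, cutoff=0.5, seed=13,
                                  tau_t=0.1, tau_p=1.0)
    return teacher, settings, cfg


@pytest.fixture(scope="session")
def equilibrated_cyc(solvated_cyc):
    """Ground-state production trajectory of the solvated chromophore.

    Desk-scale staged protocol (0.2 / 1 / 2 / 30 ps at 0.5 fs) with frames
    (and velocities) every 0.1 ps.
    """
    teacher, settings, cfg = solvated_cyc
    traj = run_equilibrium_protocol(cfg, teacher.topology, teacher.ff["S0"],
                                    settings,
                                    durations=(0.2, 1.0, 2.0, 30.0),
                                    save_interval=200)
    return teacher, settings, traj


@pytest.fixture(scope="session")
def nve_ready_water64():
    """Chromophore + 64 flexible waters, thermalized and ready for NVE."""
    teacher, cfg = build_teacher_system("CYC_S0", "water", 64, seed=21)
    cfg.velocities = maxwell_velocities(teacher.topology.masses, 300.0,
                                        np.random.default_rng(22))
    settings = IntegratorSettings(timestep=2e-4, thermostat="v_rescale",
                                  tau_t=0.05, cutoff=0.6, seed=23)
    traj = run_md(cfg, teacher.topology, teacher.ff["S0"], settings,
                  n_steps=5000, save_interval=5000,
                  rng=np.random.default_rng(23))
    return teacher, traj.frames[-1]
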