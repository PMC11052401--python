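"""Energies, forces, dihedrals, Hessians and normal modes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qmdff.errors import (ConfigurationError, DegenerateGeometryError,
                          StructureError)
from qmdff.forcefield import (DihedralWall, ForceFieldParameters,
                              NonbondedSettings, SystemConfiguration,
                              compute_dihedral, evaluate_energy,
                              evaluate_forces, ff_hessian, normal_modes,
                              pack_system, _eval_packed)
from qmdff.teachers import DELTA4, chromophore_geometry
from qmdff.topology import Atom, FlexibleDihedral, Topology

KCOUL = 138.935458


def simple_ff(topo, **over):
    n = topo.n_atoms
    kw = dict(state="S0",
              bond_k=[1000.0] * len(topo.bonds),
              bond_r0=[0.15] * len(topo.bonds),
              angle_k=[100.0] * len(topo.angles),
              angle_theta0=[2.0] * len(topo.angles),
              stiff_k=[40.0] * len(topo.stiff_dihedrals),
              stiff_phi0=[3.0] * len(topo.stiff_dihedrals),
              fourier=(np.tile([1.0, 2.0, 3.0, 0.5],
                               (len(topo.flexible_dihedrals), 1))
                       if topo.flexible_dihedrals else np.zeros((0, 1))),
              charges=np.zeros(n), lj_epsilon=np.zeros(n),
              lj_sigma=np.full(n, 0.3))
    kw.update(over)
    return ForceFieldParameters(**kw)


def chain_topology(n=4, flexible=False):
    atoms = [Atom(f"C{i}", "C", 12.011, molecule=0) for i in range(n)]
    bonds = [(i, i + 1) for i in range(n - 1)]
    angles = [(i, i + 1, i + 2) for i in range(n - 2)]
    dihs = [(i, i + 1, i + 2, i + 3) for i in range(n - 3)]
    if flexible:
        return Topology(atoms=atoms, bonds=bonds, angles=angles,
                        flexible_dihedrals=[FlexibleDihedral(d, f"d{i}")
                                            for i, d in enumerate(dihs)],
                        exclusion_policy="pairs_only")
    return Topology(atoms=atoms, bonds=bonds, angles=angles,
                    stiff_dihedrals=dihs, exclusion_policy="pairs_only")


# ---------------------------------------------------------------------------
# dihedral geometry
# ---------------------------------------------------------------------------

class TestComputeDihedral:
    trans = np.array([[0.0, 0.1, 0.0], [0.0, 0.0, 0.0],
                      [0.1, 0.0, 0.0], [0.1, -0.1, 0.0]])

    def test_planar_trans_is_180(self):
        assert compute_dihedral(self.trans, 0, 1, 2, 3) == pytest.approx(180.0)

    def test_eclipsed_is_zero(self):
        cis = self.trans.copy()
        cis[3] = [0.1, 0.1, 0.0]
        assert compute_dihedral(cis, 0, 1, 2, 3) == pytest.approx(0.0)

    def test_mirror_negates_angle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pos = rng.normal(0, 0.2, (4, 3))
            phi = compute_dihedral(pos, 0, 1, 2, 3)
            mirrored = pos.copy()
            mirrored[:, 2] *= -1.0
            phim = compute_dihedral(mirrored, 0, 1, 2, 3)
            if abs(abs(phi) - 180.0) > 1e-9:
                assert phim == pytest.approx(-phi)

    def test_range_convention(self):
        # result lies in (-180, 180]; trans maps to +180, never -180
        assert compute_dihedral(self.trans, 0, 1, 2, 3) == 180.0

    def test_collinear_raises(self):
        pos = np.array([[0.0, 0, 0], [0.1, 0, 0], [0.2, 0, 0],
                        [0.3, 0.1, 0]])
        with pytest.raises(DegenerateGeometryError):
            compute_dihedral(pos, 0, 1, 2, 3)

    def test_duplicate_atom_raises(self):
        with pytest.raises(DegenerateGeometryError):
            compute_dihedral(self.trans, 0, 1, 2, 1)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_rigid_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.normal(0, 0.2, (4, 3))
        try:
            phi = compute_dihedral(pos, 0, 1, 2, 3)
        except DegenerateGeometryError:
            return
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = rng.uniform(0, 2 * np.pi)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
        phir = compute_dihedral(pos @ R.T, 0, 1, 2, 3)
        assert phir == pytest.approx(phi, abs=1e-8)


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

class TestEnergyTerms:
    def test_bond_at_equilibrium_is_zero(self):
        topo = chain_topology(2)
        ff = simple_ff(topo)
        pos = np.array([[0.0, 0, 0], [0.15, 0, 0]])
        rep = evaluate_energy(SystemConfiguration(pos, np.zeros_like(pos)),
                              topo, ff)
        assert rep.bond == pytest.approx(0.0, abs=1e-12)

    def test_sin2_barrier_as_fourier_pair(self):
        # V = 42 sin^2(d) == 21 - 21 cos(2d); at d = 90 deg the energy is
        # the full barrier height
        topo = chain_topology(4, flexible=True)
        four = np.zeros((1, 3))
        four[0, 0], four[0, 2] = 21.0, -21.0
        ff = simple_ff(topo, fourier=four, bond_k=[0.0] * 3,
                       angle_k=[0.0] * 2)
        pos = np.array([[0.0, 0.1, 0.0], [0.0, 0.0, 0.0],
                        [0.1, 0.0, 0.0], [0.1, 0.0, 0.1]])
        assert compute_dihedral(pos, 0, 1, 2, 3) == pytest.approx(90.0)
        rep = evaluate_energy(SystemConfiguration(pos, np.zeros_like(pos)),
                              topo, ff)
        assert rep.flexible_dihedral == pytest.approx(42.0)

    def test_lj_zero_crossing_at_sigma(self):
        atoms = [Atom("A", "Ar", 40.0, molecule=i) for i in range(2)]
        topo = Topology(atoms=atoms)
        ff = simple_ff(topo, bond_k=[], bond_r0=[], angle_k=[],
                       angle_theta0=[], stiff_k=[], stiff_phi0=[],
                       fourier=np.zeros((0, 1)),
                       lj_epsilon=np.full(2, 0.5))
        pos = np.array([[0.0, 0, 0], [0.3, 0, 0]])   # r = sigma
        rep = evaluate_energy(SystemConfiguration(pos, np.zeros_like(pos)),
                              topo, ff)
        assert rep.inter_lj == pytest.approx(0.0, abs=1e-12)
        assert rep.coulomb == 0.0

    def test_coulomb_prefactor(self):
        atoms = [Atom("A", "H", 1.0, molecule=i) for i in range(2)]
        topo = Topology(atoms=atoms)
        ff = simple_ff(topo, bond_k=[], bond_r0=[], angle_k=[],
                       angle_theta0=[], stiff_k=[], stiff_phi0=[],
                       fourier=np.zeros((0, 1)), charges=np.array([1.0, 1.0]),
                       lj_epsilon=np.zeros(2))
        pos = np.array([[0.0, 0, 0], [0.5, 0, 0]])
        rep = evaluate_energy(SystemConfiguration(pos, np.zeros_like(pos)),
                              topo, ff)
        assert rep.coulomb == pytest.approx(KCOUL / 0.5)

    def test_report_total_is_sum_of_terms(self, cyc_s0):
        teacher, _ = cyc_s0
        topo = teacher.solute_topology()
        pos = chromophore_geometry() + 0.002
        rep = evaluate_energy(SystemConfiguration(pos, np.zeros_like(pos)),
                              topo, teacher.solute_ff("S0"))
        parts = (rep.bond + rep.angle + rep.stiff_dihedral
                 + rep.flexible_dihedral + rep.intra_lj + rep.inter_lj
                 + rep.coulomb + rep.restraint)
        assert rep.total == pytest.approx(parts, rel=1e-12)

    def test_size_mismatch_raises(self, cyc_s0):
        teacher, _ = cyc_s0
        pos = np.zeros((5, 3))
        with pytest.raises(StructureError):
            evaluate_energy(SystemConfiguration(pos, np.zeros_like(pos)),
                            teacher.solute_topology(),
                            teacher.solute_ff("S0"))

    def test_small_box_raises(self, lj_fluid):
        topo, ff, cfg = lj_fluid
        bad = SystemConfiguration(cfg.positions, cfg.velocities, box=1.0)
        with pytest.raises(ConfigurationError):
            evaluate_energy(bad, topo, ff,
                            NonbondedSettings(cutoff=0.9))


class TestInvariances:
    def test_translation_invariance(self, cyc_s0):
        teacher, _ = cyc_s0
        topo = teacher.solute_topology()
        ff = teacher.solute_ff("S0")
        pos = chromophore_geometry() + np.random.default_rng(0).normal(
            0, 0.003, (12, 3))
        e1 = evaluate_energy(SystemConfiguration(pos, np.zeros_like(pos)),
                             topo, ff)
        e2 = evaluate_energy(
            SystemConfiguration(pos + np.array([1.7, -2.3, 0.9]),
                                np.zeros_like(pos)), topo, ff)
        assert e2.total == pytest.approx(e1.total, abs=1e-9)

    def test_rotation_invariance(self, cyc_s0):
        teacher, _ = cyc_s0
        topo = teacher.solute_topology()
        ff = teacher.solute_ff("S0")
        pos = chromophore_geometry() + np.random.default_rng(1).normal(
            0, 0.003, (12, 3))
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        e1 = evaluate_energy(SystemConfiguration(pos, np.zeros_like(pos)),
                             topo, ff)
        e2 = evaluate_energy(SystemConfiguration(pos @ R.T,
                                                 np.zeros_like(pos)),
                             topo, ff)
        assert e2.total == pytest.approx(e1.total, abs=1e-9)

    def test_flexible_dihedral_periodicity(self):
        from qmdff.profiles import fourier_eval
        c = np.array([1.0, -2.0, 3.0, 0.5, -0.1])
        d = np.linspace(-180, 180, 73)
        assert np.allclose(fourier_eval(c, d), fourier_eval(c, d + 360.0),
                           atol=1e-12)


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

def numeric_forces(packed, pos, box, h=1e-6):
    num = np.zeros_like(pos)
    flat = pos.reshape(-1)
    for c in range(flat.size):
        orig = flat[c]
        flat[c] = orig + h
        ep, _, _ = _eval_packed(packed, pos, box)
        flat[c] = orig - h
        em, _, _ = _eval_packed(packed, pos, box)
        flat[c] = orig
        num.reshape(-1)[c] = -(ep.sum() - em.sum()) / (2 * h)
    return num


class TestForces:
    def test_isolated_atom_zero_force(self):
        topo = Topology(atoms=[Atom("A", "Ar", 40.0, molecule=0)])
        ff = simple_ff(topo, bond_k=[], bond_r0=[], angle_k=[],
                       angle_theta0=[], stiff_k=[], stiff_phi0=[],
                       fourier=np.zeros((0, 1)), charges=np.zeros(1),
                       lj_epsilon=np.zeros(1), lj_sigma=np.array([0.3]))
        f = evaluate_forces(SystemConfiguration(np.zeros((1, 3)),
                                                np.zeros((1, 3))), topo, ff)
        assert np.all(f == 0.0)

    def test_like_charges_repel_newton_third_law(self):
        atoms = [Atom("A", "H", 1.0, molecule=i) for i in range(2)]
        topo = Topology(atoms=atoms)
        ff = simple_ff(topo, bond_k=[], bond_r0=[], angle_k=[],
                       angle_theta0=[], stiff_k=[], stiff_phi0=[],
                       fourier=np.zeros((0, 1)), charges=np.array([0.5, 0.5]),
                       lj_epsilon=np.zeros(2))
        pos = np.array([[0.0, 0, 0], [0.4, 0, 0]])
        f = evaluate_forces(SystemConfiguration(pos, np.zeros_like(pos)),
                            topo, ff)
        assert f[0, 0] < 0 < f[1, 0]           # repulsion along the axis
        assert np.allclose(f[0], -f[1], atol=1e-12)
        assert np.allclose(f[:, 1:], 0.0, atol=1e-12)

    def test_forces_sum_to_zero(self, cyc_s0):
        teacher, _ = cyc_s0
        topo = teacher.solute_topology()
        pos = chromophore_geometry() + np.random.default_rng(3).normal(
            0, 0.005, (12, 3))
        f = evaluate_forces(SystemConfiguration(pos, np.zeros_like(pos)),
                            topo, teacher.solute_ff("S0"))
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-8)

    def test_forces_match_central_differences(self, cyc_s0, lj_fluid):
        teacher, _ = cyc_s0
        cases = []
        topo = teacher.solute_topology()
        cases.append((pack_system(topo, teacher.solute_ff("S0")),
                      chromophore_geometry(), 0.0, 0.005))
        ljt, ljf, ljc = lj_fluid
        cases.append((pack_system(ljt, ljf, NonbondedSettings(cutoff=0.8)),
                      ljc.positions, ljc.box, 0.01))
        rng = np.random.default_rng(7)
        for packed, base, box, amp in cases:
            for _ in range(5):
                pos = base + rng.normal(0, amp, base.shape)
                _, _, ana = _eval_packed(packed, pos, box)
                num = numeric_forces(packed, pos.copy(), box)
                scale = max(1.0, np.abs(ana).max())
                assert np.abs(num - ana).max() / scale < 1e-5


# ---------------------------------------------------------------------------
# wall restraint
# ---------------------------------------------------------------------------

class TestDihedralWall:
    def test_inside_allowed_region_is_free(self):
        wall = DihedralWall(DELTA4, 0.0, 100.0)
        assert wall.energy(10.0) == 0.0

    def test_penalty_value(self):
        wall = DihedralWall(DELTA4, 0.0, 100.0)
        expect = 0.5 * 100.0 * math.radians(10.0) ** 2
        assert wall.energy(-10.0) == pytest.approx(expect)

    def test_energy_continuous_at_wall(self):
        wall = DihedralWall(DELTA4, 0.0, 100.0)
        assert abs(wall.energy(1e-6) - wall.energy(-1e-6)) < 1e-8

    def test_wall_enters_md_energy(self, cyc_s1):
        teacher, _ = cyc_s1
        topo = teacher.solute_topology()
        ff = teacher.solute_ff("S1").copy()
        from qmdff.fitting import build_clockwise_restraint
        ff.wall = build_clockwise_restraint(DELTA4, 0.0, 100.0)
        from qmdff.minimize import rotate_dihedral_to
        pos = rotate_dihedral_to(chromophore_geometry(), topo, DELTA4, -10.0)
        rep = evaluate_energy(SystemConfiguration(pos, np.zeros_like(pos)),
                              topo, ff)
        ff_nowall = teacher.solute_ff("S1")
        rep0 = evaluate_energy(SystemConfiguration(pos, np.zeros_like(pos)),
                               topo, ff_nowall)
        dwall = rep.flexible_dihedral - rep0.flexible_dihedral
        assert dwall == pytest.approx(0.5 * 100.0 * math.radians(10.0) ** 2,
                                      rel=1e-6)


# ---------------------------------------------------------------------------
# Hessian and normal modes
# ---------------------------------------------------------------------------

class TestHessianAndModes:
    def test_single_bond_hessian_block(self):
        topo = chain_topology(2)
        ff = simple_ff(topo)
        pos = np.array([[0.0, 0, 0], [0.15, 0, 0]])
        h = ff_hessian(SystemConfiguration(pos, np.zeros_like(pos)),
                       topo, ff)
        # curvature k along the bond axis, with the -k cross block
        assert h[0, 0] == pytest.approx(1000.0, rel=1e-6)
        assert h[0, 3] == pytest.approx(-1000.0, rel=1e-6)
        assert h[3, 3] == pytest.approx(1000.0, rel=1e-6)

    def test_hessian_symmetry(self, cyc_s0):
        teacher, _ = cyc_s0
        topo = teacher.solute_topology()
        pos = chromophore_geometry()
        h = ff_hessian(SystemConfiguration(pos, np.zeros_like(pos)), topo,
                       teacher.solute_ff("S0"))
        assert np.linalg.norm(h - h.T) / np.linalg.norm(h) < 1e-8

    def test_diatomic_frequency_closed_form(self):
        from qmdff import units
        topo = chain_topology(2)
        k, m = 1000.0, 12.011
        ff = simple_ff(topo)
        pos = np.array([[0.0, 0, 0], [0.15, 0, 0]])
        h = ff_hessian(SystemConfiguration(pos, np.zeros_like(pos)),
                       topo, ff)
        freqs, _ = normal_modes(h, topo.masses, pos)
        mu = m / 2.0
        expect = units.omega_to_wavenumber(math.sqrt(k / mu))
        assert freqs[-1] == pytest.approx(expect, rel=1e-6)

    def test_six_zero_modes_at_minimum(self, cyc_s0):
        teacher, _ = cyc_s0
        topo = teacher.solute_topology()
        pos = chromophore_geometry()
        h = ff_hessian(SystemConfiguration(pos, np.zeros_like(pos)), topo,
                       teacher.solute_ff("S0"))
        freqs, _ = normal_modes(h, topo.masses, pos)
        assert (np.abs(freqs) < 1.0).sum() == 6
        assert (freqs < -1.0).sum() == 0

    def test_nonsquare_hessian_raises(self):
        with pytest.raises(StructureError):
            normal_modes(np.zeros((5, 6)), np.ones(2))
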