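"""Force-field data model and evaluation of energies, forces and Hessians.

One :class:`ForceFieldParameters` instance holds the complete classical
potential of a single electronic state:

* harmonic bonds and angles, ``V = 1/2 k (x - x0)^2`` (GROMACS convention);
* harmonic "stiff" dihedrals with the deviation wrapped to (-pi, pi];
* flexible dihedrals as a cosine Fourier series ``V = sum_j c_j cos(j d)``;
* atomic point charges and per-atom LJ epsilon/sigma;
* optional explicit intramolecular LJ pairs and a one-sided harmonic
  dihedral wall (clockwise-only rotation restraint).

Nonbonded interactions use a spherical cutoff with the minimum-image
convention in a cubic box.  The default Coulomb treatment is plain
truncation; a potential-shift and a reaction-field form (continuous force
at the cutoff, for energy-conserving dynamics) are available through
:class:`NonbondedSettings`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels, units
from ._kernels import COUL_REACTION_FIELD, COUL_SHIFT, COUL_TRUNCATE
from .errors import (ConfigurationError, DegenerateGeometryError,
                     ParameterError, StructureError)
from .topology import Topology

__all__ = [
    "SystemConfiguration", "ForceFieldParameters", "DihedralWall",
    "NonbondedSettings", "EnergyReport", "evaluate_energy",
    "evaluate_forces", "compute_dihedral", "dihedral_gradient",
    "ff_hessian", "normal_modes", "pack_system", "PackedSystem",
]

_COUL_CODES = {"truncate": COUL_TRUNCATE, "shift": COUL_SHIFT,
               "reaction_field": COUL_REACTION_FIELD}


@dataclass
class SystemConfiguration:
    """Positions, velocities, cubic box and clock time of all atoms."""

    positions: np.ndarray          # (N, 3) nm
    velocities: np.ndarray         # (N, 3) nm/ps
    box: float = 0.0               # cubic edge, nm; 0 = no periodicity
    time: float = 0.0              # ps

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=float)
        if self.positions.shape != self.velocities.shape or self.positions.ndim != 2:
            raise StructureError("positions/velocities must both be (N, 3)")
        if not np.isfinite(self.positions).all():
            raise StructureError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "SystemConfiguration":
        return SystemConfiguration(self.positions.copy(), self.velocities.copy(),
                                   self.box, self.time)


@dataclass(frozen=True)
class DihedralWall:
    """One-sided harmonic wall ``V = 1/2 k (d - wall)^2`` for ``d < wall``.

    ``d`` is the wrapped signed dihedral; the wall permits rotation in one
    (clockwise) direction only.  Intended for torsions prepared in
    [0, 180] degrees, away from the +/-180 seam.
    """

    indices: tuple[int, int, int, int]
    wall_degrees: float = 0.0
    k_wall: float = 100.0    # kJ mol^-1 rad^-2

    def energy(self, delta_degrees: float) -> float:
        d = (delta_degrees - self.wall_degrees + 180.0) % 360.0 - 180.0
        if d >= 0.0:
            return 0.0
        dr = d * units.RAD_PER_DEG
        return 0.5 * self.k_wall * dr * dr


@dataclass
class ForceFieldParameters:
    """Complete parameter set of one electronic state.

    Array fields are aligned with the corresponding topology lists:
    ``bond_k``/``bond_r0`` with ``topology.bonds``, ``fourier`` rows with
    ``topology.flexible_dihedrals`` (columns are c_0 ... c_N), and the
    per-atom ``charges``/``lj_epsilon``/``lj_sigma`` with ``topology.atoms``.
    """

    state: str                      # "S0" | "S1"
    bond_k: np.ndarray              # kJ mol^-1 nm^-2
    bond_r0: np.ndarray             # nm
    angle_k: np.ndarray             # kJ mol^-1 rad^-2
    angle_theta0: np.ndarray        # rad
    stiff_k: np.ndarray             # kJ mol^-1 rad^-2
    stiff_phi0: np.ndarray          # rad
    fourier: np.ndarray             # (n_flexible, order + 1), kJ/mol
    charges: np.ndarray             # e
    lj_epsilon: np.ndarray          # kJ/mol
    lj_sigma: np.ndarray            # nm
    pair_epsilon: np.ndarray | None = None   # explicit-pair overrides
    pair_sigma: np.ndarray | None = None
    wall: DihedralWall | None = None
    fudge_lj: float = 0.5
    fudge_qq: float = 0.5

    def __post_init__(self) -> None:
        for name in ("bond_k", "bond_r0", "angle_k", "angle_theta0",
                     "stiff_k", "stiff_phi0", "charges", "lj_epsilon",
                     "lj_sigma"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.fourier = np.atleast_2d(np.asarray(self.fourier, dtype=float))
        if self.fourier.size == 0:
            self.fourier = self.fourier.reshape(0, 1)
        for name in ("bond_k", "angle_k", "stiff_k", "lj_epsilon"):
            if (getattr(self, name) < 0).any():
                raise ParameterError(f"{name} must be nonnegative")
        if (self.lj_sigma <= 0).any():
            raise ParameterError("lj_sigma must be positive")

    @property
    def fourier_order(self) -> int:
        return self.fourier.shape[1] - 1

    def validate_against(self, topo: Topology) -> None:
        n = topo.n_atoms
        checks = [
            (len(self.bond_k), len(topo.bonds), "bonds"),
            (len(self.bond_r0), len(topo.bonds), "bonds"),
            (len(self.angle_k), len(topo.angles), "angles"),
            (len(self.stiff_k), len(topo.stiff_dihedrals), "stiff dihedrals"),
            (self.fourier.shape[0], len(topo.flexible_dihedrals),
             "flexible dihedrals"),
            (len(self.charges), n, "atoms"),
            (len(self.lj_epsilon), n, "atoms"),
            (len(self.lj_sigma), n, "atoms"),
        ]
        for got, want, what in checks:
            if got != want:
                raise StructureError(
                    f"parameter block sized {got} does not match {want} {what}")
        # Solvent molecules must be individually neutral.
        mol = topo.molecule_ids
        roles = np.array([a.role for a in topo.atoms])
        for m in np.unique(mol[roles == "solvent"]):
            q = self.charges[mol == m].sum()
            if abs(q) > 1e-10:
                raise ParameterError(
                    f"solvent molecule {m} carries net charge {q:.2e} e")

    def copy(self) -> "ForceFieldParameters":
        new = replace(self)
        for name in ("bond_k", "bond_r0", "angle_k", "angle_theta0",
                     "stiff_k", "stiff_phi0", "fourier", "charges",
                     "lj_epsilon", "lj_sigma"):
            setattr(new, name, getattr(self, name).copy())
        if self.pair_epsilon is not None:
            new.pair_epsilon = self.pair_epsilon.copy()
        if self.pair_sigma is not None:
            new.pair_sigma = self.pair_sigma.copy()
        return new


@dataclass(frozen=True)
class NonbondedSettings:
    """Cutoff scheme shared by energy evaluation and dynamics.

    ``coulomb`` is one of ``"truncate"`` (plain cutoff, default),
    ``"shift"`` (potential shifted to zero at the cutoff) or
    ``"reaction_field"`` (infinite-dielectric reaction field: both potential
    and force are continuous at the cutoff).  ``lj_shift`` subtracts the LJ
    potential at the cutoff (forces unchanged).
    """

    cutoff: float = 1.2   # nm
    coulomb: str = "truncate"
    lj_shift: bool = False

    def __post_init__(self) -> None:
        if self.coulomb not in _COUL_CODES:
            raise ParameterError(f"unknown coulomb treatment {self.coulomb!r}")
        if self.cutoff <= 0:
            raise ParameterError("cutoff must be positive")


@dataclass(frozen=True)
class EnergyReport:
    """Total potential energy with a per-term decomposition (kJ/mol)."""

    bond: float
    angle: float
    stiff_dihedral: float
    flexible_dihedral: float
    intra_lj: float
    inter_lj: float
    coulomb: float
    restraint: float = 0.0

    @property
    def total(self) -> float:
        return (self.bond + self.angle + self.stiff_dihedral
                + self.flexible_dihedral + self.intra_lj + self.inter_lj
                + self.coulomb + self.restraint)


# ---------------------------------------------------------------------------
# packing into kernel arrays
# ---------------------------------------------------------------------------

_I = np.int64


@dataclass
class PackedSystem:
    """Kernel-ready array view of (topology, force field, nonbonded settings)."""

    n_atoms: int
    cutoff: float
    coul_mode: int
    lj_shift: bool
    bond_ij: np.ndarray
    bond_kf: np.ndarray
    bond_r0: np.ndarray
    ang_ijk: np.ndarray
    ang_kf: np.ndarray
    ang_t0: np.ndarray
    dih_ijkl: np.ndarray
    dih_kf: np.ndarray
    dih_phi0: np.ndarray
    flex_ijkl: np.ndarray
    flex_c: np.ndarray
    wall_ijkl: np.ndarray
    wall_phi0: np.ndarray
    wall_kf: np.ndarray
    nb_ij: np.ndarray
    nb_qq: np.ndarray
    nb_c6: np.ndarray
    nb_c12: np.ndarray
    nb_intra: np.ndarray
    xp_ij: np.ndarray
    xp_c6: np.ndarray
    xp_c12: np.ndarray
    posres_idx: np.ndarray = field(
        default_factory=lambda: np.zeros(0, dtype=_I))
    posres_ref: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 3)))
    posres_kf: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def kernel_args(self):
        return (self.bond_ij, self.bond_kf, self.bond_r0,
                self.ang_ijk, self.ang_kf, self.ang_t0,
                self.dih_ijkl, self.dih_kf, self.dih_phi0,
                self.flex_ijkl, self.flex_c,
                self.wall_ijkl, self.wall_phi0, self.wall_kf,
                self.nb_ij, self.nb_qq, self.nb_c6, self.nb_c12, self.nb_intra,
                self.xp_ij, self.xp_c6, self.xp_c12,
                self.coul_mode, self.lj_shift,
                self.posres_idx, self.posres_ref, self.posres_kf)

    def with_restraints(self, idx, ref, k) -> "PackedSystem":
        new = replace(self)
        new.posres_idx = np.asarray(idx, dtype=_I)
        new.posres_ref = np.asarray(ref, dtype=float)
        new.posres_kf = np.full(len(new.posres_idx), float(k))
        return new


def _combine_lj(eps_i, eps_j, sig_i, sig_j):
    eps = math.sqrt(eps_i * eps_j)
    sig = 0.5 * (sig_i + sig_j)
    s6 = sig ** 6
    return 4.0 * eps * s6, 4.0 * eps * s6 * s6   # c6, c12


def pack_system(topo: Topology, ff: ForceFieldParameters,
                nb: NonbondedSettings | None = None) -> PackedSystem:
    """Flatten topology + parameters into contiguous kernel arrays."""
    nb = nb or NonbondedSettings()
    ff.validate_against(topo)
    n = topo.n_atoms

    bond_ij = np.array(topo.bonds, dtype=_I).reshape(-1, 2)
    ang_ijk = np.array(topo.angles, dtype=_I).reshape(-1, 3)
    dih_ijkl = np.array(topo.stiff_dihedrals, dtype=_I).reshape(-1, 4)
    flex_ijkl = np.array([f.indices for f in topo.flexible_dihedrals],
                         dtype=_I).reshape(-1, 4)
    if ff.wall is not None:
        wall_ijkl = np.array([ff.wall.indices], dtype=_I)
        wall_phi0 = np.array([ff.wall.wall_degrees * units.RAD_PER_DEG])
        wall_kf = np.array([ff.wall.k_wall])
    else:
        wall_ijkl = np.zeros((0, 4), dtype=_I)
        wall_phi0 = np.zeros(0)
        wall_kf = np.zeros(0)

    # --- nonbonded pair list -------------------------------------------
    mol = topo.molecule_ids
    eps = ff.lj_epsilon
    sig = ff.lj_sigma
    q = ff.charges

    pi: list[int] = []
    pj: list[int] = []
    slj: list[float] = []
    sqq: list[float] = []
    intra: list[bool] = []

    # intramolecular part (small molecules; explicit python loop)
    if topo.exclusion_policy == "graph14":
        dists = topo.graph_distances(max_dist=3)
        for m_atoms in topo.molecules():
            for a in range(len(m_atoms)):
                for b in range(a + 1, len(m_atoms)):
                    i, j = int(m_atoms[a]), int(m_atoms[b])
                    d = dists.get((min(i, j), max(i, j)), 99)
                    if d <= 2:
                        continue
                    if d == 3:
                        pi.append(i); pj.append(j)
                        slj.append(ff.fudge_lj); sqq.append(ff.fudge_qq)
                    else:
                        pi.append(i); pj.append(j)
                        slj.append(1.0); sqq.append(1.0)
                    intra.append(True)
    # "pairs_only": no generic intramolecular nonbonded interactions

    iu, ju = np.triu_indices(n, 1)
    inter = mol[iu] != mol[ju]
    iu, ju = iu[inter], ju[inter]

    all_i = np.concatenate([np.array(pi, dtype=_I), iu.astype(_I)])
    all_j = np.concatenate([np.array(pj, dtype=_I), ju.astype(_I)])
    lj_scale = np.concatenate([np.array(slj), np.ones(len(iu))])
    qq_scale = np.concatenate([np.array(sqq), np.ones(len(iu))])
    nb_intra = np.concatenate([np.array(intra, dtype=bool),
                               np.zeros(len(iu), dtype=bool)])

    # Lorentz-Berthelot combination on (eps, sigma), then c6/c12
    eps_ij = np.sqrt(eps[all_i] * eps[all_j])
    sig_ij = 0.5 * (sig[all_i] + sig[all_j])
    c6 = 4.0 * eps_ij * sig_ij ** 6 * lj_scale
    c12 = 4.0 * eps_ij * sig_ij ** 12 * lj_scale
    qq = units.F_COULOMB * q[all_i] * q[all_j] * qq_scale

    nb_ij = np.stack([all_i, all_j], axis=1).astype(_I)

    # explicit intramolecular LJ pairs
    xp = np.array(topo.pairs, dtype=_I).reshape(-1, 2)
    xp_c6 = np.zeros(len(xp))
    xp_c12 = np.zeros(len(xp))
    for p, (i, j) in enumerate(xp):
        if ff.pair_epsilon is not None and ff.pair_sigma is not None:
            e, s = ff.pair_epsilon[p], ff.pair_sigma[p]
            xp_c6[p] = 4.0 * e * s ** 6
            xp_c12[p] = 4.0 * e * s ** 12
        else:
            xp_c6[p], xp_c12[p] = _combine_lj(eps[i], eps[j], sig[i], sig[j])

    return PackedSystem(
        n_atoms=n, cutoff=nb.cutoff, coul_mode=_COUL_CODES[nb.coulomb],
        lj_shift=nb.lj_shift,
        bond_ij=bond_ij, bond_kf=ff.bond_k, bond_r0=ff.bond_r0,
        ang_ijk=ang_ijk, ang_kf=ff.angle_k, ang_t0=ff.angle_theta0,
        dih_ijkl=dih_ijkl, dih_kf=ff.stiff_k, dih_phi0=ff.stiff_phi0,
        flex_ijkl=flex_ijkl, flex_c=ff.fourier,
        wall_ijkl=wall_ijkl, wall_phi0=wall_phi0, wall_kf=wall_kf,
        nb_ij=nb_ij, nb_qq=qq, nb_c6=c6, nb_c12=c12, nb_intra=nb_intra,
        xp_ij=xp, xp_c6=xp_c6, xp_c12=xp_c12,
    )


def auto_nonbonded(box: float, base: NonbondedSettings | None = None
                   ) -> NonbondedSettings:
    """Settings with the cutoff clipped to half the box when needed."""
    base = base or NonbondedSettings()
    if box > 0.0 and base.cutoff > box / 2.0:
        return NonbondedSettings(cutoff=0.4999 * box, coulomb=base.coulomb,
                                 lj_shift=base.lj_shift)
    return base


def _effective_cutoff(box: float, cutoff: float) -> float:
    if box <= 0.0:
        return -1.0   # no cutoff in gas phase
    if box < 2.0 * cutoff:
        raise ConfigurationError(
            f"box edge {box} nm smaller than twice the cutoff {cutoff} nm")
    return cutoff


def _eval_packed(packed: PackedSystem, positions: np.ndarray, box: float):
    forces = np.empty_like(positions)
    cutoff = _effective_cutoff(box, packed.cutoff)
    terms, virial = _kernels.forces_energy(
        positions, box, cutoff, *packed.kernel_args(), forces)
    return terms, virial, forces


def evaluate_energy(config: SystemConfiguration, topo: Topology,
                    ff: ForceFieldParameters,
                    nb: NonbondedSettings | None = None) -> EnergyReport:
    """Potential energy of a configuration, decomposed by term."""
    if config.n_atoms != topo.n_atoms:
        raise StructureError(
            f"configuration has {config.n_atoms} atoms, topology {topo.n_atoms}")
    packed = pack_system(topo, ff, nb)
    terms, _, _ = _eval_packed(packed, config.positions, config.box)
    return EnergyReport(*terms)


def evaluate_forces(config: SystemConfiguration, topo: Topology,
                    ff: ForceFieldParameters,
                    nb: NonbondedSettings | None = None) -> np.ndarray:
    """Analytic forces, kJ mol^-1 nm^-1, shape (N, 3)."""
    if config.n_atoms != topo.n_atoms:
        raise StructureError(
            f"configuration has {config.n_atoms} atoms, topology {topo.n_atoms}")
    packed = pack_system(topo, ff, nb)
    _, _, forces = _eval_packed(packed, config.positions, config.box)
    return forces


# ---------------------------------------------------------------------------
# internal coordinates
# ---------------------------------------------------------------------------

def compute_dihedral(positions: np.ndarray, i: int, j: int, k: int, l: int,
                     box: float = 0.0) -> float:
    """Signed dihedral angle in degrees, in (-180, 180]; cis = 0."""
    if len({i, j, k, l}) != 4:
        raise DegenerateGeometryError("dihedral needs four distinct atoms")
    pos = np.asarray(positions, dtype=float)

    def d(a, b):
        v = pos[b] - pos[a]
        if box > 0.0:
            v = v - box * np.floor(v / box + 0.5)
        return v

    b1, b2, b3 = d(i, j), d(j, k), d(k, l)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise DegenerateGeometryError("collinear atoms in dihedral")
    m = np.cross(n1, n2)
    y = float(m @ b2) / np.linalg.norm(b2)
    x = float(n1 @ n2)
    phi = math.degrees(math.atan2(y, x))
    if phi <= -180.0:
        phi += 360.0
    return phi


def dihedral_gradient(positions: np.ndarray, i: int, j: int, k: int, l: int,
                      box: float = 0.0) -> tuple[float, np.ndarray]:
    """Dihedral in radians and its gradient wrt all N*3 coordinates."""
    pos = np.ascontiguousarray(positions, dtype=float)
    phi, g = _kernels._dihedral_geometry(pos, i, j, k, l, box)
    grad = np.zeros_like(pos)
    for m, a in enumerate((i, j, k, l)):
        grad[a] = g[m]
    return phi, grad


# ---------------------------------------------------------------------------
# Hessian and normal modes
# ---------------------------------------------------------------------------

def ff_hessian(config: SystemConfiguration, topo: Topology,
               ff: ForceFieldParameters, nb: NonbondedSettings | None = None,
               step: float = 1e-5) -> np.ndarray:
    """3N x 3N second-derivative matrix by central differences of forces.

    Symmetrized as (H + H^T)/2; kJ mol^-1 nm^-2.
    """
    packed = pack_system(topo, ff, nb)
    pos = config.positions.copy()
    n3 = pos.size
    h = np.empty((n3, n3))
    flat = pos.reshape(-1)
    for c in range(n3):
        orig = flat[c]
        flat[c] = orig + step
        _, _, fp = _eval_packed(packed, pos, config.box)
        flat[c] = orig - step
        _, _, fm = _eval_packed(packed, pos, config.box)
        flat[c] = orig
        h[:, c] = -(fp - fm).reshape(-1) / (2.0 * step)
    return 0.5 * (h + h.T)


def normal_modes(hessian: np.ndarray, masses: np.ndarray,
                 positions: np.ndarray | None = None):
    """Harmonic frequencies (cm^-1) and Cartesian mode vectors.

    Mass-weighted diagonalization; rigid translations (and rotations, when
    ``positions`` is given) are projected out in the Eckart frame before
    diagonalizing, so the six external modes come out at exactly zero.
    Negative eigenvalues are reported as negative wavenumbers (imaginary
    frequencies).

    Returns ``(frequencies, modes)`` with ``modes[:, m]`` the Cartesian
    displacement of mode ``m``.
    """
    hessian = np.asarray(hessian, dtype=float)
    masses = np.asarray(masses, dtype=float)
    n = len(masses)
    if hessian.shape != (3 * n, 3 * n):
        raise StructureError(
            f"hessian shape {hessian.shape} does not match {n} masses")
    invsqrt = np.repeat(1.0 / np.sqrt(masses), 3)
    hw = hessian * invsqrt[:, None] * invsqrt[None, :]

    # external-mode basis in mass-weighted coordinates
    ext = []
    sqrtm = np.repeat(np.sqrt(masses), 3)
    for c in range(3):
        v = np.zeros(3 * n)
        v[c::3] = 1.0
        ext.append(v * sqrtm)
    if positions is not None:
        pos = np.asarray(positions, dtype=float)
        com = (masses[:, None] * pos).sum(axis=0) / masses.sum()
        rel = pos - com
        for axis in np.eye(3):
            disp = np.cross(rel, axis)      # rigid rotation field
            ext.append(disp.reshape(-1) * sqrtm)
    basis = np.array(ext).T
    # rank-revealing orthonormalization (linear molecules have only two
    # rotational modes)
    u, s, _ = np.linalg.svd(basis, full_matrices=False)
    qmat = u[:, s > 1e-8 * s[0]]
    proj = np.eye(3 * n) - qmat @ qmat.T
    hw = proj @ hw @ proj
    hw = 0.5 * (hw + hw.T)

    evals, evecs = np.linalg.eigh(hw)
    omega = np.sign(evals) * np.sqrt(np.abs(evals))   # rad/ps
    freqs = units.omega_to_wavenumber(omega)
    modes = evecs * invsqrt[:, None]
    return freqs, modes
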