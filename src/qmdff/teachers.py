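"""Synthetic "teacher" systems standing in for electronic-structure data.

Real state-specific force fields are fitted to quantum-mechanical
descriptors (optimized geometry, Hessian, relaxed torsional scans,
per-state charges).  Here those descriptors are generated from analytically
defined teacher potentials with *known* parameters, so the whole
parameterization and non-equilibrium pipeline can be validated by exact
parameter recovery.

The teacher chromophore is a 12-atom planar conjugated toy with the
photochemically relevant sites of a curcuminoid-like dye:

* a hydroxyl hydrogen-bond donor (``Oh``-``Ho``),
* a carbonyl acceptor (``C2``=``O2``) whose partial charge shrinks in
  magnitude upon excitation,
* one flexible aryl torsion (label ``delta3``), ground-state profile
  ``B sin^2(delta)`` with B = 23 kJ/mol (CYC presets) or 19 kJ/mol (PYR),
* one isomerizable torsion (label ``delta4``) whose excited-state profile
  has either a high 42 kJ/mol barrier before the 90-degree conical
  intersection funnel (CYC_S1) or a low 7 kJ/mol barrier with a -20 kJ/mol
  funnel (PYR_S1).

Solvents are flexible 3-site models: TIP3P-charge water, a polar protic
ethanol-like and an aprotic acetonitrile-like liquid (negative nitrogen
site ``Nz``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import units
from .errors import ConvergenceError, ParameterError, StructureError
from .forcefield import (ForceFieldParameters, SystemConfiguration,
                         compute_dihedral, ff_hessian)
from .minimize import minimize_geometry, minimize_with_frozen_dihedral
from .profiles import TorsionProfile, fourier_eval
from .topology import Atom, FlexibleDihedral, Topology

__all__ = [
    "TeacherSystem", "QMDescriptorBundle", "build_teacher_system",
    "generate_state_charges", "generate_hessian", "relaxed_scan",
    "generate_descriptor_bundle", "mock_vertical_transitions",
    "add_descriptor_noise", "PRESETS", "SOLVENTS", "pyr_s1_coefficients",
]

PRESETS = ("CYC_S0", "CYC_S1", "PYR_S0", "PYR_S1")
SOLVENTS = ("water", "ethanol_like", "acetonitrile_like", "none")

#: documented torsional barriers of the teacher presets (kJ/mol)
ARYL_BARRIER = {"CYC": 23.0, "PYR": 19.0}
ISO_BARRIER_S1 = {"CYC": 42.0, "PYR": 7.0}
ISO_BARRIER_S0 = 60.0
PYR_FUNNEL_DEPTH = -20.0

#: per-state charge of the carbonyl oxygen O2 (e)
O2_CHARGE = {("CYC", "S0"): -0.71, ("CYC", "S1"): -0.63,
             ("PYR", "S0"): -0.74, ("PYR", "S1"): -0.66}


def pyr_s1_coefficients(funnel=PYR_FUNNEL_DEPTH, barrier=ISO_BARRIER_S1["PYR"]):
    """Cosine coefficients (c0, c2, c4) of the PYR-like S1 isomerization
    potential, solved from V(180) = 0, V(90) = funnel, local barrier above
    V(180) equal to ``barrier``."""
    c2 = -funnel / 2.0
    disc = (barrier + c2) ** 2 - c2 ** 2
    if disc <= 0:
        raise ParameterError("no solution: barrier too small for this funnel")
    c4 = (-(barrier + c2) - math.sqrt(disc)) / 4.0
    c0 = -c2 - c4
    return c0, c2, c4


# ---------------------------------------------------------------------------
# geometry construction (internal-coordinate placement)
# ---------------------------------------------------------------------------

def _place(c, b, a, r, theta_deg, phi_deg):
    """Position a new atom D bonded to C with angle D-C-B and dihedral
    D-C-B-A (degrees)."""
    theta = math.radians(theta_deg)
    phi = math.radians(phi_deg)
    u_cb = (b - c) / np.linalg.norm(b - c)
    n = np.cross(b - a, c - b)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        n = np.array([0.0, 0.0, 1.0])
    else:
        n = n / nn
    m = np.cross(n, u_cb)
    d = c + r * (math.cos(theta) * u_cb
                 - math.sin(theta) * (math.cos(phi) * m + math.sin(phi) * n))
    return d


_ZMAT = [
    # idx, C, B, A, r(nm), angle(deg), dihedral(deg)
    (0, 1, 2, None, 0.108, 120.0, None),     # H1 on Cb1
    (10, 1, 2, 0, 0.136, 120.0, 180.0),      # Oh on Cb1, opposite H1
    (3, 2, 1, 0, 0.108, 120.0, 0.0),         # H2 on Cb2
    (4, 2, 1, 0, 0.148, 120.0, 180.0),       # Cm on Cb2
    (11, 10, 1, 2, 0.096, 109.0, 0.0),       # Ho on Oh, toward the carbonyl
    (5, 4, 2, 1, 0.146, 123.0, 180.0),       # C2 on Cm   -> delta3 = 180
    (6, 5, 4, 2, 0.122, 121.0, 0.0),         # O2 on C2
    (7, 5, 4, 2, 0.148, 117.0, 180.0),       # Cv on C2
    (8, 7, 5, 4, 0.134, 122.0, 180.0),       # Cw on Cv
    (9, 8, 7, 5, 0.108, 120.0, 180.0),       # H3 on Cw   -> delta4 = 180
]

_ATOMS = [
    ("H1", "H", 1.008), ("Cb1", "C", 12.011), ("Cb2", "C", 12.011),
    ("H2", "H", 1.008), ("Cm", "C", 12.011), ("C2", "C", 12.011),
    ("O2", "O", 15.999), ("Cv", "C", 12.011), ("Cw", "C", 12.011),
    ("H3", "H", 1.008), ("Oh", "O", 15.999), ("Ho", "H", 1.008),
]

_BONDS = [(0, 1), (1, 2), (1, 10), (10, 11), (2, 3), (2, 4),
          (4, 5), (5, 6), (5, 7), (7, 8), (8, 9)]

_ANGLES = [(0, 1, 2), (0, 1, 10), (2, 1, 10),
           (1, 2, 3), (1, 2, 4), (3, 2, 4),
           (2, 4, 5),
           (4, 5, 6), (4, 5, 7), (6, 5, 7),
           (5, 7, 8), (7, 8, 9), (1, 10, 11)]

_STIFF = [(0, 1, 2, 4), (10, 1, 2, 3), (2, 1, 10, 11), (0, 1, 10, 11),
          (2, 4, 5, 6), (2, 4, 5, 7), (4, 5, 7, 8)]

DELTA3 = (1, 2, 4, 5)   # aryl torsion
DELTA4 = (5, 7, 8, 9)   # isomerizable torsion

# base charges; C2/O2 filled per family and state so the total stays 0
_BASE_Q = {"H1": 0.10, "Cb1": 0.15, "Cb2": -0.10, "H2": 0.10, "Cm": -0.10,
           "Cv": -0.10, "Cw": -0.05, "H3": 0.10, "Oh": -0.60, "Ho": 0.40}

_LJ = {"C": (0.360, 0.340), "O": (0.710, 0.300), "H": (0.063, 0.242)}
_LJ_HO = (0.0, 0.10)   # polar hydrogen: no dispersion, token radius


def chromophore_geometry() -> np.ndarray:
    pos = np.zeros((12, 3))
    pos[1] = (0.0, 0.0, 0.0)
    pos[2] = (0.140, 0.0, 0.0)
    for idx, c, b, a, r, theta, phi in _ZMAT:
        if a is None:
            ang = math.radians(theta)
            pos[idx] = pos[c] + r * np.array([math.cos(ang), math.sin(ang), 0.0])
        else:
            pos[idx] = _place(pos[c], pos[b], pos[a], r, theta, phi)
    return pos


def chromophore_topology() -> Topology:
    atoms = [Atom(n, e, m, molecule=0, role="solute") for n, e, m in _ATOMS]
    return Topology(
        atoms=atoms, bonds=list(_BONDS), angles=list(_ANGLES),
        stiff_dihedrals=list(_STIFF),
        flexible_dihedrals=[FlexibleDihedral(DELTA3, "delta3"),
                            FlexibleDihedral(DELTA4, "delta4")],
        exclusion_policy="pairs_only",
    )


def _measure_equilibria(pos: np.ndarray):
    r0 = np.array([np.linalg.norm(pos[j] - pos[i]) for i, j in _BONDS])
    th0 = np.empty(len(_ANGLES))
    for n, (i, j, k) in enumerate(_ANGLES):
        u = pos[i] - pos[j]
        v = pos[k] - pos[j]
        th0[n] = math.acos(np.clip(
            u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0))
    phi0 = np.array([
        compute_dihedral(pos, *d) * units.RAD_PER_DEG for d in _STIFF])
    return r0, th0, phi0


def _fourier_sin2(barrier: float, order: int = 6) -> np.ndarray:
    """B sin^2(delta) = B/2 - (B/2) cos(2 delta)."""
    c = np.zeros(order + 1)
    c[0] = barrier / 2.0
    c[2] = -barrier / 2.0
    return c


def _chromophore_ff(family: str, state: str, order: int = 6
                    ) -> ForceFieldParameters:
    pos = chromophore_geometry()
    r0, th0, phi0 = _measure_equilibria(pos)

    bond_k = np.array([284512.0, 265000.0, 267776.0, 462750.0, 284512.0,
                       265000.0, 265000.0, 476976.0, 265000.0, 418400.0,
                       284512.0])
    angle_k = np.array([320.0, 320.0, 450.0, 320.0, 450.0, 320.0, 450.0,
                        450.0, 450.0, 450.0, 450.0, 320.0, 350.0])
    stiff_k = np.full(len(_STIFF), 40.0)

    if state == "S1":
        # weakened carbonyl and isomerizable double bond, reinforced linker
        bond_k = bond_k.copy()
        bond_k[7] = 420000.0    # C2=O2
        bond_k[9] = 320000.0    # Cv=Cw
        bond_k[8] = 300000.0    # C2-Cv
        r0 = r0.copy()
        r0[7] += 0.004
        r0[9] += 0.004
        angle_k = angle_k.copy()
        angle_k[7] = 400.0
        angle_k[10] = 400.0
        stiff_k = stiff_k.copy()
        stiff_k[6] = 35.0   # softened backbone torsion next to Cv=Cw

    fourier = np.zeros((2, order + 1))
    fourier[0] = _fourier_sin2(ARYL_BARRIER[family], order)
    if state == "S0":
        fourier[1] = _fourier_sin2(ISO_BARRIER_S0, order)
    elif family == "CYC":
        fourier[1] = _fourier_sin2(ISO_BARRIER_S1["CYC"], order)
    else:
        c0, c2, c4 = pyr_s1_coefficients()
        fourier[1, 0], fourier[1, 2], fourier[1, 4] = c0, c2, c4

    names = [n for n, _, _ in _ATOMS]
    q = np.array([_BASE_Q.get(n, 0.0) for n in names])
    q_o2 = O2_CHARGE[(family, state)]
    q[names.index("O2")] = q_o2
    q[names.index("C2")] = -(q.sum() - q[names.index("C2")])

    eps = np.empty(12)
    sig = np.empty(12)
    for i, (n, e, _) in enumerate(_ATOMS):
        eps[i], sig[i] = _LJ_HO if n == "Ho" else _LJ[e]

    return ForceFieldParameters(
        state=state, bond_k=bond_k, bond_r0=r0, angle_k=angle_k,
        angle_theta0=th0, stiff_k=stiff_k, stiff_phi0=phi0,
        fourier=fourier, charges=q, lj_epsilon=eps, lj_sigma=sig)


# ---------------------------------------------------------------------------
# solvents
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _SolventModel:
    names: tuple[str, ...]
    elements: tuple[str, ...]
    masses: tuple[float, ...]
    charges: tuple[float, ...]
    lj: tuple[tuple[float, float], ...]         # (eps, sigma) per site
    template: tuple[tuple[float, float, float], ...]
    bonds: tuple[tuple[int, int], ...]
    bond_k: tuple[float, ...]
    bond_r0: tuple[float, ...]
    angle: tuple[int, int, int]
    angle_k: float
    angle_theta0_deg: float
    number_density: float                        # molecules / nm^3


def _water() -> _SolventModel:
    r = 0.09572
    half = math.radians(104.52 / 2.0)
    return _SolventModel(
        names=("Ow", "Hw", "Hw"), elements=("O", "H", "H"),
        masses=(15.999, 1.008, 1.008), charges=(-0.834, 0.417, 0.417),
        lj=((0.63639, 0.31506), (0.0, 0.04), (0.0, 0.04)),
        template=((0.0, 0.0, 0.0),
                  (r * math.cos(half), r * math.sin(half), 0.0),
                  (r * math.cos(half), -r * math.sin(half), 0.0)),
        bonds=((0, 1), (0, 2)), bond_k=(462750.0, 462750.0),
        bond_r0=(r, r), angle=(1, 0, 2), angle_k=383.0,
        angle_theta0_deg=104.52, number_density=33.37)


def _ethanol_like() -> _SolventModel:
    # united ethyl / hydroxyl oxygen / polar hydrogen
    ang = math.radians(108.5)
    return _SolventModel(
        names=("Et", "Oe", "He"), elements=("C", "O", "H"),
        masses=(29.062, 15.999, 1.008), charges=(0.265, -0.700, 0.435),
        lj=((0.60, 0.395), (0.711, 0.312), (0.0, 0.04)),
        template=((-0.143, 0.0, 0.0), (0.0, 0.0, 0.0),
                  (0.0945 * math.cos(math.pi - ang),
                   0.0945 * math.sin(math.pi - ang), 0.0)),
        bonds=((0, 1), (1, 2)), bond_k=(267776.0, 462750.0),
        bond_r0=(0.143, 0.0945), angle=(0, 1, 2), angle_k=460.0,
        angle_theta0_deg=108.5, number_density=10.3)


def _acetonitrile_like() -> _SolventModel:
    return _SolventModel(
        names=("Me", "Cz", "Nz"), elements=("C", "C", "N"),
        masses=(15.035, 12.011, 14.007), charges=(0.269, 0.129, -0.398),
        lj=((0.78, 0.360), (0.42, 0.340), (0.42, 0.330)),
        template=((-0.1458, 0.0, 0.0), (0.0, 0.0, 0.0), (0.1157, 0.0, 0.0)),
        bonds=((0, 1), (1, 2)), bond_k=(313800.0, 502080.0),
        bond_r0=(0.1458, 0.1157), angle=(0, 1, 2), angle_k=300.0,
        angle_theta0_deg=180.0, number_density=11.5)


_SOLVENT_MODELS = {"water": _water, "ethanol_like": _ethanol_like,
                   "acetonitrile_like": _acetonitrile_like}


# ---------------------------------------------------------------------------
# teacher system
# ---------------------------------------------------------------------------

@dataclass
class TeacherSystem:
    """Ground-truth potentials and topology for one preset chromophore,
    optionally solvated."""

    preset: str
    family: str                                  # "CYC" | "PYR"
    topology: Topology                           # chromophore + solvent
    ff: dict[str, ForceFieldParameters]          # per electronic state
    solvent_kind: str = "none"
    n_solvent: int = 0
    seed: int = 0
    anharmonic_amplitude: float = 0.0

    @property
    def active_state(self) -> str:
        return self.preset.split("_")[1]

    def solute_topology(self) -> Topology:
        return self.topology.subset(self.topology.solute_atoms())

    def solute_ff(self, state: str) -> ForceFieldParameters:
        ns = len(self.topology.solute_atoms())
        full = self.ff[state]
        out = full.copy()
        out.charges = full.charges[:ns]
        out.lj_epsilon = full.lj_epsilon[:ns]
        out.lj_sigma = full.lj_sigma[:ns]
        # chromophore bonded terms come first by construction
        nb, na = len(_BONDS), len(_ANGLES)
        out.bond_k = full.bond_k[:nb]
        out.bond_r0 = full.bond_r0[:nb]
        out.angle_k = full.angle_k[:na]
        out.angle_theta0 = full.angle_theta0[:na]
        return out


@dataclass
class QMDescriptorBundle:
    """Everything the fitting stage consumes for one electronic state."""

    geometry: np.ndarray                      # (N, 3) nm, optimized
    hessian: np.ndarray                       # (3N, 3N) kJ mol^-1 nm^-2
    profiles: list[TorsionProfile]
    charges: np.ndarray                       # e, for this state
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        h = np.asarray(self.hessian, dtype=float)
        if h.ndim != 2 or h.shape[0] != h.shape[1]:
            raise StructureError("hessian must be square")
        asym = np.abs(h - h.T).max()
        if asym > 1e-6 * max(1.0, np.abs(h).max()):
            raise StructureError(f"hessian not symmetric (max asym {asym:.2e})")
        for p in self.profiles:
            if abs(p.energies.min()) > 1e-9:
                raise StructureError(
                    f"profile {p.label!r} not normalized to zero minimum")


def _preset_family(preset: str) -> str:
    if preset not in PRESETS:
        raise ParameterError(f"unknown preset {preset!r}; use one of {PRESETS}")
    return preset.split("_")[0]


def build_teacher_system(preset: str, solvent_kind: str = "none",
                         n_solvent: int = 0, seed: int = 0,
                         box_padding: float = 0.0
                         ) -> tuple[TeacherSystem, SystemConfiguration]:
    """Assemble a teacher chromophore (optionally soaked in solvent) and an
    initial configuration.

    The box edge follows the solvent's liquid number density; solvent
    molecules are placed on a jittered grid, skipping sites that clash with
    the solute.
    """
    family = _preset_family(preset)
    if solvent_kind not in SOLVENTS:
        raise ParameterError(
            f"unknown solvent {solvent_kind!r}; use one of {SOLVENTS}")
    if n_solvent < 0:
        raise ParameterError("n_solvent must be >= 0")
    if solvent_kind == "none":
        n_solvent = 0

    topo_solute = chromophore_topology()
    pos_solute = chromophore_geometry()
    ffs = {s: _chromophore_ff(family, s) for s in ("S0", "S1")}

    atoms = list(topo_solute.atoms)
    bonds = list(topo_solute.bonds)
    angles = list(topo_solute.angles)
    positions = [pos_solute]

    if n_solvent > 0:
        model = _SOLVENT_MODELS[solvent_kind]()
        v_solute = 0.30
        edge = ((n_solvent / model.number_density) + v_solute) ** (1.0 / 3.0)
        edge += box_padding
        rng = np.random.default_rng(seed)
        ncell = max(2, math.ceil(n_solvent ** (1.0 / 3.0)))
        while ncell ** 3 < n_solvent * 3:
            ncell += 1
        spacing = edge / ncell
        center = np.full(3, edge / 2.0)
        solute_shift = center - pos_solute.mean(axis=0)
        positions[0] = pos_solute + solute_shift
        template = np.array(model.template)
        placed = 0
        sites = [(ix, iy, iz) for ix in range(ncell)
                 for iy in range(ncell) for iz in range(ncell)]
        rng.shuffle(sites)
        sol_pos = []
        for ix, iy, iz in sites:
            if placed == n_solvent:
                break
            base = (np.array([ix, iy, iz]) + 0.5) * spacing
            base += rng.uniform(-0.08, 0.08, 3) * spacing
            if np.min(np.linalg.norm(positions[0] - base, axis=1)) < 0.30:
                continue
            # random orientation
            qv = rng.normal(size=4)
            qv /= np.linalg.norm(qv)
            w, x, y, z = qv
            rot = np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ])
            sol_pos.append(template @ rot.T + base)
            placed += 1
        if placed < n_solvent:
            raise ConvergenceError(
                f"could only place {placed}/{n_solvent} solvent molecules")
        nsites = len(model.names)
        for m in range(n_solvent):
            off = 12 + m * nsites
            for s in range(nsites):
                atoms.append(Atom(model.names[s], model.elements[s],
                                  model.masses[s], molecule=1 + m,
                                  role="solvent"))
            for (a, b) in model.bonds:
                bonds.append((off + a, off + b))
            i, j, k = model.angle
            angles.append((off + i, off + j, off + k))
            positions.append(sol_pos[m])

        full_topo = Topology(
            atoms=atoms, bonds=bonds, angles=angles,
            stiff_dihedrals=list(topo_solute.stiff_dihedrals),
            flexible_dihedrals=list(topo_solute.flexible_dihedrals),
            pairs=list(topo_solute.pairs),
            exclusion_policy="pairs_only")
        for s in ("S0", "S1"):
            ff = ffs[s]
            ffs[s] = ForceFieldParameters(
                state=s,
                bond_k=np.concatenate(
                    [ff.bond_k, np.tile(model.bond_k, n_solvent)]),
                bond_r0=np.concatenate(
                    [ff.bond_r0, np.tile(model.bond_r0, n_solvent)]),
                angle_k=np.concatenate(
                    [ff.angle_k, np.full(n_solvent, model.angle_k)]),
                angle_theta0=np.concatenate(
                    [ff.angle_theta0,
                     np.full(n_solvent,
                             math.radians(model.angle_theta0_deg))]),
                stiff_k=ff.stiff_k, stiff_phi0=ff.stiff_phi0,
                fourier=ff.fourier,
                charges=np.concatenate(
                    [ff.charges, np.tile(model.charges, n_solvent)]),
                lj_epsilon=np.concatenate(
                    [ff.lj_epsilon,
                     np.tile([e for e, _ in model.lj], n_solvent)]),
                lj_sigma=np.concatenate(
                    [ff.lj_sigma,
                     np.tile([s_ for _, s_ in model.lj], n_solvent)]),
            )
        box = edge
    else:
        full_topo = topo_solute
        box = 0.0

    all_pos = np.vstack(positions)
    config = SystemConfiguration(all_pos, np.zeros_like(all_pos), box=box)
    teacher = TeacherSystem(preset=preset, family=family, topology=full_topo,
                            ff=ffs, solvent_kind=solvent_kind,
                            n_solvent=n_solvent, seed=seed)
    _assert_preset_barriers(teacher)
    return teacher, config


def _assert_preset_barriers(teacher: TeacherSystem) -> None:
    """Teacher barrier heights must equal the documented values exactly."""
    grid = np.linspace(0.0, 180.0, 3601)
    for state in ("S0", "S1"):
        ff = teacher.ff[state]
        aryl = fourier_eval(ff.fourier[0], grid)
        assert abs((aryl.max() - aryl.min())
                   - ARYL_BARRIER[teacher.family]) < 1e-9
        if state == "S1":
            # local barrier relative to the trans (180 deg) minimum
            from scipy.optimize import minimize_scalar
            iso = fourier_eval(ff.fourier[1], grid)
            lo = max(0.0, grid[iso.argmax()] - 1.0)
            hi = min(180.0, grid[iso.argmax()] + 1.0)
            res = minimize_scalar(
                lambda a: -fourier_eval(ff.fourier[1], np.array([a]))[0],
                bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-10})
            v180 = fourier_eval(ff.fourier[1], np.array([180.0]))[0]
            target = ISO_BARRIER_S1[teacher.family]
            assert abs((-res.fun - v180) - target) < 1e-6


def generate_state_charges(teacher: TeacherSystem, state: str) -> np.ndarray:
    """Chromophore point charges for one electronic state (e).

    The O2 charge takes the state-specific value; the compensating shift
    sits on the bonded carbonyl carbon, so the total molecular charge is
    state-independent.
    """
    if state not in ("S0", "S1"):
        raise ParameterError(f"state must be S0 or S1, got {state!r}")
    ns = len(teacher.topology.solute_atoms())
    return teacher.ff[state].charges[:ns].copy()


def generate_hessian(teacher: TeacherSystem, state: str,
                     gtol: float = 1e-7) -> tuple[np.ndarray, np.ndarray]:
    """Optimize the isolated chromophore on the teacher potential and
    return (geometry, Hessian)."""
    topo = teacher.solute_topology()
    ff = teacher.solute_ff(state)
    pos = minimize_geometry(chromophore_geometry(), topo, ff, gtol_rms=gtol)
    cfg = SystemConfiguration(pos, np.zeros_like(pos))
    hess = ff_hessian(cfg, topo, ff)
    return pos, hess


def _resolve_dihedral(topo: Topology, dihedral) -> tuple[tuple, str]:
    if isinstance(dihedral, str):
        for f in topo.flexible_dihedrals:
            if f.label == dihedral:
                return f.indices, f.label
        raise ParameterError(f"no flexible dihedral labelled {dihedral!r}")
    tup = tuple(int(x) for x in dihedral)
    for f in topo.flexible_dihedrals:
        if f.indices == tup or f.indices == tup[::-1]:
            return f.indices, f.label
    raise ParameterError(f"dihedral {tup} is not flagged flexible")


def relaxed_scan(teacher: TeacherSystem, state: str, dihedral,
                 grid_degrees: np.ndarray) -> TorsionProfile:
    """Frozen-rotation relaxed scan of a flexible dihedral.

    At each grid point the scanned dihedral is constrained exactly and all
    other coordinates are relaxed; energies are reported relative to the
    grid minimum.  Each point starts from the previous relaxed structure to
    follow the adiabatic valley.
    """
    grid = np.asarray(grid_degrees, dtype=float)
    if grid.ndim != 1 or not np.all(np.diff(grid) > 0):
        raise ParameterError("grid must be strictly increasing")
    topo = teacher.solute_topology()
    ff = teacher.solute_ff(state)
    indices, label = _resolve_dihedral(topo, dihedral)

    pos = minimize_geometry(chromophore_geometry(), topo, ff, gtol_rms=1e-7)
    energies = np.empty(grid.size)
    geoms: list[np.ndarray] = []
    for g, angle in enumerate(grid):
        try:
            pos, e = minimize_with_frozen_dihedral(pos, topo, ff, indices,
                                                   angle)
        except Exception as exc:   # pragma: no cover - defensive
            raise ConvergenceError(
                f"relaxed scan failed at grid point {angle} deg: {exc}")
        energies[g] = e
        geoms.append(pos.copy())
    energies -= energies.min()
    return TorsionProfile(dihedral=indices, angles_deg=grid,
                          energies=energies, label=label, geometries=geoms)


def generate_descriptor_bundle(teacher: TeacherSystem, state: str,
                               grid_degrees: np.ndarray | None = None
                               ) -> QMDescriptorBundle:
    """Full descriptor set: optimized geometry + Hessian + one relaxed scan
    per flexible dihedral + state charges."""
    if grid_degrees is None:
        grid_degrees = np.arange(0.0, 180.0 + 1e-9, 15.0)
    geom, hess = generate_hessian(teacher, state)
    profiles = [relaxed_scan(teacher, state, f.label, grid_degrees)
                for f in teacher.solute_topology().flexible_dihedrals]
    return QMDescriptorBundle(
        geometry=geom, hessian=hess, profiles=profiles,
        charges=generate_state_charges(teacher, state),
        metadata={"preset": teacher.preset, "state": state,
                  "seed": teacher.seed, "noise": 0.0})


def mock_vertical_transitions(config: SystemConfiguration, topo: Topology,
                              ff_s0: ForceFieldParameters,
                              ff_s1: ForceFieldParameters,
                              offset_ev: float = 3.2,
                              f0: float = 1.0, nb=None
                              ) -> list[tuple[float, float]]:
    """Vertical excitation energy and oscillator strength for a snapshot.

    The energy gap is the classical potential-energy difference between the
    two teacher surfaces plus a constant electronic offset; the oscillator
    strength follows the planarity of the isomerizable torsion,
    ``f = f0 cos^2(delta)``, mimicking a bright planar pi-pi* state that
    darkens toward the conical-intersection geometry.
    """
    from .forcefield import auto_nonbonded, evaluate_energy
    nb = auto_nonbonded(config.box, nb)
    e0 = evaluate_energy(config, topo, ff_s0, nb).total
    e1 = evaluate_energy(config, topo, ff_s1, nb).total
    gap = units.kjmol_to_ev(e1 - e0) + offset_ev
    indices, _ = _resolve_dihedral(topo, "delta4")
    delta = compute_dihedral(config.positions, *indices, box=config.box)
    f = f0 * math.cos(math.radians(delta)) ** 2
    return [(gap, f)]


def add_descriptor_noise(bundle: QMDescriptorBundle, sigma_hessian: float,
                         sigma_scan: float, seed: int) -> QMDescriptorBundle:
    """Gaussian-perturbed copy of a bundle (Hessian re-symmetrized, scans
    re-normalized to zero minimum); reproducible for a given seed."""
    if sigma_hessian < 0 or sigma_scan < 0:
        raise ParameterError("noise sigmas must be nonnegative")
    if sigma_hessian == 0 and sigma_scan == 0:
        return QMDescriptorBundle(
            geometry=bundle.geometry.copy(), hessian=bundle.hessian.copy(),
            profiles=[TorsionProfile(p.dihedral, p.angles_deg.copy(),
                                     p.energies.copy(), p.label, p.geometries)
                      for p in bundle.profiles],
            charges=bundle.charges.copy(),
            metadata=dict(bundle.metadata))
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, 1.0, bundle.hessian.shape) * sigma_hessian
    hess = bundle.hessian + 0.5 * (noise + noise.T)
    profiles = []
    for p in bundle.profiles:
        e = p.energies + rng.normal(0.0, 1.0, p.energies.shape) * sigma_scan
        e -= e.min()
        profiles.append(TorsionProfile(p.dihedral, p.angles_deg.copy(), e,
                                       p.label, p.geometries))
    meta = dict(bundle.metadata)
    meta["noise"] = (sigma_hessian, sigma_scan, seed)
    return QMDescriptorBundle(geometry=bundle.geometry.copy(), hessian=hess,
                              profiles=profiles,
                              charges=bundle.charges.copy(), metadata=meta)
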