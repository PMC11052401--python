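"""File formats: topology/parameter dialect, GRO/XYZ coordinates, TSV
tables and the QM-descriptor bundle.

The native parameter file is a GROMACS-flavoured sectioned text format
(one combined file carries topology and one state's parameters); GRO and
XYZ round-trip through MDAnalysis with the nm <-> Angstrom conversion
handled here.  Descriptor bundles serialize to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import units
from .errors import ParameterError
from .forcefield import (DihedralWall, ForceFieldParameters,
                         SystemConfiguration)
from .profiles import TorsionProfile
from .teachers import QMDescriptorBundle
from .topology import Atom, FlexibleDihedral, Topology

__all__ = [
    "write_forcefield", "read_forcefield", "write_gro", "read_gro",
    "write_xyz", "read_xyz", "save_bundle", "load_bundle",
    "profile_to_tsv", "profile_from_tsv", "energy_series_to_tsv",
]


# ---------------------------------------------------------------------------
# topology + parameter dialect
# ---------------------------------------------------------------------------

def write_forcefield(path, topo: Topology, ff: ForceFieldParameters) -> None:
    """Write topology and one state's parameters in the sectioned dialect.

    Units on file: nm, kJ/mol, degrees (angles and phases), amu, e.
    """
    ff.validate_against(topo)
    lines = ["; qmdff topology/parameter file",
             "", "[ defaults ]",
             f"state {ff.state}",
             f"exclusion_policy {topo.exclusion_policy}",
             f"fudge_lj {ff.fudge_lj}", f"fudge_qq {ff.fudge_qq}",
             "", "[ atoms ]",
             "; idx name element mass molecule role charge sigma epsilon"]
    for i, a in enumerate(topo.atoms):
        lines.append(
            f"{i} {a.name} {a.element} {a.mass:.6g} {a.molecule} {a.role} "
            f"{ff.charges[i]:.10g} {ff.lj_sigma[i]:.10g} "
            f"{ff.lj_epsilon[i]:.10g}")
    lines += ["", "[ bonds ]", "; i j k r0"]
    for n, (i, j) in enumerate(topo.bonds):
        lines.append(f"{i} {j} {ff.bond_k[n]:.10g} {ff.bond_r0[n]:.10g}")
    lines += ["", "[ angles ]", "; i j k kf theta0_deg"]
    for n, (i, j, k) in enumerate(topo.angles):
        lines.append(f"{i} {j} {k} {ff.angle_k[n]:.10g} "
                     f"{ff.angle_theta0[n] * units.DEG_PER_RAD:.10g}")
    lines += ["", "[ dihedrals ]", "; i j k l kf phi0_deg"]
    for n, (i, j, k, l) in enumerate(topo.stiff_dihedrals):
        lines.append(f"{i} {j} {k} {l} {ff.stiff_k[n]:.10g} "
                     f"{ff.stiff_phi0[n] * units.DEG_PER_RAD:.10g}")
    lines += ["", "[ flexible_dihedrals ]", "; i j k l label c0 ... cN"]
    for n, f in enumerate(topo.flexible_dihedrals):
        cs = " ".join(f"{c:.10g}" for c in ff.fourier[n])
        i, j, k, l = f.indices
        lines.append(f"{i} {j} {k} {l} {f.label} {cs}")
    lines += ["", "[ pairs ]", "; i j [epsilon sigma]"]
    for n, (i, j) in enumerate(topo.pairs):
        if ff.pair_epsilon is not None:
            lines.append(f"{i} {j} {ff.pair_epsilon[n]:.10g} "
                         f"{ff.pair_sigma[n]:.10g}")
        else:
            lines.append(f"{i} {j}")
    if ff.wall is not None:
        i, j, k, l = ff.wall.indices
        lines += ["", "[ wall ]", "; i j k l wall_deg k_wall",
                  f"{i} {j} {k} {l} {ff.wall.wall_degrees:.10g} "
                  f"{ff.wall.k_wall:.10g}"]
    Path(path).write_text("\n".join(lines) + "\n")


def _sections(text: str) -> dict[str, list[list[str]]]:
    out: dict[str, list[list[str]]] = {}
    current = None
    for raw in text.splitlines():
        line = raw.split(";")[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line.strip("[] ").strip()
            out.setdefault(current, [])
            continue
        if current is None:
            raise ParameterError(f"content outside any section: {raw!r}")
        out[current].append(line.split())
    return out


def read_forcefield(path) -> tuple[Topology, ForceFieldParameters]:
    sec = _sections(Path(path).read_text())
    for required in ("atoms", "bonds", "angles"):
        if required not in sec:
            raise ParameterError(f"missing [ {required} ] section")
    defaults = {row[0]: row[1] for row in sec.get("defaults", [])}

    atoms, charges, sig, eps = [], [], [], []
    for row in sec["atoms"]:
        _, name, elem, mass, mol, role, q, s, e = row[:9]
        atoms.append(Atom(name, elem, float(mass), int(mol), role))
        charges.append(float(q))
        sig.append(float(s))
        eps.append(float(e))

    bonds, bond_k, bond_r0 = [], [], []
    for i, j, kf, r0 in sec["bonds"]:
        bonds.append((int(i), int(j)))
        bond_k.append(float(kf))
        bond_r0.append(float(r0))
    angles, ang_k, ang_t0 = [], [], []
    for i, j, k, kf, t0 in sec["angles"]:
        angles.append((int(i), int(j), int(k)))
        ang_k.append(float(kf))
        ang_t0.append(float(t0) * units.RAD_PER_DEG)
    stiff, st_k, st_p0 = [], [], []
    for i, j, k, l, kf, p0 in sec.get("dihedrals", []):
        stiff.append((int(i), int(j), int(k), int(l)))
        st_k.append(float(kf))
        st_p0.append(float(p0) * units.RAD_PER_DEG)
    flex, fourier = [], []
    for row in sec.get("flexible_dihedrals", []):
        idx = tuple(int(x) for x in row[:4])
        flex.append(FlexibleDihedral(idx, row[4]))
        fourier.append([float(c) for c in row[5:]])
    if fourier:
        width = max(len(c) for c in fourier)
        fourier = [c + [0.0] * (width - len(c)) for c in fourier]
    pairs, p_eps, p_sig = [], [], []
    for row in sec.get("pairs", []):
        pairs.append((int(row[0]), int(row[1])))
        if len(row) >= 4:
            p_eps.append(float(row[2]))
            p_sig.append(float(row[3]))
    wall = None
    for i, j, k, l, w, kw in sec.get("wall", []):
        wall = DihedralWall((int(i), int(j), int(k), int(l)),
                            float(w), float(kw))

    topo = Topology(atoms=atoms, bonds=bonds, angles=angles,
                    stiff_dihedrals=stiff, flexible_dihedrals=flex,
                    pairs=pairs,
                    exclusion_policy=defaults.get("exclusion_policy",
                                                  "graph14"))
    ff = ForceFieldParameters(
        state=defaults.get("state", "S0"),
        bond_k=np.array(bond_k), bond_r0=np.array(bond_r0),
        angle_k=np.array(ang_k), angle_theta0=np.array(ang_t0),
        stiff_k=np.array(st_k), stiff_phi0=np.array(st_p0),
        fourier=(np.array(fourier) if fourier else np.zeros((0, 1))),
        charges=np.array(charges), lj_epsilon=np.array(eps),
        lj_sigma=np.array(sig),
        pair_epsilon=np.array(p_eps) if p_eps else None,
        pair_sigma=np.array(p_sig) if p_sig else None,
        wall=wall,
        fudge_lj=float(defaults.get("fudge_lj", 0.5)),
        fudge_qq=float(defaults.get("fudge_qq", 0.5)))
    ff.validate_against(topo)
    return topo, ff


# ---------------------------------------------------------------------------
# coordinates (GRO / XYZ via MDAnalysis)
# ---------------------------------------------------------------------------

def _mda_universe(topo: Topology, config: SystemConfiguration):
    import MDAnalysis as mda
    n = topo.n_atoms
    u = mda.Universe.empty(n, n_residues=int(topo.molecule_ids.max()) + 1,
                           atom_resindex=topo.molecule_ids,
                           trajectory=True, velocities=True)
    u.add_TopologyAttr("names", topo.names)
    resnames = []
    for m_atoms in topo.molecules():
        resnames.append("SOL" if topo.atoms[int(m_atoms[0])].role == "solvent"
                        else "CHR")
    u.add_TopologyAttr("resnames", resnames)
    u.atoms.positions = config.positions * units.ANGSTROM_PER_NM
    u.atoms.velocities = config.velocities * units.ANGSTROM_PER_NM
    if config.box > 0:
        u.dimensions = [config.box * units.ANGSTROM_PER_NM] * 3 + [90.0] * 3
    return u


def write_gro(path, topo: Topology, config: SystemConfiguration) -> None:
    u = _mda_universe(topo, config)
    u.atoms.write(str(path))


def read_gro(path) -> tuple[np.ndarray, np.ndarray | None, float]:
    """Returns (positions nm, velocities nm/ps or None, box edge nm)."""
    import MDAnalysis as mda
    u = mda.Universe(str(path))
    pos = u.atoms.positions * units.NM_PER_ANGSTROM
    vel = None
    if hasattr(u.atoms, "velocities"):
        try:
            vel = u.atoms.velocities * units.NM_PER_ANGSTROM
        except Exception:
            vel = None
    box = 0.0
    if u.dimensions is not None and u.dimensions[0] > 0:
        box = float(u.dimensions[0]) * units.NM_PER_ANGSTROM
    return pos.astype(float), vel, box


def write_xyz(path, names: list[str], positions: np.ndarray,
              comment: str = "") -> None:
    pos = np.asarray(positions, dtype=float) * units.ANGSTROM_PER_NM
    with open(path, "w") as fh:
        fh.write(f"{len(names)}\n{comment}\n")
        for name, (x, y, z) in zip(names, pos):
            fh.write(f"{name:<4s} {x:14.8f} {y:14.8f} {z:14.8f}\n")


def read_xyz(path) -> tuple[list[str], np.ndarray]:
    import MDAnalysis as mda
    u = mda.Universe(str(path))
    return list(u.atoms.names), u.atoms.positions * units.NM_PER_ANGSTROM


# ---------------------------------------------------------------------------
# descriptor bundles and tables
# ---------------------------------------------------------------------------

def save_bundle(path, bundle: QMDescriptorBundle,
                with_geometries: bool = True) -> None:
    data = {
        "geometry": bundle.geometry.tolist(),
        "hessian": bundle.hessian.tolist(),
        "charges": bundle.charges.tolist(),
        "metadata": bundle.metadata,
        "profiles": [{
            "dihedral": list(p.dihedral),
            "label": p.label,
            "angles_deg": p.angles_deg.tolist(),
            "energies": p.energies.tolist(),
            "geometries": ([g.tolist() for g in p.geometries]
                           if (with_geometries and p.geometries) else None),
        } for p in bundle.profiles],
    }
    Path(path).write_text(json.dumps(data))


def load_bundle(path) -> QMDescriptorBundle:
    data = json.loads(Path(path).read_text())
    profiles = []
    for p in data["profiles"]:
        geoms = ([np.array(g) for g in p["geometries"]]
                 if p.get("geometries") else None)
        profiles.append(TorsionProfile(
            tuple(p["dihedral"]), np.array(p["angles_deg"]),
            np.array(p["energies"]), p["label"], geometries=geoms))
    return QMDescriptorBundle(
        geometry=np.array(data["geometry"]),
        hessian=np.array(data["hessian"]),
        profiles=profiles, charges=np.array(data["charges"]),
        metadata=data.get("metadata", {}))


def profile_to_tsv(path, profile: TorsionProfile) -> None:
    pd.DataFrame({"angle_deg": profile.angles_deg,
                  "energy_kjmol": profile.energies}).to_csv(
        path, sep="\t", index=False)


def profile_from_tsv(path, dihedral=(0, 1, 2, 3),
                     label: str = "") -> TorsionProfile:
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    return TorsionProfile(tuple(dihedral), df[cols[0]].to_numpy(),
                          df[cols[1]].to_numpy(), label)


def energy_series_to_tsv(path, traj) -> None:
    df = pd.DataFrame({"time_ps": traj.times, **traj.series})
    df.to_csv(path, sep="\t", index=False)
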