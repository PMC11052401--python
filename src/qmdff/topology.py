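"""Molecular topology: atoms, bonded terms and nonbonded bookkeeping.

A :class:`Topology` is purely structural — it lists atoms with masses and
roles, the bonded index tuples, which proper dihedrals are treated as
*flexible* (anharmonic, Fourier-expanded) rather than *stiff* (harmonic),
explicit intramolecular nonbonded pairs, and molecule boundaries.  All force
constants, equilibrium values and charges live in
:class:`qmdff.forcefield.ForceFieldParameters` so that the same topology can
carry several electronic states.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Atom", "FlexibleDihedral", "Topology", "TopologyError"]


class TopologyError(ValueError):
    """Raised for structurally inconsistent topologies."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    mass: float          # amu
    molecule: int        # 0-based molecule id
    role: str = "solute"  # "solute" | "solvent"
    charge_group: int = 0


@dataclass(frozen=True)
class FlexibleDihedral:
    indices: tuple[int, int, int, int]
    label: str


@dataclass
class Topology:
    """Connectivity and bookkeeping for one simulated system.

    ``exclusion_policy`` controls intramolecular nonbonded interactions:

    ``"graph14"``
        1-2 and 1-3 pairs excluded, 1-4 pairs scaled (fudge factors are
        supplied at evaluation time), more distant intramolecular pairs
        interact fully.
    ``"pairs_only"``
        all intramolecular nonbonded interactions excluded except the
        explicit ``pairs`` list (used to couple selected rotors through
        dedicated LJ contacts).
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    angles: list[tuple[int, int, int]] = field(default_factory=list)
    stiff_dihedrals: list[tuple[int, int, int, int]] = field(default_factory=list)
    flexible_dihedrals: list[FlexibleDihedral] = field(default_factory=list)
    pairs: list[tuple[int, int]] = field(default_factory=list)
    exclusion_policy: str = "graph14"

    def __post_init__(self) -> None:
        self.validate()

    # -- basic views ---------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def molecule_ids(self) -> np.ndarray:
        return np.array([a.molecule for a in self.atoms], dtype=np.int64)

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.atoms]

    def atom_indices(self, name: str) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.name == name]

    def solute_atoms(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.role == "solute"],
                        dtype=np.int64)

    def solvent_atoms(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.role == "solvent"],
                        dtype=np.int64)

    def molecules(self) -> list[np.ndarray]:
        mol = self.molecule_ids
        return [np.flatnonzero(mol == m) for m in range(int(mol.max()) + 1)]

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        n = self.n_atoms
        if n == 0:
            raise TopologyError("topology has no atoms")

        def chk(tup, name):
            for t in tup:
                if any((i < 0 or i >= n) for i in t):
                    raise TopologyError(f"{name} index out of range: {t}")
                if len(set(t)) != len(t):
                    raise TopologyError(f"duplicate atom in {name} tuple: {t}")

        chk(self.bonds, "bond")
        chk(self.angles, "angle")
        chk(self.stiff_dihedrals, "dihedral")
        chk([f.indices for f in self.flexible_dihedrals], "flexible dihedral")
        chk(self.pairs, "pair")

        def canon(t):
            return t if t[0] < t[-1] else tuple(reversed(t))

        for name, tuples in (("bond", self.bonds), ("angle", self.angles)):
            seen = set()
            for t in tuples:
                c = canon(t)
                if c in seen:
                    raise TopologyError(f"duplicate {name}: {t}")
                seen.add(c)

        stiff = {canon(t) for t in self.stiff_dihedrals}
        if len(stiff) != len(self.stiff_dihedrals):
            raise TopologyError("duplicate stiff dihedral")
        flex = {canon(f.indices) for f in self.flexible_dihedrals}
        if len(flex) != len(self.flexible_dihedrals):
            raise TopologyError("duplicate flexible dihedral")
        if stiff & flex:
            raise TopologyError(
                f"dihedrals declared both stiff and flexible: {stiff & flex}")

        bond_set = {canon(b) for b in self.bonds}
        angle_13 = {canon((a[0], a[2])) for a in self.angles}
        for p in self.pairs:
            c = canon(p)
            if c in bond_set or c in angle_13:
                raise TopologyError(
                    f"explicit pair {p} already covered by a bond or angle")
        mol = self.molecule_ids
        for i, j in self.bonds:
            if mol[i] != mol[j]:
                raise TopologyError(f"bond {i}-{j} crosses molecules")
        if self.exclusion_policy not in ("graph14", "pairs_only"):
            raise TopologyError(f"unknown exclusion policy {self.exclusion_policy!r}")

    # -- graph machinery ------------------------------------------------
    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for i, j in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def graph_distances(self, max_dist: int = 3) -> dict[tuple[int, int], int]:
        """Bond-graph distances up to ``max_dist`` for all connected pairs."""
        adj = self.adjacency()
        out: dict[tuple[int, int], int] = {}
        for src in range(self.n_atoms):
            dist = {src: 0}
            q = deque([src])
            while q:
                u = q.popleft()
                if dist[u] == max_dist:
                    continue
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        q.append(v)
            for v, d in dist.items():
                if v > src:
                    out[(src, v)] = d
        return out

    def subtree(self, root: int, blocked: int) -> np.ndarray:
        """Atoms reachable from ``root`` without passing through ``blocked``."""
        adj = self.adjacency()
        seen = {root}
        q = deque([root])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if v != blocked and v not in seen:
                    seen.add(v)
                    q.append(v)
        return np.array(sorted(seen), dtype=np.int64)

    def subset(self, atom_indices: np.ndarray) -> "Topology":
        """Topology restricted to the given atoms (bonded terms fully inside)."""
        idx = np.asarray(atom_indices, dtype=np.int64)
        remap = {int(a): i for i, a in enumerate(idx)}
        keep = set(remap)

        def take(tuples):
            return [tuple(remap[i] for i in t) for t in tuples if set(t) <= keep]

        return Topology(
            atoms=[self.atoms[int(a)] for a in idx],
            bonds=take(self.bonds),
            angles=take(self.angles),
            stiff_dihedrals=take(self.stiff_dihedrals),
            flexible_dihedrals=[
                FlexibleDihedral(tuple(remap[i] for i in f.indices), f.label)
                for f in self.flexible_dihedrals if set(f.indices) <= keep
            ],
            pairs=take(self.pairs),
            exclusion_policy=self.exclusion_policy,
        )
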