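"""Vertical-excitation force-field switch and non-equilibrium swarms.

Photoexcitation is mimicked in the Franck-Condon spirit: ground-state
positions and velocities are kept while the chromophore's intramolecular
parameters and charges are swapped from the S0 to the S1 set (solvent
parameters are identical across states).  A swarm of independent
trajectories, each started from an uncorrelated equilibrium snapshot and
aligned at the switch time t = 0, samples the subsequent solvent
reorganization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units
from .errors import IntegrationBlowupError, ParameterError, StructureError
from .forcefield import (ForceFieldParameters, SystemConfiguration,
                         evaluate_energy)
from .md import IntegratorSettings, Trajectory
from .topology import Topology

__all__ = ["SwarmSpec", "TrajectorySwarm", "switch_state", "vertical_gap",
           "run_swarm", "default_frame_schedule"]


def _solvent_params_match(topo: Topology, ff_a: ForceFieldParameters,
                          ff_b: ForceFieldParameters) -> bool:
    sol = topo.solvent_atoms()
    if sol.size == 0:
        return True
    same = (np.array_equal(ff_a.charges[sol], ff_b.charges[sol])
            and np.array_equal(ff_a.lj_epsilon[sol], ff_b.lj_epsilon[sol])
            and np.array_equal(ff_a.lj_sigma[sol], ff_b.lj_sigma[sol]))
    # solvent bonded terms: bonds/angles whose atoms are all solvent
    solset = set(int(i) for i in sol)
    for n, b in enumerate(topo.bonds):
        if set(b) <= solset:
            same &= (ff_a.bond_k[n] == ff_b.bond_k[n]
                     and ff_a.bond_r0[n] == ff_b.bond_r0[n])
    for n, a in enumerate(topo.angles):
        if set(a) <= solset:
            same &= (ff_a.angle_k[n] == ff_b.angle_k[n]
                     and ff_a.angle_theta0[n] == ff_b.angle_theta0[n])
    return bool(same)


def switch_state(config: SystemConfiguration, topo: Topology,
                 ff_s0: ForceFieldParameters, ff_s1: ForceFieldParameters
                 ) -> tuple[SystemConfiguration, ForceFieldParameters]:
    """Franck-Condon switch: same coordinates and velocities, S1 potential.

    Returns the (bit-identical) configuration and the now-active S1
    parameter set.  Both parameter sets must share the topology, and the
    solvent must be described identically in both.
    """
    for ff in (ff_s0, ff_s1):
        ff.validate_against(topo)
    if not _solvent_params_match(topo, ff_s0, ff_s1):
        raise StructureError(
            "solvent parameters differ between the two electronic states")
    return config, ff_s1


def vertical_gap(config: SystemConfiguration, topo: Topology,
                 ff_s0: ForceFieldParameters, ff_s1: ForceFieldParameters,
                 offset_ev: float = 0.0, nb=None) -> float:
    """Instantaneous S1 - S0 potential-energy gap in eV (plus electronic
    offset), evaluated at fixed nuclear coordinates."""
    from .forcefield import auto_nonbonded
    nb = auto_nonbonded(config.box, nb)
    e0 = evaluate_energy(config, topo, ff_s0, nb).total
    e1 = evaluate_energy(config, topo, ff_s1, nb).total
    return units.kjmol_to_ev(e1 - e0) + offset_ev


def default_frame_schedule(length_ps: float) -> np.ndarray:
    """Frame-saving times resolving both sub-ps and >100 ps responses:
    every 5 fs below 2 ps, every 1 ps below 100 ps, every 10 ps beyond."""
    pieces = [np.arange(0.005, min(length_ps, 2.0) + 1e-9, 0.005)]
    if length_ps > 2.0:
        pieces.append(np.arange(3.0, min(length_ps, 100.0) + 1e-9, 1.0))
    if length_ps > 100.0:
        pieces.append(np.arange(110.0, length_ps + 1e-9, 10.0))
    sched = np.unique(np.concatenate(pieces))
    return sched[sched <= length_ps + 1e-9]


@dataclass
class SwarmSpec:
    """Everything needed to launch one swarm of independent members."""

    initial_conditions: list[SystemConfiguration]
    ff_s0: ForceFieldParameters
    ff_s1: ForceFieldParameters
    settings: IntegratorSettings
    length_ps: float
    seeds: list[int] | None = None
    schedule_ps: np.ndarray | None = None     # times after the switch

    def __post_init__(self) -> None:
        if not self.initial_conditions:
            raise ParameterError("swarm needs at least one initial condition")
        if self.seeds is None:
            self.seeds = list(range(len(self.initial_conditions)))
        if len(self.seeds) != len(self.initial_conditions):
            raise ParameterError("one seed per member required")
        if len(set(self.seeds)) != len(self.seeds):
            raise ParameterError("member seeds must be unique")
        if self.schedule_ps is None:
            self.schedule_ps = default_frame_schedule(self.length_ps)
        self.schedule_ps = np.asarray(self.schedule_ps, dtype=float)
        if not np.all(np.diff(self.schedule_ps) > 0):
            raise ParameterError("frame schedule must be sorted")

    @property
    def n_members(self) -> int:
        return len(self.initial_conditions)


@dataclass
class TrajectorySwarm:
    """Independent non-equilibrium trajectories aligned at the switch."""

    members: list[Trajectory]
    topology: Topology
    schedule_ps: np.ndarray
    failures: dict[int, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return len(self.members)


def _run_member(cfg0: SystemConfiguration, topo: Topology,
                packed, settings: IntegratorSettings,
                schedule_ps: np.ndarray, seed: int) -> Trajectory:
    from .md import _RunState
    dt = settings.timestep
    steps_at = np.round(schedule_ps / dt).astype(int)
    if np.any(np.diff(np.concatenate([[0], steps_at])) < 1):
        raise ParameterError("frame schedule finer than the timestep")
    rng = np.random.default_rng(seed)
    start = cfg0.copy()
    start.time = 0.0
    state = _RunState(start, topo, packed, settings)
    frames = [start]
    times = [0.0]
    temps = [state.temperature()]
    prev = 0
    for target in steps_at:
        state.advance_coupled(int(target) - prev, rng)
        prev = int(target)
        frames.append(state.as_config())
        times.append(state.time)
        temps.append(state.temperature())
    return Trajectory(frames=frames, times=np.array(times),
                      ensemble="neq-s1", seed=seed,
                      series={"temperature": np.array(temps)})


def run_swarm(spec: SwarmSpec, topo: Topology) -> TrajectorySwarm:
    """Propagate every member on the S1 surface from its snapshot.

    Members are independent (own seed, own integrator state); the result
    does not depend on execution order.  A member whose integration blows
    up is recorded in ``failures`` without aborting the rest.  The t = 0
    frame of every member is its initial condition.
    """
    from .forcefield import pack_system
    for cfg in spec.initial_conditions:
        switch_state(cfg, topo, spec.ff_s0, spec.ff_s1)   # validates
    packed = pack_system(topo, spec.ff_s1, spec.settings.nonbonded)
    members: list[Trajectory] = []
    failures: dict[int, str] = {}
    for m, (cfg0, seed) in enumerate(zip(spec.initial_conditions,
                                         spec.seeds)):
        try:
            members.append(_run_member(cfg0, topo, packed,
                                       spec.settings, spec.schedule_ps,
                                       seed))
        except IntegrationBlowupError as exc:
            failures[m] = str(exc)
    return TrajectorySwarm(
        members=members, topology=topo, schedule_ps=spec.schedule_ps.copy(),
        failures=failures,
        provenance={"n_members": spec.n_members,
                    "seeds": list(spec.seeds),
                    "length_ps": spec.length_ps,
                    "timestep_ps": spec.settings.timestep})
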