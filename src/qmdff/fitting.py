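"""Two-step force-field parameterization from QM-style descriptors.

Step 1 (:func:`fit_harmonic_parameters`) fixes every equilibrium value to
the coordinate measured at the reference geometry and obtains all harmonic
force constants at once by bounded linear least squares over the Cartesian
Hessian elements — the force-field Hessian is exactly linear in the force
constants once the equilibria are frozen.

Step 2 (:func:`fit_torsional_fourier`) handles the flexible, anharmonic
torsions with the frozen-internal-rotation (FIRA) residual: at every
relaxed-scan geometry the energy of all *other* force-field terms is
subtracted from the reference scan energy, and the remainder is fitted
with a cosine Fourier series.

Torsions that the reference electronic-structure level cannot describe
(e.g. across a conical intersection) are imported from a higher-level
tabulated profile with :func:`import_highlevel_torsion`, optionally after
mirror-symmetrizing the table about 90 degrees, and are then excluded from
any later fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from . import units
from .errors import (DegenerateGeometryError, ParameterError,
                     StructureError)
from .forcefield import (DihedralWall, ForceFieldParameters,
                         SystemConfiguration, evaluate_energy, ff_hessian,
                         normal_modes, compute_dihedral)
from .minimize import minimize_geometry
from .profiles import TorsionProfile, fourier_design_matrix
from .teachers import QMDescriptorBundle
from .topology import Topology

__all__ = [
    "FitReport", "fit_harmonic_parameters", "fit_torsional_fourier",
    "symmetrize_profile", "import_highlevel_torsion",
    "build_clockwise_restraint", "validate_frequencies", "fit_state",
]


@dataclass
class FitReport:
    """Outcome of one least-squares parameterization step."""

    parameters: ForceFieldParameters
    std_dev: float                       # RMS residual, descriptor units
    residuals: np.ndarray
    condition_number: float
    frequency_table: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.std_dev < 0:
            raise ParameterError("standard deviation cannot be negative")


def _measured_equilibria(pos: np.ndarray, topo: Topology):
    r0 = np.array([float(np.linalg.norm(pos[j] - pos[i]))
                   for i, j in topo.bonds])
    th0 = np.empty(len(topo.angles))
    for n, (i, j, k) in enumerate(topo.angles):
        u = pos[i] - pos[j]
        v = pos[k] - pos[j]
        th0[n] = math.acos(float(np.clip(
            u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0)))
    phi0 = np.empty(len(topo.stiff_dihedrals))
    for n, d in enumerate(topo.stiff_dihedrals):
        try:
            phi0[n] = compute_dihedral(pos, *d) * units.RAD_PER_DEG
        except DegenerateGeometryError:
            # collinear at the reference: the term has no Hessian signature
            # and will surface as unidentifiable in the least squares
            phi0[n] = 0.0
    return r0, th0, phi0


def _zeroed_ff(topo: Topology, state: str, charges, lj_eps, lj_sig,
               order: int = 6) -> ForceFieldParameters:
    nf = len(topo.flexible_dihedrals)
    return ForceFieldParameters(
        state=state,
        bond_k=np.zeros(len(topo.bonds)), bond_r0=np.zeros(len(topo.bonds)),
        angle_k=np.zeros(len(topo.angles)),
        angle_theta0=np.zeros(len(topo.angles)),
        stiff_k=np.zeros(len(topo.stiff_dihedrals)),
        stiff_phi0=np.zeros(len(topo.stiff_dihedrals)),
        fourier=np.zeros((nf, order + 1)) if nf else np.zeros((0, 1)),
        charges=np.asarray(charges, dtype=float),
        lj_epsilon=np.asarray(lj_eps, dtype=float),
        lj_sigma=np.asarray(lj_sig, dtype=float))


def fit_harmonic_parameters(bundle: QMDescriptorBundle, topo: Topology,
                            frozen: set | None = None,
                            flexible_ff: ForceFieldParameters | None = None,
                            state: str = "S0",
                            lj_epsilon=None, lj_sigma=None,
                            ) -> tuple[ForceFieldParameters, FitReport]:
    """Fit all harmonic force constants to the reference Hessian.

    Equilibrium bond lengths, angles and stiff-dihedral phases are fixed to
    the values measured at the bundle geometry (assumed a stationary
    point).  Force constants solve a nonnegativity-bounded linear least
    squares over all 3N x 3N Cartesian Hessian elements.  When
    ``flexible_ff`` is given, the Hessian contribution of its flexible
    torsions (and nonbonded terms) is subtracted from the reference before
    fitting, which makes teacher-parameter recovery exact.

    ``frozen`` may list term identifiers ``("bond", i)`` etc. to exclude
    from the fit (their constants stay zero).
    """
    frozen = frozen or set()
    pos = np.asarray(bundle.geometry, dtype=float)
    n = topo.n_atoms
    if bundle.hessian.shape != (3 * n, 3 * n):
        raise StructureError("bundle Hessian does not match topology size")

    lj_eps = np.zeros(n) if lj_epsilon is None else np.asarray(lj_epsilon)
    lj_sig = np.full(n, 0.3) if lj_sigma is None else np.asarray(lj_sigma)

    r0, th0, phi0 = _measured_equilibria(pos, topo)
    cfg = SystemConfiguration(pos, np.zeros_like(pos))

    target = np.asarray(bundle.hessian, dtype=float).copy()

    # subtract terms that are supplied rather than fitted
    base = _zeroed_ff(topo, state, bundle.charges, lj_eps, lj_sig)
    base.bond_r0 = r0
    base.angle_theta0 = th0
    base.stiff_phi0 = phi0
    if flexible_ff is not None:
        base.fourier = flexible_ff.fourier.copy()
        base.wall = flexible_ff.wall
    target -= ff_hessian(cfg, topo, base)

    terms: list[tuple[str, int]] = []
    columns: list[np.ndarray] = []

    def term_column(kind: str, index: int) -> np.ndarray:
        probe = _zeroed_ff(topo, state, np.zeros(n), np.zeros(n),
                           np.full(n, 0.3))
        probe.bond_r0 = r0
        probe.angle_theta0 = th0
        probe.stiff_phi0 = phi0
        getattr(probe, kind)[index] = 1.0
        return ff_hessian(cfg, topo, probe).reshape(-1)

    for kind, count in (("bond_k", len(topo.bonds)),
                        ("angle_k", len(topo.angles)),
                        ("stiff_k", len(topo.stiff_dihedrals))):
        short = kind.split("_")[0]
        for i in range(count):
            if (short, i) in frozen or (kind, i) in frozen:
                continue
            terms.append((kind, i))
            columns.append(term_column(kind, i))

    a = np.stack(columns, axis=1)
    b = target.reshape(-1)
    sv = np.linalg.svd(a, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    if sv[-1] < 1e-10 * sv[0]:
        # identify unidentifiable terms from the null space
        _, _, vt = np.linalg.svd(a)
        null = vt[-1]
        bad = [terms[i] for i in np.flatnonzero(np.abs(null) > 0.1)]
        raise StructureError(
            f"rank-deficient harmonic design matrix; unidentifiable terms: {bad}")

    res = lsq_linear(a, b, bounds=(0.0, np.inf), tol=1e-14)
    x = res.x
    residuals = a @ x - b
    m = b.size
    std = float(np.sqrt((residuals ** 2).sum() / m))

    fitted = _zeroed_ff(topo, state, bundle.charges, lj_eps, lj_sig)
    fitted.bond_r0 = r0
    fitted.angle_theta0 = th0
    fitted.stiff_phi0 = phi0
    if flexible_ff is not None:
        fitted.fourier = flexible_ff.fourier.copy()
        fitted.wall = flexible_ff.wall
    for (kind, i), val in zip(terms, x):
        getattr(fitted, kind)[i] = val

    report = FitReport(parameters=fitted, std_dev=std, residuals=residuals,
                       condition_number=cond,
                       metadata={"n_parameters": len(terms),
                                 "n_descriptors": m})
    return fitted, report


def _profile_geometries(profile: TorsionProfile) -> list[np.ndarray]:
    if profile.geometries is None:
        raise StructureError(
            "torsion profile carries no scan geometries; regenerate the "
            "relaxed scan with geometries attached")
    return profile.geometries


def fit_torsional_fourier(profile: TorsionProfile, topo: Topology,
                          partial_ff: ForceFieldParameters,
                          dihedral: tuple | int | None = None,
                          order: int = 6) -> tuple[np.ndarray, float]:
    """FIRA fit of one flexible torsion; returns (coefficients, residual RMS).

    The residual ``E_res(d_i) = E_ref(d_i) - E_other(x_i)`` subtracts, at
    every scan geometry, the energy of the whole partial force field except
    the torsion being fitted (harmonic terms, other flexible torsions,
    nonbonded intramolecular contributions such as explicit rotor-coupling
    LJ pairs).  The Fourier coefficients then solve a plain linear least
    squares on the cosine basis.
    """
    if order >= profile.n_points:
        raise ParameterError(
            f"Fourier order {order} needs more than {profile.n_points} "
            "grid points")
    fidx = _flexible_index(topo, profile, dihedral)
    geoms = _profile_geometries(profile)

    other = partial_ff.copy()
    other.fourier[fidx, :] = 0.0
    e_other = np.array([
        evaluate_energy(SystemConfiguration(g, np.zeros_like(g)), topo,
                        other).total
        for g in geoms])
    e_res = profile.energies - e_other

    a = fourier_design_matrix(profile.angles_deg, order)
    coeffs, *_ = np.linalg.lstsq(a, e_res, rcond=None)
    rms = float(np.sqrt(np.mean((a @ coeffs - e_res) ** 2)))
    return coeffs, rms


def _flexible_index(topo: Topology, profile: TorsionProfile,
                    dihedral) -> int:
    if isinstance(dihedral, int):
        return dihedral
    want = tuple(dihedral) if dihedral is not None else tuple(profile.dihedral)
    for i, f in enumerate(topo.flexible_dihedrals):
        if f.indices == want or f.indices == want[::-1]:
            return i
    raise ParameterError(f"dihedral {want} is not flagged flexible")


def symmetrize_profile(profile: TorsionProfile,
                       axis_degrees: float) -> TorsionProfile:
    """Mirror a one-sided profile about an axis; overlapping points are
    averaged and the output grid is sorted."""
    if profile.n_points == 0:
        raise StructureError("cannot symmetrize an empty profile")
    pts: dict[float, list[float]] = {}
    for a, e in zip(profile.angles_deg, profile.energies):
        pts.setdefault(round(float(a), 9), []).append(float(e))
        pts.setdefault(round(2.0 * axis_degrees - float(a), 9), []).append(
            float(e))
    grid = np.array(sorted(pts))
    energies = np.array([np.mean(pts[a]) for a in grid])
    # mirrored geometries are not available; downstream import fits need
    # only (angle, energy) pairs
    return TorsionProfile(profile.dihedral, grid, energies, profile.label)


def import_highlevel_torsion(table: TorsionProfile, order: int = 6
                             ) -> np.ndarray:
    """Fit Fourier coefficients directly to a high-level torsional table.

    Unlike the FIRA fit, the table *replaces* the description of this
    coordinate: no force-field energy is subtracted, and the resulting
    coefficients should be assigned to the dihedral before all remaining
    terms are fitted (the dihedral is then excluded from later fits).

    The table must cover [0, 180] degrees at a spacing of at most 15
    degrees (symmetrize first if only one half was sampled).
    """
    ang = table.angles_deg
    if ang.min() > 1e-9 or ang.max() < 180.0 - 1e-9:
        raise ParameterError(
            f"table covers [{ang.min()}, {ang.max()}] deg; need [0, 180]")
    if np.max(np.diff(ang)) > 15.0 + 1e-9:
        raise ParameterError("table spacing exceeds 15 degrees")
    if order >= table.n_points:
        raise ParameterError("Fourier order too high for the table size")
    a = fourier_design_matrix(ang, order)
    coeffs, *_ = np.linalg.lstsq(a, table.energies, rcond=None)
    return coeffs


def build_clockwise_restraint(dihedral: tuple[int, int, int, int],
                              wall_angle_degrees: float = 0.0,
                              k_wall: float = 100.0) -> DihedralWall:
    """One-sided harmonic wall permitting clockwise rotation only.

    The cosine torsional series is even in the dihedral, so a trajectory
    leaving the Franck-Condon region could rotate either way; the wall
    penalizes angles below ``wall_angle_degrees`` (default 0) so the
    isomerization proceeds through [0, 180] only.
    """
    return DihedralWall(indices=tuple(dihedral),
                        wall_degrees=wall_angle_degrees, k_wall=k_wall)


def validate_frequencies(fitted_ff: ForceFieldParameters,
                         bundle: QMDescriptorBundle, topo: Topology,
                         zero_tol_cm: float = 1.0) -> pd.DataFrame:
    """Compare harmonic frequencies of the fitted FF (at its own minimum)
    with those of the reference Hessian (at the bundle geometry)."""
    masses = topo.masses
    ref_freqs, _ = normal_modes(bundle.hessian, masses, bundle.geometry)
    pos = minimize_geometry(bundle.geometry, topo, fitted_ff)
    cfg = SystemConfiguration(pos, np.zeros_like(pos))
    fit_freqs, _ = normal_modes(ff_hessian(cfg, topo, fitted_ff), masses, pos)

    ref = np.sort(ref_freqs[np.abs(ref_freqs) > zero_tol_cm])
    fit = np.sort(fit_freqs[np.abs(fit_freqs) > zero_tol_cm])
    if ref.size != fit.size:
        raise StructureError(
            f"mode-count mismatch: reference {ref.size}, fitted {fit.size}")
    return pd.DataFrame({
        "reference_cm": ref,
        "fitted_cm": fit,
        "abs_dev_cm": np.abs(fit - ref),
        "rel_dev": np.abs(fit - ref) / np.abs(ref),
    })


def fit_state(bundle: QMDescriptorBundle, topo: Topology, state: str,
              order: int = 6, lj_epsilon=None, lj_sigma=None,
              highlevel_tables: dict[str, TorsionProfile] | None = None,
              wall: DihedralWall | None = None,
              ) -> tuple[ForceFieldParameters, FitReport]:
    """Full two-step parameterization of one electronic state.

    1. provisional harmonic fit to the Hessian;
    2. flexible torsions: high-level import where a table is supplied,
       FIRA residual fit otherwise;
    3. final harmonic refit with the flexible contribution subtracted.
    """
    highlevel_tables = highlevel_tables or {}
    provisional, _ = fit_harmonic_parameters(
        bundle, topo, state=state, lj_epsilon=lj_epsilon, lj_sigma=lj_sigma)

    nf = len(topo.flexible_dihedrals)
    fourier = np.zeros((nf, order + 1)) if nf else np.zeros((0, 1))
    imported: set[int] = set()
    for i, f in enumerate(topo.flexible_dihedrals):
        if f.label in highlevel_tables:
            fourier[i] = import_highlevel_torsion(highlevel_tables[f.label],
                                                  order)
            imported.add(i)
    profiles = {p.label: p for p in bundle.profiles}
    for i, f in enumerate(topo.flexible_dihedrals):
        if i in imported:
            continue
        if f.label not in profiles:
            raise StructureError(
                f"no relaxed scan for flexible dihedral {f.label!r}")
        coeffs, _ = fit_torsional_fourier(profiles[f.label], topo,
                                          provisional, dihedral=i,
                                          order=order)
        fourier[i] = coeffs

    flexible = provisional.copy()
    flexible.fourier = fourier
    flexible.wall = wall
    fitted, report = fit_harmonic_parameters(
        bundle, topo, flexible_ff=flexible, state=state,
        lj_epsilon=lj_epsilon, lj_sigma=lj_sigma)
    report.metadata["imported_torsions"] = sorted(
        topo.flexible_dihedrals[i].label for i in imported)
    return fitted, report
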