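# Methods

`qmdff` implements, at desk scale, the full workflow behind state-specific
quantum-derived force fields (QMD-FFs) for photoswitchable chromophores:
fitting classical potentials to quantum-mechanical descriptors of a single
molecule and electronic state, mimicking vertical photoexcitation by an
instantaneous force-field switch in a swarm of non-equilibrium MD
trajectories, and quantifying the subsequent solvent reorganization through
time-windowed radial distribution functions and ensemble-averaged spectra.
Electronic-structure calculations are out of scope; their role is played by
analytic *teacher* potentials with known parameters, so every stage of the
pipeline can be validated by exact parameter recovery.

## Potential-energy model

One `ForceFieldParameters` object holds one electronic state:

- bonds and angles, `V = 1/2 k (x - x0)^2` (GROMACS convention — note the
  factor 1/2; force constants in kJ mol⁻¹ nm⁻² / kJ mol⁻¹ rad⁻²);
- stiff dihedrals, harmonic in the deviation wrapped to (−180°, 180°];
- flexible dihedrals, a cosine series `V(δ) = Σ_j c_j cos(jδ)`, order 6 by
  default (configurable) — `B sin²δ` is the special case
  `c0 = B/2, c2 = −B/2`;
- 12-6 Lennard-Jones (per-atom ε, σ; Lorentz–Berthelot combination) plus
  Coulomb point charges with prefactor f = 138.935458 kJ mol⁻¹ nm e⁻²;
- optionally a one-sided harmonic dihedral wall (below) and explicit
  intramolecular LJ pairs used to couple selected rotors.

Units follow the GROMACS convention throughout (nm, ps, amu, kJ/mol, e;
degrees at public interfaces, radians internally), which makes the unit
system closed: 1 amu nm² ps⁻² = 1 kJ/mol.

**Exclusions.** Two policies exist. `graph14` (general default): 1-2 and
1-3 neighbours excluded, 1-4 pairs scaled (default 0.5/0.5 for LJ/Coulomb,
configurable), all more distant intramolecular pairs full. `pairs_only`:
all intramolecular nonbonded interactions dropped except an explicit pair
list. The synthetic teachers use `pairs_only` with an empty list so that
their constructed geometry is an exact minimum of the bonded terms — the
property that makes noise-free parameter recovery exact rather than
approximate.

**Nonbonded truncation.** Spherical cutoff (default 1.2 nm) with the
minimum-image convention in a cubic box. Energy evaluation defaults to
plain truncation; dynamics default to an infinite-dielectric reaction-field
Coulomb form (potential *and* force continuous at the cutoff) and
potential-shifted LJ. Plain truncation of water–water electrostatics makes
microcanonical energy conservation impossible at any time step — pairs
crossing the cutoff carry tens of kJ/mol — so the conserving treatment is
the integrator's default while the bare evaluator stays faithful to the
simplest convention. No Ewald/PME is provided; at the box sizes used here
(1–2.6 nm) a reaction field is the strongest affordable treatment, and only
mean solvation structure, not long-range dielectric response, enters the
analyses.

**Neighbour handling.** The force kernel iterates a precomputed full pair
list (all intermolecular pairs plus scaled intramolecular ones) and applies
the cutoff per evaluation. At the package's design sizes (≤ ~700 atoms) a
cell or Verlet list does not pay for its bookkeeping; the kernel is
compiled with numba (fastmath off, so trajectories are bit-reproducible for
a given seed on one platform).

## The synthetic teachers

The teacher chromophore is a 12-atom planar conjugated toy carrying the
photochemically relevant functional groups of a curcuminoid-like dye: a
hydroxyl donor (Oh–Ho), a carbonyl acceptor (C2=O2), one flexible aryl
torsion (`delta3`) and one isomerizable double-bond torsion (`delta4`).
Geometry is built from internal coordinates (all torsions trans), and all
equilibrium bond lengths, angles and dihedral phases are *measured* from
that geometry, so it is the exact global minimum by construction. Seven
stiff dihedrals restrain planarity; with six, one collective out-of-plane
combination had zero curvature (9 out-of-plane internal coordinates need 9
independent restraining terms; the two flexible torsions supply two).

Preset torsional potentials (barriers exact by construction, asserted at
build time):

| preset | `delta3` (aryl) | `delta4` (isomerizable) |
|---|---|---|
| CYC_S0 | 23 sin²δ | 60 sin²δ |
| PYR_S0 | 19 sin²δ | 60 sin²δ |
| CYC_S1 | 23 sin²δ | 42 sin²δ |
| PYR_S1 | 19 sin²δ | c0 + c2 cos 2δ + c4 cos 4δ |

The PYR_S1 coefficients are solved in closed form from three constraints:
V(180°) = 0, V(90°) = −20 kJ/mol (the conical-intersection funnel depth, a
free modeling choice — any negative value preserving the barrier would do)
and a local barrier of 7 kJ/mol above the trans minimum; this gives
c2 = 10, c4 = (−17 − √189)/4 ≈ −7.687, c0 = −c2 − c4. The ground-state
`delta4` barrier (60 kJ/mol) is a stand-in for a stiff double bond; no
printed value constrains it.

Per-state charges: the carbonyl oxygen carries −0.71 e (S0) / −0.63 e (S1)
for CYC-like and −0.74 e / −0.66 e for PYR-like presets; the compensating
shift sits on the bonded carbonyl carbon so the molecular charge is
state-independent. The excited state also slightly weakens the C2=O2 and
Cv=Cw force constants and lengthens those bonds — enough to give the
vertical gap a configuration dependence without moving the minimum off the
harmonic-consistency manifold.

Solvents are flexible 3-site models (stiff harmonic bonds/angles, no
constraints — hence the 0.1 fs reference time step): TIP3P-charge water
(O −0.834 e), an ethanol-like protic liquid with a united ethyl site
(heavier and slower than water), and an acetonitrile-like aprotic liquid
with a negative nitrogen site and a linear (θ0 = 180°) angle. Number
densities 33.37 / 10.3 / 11.5 nm⁻³. Boxes are built by placing molecules
on a jittered grid at the liquid density, skipping sites clashing with the
solute, and relaxing through the staged protocol.

**What the teachers do not emulate:** real electronic structure (charges
beyond the four preset carbonyl-oxygen values, real geometries,
polarization), Hessian anharmonicity away from the minimum, coupling
between internal rotors (unless explicit LJ pairs are supplied), and
production-scale boxes of a thousand solvent molecules. Passing tests
therefore demonstrate correctness of the *pipeline* — fitting, switching,
propagation, analysis — not chemical accuracy for any real dye.

## Descriptor generation

`generate_hessian` minimizes the isolated chromophore (L-BFGS followed by
Newton polishing on the analytic-force Hessian; gradient RMS < 1e-6
kJ mol⁻¹ nm⁻¹) and differentiates analytic forces centrally (step 1e-5 nm,
symmetrized). `relaxed_scan` freezes the scanned dihedral *exactly*: the
far-side subtree is rigidly rotated onto each grid point, SLSQP minimizes
subject to an equality constraint on the dihedral, and the subtree is
re-rotated onto the target afterwards (second-order energy cost). For the
tree-topology teachers every other internal coordinate stays at
equilibrium, so scans reproduce the teacher torsional potentials to ~1e-14
— the property behind the exact barrier-preservation results.
`add_descriptor_noise` adds seeded Gaussian noise to Hessian elements
(re-symmetrized) and scan energies for robustness studies.

## Fitting

**Harmonic step.** Equilibrium values are fixed to the coordinates measured
at the reference geometry; all force constants then enter the force-field
Hessian linearly, so they solve one bounded (k ≥ 0) linear least squares
over all 3N×3N Cartesian Hessian elements, unit weights. The design matrix
holds one centrally-differenced Hessian per unit-force-constant term —
because forces are linear in each k, these columns are exact to the same
stencil as the reference, and noise-free recovery is limited only by
round-off (observed ~1e-12 relative). The fit standard deviation is
√(Σr²/M) over the M = (3N)² elements, in Hessian units; rank deficiency is
reported with the null-space terms named. Weighted or internal-coordinate
objectives are deliberately not implemented: the Cartesian form is
reproducible without internal-coordinate machinery, and the synthetic
validation is insensitive to the choice.

**Flexible torsions (FIRA).** For each scan point the energy of the whole
partial force field *except* the fitted torsion is evaluated at the actual
scan geometry and subtracted from the reference energy; the residual is fit
with the cosine basis by ordinary least squares (c0 absorbs the arbitrary
energy origin). `fit_state` runs harmonic → torsions → harmonic-refit; the
second harmonic pass subtracts the now-known flexible contribution from the
reference Hessian, which closes the two-step loop exactly. For the
teachers, scan geometries keep all stiff coordinates at equilibrium, so
torsion-first and harmonic-first orderings give identical parameters (a
tested invariant).

**High-level import.** A torsion whose reference level fails near a conical
intersection is instead fit directly to a tabulated profile (≤ 15° spacing
covering [0°, 180°], optionally after mirroring a one-sided scan about
90°); the resulting coefficients are assigned up front and that dihedral is
excluded from later fits.

**Clockwise wall.** The cosine series is even in δ, so a trajectory leaving
the Franck–Condon region could rotate either way; the optional one-sided
wall `V = 1/2 k (δ − δwall)²` for wrapped δ < δwall (default wall at 0°)
restricts isomerization to the [0°, 180°] branch. Because the wrapped
difference jumps at ±180°, the wall is meant for torsions prepared inside
(0°, 180°) and is off by default in swarm runs (the 42 kJ/mol CYC barrier
confines trajectories by itself).

## Dynamics

Velocity Verlet, no constraints. Temperature: stochastic velocity
rescaling (canonical sampling through velocity rescaling): the kinetic
energy follows the exact one-step update with an exponential memory e^(−dt/τ)
and Wiener noise, applied as a single scaling factor every coupling
interval (default 10 steps); verified unbiased against the canonical
kinetic-energy distribution. Pressure: isotropic weak-coupling barostat
(scaling factor clamped to ±2% per update, box never pushed below twice the
cutoff). This is a functional stand-in for an extended-Lagrangian barostat:
downstream analyses consume mean density only, not cell-fluctuation
statistics. Center-of-mass motion is removed every 100 steps. Positions
are propagated unwrapped; minimum image handles periodicity, and wrapping
is applied only on export.

The staged equilibration protocol mirrors the reference workflow: (1) 
solvent relaxation with the solute position-restrained (k = 1000
kJ mol⁻¹ nm⁻²), (2) NVT, (3) NPT, (4) NPT production with velocities saved
at every frame. Desk-scale default durations are 1 / 10 / 50 / 500 ps (the
reference protocol used 1 ps / 1 ns / 5 ns / 50 ns); the test suite runs a
further-shortened 0.2 / 1 / 2 / 30 ps profile on a 32-water box at 0.5 fs,
sizes chosen so the full pipeline stays interactive on one CPU while
leaving >100 solvent-relaxation times of production sampling.
Equilibrium snapshots are drawn at uniform spacing counting back from the
last frame (the decorrelation criterion is uniform spacing; `n = 1` returns
the final frame).

## Force-field switch and swarms

`switch_state` implements vertical excitation in the Franck–Condon spirit:
positions and velocities are kept bit-identical while the chromophore's
intramolecular terms and charges change to the S1 set; solvent parameters
must be identical across states (validated). Swarm members propagate
independently on the S1 surface (own seed and integrator state; results are
independent of execution order; a member that blows up is recorded without
aborting the rest). The default frame schedule resolves both fast and slow
solvent response: every 5 fs below 2 ps, every 1 ps below 100 ps, every
10 ps beyond. Thermostat and barostat stay active after the switch (NPT),
with NVT available by flag. Desk-scale default: 100 members × 10 ps; the
production-scale profile (500 × 20 ns) is configurable but not exercised by
tests.

## Analysis

**Time-windowed RDFs.** Frames from all members are pooled per closed-open
time window; g(r) is normalized by shell volume 4πr²Δr, pooled frame
count, reference-site count and the mean instantaneous partner density
(per-frame box volume, so NPT runs normalize correctly). Self-pairs of
overlapping selections are excluded and the density uses the partner count
each reference actually sees. Raw pair counts and per-frame squared counts
are kept; standard errors come from the frame-to-frame scatter (Poisson SE
underestimates the correlated fluctuations of distance histograms — the
ideal-gas 3σ coverage test showed this directly — with Poisson as the
single-frame fallback). Defaults: bin width 0.01 nm, r_max = min(box/2,
1.0 nm); windows are configurable, with a dense-early default mirroring the
frame schedule.

**Relaxation time.** The observable is the 3-point-smoothed peak height of
g(r) inside a stated radial window. The long-time reference h∞ is the mean
over the final 10% of windows; τ is the left edge of the earliest window
after which every *later, non-reference* window stays within ε·|h(0) − h∞|
of h∞ (ε = 0.2 default). Excluding the reference tail from the search is
what makes a monotone (unconverged) series report "not converged" rather
than trivially converging at its own reference. A response smaller than
the per-bin noise floor reports τ at the first window edge with
`detectable=False`. For a clean exponential the estimator returns
τ ≈ τ0 ln(1/ε) to within one window width (tested).

**Shell extraction.** Whole solvent molecules are selected if any atom lies
within 0.4 nm of the solute center of mass or within 0.25 nm of a named
donor/acceptor site (default Oh, Ho, O2 — the toy has no second ether-type
acceptor), and exported with the solute as XYZ for downstream vertical
excitation calculations.

## Spectra

The classical ensemble average of vertical energies sums one broadened line
per transition over all snapshots and divides by the snapshot count
(duplication-invariant by construction). The pseudo-Voigt profile is
(1−η)·G + η·L with unit-area components sharing one HWHM; the default
display choice is η = 0.25, HWHM = 0.15 eV, with pure Gaussian and pure
Lorentzian as special cases (η = 0 reproduces the Gaussian path
bit-for-bit). Both conventions reported for the reference spectra —
pseudo-Voigt 75/25 and pure Gaussian HWHM 0.15 eV — are therefore
available; pseudo-Voigt is the default and the discrepancy between the two
statements is surfaced here rather than resolved. Broadening happens on
the energy axis; the wavelength view is λ = 1239.84198/E with an optional
cosmetic shift in nm recorded in metadata and never applied to the energy
axis (no Jacobian reweighting by default). Mock vertical transitions for
the teachers use ΔE = E_S1 − E_S0 + offset (default 3.2 eV) and a bright
planar π-π* oscillator-strength model f = f0 cos²δ4 that darkens toward
the conical-intersection geometry.

## Numerical choices and degenerate inputs

- Dihedral sign convention: IUPAC, cis = 0°, range (−180°, 180°] with the
  trans seam mapped to +180°; collinear triples raise a degenerate-geometry
  error (a stiff dihedral that is collinear at the fit reference is instead
  reported as unidentifiable by the least squares).
- Angle forces guard sin θ < 1e-8 (relevant for the linear
  acetonitrile-like angle at θ0 = 180°, where the analytic force vanishes).
- Hessians: central differences of analytic forces, step 1e-5 nm,
  symmetrized as (H + Hᵀ)/2; normal modes mass-weighted with translations
  (and rotations, when a geometry is supplied) projected out through a
  rank-revealing orthonormal basis, so linear molecules lose only five
  external modes; negative eigenvalues are reported as negative
  wavenumbers.
- Exact atom overlap raises an integration-blowup error naming the time
  (converted from the kernel's division error); non-finite forces name the
  offending atom.
- Thermostatting a zero-kinetic-energy state is an error; the τ → ∞ limit
  of the rescaling factor is 1.

## Known limitations

- The mass-ordering of solvation relaxation times (heavier solvent →
  slower response) is below the noise floor of the ε-band estimator at
  desk-scale swarm sizes: the teacher water's first-shell response
  completes in under 0.2 ps, and the peak-height noise of ~0.025-ps
  windows at ≤ 100 members exceeds the mass effect. Resolving it needs
  swarms of several hundred members. The directional response to the
  excited-state charge shift, by contrast, is a large effect and is
  asserted on ensemble averages.

- No Ewald summation, bond constraints, anisotropic cells or replica
  methods; accuracy statements are confined to the desk-scale synthetic
  systems.
- The one-sided dihedral wall is discontinuous across the ±180° seam (see
  above); it is not enabled in any default protocol.
- The weak-coupling barostat does not sample the isobaric ensemble's volume
  fluctuations; densities equilibrate correctly but compressibility
  estimates from volume variance would be biased.
- Fit quality metrics (standard deviation in Hessian units) are comparable
  between runs of this package but not directly to figures fitted in
  internal coordinates or with non-uniform weights.
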