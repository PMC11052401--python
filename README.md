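# qmdff

State-specific quantum-derived force fields, excited-state force-field
switching, and solvation-relaxation analysis — a desk-scale, fully tested
implementation of the QMD-FF photochemistry workflow.

## The problem

Photoswitchable chromophores (curcuminoid-like dyes and their biomimetic
analogues) isomerize on an excited-state surface whose shape — and whose
coupling to the surrounding solvent — decides the photoreaction's speed and
efficiency. Modeling this with classical MD needs *two* force fields for
the same molecule: one fitted to ground-state (S0) quantum-mechanical
descriptors and one to the bright π-π* excited state (S1), differing in
bonded terms, in the torsional profile of the isomerizable double bond, and
in the partial charges of the carbonyl acceptor. Photoexcitation is then
mimicked by an instantaneous Franck–Condon switch: keep every position and
velocity, swap the chromophore's potential from S0 to S1, and watch a swarm
of independent non-equilibrium trajectories relax the solvent around the
new charge distribution.

`qmdff` implements this whole workflow for users who want to study,
validate or teach the method itself:

- **`qmdff.forcefield`** — the potential model (harmonic bonds/angles/stiff
  dihedrals, cosine-series flexible torsions `V(δ) = Σ c_j cos jδ`, LJ +
  Coulomb with cutoff and minimum image), analytic forces, Hessians and
  normal modes; numba-compiled kernels.
- **`qmdff.teachers`** — synthetic *teacher* systems standing in for the
  electronic-structure layer: a 12-atom planar chromophore with hydroxyl
  donor, carbonyl acceptor, an aryl torsion (23 or 19 kJ/mol barrier) and
  an isomerizable torsion (S1 barrier 42 kJ/mol for the CYC-like preset,
  7 kJ/mol with a −20 kJ/mol conical-intersection funnel for the PYR-like
  one); per-state carbonyl charges (−0.71 → −0.63 e, −0.74 → −0.66 e);
  water / ethanol-like / acetonitrile-like 3-site solvents; generation of
  optimized geometries, Hessians and relaxed torsional scans.
- **`qmdff.fitting`** — Hessian-first harmonic least squares, FIRA residual
  fits for flexible torsions, symmetrization and high-level torsion import,
  clockwise-rotation restraints, frequency validation.
- **`qmdff.md`** — velocity Verlet, canonical velocity-rescaling
  thermostat, weak-coupling barostat, the staged
  restrained → NVT → NPT → production protocol, uncorrelated snapshot
  sampling.
- **`qmdff.swarm`** — the S0 → S1 force-field switch and swarms of
  independent non-equilibrium trajectories aligned at t = 0.
- **`qmdff.analysis`** — time-windowed swarm-averaged radial distribution
  functions with per-bin errors, coordination numbers, 3-point smoothing,
  dihedral populations, relaxation-time estimates, explicit solvent-shell
  extraction.
- **`qmdff.spectra`** — ensemble-averaged absorption spectra from vertical
  transitions (CEA-VE) with pseudo-Voigt (75% Gaussian / 25% Lorentzian)
  or pure Gaussian broadening.

Because the teachers have *known* parameters, every stage is falsifiable:
fitting their descriptors must return their parameters exactly, and the
printed torsional barriers must survive the scan → fit pipeline unchanged.

## Worked example

Fit the excited-state force field of the CYC-like preset from synthetic
descriptors, check the fit, and measure the isomerization barrier of the
fitted torsion:

```python
import numpy as np
from qmdff.teachers import build_teacher_system, generate_descriptor_bundle
from qmdff.fitting import fit_state
from qmdff.profiles import fourier_eval

teacher, _ = build_teacher_system("CYC_S1")
topo = teacher.solute_topology()
bundle = generate_descriptor_bundle(teacher, "S1")   # geometry + Hessian
                                                     # + 15-degree scans
ref = teacher.solute_ff("S1")
fitted, report = fit_state(bundle, topo, "S1",
                           lj_epsilon=ref.lj_epsilon,
                           lj_sigma=ref.lj_sigma)
print(f"fit standard deviation: {report.std_dev:.2e} (Hessian units)")

delta = np.linspace(0.0, 180.0, 18001)
v = fourier_eval(fitted.fourier[1], delta)           # isomerizable torsion
print(f"fitted S1 isomerization barrier: {v.max() - v[-1]:.3f} kJ/mol")
```

prints

```
fit standard deviation: 5.69e-09 (Hessian units)
fitted S1 isomerization barrier: 42.000 kJ/mol
```

— noise-free descriptors are reproduced to numerical precision, and the
42 kJ/mol barrier separating the Franck–Condon region from the
conical-intersection geometry is preserved exactly through the pipeline.
The same objects feed the dynamics layer: equilibrate the solvated S0
system (`qmdff.md.run_equilibrium_protocol`), draw uncorrelated snapshots,
switch to S1 (`qmdff.swarm.run_swarm`) and compare the carbonyl–water
first-shell RDF across time windows (`qmdff.analysis.time_windowed_rdf`) —
the weakened S1 carbonyl charge visibly depletes the hydrogen-bonded first
shell within a few picoseconds.

A `qmdff` console script exposes the file-oriented stages
(`qmdff descriptors`, `qmdff fit`, `qmdff scan`, `qmdff spectrum`); run any
of them with `--help`.

## Documentation

`docs/methods.md` describes the potential model and its conventions, the
teacher systems and what they do and do not emulate, the fitting
machinery, the integrator and coupling schemes, the analysis estimators,
and the package's numerical choices and known limitations.
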