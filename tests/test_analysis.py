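"""RDFs, smoothing, dihedral populations, relaxation estimation and shell
extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qmdff.analysis import (dihedral_population,
                            equilibrium_rdf, estimate_relaxation_time,
                            extract_solvent_shell, shell_peak_metrics,
                            smooth_running_average, time_windowed_rdf,
                            TimeResolvedRDF)
from qmdff.errors import ParameterError, StructureError
from qmdff.forcefield import SystemConfiguration
from qmdff.md import Trajectory
from qmdff.topology import Atom, Topology


def ideal_gas_traj(n=200, box=3.0, n_frames=40, seed=0):
    """Noninteracting points placed uniformly: g(r) = 1 by construction."""
    rng = np.random.default_rng(seed)
    atoms = [Atom("X", "Ar", 40.0, molecule=i, role="solvent")
             for i in range(n)]
    topo = Topology(atoms=atoms)
    frames = [SystemConfiguration(rng.uniform(0, box, (n, 3)),
                                  np.zeros((n, 3)), box=box, time=float(t))
              for t in range(n_frames)]
    return topo, Trajectory(frames=frames,
                            times=np.arange(n_frames, dtype=float))


class TestTimeWindowedRDF:
    def test_ideal_gas_is_uniform(self):
        topo, traj = ideal_gas_traj()
        rdf = time_windowed_rdf(traj, topo, "X", "X",
                                windows=[(0.0, 100.0)], r_max=1.4,
                                bin_width=0.02)
        se = rdf.standard_error()[0]
        inner = slice(3, None)      # skip near-empty innermost bins
        dev = np.abs(rdf.g[0][inner] - 1.0)
        assert (dev <= 3.0 * se[inner]).mean() > 0.98
        assert abs(rdf.g[0][inner].mean() - 1.0) < 0.01

    def test_single_window_equals_equilibrium_rdf(self, equilibrated_cyc):
        teacher, _, traj = equilibrated_cyc
        topo = teacher.topology
        win = time_windowed_rdf(traj, topo, "O2", "Hw",
                                windows=[(-1e30, 1e30)], r_max=0.5)
        eq = equilibrium_rdf(traj, topo, "O2", "Hw", r_max=0.5)
        assert np.array_equal(win.counts, eq.counts)
        assert np.allclose(win.g, eq.g)

    def test_pooling_two_sources_matches_joint(self, equilibrated_cyc):
        teacher, _, traj = equilibrated_cyc
        topo = teacher.topology
        half = len(traj.frames) // 2
        t_a = Trajectory(frames=traj.frames[:half], times=traj.times[:half])
        t_b = Trajectory(frames=traj.frames[half:], times=traj.times[half:])
        joint = time_windowed_rdf(traj, topo, "O2", "Hw",
                                  windows=[(-1e30, 1e30)], r_max=0.5)
        pooled = time_windowed_rdf([t_a, t_b], topo, "O2", "Hw",
                                   windows=[(-1e30, 1e30)], r_max=0.5)
        assert np.array_equal(joint.counts, pooled.counts)

    def test_normalization_recovers_pair_count(self):
        # integral of g(r) rho 4 pi r^2 dr over the probed range equals the
        # mean number of partners found there
        topo, traj = ideal_gas_traj(n=150, box=3.0)
        rdf = time_windowed_rdf(traj, topo, "X", "X",
                                windows=[(0.0, 100.0)], r_max=1.4,
                                bin_width=0.02)
        rho = rdf.mean_density_b[0]
        shell = 4 * np.pi * rdf.r_centers ** 2 * 0.02
        integral = (rdf.g[0] * rho * shell).sum()
        direct = rdf.counts[0].sum() / (rdf.n_frames[0] * rdf.n_a)
        assert integral == pytest.approx(direct, rel=1e-9)
        # and the uniform-gas expectation within a few percent
        assert integral == pytest.approx(rho * 4 / 3 * np.pi * 1.4 ** 3,
                                         rel=0.05)

    def test_doubling_frames_shrinks_error_as_sqrt(self):
        topo, traj = ideal_gas_traj(n=150, box=3.0, n_frames=80, seed=9)
        half = Trajectory(frames=traj.frames[:40], times=traj.times[:40])
        se_half = time_windowed_rdf(half, topo, "X", "X",
                                    windows=[(0.0, 1e3)], r_max=1.4,
                                    bin_width=0.05).standard_error()[0]
        se_full = time_windowed_rdf(traj, topo, "X", "X",
                                    windows=[(0.0, 1e3)], r_max=1.4,
                                    bin_width=0.05).standard_error()[0]
        outer = slice(5, None)
        ratio = np.nanmedian(se_half[outer] / se_full[outer])
        assert ratio == pytest.approx(np.sqrt(2.0), rel=0.2)

    def test_r_max_beyond_half_box_rejected(self):
        topo, traj = ideal_gas_traj(n=20, box=2.0, n_frames=2)
        with pytest.raises(ParameterError):
            time_windowed_rdf(traj, topo, "X", "X", windows=[(0.0, 10.0)],
                              r_max=1.5)

    def test_empty_window_flagged_not_fatal(self):
        topo, traj = ideal_gas_traj(n=20, n_frames=4)
        rdf = time_windowed_rdf(traj, topo, "X", "X",
                                windows=[(0.0, 4.0), (50.0, 60.0)],
                                r_max=1.4)
        assert rdf.n_frames[1] == 0
        assert np.all(rdf.g[1] == 0.0)

    def test_matches_mdanalysis_oracle(self, equilibrated_cyc):
        mda = pytest.importorskip("MDAnalysis")
        from MDAnalysis.analysis.rdf import InterRDF
        teacher, _, traj = equilibrated_cyc
        topo = teacher.topology
        ours = equilibrium_rdf(traj, topo, "O2", "Hw", r_max=0.5,
                               bin_width=0.01)
        from qmdff.io import _mda_universe
        import warnings
        sel_a = topo.atom_indices("O2")
        sel_b = topo.atom_indices("Hw")
        gs = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for frame in traj.frames:
                u = _mda_universe(topo, frame)
                a = u.atoms[sel_a]
                b = u.atoms[sel_b]
                r = InterRDF(a, b, nbins=50, range=(0.0, 5.0)).run()
                gs.append(r.results.rdf)
        ref = np.mean(gs, axis=0)
        mask = ours.counts[0] > 10
        assert np.abs(ours.g[0][mask] - ref[mask]).max() < 0.15


class TestSmoothing:
    def test_constant_series_unchanged(self):
        out = smooth_running_average(np.full(7, 2.5), 3)
        assert np.array_equal(out, np.full(7, 2.5))

    def test_truncated_end_windows(self):
        out = smooth_running_average([0.0, 3.0, 0.0], 3)
        assert list(out) == [1.5, 1.0, 1.5]

    def test_width_one_is_identity(self):
        v = np.array([4.0, -1.0, 2.0])
        assert np.array_equal(smooth_running_average(v, 1), v)

    def test_even_width_rejected(self):
        with pytest.raises(ParameterError):
            smooth_running_average([1.0, 2.0], 2)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40))
    def test_length_and_mean_preserved_for_width_ge_series(self, values):
        out = smooth_running_average(values, 3)
        assert out.size == len(values)
        assert np.min(out) >= np.min(values) - 1e-9
        assert np.max(out) <= np.max(values) + 1e-9


class TestDihedralPopulation:
    def test_frozen_dihedral_single_bin(self, equilibrated_cyc):
        teacher, _, _ = equilibrated_cyc
        from qmdff.teachers import chromophore_geometry, DELTA4
        topo = teacher.solute_topology()
        pos = chromophore_geometry()
        frames = [SystemConfiguration(pos, np.zeros_like(pos),
                                      time=float(t)) for t in range(5)]
        traj = Trajectory(frames=frames, times=np.arange(5.0))
        centers, prob = dihedral_population(traj, topo, DELTA4, 10.0)
        assert (prob > 0).sum() == 1
        assert centers[prob.argmax()] == pytest.approx(175.0)

    def test_probability_sums_to_one(self, equilibrated_cyc):
        teacher, _, traj = equilibrated_cyc
        _, prob = dihedral_population(traj, teacher.topology, "delta3", 5.0)
        assert prob.sum() == pytest.approx(1.0, abs=1e-12)

    def test_aryl_population_symmetric_about_trans(self, equilibrated_cyc):
        # the delta3 teacher potential is even about 180: the population of
        # +/- deviations from trans should agree within sampling error
        teacher, _, traj = equilibrated_cyc
        centers, prob = dihedral_population(traj, teacher.topology,
                                            "delta3", 20.0)
        below = prob[(centers > 90) & (centers < 180)].sum()
        above = prob[(centers < -90)].sum()
        assert abs(below - above) < 0.25


class TestRelaxationEstimate:
    def window_series(self, heights, width=0.1):
        n = len(heights)
        windows = [(i * width, (i + 1) * width) for i in range(n)]
        nbins = 20
        g = np.tile(np.linspace(0, 1, nbins), (n, 1))
        g = g * np.asarray(heights)[:, None]
        return TimeResolvedRDF(
            selection_a="a", selection_b="b", windows=windows,
            r_edges=np.linspace(0, 0.2, nbins + 1), g=g,
            counts=np.full((n, nbins), 4000.0),
            n_frames=np.full(n, 100), n_a=1,
            mean_density_b=np.full(n, 30.0))

    def test_flat_series_converges_at_first_window(self):
        rdf = self.window_series([2.0] * 8)
        est = estimate_relaxation_time(rdf, (0.0, 0.2), epsilon=0.2)
        assert est.converged
        assert est.tau_ps == 0.0
        # indistinguishable start and reference is flagged as no response
        assert not est.detectable

    def test_exponential_series_recovers_tau(self):
        tau0, eps, width = 0.7, 0.2, 0.05
        t = np.arange(0, 5.0, width)
        h = 3.0 + (1.0 - 3.0) * np.exp(-t / tau0)
        rdf = self.window_series(list(h), width)
        est = estimate_relaxation_time(rdf, (0.0, 0.2), epsilon=eps)
        assert est.converged and est.detectable
        expect = tau0 * np.log(1.0 / eps)
        assert abs(est.tau_ps - expect) <= width + 1e-9

    def test_monotone_series_never_converges(self):
        h = np.linspace(1.0, 5.0, 12)
        rdf = self.window_series(list(h))
        est = estimate_relaxation_time(rdf, (0.0, 0.2), epsilon=0.01)
        assert not est.converged
        assert est.tau_ps is None

    def test_too_few_windows_rejected(self):
        rdf = self.window_series([1.0, 2.0, 3.0])
        with pytest.raises(ParameterError):
            estimate_relaxation_time(rdf, (0.0, 0.2))


class TestSolventShell:
    def test_no_solvent_in_range_returns_solute_only(self, cyc_s0):
        teacher, cfg = cyc_s0
        sel = extract_solvent_shell(cfg, teacher.topology)
        assert np.array_equal(sel, teacher.topology.solute_atoms())

    def test_whole_molecule_rule_and_bruteforce_oracle(self,
                                                      equilibrated_cyc):
        teacher, _, traj = equilibrated_cyc
        topo = teacher.topology
        cfg = traj.frames[-1]
        sel = extract_solvent_shell(cfg, topo, r_com=0.4, r_sites=0.25)

        # brute-force double loop
        box = cfg.box
        def mi(d):
            return d - box * np.floor(d / box + 0.5)
        solute = topo.solute_atoms()
        masses = topo.masses
        com = (masses[solute, None] * cfg.positions[solute]).sum(axis=0) \
            / masses[solute].sum()
        sites = [i for i in solute
                 if topo.atoms[i].name in ("Oh", "Ho", "O2")]
        expect = set(int(i) for i in solute)
        for mol_atoms in topo.molecules():
            if topo.atoms[int(mol_atoms[0])].role != "solvent":
                continue
            hit = False
            for a in mol_atoms:
                if np.linalg.norm(mi(cfg.positions[a] - com)) <= 0.4:
                    hit = True
                for s in sites:
                    if np.linalg.norm(
                            mi(cfg.positions[a] - cfg.positions[s])) <= 0.25:
                        hit = True
            if hit:
                expect |= set(int(i) for i in mol_atoms)
        assert set(int(i) for i in sel) == expect
        # whole molecules only: every selected solvent molecule complete
        mol_ids = topo.molecule_ids[sel]
        for m in np.unique(mol_ids):
            assert (mol_ids == m).sum() in (3, 12)

    def test_unknown_site_rejected(self, equilibrated_cyc):
        teacher, _, traj = equilibrated_cyc
        with pytest.raises(ParameterError):
            extract_solvent_shell(traj.frames[0], teacher.topology,
                                  site_names=("Oa",))


class TestPeakMetrics:
    def test_flat_unity_has_no_peaks(self):
        r = np.linspace(0.05, 1.0, 96)
        assert shell_peak_metrics(np.ones_like(r), r) == []

    def test_two_bump_recovery(self):
        r = np.linspace(0.05, 1.0, 96)
        g = (1.0 + 1.5 * np.exp(-((r - 0.30) / 0.03) ** 2)
             + 0.6 * np.exp(-((r - 0.55) / 0.05) ** 2))
        peaks = shell_peak_metrics(g, r)
        assert len(peaks) == 2
        assert peaks[0]["r_nm"] == pytest.approx(0.30, abs=0.011)
        assert peaks[1]["r_nm"] == pytest.approx(0.55, abs=0.011)

    def test_too_few_bins_rejected(self):
        with pytest.raises(StructureError):
            shell_peak_metrics(np.array([1.0, 2.0]), np.array([0.1, 0.2]))
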