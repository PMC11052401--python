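"""Observables of solvent reorganization: time-windowed radial distribution
functions, dihedral populations, relaxation-time estimates and explicit
solvent-shell extraction.

The central object is the time-resolved RDF: frames from *all* swarm
members whose post-switch times fall inside a window are pooled, and g(r)
is normalized per window by shell volume, pooled frame count, the number
of reference sites and the mean number density of the partner sites.  Raw
pair counts are kept so Poisson standard errors can be attached per bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, StructureError
from .forcefield import SystemConfiguration, compute_dihedral
from .md import Trajectory
from .swarm import TrajectorySwarm
from .topology import Topology

__all__ = [
    "TimeResolvedRDF", "RelaxationEstimate", "time_windowed_rdf",
    "equilibrium_rdf", "smooth_running_average", "dihedral_population",
    "estimate_relaxation_time", "extract_solvent_shell",
    "shell_peak_metrics", "coordination_number",
]


@dataclass
class TimeResolvedRDF:
    """g(r) per (pair selection, time window) with raw counts."""

    selection_a: str
    selection_b: str
    windows: list[tuple[float, float]]        # ps, closed-open
    r_edges: np.ndarray                       # nm, uniform
    g: np.ndarray                             # (n_windows, n_bins)
    counts: np.ndarray                        # raw pair counts, same shape
    n_frames: np.ndarray                      # pooled frames per window
    n_a: int
    mean_density_b: np.ndarray                # per window, nm^-3
    counts_sq: np.ndarray | None = None       # sum of squared per-frame counts

    def __post_init__(self) -> None:
        widths = np.diff(self.r_edges)
        if not np.allclose(widths, widths[0]):
            raise StructureError("radial bins must be uniform")
        if (self.g < 0).any():
            raise StructureError("g(r) cannot be negative")
        for (a0, a1), (b0, b1) in zip(self.windows[:-1], self.windows[1:]):
            if b0 < a1 - 1e-9:
                raise StructureError("windows must be sorted, non-overlapping")

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    def standard_error(self) -> np.ndarray:
        """Per-bin standard error of g from the frame-to-frame scatter of
        the pair counts (falls back to Poisson when squared counts are
        unavailable or a window holds a single frame)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            poisson = np.where(self.counts > 0,
                               self.g / np.sqrt(np.maximum(self.counts, 1)),
                               np.nan)
            if self.counts_sq is None:
                return poisson
            nf = np.maximum(self.n_frames, 1)[:, None].astype(float)
            mean = self.counts / nf
            var = np.maximum(self.counts_sq / nf - mean ** 2, 0.0)
            se_counts = np.sqrt(var / nf) * nf    # SE of the pooled total
            se = np.where(self.counts > 0, self.g * se_counts
                          / np.maximum(self.counts, 1e-300), np.nan)
            one_frame = (self.n_frames <= 1)[:, None]
            return np.where(one_frame, poisson, se)


@dataclass
class RelaxationEstimate:
    observable: str
    window_times: np.ndarray        # left edges, ps
    values: np.ndarray
    reference: float                # long-time value h_inf
    tau_ps: float | None            # None => not converged
    epsilon: float
    converged: bool
    detectable: bool = True


def _iter_frames(source) -> list[tuple[float, SystemConfiguration]]:
    if isinstance(source, TrajectorySwarm):
        out = []
        for m in source.members:
            out.extend(zip(m.times, m.frames))
        return out
    if isinstance(source, Trajectory):
        return list(zip(source.times, source.frames))
    if isinstance(source, (list, tuple)):
        out = []
        for t in source:
            out.extend(_iter_frames(t))
        return out
    raise ParameterError(f"unsupported trajectory source {type(source)!r}")


def _resolve_selection(topo: Topology, sel) -> np.ndarray:
    if isinstance(sel, str):
        idx = np.array(topo.atom_indices(sel), dtype=np.int64)
    else:
        idx = np.asarray(sel, dtype=np.int64)
    if idx.size == 0:
        raise ParameterError(f"selection {sel!r} matches no atoms")
    return idx


def _min_image_distances(pa: np.ndarray, pb: np.ndarray, box: float,
                         self_mask: np.ndarray | None = None) -> np.ndarray:
    d = pb[None, :, :] - pa[:, None, :]
    if box > 0.0:
        d -= box * np.floor(d / box + 0.5)
    r = np.sqrt((d * d).sum(axis=2))
    if self_mask is not None:
        r = r[~self_mask]
    return r.reshape(-1)


def time_windowed_rdf(source, topo: Topology, selection_a, selection_b,
                      windows: list[tuple[float, float]],
                      r_max: float = 1.0, bin_width: float = 0.01
                      ) -> TimeResolvedRDF:
    """Swarm-averaged g(r) per time window.

    ``source`` may be a :class:`TrajectorySwarm`, a single
    :class:`Trajectory` or a list of either; frames from all members are
    pooled per closed-open window ``[t0, t1)``.  ``r_max`` must not exceed
    half the box.  Empty windows are kept (flagged by ``n_frames = 0``),
    not fatal.
    """
    sel_a = _resolve_selection(topo, selection_a)
    sel_b = _resolve_selection(topo, selection_b)
    frames = _iter_frames(source)
    if not frames:
        raise StructureError("no frames to analyze")

    n_bins = int(round(r_max / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    nw = len(windows)
    counts = np.zeros((nw, n_bins))
    counts_sq = np.zeros((nw, n_bins))
    nf = np.zeros(nw, dtype=np.int64)
    dens_sum = np.zeros(nw)

    # shared atoms contribute zero-distance self pairs; exclude them and
    # normalize with the partner count actually visible to each reference
    self_mask = sel_a[:, None] == sel_b[None, :]
    n_overlap = int(self_mask.sum())
    if not n_overlap:
        self_mask = None
    n_pairs_eff = sel_a.size * sel_b.size - n_overlap

    for t, cfg in frames:
        if cfg.box > 0.0 and r_max > cfg.box / 2.0 + 1e-12:
            raise ParameterError(
                f"r_max {r_max} nm exceeds half the box {cfg.box / 2.0} nm")
        w = next((i for i, (t0, t1) in enumerate(windows)
                  if t0 <= t < t1), None)
        if w is None:
            continue
        dist = _min_image_distances(cfg.positions[sel_a],
                                    cfg.positions[sel_b], cfg.box,
                                    self_mask)
        hist, _ = np.histogram(dist, bins=edges)
        counts[w] += hist
        counts_sq[w] += hist.astype(float) ** 2
        nf[w] += 1
        vol = cfg.box ** 3 if cfg.box > 0 else 4.0 / 3.0 * np.pi * r_max ** 3
        dens_sum[w] += n_pairs_eff / (sel_a.size * vol)

    shell = 4.0 * np.pi * (0.5 * (edges[:-1] + edges[1:])) ** 2 * bin_width
    g = np.zeros_like(counts)
    dens = np.zeros(nw)
    for w in range(nw):
        if nf[w] == 0:
            continue
        dens[w] = dens_sum[w] / nf[w]
        g[w] = counts[w] / (nf[w] * sel_a.size * shell * dens[w])
    return TimeResolvedRDF(
        selection_a=str(selection_a), selection_b=str(selection_b),
        windows=list(windows), r_edges=edges, g=g, counts=counts,
        n_frames=nf, n_a=int(sel_a.size), mean_density_b=dens,
        counts_sq=counts_sq)


def equilibrium_rdf(traj, topo, selection_a, selection_b,
                    r_max: float = 1.0, bin_width: float = 0.01
                    ) -> TimeResolvedRDF:
    """Standard equilibrium RDF: one window covering all frames."""
    frames = _iter_frames(traj)
    t_max = max(t for t, _ in frames)
    return time_windowed_rdf(traj, topo, selection_a, selection_b,
                             windows=[(-np.inf, t_max + 1.0)],
                             r_max=r_max, bin_width=bin_width)


def smooth_running_average(values, width: int = 3) -> np.ndarray:
    """Centered moving mean with truncated end windows; length-preserving."""
    if width < 1 or width % 2 == 0:
        raise ParameterError("smoothing width must be odd and >= 1")
    v = np.asarray(values, dtype=float)
    half = width // 2
    out = np.empty_like(v)
    for i in range(v.size):
        lo = max(0, i - half)
        hi = min(v.size, i + half + 1)
        out[i] = v[lo:hi].mean()
    return out


def dihedral_population(source, topo: Topology,
                        dihedral: tuple[int, int, int, int] | str,
                        bin_width_degrees: float = 5.0) -> tuple[np.ndarray,
                                                                 np.ndarray]:
    """Probability-normalized dihedral histogram over (-180, 180].

    Returns ``(bin_centers_deg, probability)``; probabilities sum to 1.
    """
    if isinstance(dihedral, str):
        match = [f.indices for f in topo.flexible_dihedrals
                 if f.label == dihedral]
        if not match:
            raise ParameterError(f"unknown dihedral label {dihedral!r}")
        dihedral = match[0]
    frames = _iter_frames(source)
    if not frames:
        raise StructureError("no frames to analyze")
    nbins = int(round(360.0 / bin_width_degrees))
    edges = np.linspace(-180.0, 180.0, nbins + 1)
    angles = np.array([
        compute_dihedral(cfg.positions, *dihedral, box=cfg.box)
        for _, cfg in frames])
    # map the +180 endpoint into the last bin (periodic convention)
    angles[angles >= 180.0] = 180.0 - 1e-9
    hist, _ = np.histogram(angles, bins=edges)
    prob = hist / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, prob


def estimate_relaxation_time(rdf: TimeResolvedRDF,
                             peak_window_nm: tuple[float, float],
                             epsilon: float = 0.2,
                             smooth_width: int = 3) -> RelaxationEstimate:
    """Relaxation time of a solvation-shell peak height.

    The observable is the maximum of the (3-point smoothed) g(r) inside
    ``peak_window_nm`` per time window.  The long-time reference is the
    mean over the final 10% of windows (at least one), and tau is the left
    edge of the earliest window after which the peak height stays within
    ``epsilon * |h(0) - h_inf|`` of the reference for all later windows.
    """
    if len(rdf.windows) < 4:
        raise ParameterError("need at least four time windows")
    r = rdf.r_centers
    mask = (r >= peak_window_nm[0]) & (r <= peak_window_nm[1])
    if not mask.any():
        raise ParameterError("peak window contains no bins")
    heights = np.array([
        smooth_running_average(gw, smooth_width)[mask].max()
        for gw in rdf.g])
    lefts = np.array([w[0] for w in rdf.windows])

    n_ref = max(1, len(heights) // 10)
    h_inf = float(heights[-n_ref:].mean())
    h0 = float(heights[0])
    amplitude = abs(h0 - h_inf)

    se = rdf.standard_error()
    noise = np.nanmedian(se[0]) if np.isfinite(se[0]).any() else 0.0
    if amplitude <= noise:
        # no resolvable response: already at the reference everywhere
        return RelaxationEstimate(
            observable="first-shell peak height", window_times=lefts,
            values=heights, reference=h_inf, tau_ps=float(lefts[0]),
            epsilon=epsilon, converged=True, detectable=False)

    band = epsilon * amplitude
    inside = np.abs(heights - h_inf) <= band
    tau = None
    # the reference tail itself cannot certify convergence
    for i in range(len(heights) - n_ref):
        if inside[i:].all():
            tau = float(lefts[i])
            break
    return RelaxationEstimate(
        observable="first-shell peak height", window_times=lefts,
        values=heights, reference=h_inf, tau_ps=tau, epsilon=epsilon,
        converged=tau is not None)


def coordination_number(rdf: TimeResolvedRDF, r_shell: float,
                        window: int = 0) -> float:
    """Mean number of partner atoms within ``r_shell`` of a reference site,
    from the raw pooled counts of one time window."""
    if rdf.n_frames[window] == 0:
        raise StructureError(f"window {window} holds no frames")
    mask = rdf.r_edges[1:] <= r_shell + 1e-12
    return float(rdf.counts[window][mask].sum()
                 / (rdf.n_frames[window] * rdf.n_a))


def extract_solvent_shell(config: SystemConfiguration, topo: Topology,
                          r_com: float = 0.4, r_sites: float = 0.25,
                          site_names: tuple[str, ...] = ("Oh", "Ho", "O2"),
                          ) -> np.ndarray:
    """Atom indices of the solute plus its explicit solvation shell.

    A whole solvent molecule is included if any of its atoms lies within
    ``r_com`` of the solute center of mass or within ``r_sites`` of any of
    the named solute sites (union; minimum-image distances).
    """
    solute = topo.solute_atoms()
    masses = topo.masses
    pos = config.positions
    box = config.box

    site_idx = []
    for name in site_names:
        hits = [i for i in solute if topo.atoms[i].name == name]
        if not hits:
            raise ParameterError(f"site {name!r} not found in the solute")
        site_idx.extend(hits)

    com = (masses[solute, None] * pos[solute]).sum(axis=0) \
        / masses[solute].sum()

    def mi(d):
        if box > 0.0:
            d = d - box * np.floor(d / box + 0.5)
        return d

    selected = list(solute)
    mol = topo.molecule_ids
    for m_atoms in topo.molecules():
        if topo.atoms[int(m_atoms[0])].role != "solvent":
            continue
        p = pos[m_atoms]
        near_com = np.linalg.norm(mi(p - com), axis=1).min() <= r_com
        near_site = False
        for s in site_idx:
            if np.linalg.norm(mi(p - pos[s]), axis=1).min() <= r_sites:
                near_site = True
                break
        if near_com or near_site:
            selected.extend(int(i) for i in m_atoms)
    return np.unique(np.array(selected, dtype=np.int64))


def shell_peak_metrics(g: np.ndarray, r_centers: np.ndarray,
                       threshold: float = 1.0) -> list[dict]:
    """First and second solvation-shell peaks of a smoothed g(r).

    Local maxima above ``threshold`` are located by discrete neighborhood
    comparison; up to two are returned as ``{"r_nm", "height"}`` dicts (an
    empty list means no structured shell)."""
    g = np.asarray(g, dtype=float)
    r_centers = np.asarray(r_centers, dtype=float)
    if g.size < 3:
        raise StructureError("need at least three bins for peak analysis")
    peaks = []
    for i in range(1, g.size - 1):
        if g[i] > threshold and g[i] >= g[i - 1] and g[i] > g[i + 1]:
            peaks.append({"r_nm": float(r_centers[i]),
                          "height": float(g[i])})
    return peaks[:2]
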