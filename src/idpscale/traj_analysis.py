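"""Cluster detection, density profiles, contact maps and scaling statistics.

Turns bead trajectories into the quantities the experiments measure: which
chains form one assembly, how each sequence block distributes radially about
the cluster centre of mass, which residues touch across chains, and — the
headline statistic — the apparent Flory exponent from mean inter-residue
distances at the FRET labelling positions.

Frame-to-frame correlation is accounted for through an effective sample
size: the distance autocorrelation is fitted with a stretched exponential
A exp(-(t/tau0)^beta), the integrated relaxation time
tau = (tau0/beta) Gamma(1/beta) converts n_frames into
n_eff = n_frames / tau (floored at 1 frame of relaxation), and
SEM = SD / sqrt(n_eff * n_chains).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import gamma as gamma_fn

from idpscale.cg_sim.engine import TrajectoryFrames
from idpscale.cg_sim.topology import Topology
from idpscale.polymer_fret import ScalingFit, fit_scaling

__all__ = [
    "ClusterAssignment",
    "EffectiveSampleStats",
    "PairDistanceStats",
    "DensityProfile",
    "ContactMap",
    "assign_clusters",
    "pairwise_re",
    "flory_fit",
    "density_profile",
    "contact_map",
]

AVOGADRO = 6.02214076e23
# (beads/A^3) -> mol/L
MOLAR_PER_A3 = 1e27 / AVOGADRO

CLUSTER_CUTOFF_A = 7.0
CONTACT_SCALE = 1.5


def _min_image(d: np.ndarray, box: float) -> np.ndarray:
    if box and box > 0:
        d = d - box * np.round(d / box)
    return d


@dataclass
class ClusterAssignment:
    """Per-chain cluster labels for one frame; labels are 0..k-1 by descending size."""

    labels: np.ndarray
    sizes: np.ndarray

    @property
    def n_clusters(self) -> int:
        return self.sizes.size

    def largest(self) -> np.ndarray:
        """Chain indices of the largest cluster."""
        return np.flatnonzero(self.labels == 0)


def assign_clusters(
    frame: np.ndarray,
    topology: Topology,
    box: float,
    cutoff: float = CLUSTER_CUTOFF_A,
) -> ClusterAssignment:
    """Connected components of the chain-contact graph for one frame.

    Two chains are linked when any bead pair between them is closer than
    ``cutoff`` (minimum-image).  Deterministic given coordinates.
    """
    n_res, n_chains = topology.n_res, topology.n_chains
    if n_res == 0:
        raise ValueError("topology has chains with zero beads")
    pos = np.asarray(frame, dtype=float).reshape(n_chains, n_res, 3)
    adj = np.eye(n_chains, dtype=bool)
    for a in range(n_chains):
        for b in range(a + 1, n_chains):
            d = _min_image(pos[a][:, None, :] - pos[b][None, :, :], box)
            if np.any(np.einsum("ijk,ijk->ij", d, d) < cutoff * cutoff):
                adj[a, b] = adj[b, a] = True
    from scipy.sparse.csgraph import connected_components

    n_comp, raw = connected_components(adj, directed=False)
    sizes = np.bincount(raw, minlength=n_comp)
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(n_comp, dtype=int)
    relabel[order] = np.arange(n_comp)
    labels = relabel[raw]
    return ClusterAssignment(labels=labels, sizes=sizes[order])


@dataclass
class EffectiveSampleStats:
    """Correlation-corrected sampling statistics of a per-frame observable."""

    n_frames: int
    n_chains: int
    tau_frames: float
    beta: float
    n_eff: float
    sd: float
    sem: float


def effective_sample_stats(series: np.ndarray) -> EffectiveSampleStats:
    """Stats for ``series`` of shape (n_frames, n_chains).

    The autocorrelation (averaged over chains) is fitted with a stretched
    exponential; when the relaxation time falls below one frame the frames
    are treated as independent (n_eff = n_frames).  A frame-static series
    has one effective frame, so the SEM is carried by the chains alone.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if series.ndim == 1:
        series = series[:, None]
    n_frames, n_chains = series.shape
    sd = float(series.std(ddof=1)) if series.size > 1 else 0.0

    if n_frames < 4:
        tau, beta, n_eff = float(n_frames), 1.0, 1.0
    else:
        centred = series - series.mean(axis=0, keepdims=True)
        var = np.mean(centred**2)
        if var <= 1e-30:
            tau, beta, n_eff = float(n_frames), 1.0, 1.0
        else:
            k_max = min(n_frames // 3, 500)
            lags = np.arange(1, k_max + 1)
            acf = np.array(
                [np.mean(centred[:-k] * centred[k:]) for k in lags]
            ) / var
            tau, beta = _fit_stretched_exponential(lags, acf)
            n_eff = n_frames if tau < 1.0 else float(np.clip(n_frames / tau, 1.0, n_frames))
    sem = sd / np.sqrt(n_eff * n_chains)
    return EffectiveSampleStats(
        n_frames=n_frames, n_chains=n_chains, tau_frames=float(tau),
        beta=float(beta), n_eff=float(n_eff), sd=sd, sem=float(sem),
    )


def _fit_stretched_exponential(lags: np.ndarray, acf: np.ndarray) -> tuple[float, float]:
    """Fit A exp(-(t/tau0)^beta); return integrated relaxation time and beta."""
    pos = acf > 0.02
    if pos.sum() < 3:
        return 0.5, 1.0  # decorrelated within a frame
    # Seed tau0 from the 1/e crossing
    below = np.flatnonzero(acf < np.exp(-1.0))
    tau0_seed = float(lags[below[0]]) if below.size else float(lags[-1])
    try:
        popt, _ = optimize.curve_fit(
            lambda t, a, tau0, beta: a * np.exp(-((t / tau0) ** beta)),
            lags, acf,
            p0=(max(acf[0], 0.1), max(tau0_seed, 0.5), 1.0),
            bounds=([0.0, 1e-3, 0.2], [1.5, 1e7, 2.0]),
            maxfev=10000,
        )
        a, tau0, beta = popt
    except RuntimeError:
        return float(np.clip(np.sum(np.clip(acf, 0, None)) * 2 + 1, 0.5, None)), 1.0
    tau = tau0 / beta * gamma_fn(1.0 / beta)
    return float(tau), float(beta)


@dataclass
class PairDistanceStats:
    """Mean inter-residue distance for one labelled pair."""

    pair: tuple
    n_res: int
    mean_a: float
    sem_a: float
    stats: EffectiveSampleStats = field(repr=False)

    @property
    def mean_nm(self) -> float:
        return self.mean_a / 10.0

    @property
    def sem_nm(self) -> float:
        return self.sem_a / 10.0


def pairwise_re(
    traj: TrajectoryFrames,
    topology: Topology,
    residue_pairs,
    cluster_filter: bool = False,
    cluster_cutoff: float = CLUSTER_CUTOFF_A,
    statistic: str = "mean",
) -> list[PairDistanceStats]:
    """Mean distance (A) between intrachain residue pairs, over frames x chains.

    ``residue_pairs`` are (i, j) per-chain residue indices.  With
    ``cluster_filter`` only chains inside the largest cluster of each frame
    contribute (chains outside are masked).  ``statistic`` selects the plain
    mean distance or the root-mean-square distance.
    """
    n_res, n_chains = topology.n_res, topology.n_chains
    frames = traj.coords.reshape(traj.n_frames, n_chains, n_res, 3)
    for i, j in residue_pairs:
        if not (0 <= i < n_res and 0 <= j < n_res):
            raise IndexError(f"residue pair ({i}, {j}) out of range 0..{n_res - 1}")

    mask = np.ones((traj.n_frames, n_chains), dtype=bool)
    if cluster_filter and n_chains > 1:
        for f in range(traj.n_frames):
            ca = assign_clusters(traj.coords[f], topology, traj.box, cluster_cutoff)
            mask[f] = ca.labels == 0

    out = []
    always_in = mask.all(axis=0)
    for i, j in residue_pairs:
        d = _min_image(frames[:, :, j, :] - frames[:, :, i, :], traj.box)
        r = np.sqrt(np.einsum("fck,fck->fc", d, d))
        valid = r[mask]
        if statistic == "rms":
            mean = float(np.sqrt(np.mean(valid**2)))
        else:
            mean = float(np.mean(valid))
        # correlation stats need gap-free series: use chains present in the
        # cluster throughout (all chains when no filter is applied)
        series = r[:, always_in] if always_in.any() else r
        stats = effective_sample_stats(series)
        out.append(
            PairDistanceStats(pair=(i, j), n_res=abs(j - i), mean_a=mean,
                              sem_a=stats.sem, stats=stats)
        )
    return out


def flory_fit(pair_stats: list, min_sem_nm: float = 1e-6) -> ScalingFit:
    """Scaling-law fit of mean distances vs sequence separation.

    Delegates to the shared power-law fitter with the simulation SEMs as
    weights (floored to keep weights finite for frame-static toy inputs).
    """
    n_res = [p.n_res for p in pair_stats]
    re = [p.mean_nm for p in pair_stats]
    sem = np.maximum([p.sem_nm for p in pair_stats], min_sem_nm)
    return fit_scaling(n_res, re, sigma_nm=sem)


@dataclass
class DensityProfile:
    """Radial block density about the cluster centre of mass."""

    bin_edges_a: np.ndarray
    density_mol_l: np.ndarray
    sem_mol_l: np.ndarray
    mean_counts: np.ndarray      # beads per shell per frame, before block scaling
    block_scale: float
    n_frames: int

    @property
    def bin_centres_a(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_a[:-1] + self.bin_edges_a[1:])

    def peak_radius_a(self) -> float:
        return float(self.bin_centres_a[np.argmax(self.density_mol_l)])

    def total_beads(self) -> float:
        """Shell-volume integral of the unscaled density: mean bead count."""
        return float(self.mean_counts.sum())


def _unwrap_cluster(frame, topology, chains, box):
    """Unwrap cluster chains into one periodic image via minimum-image walking."""
    n_res = topology.n_res
    pos = frame.reshape(topology.n_chains, n_res, 3)
    out = []
    anchor = None
    for c in chains:
        xyz = pos[c].copy()
        for i in range(1, n_res):
            step = _min_image(xyz[i] - xyz[i - 1], box)
            xyz[i] = xyz[i - 1] + step
        if anchor is None:
            anchor = xyz.mean(axis=0)
        else:
            com = xyz.mean(axis=0)
            shift = _min_image(com - anchor, box) - (com - anchor)
            xyz = xyz + shift
        out.append(xyz)
    return np.asarray(out)


def density_profile(
    traj: TrajectoryFrames,
    topology: Topology,
    block: str,
    bin_width_a: float = 5.0,
    r_max_a: float | None = None,
    cluster_cutoff: float = CLUSTER_CUTOFF_A,
) -> DensityProfile:
    """Radial density (mol amino acids / L) of one block about the cluster COM.

    Per frame, the largest cluster is unwrapped, its mass-weighted COM
    computed, and the block's beads histogrammed by COM distance over all
    cluster chains.  Bin counts are converted with shell volumes; the block
    profile is scaled by n_aa_chain / n_aa_block so blocks of different
    length are directly comparable.  The SEM treats frames as independent
    (the density relaxation time here is below one frame) with the usual
    1/sqrt(n_frames * n_chains) reduction.
    """
    block_ids = topology.block_indices(block, chain=0)
    if block_ids.size == 0:
        raise ValueError("empty block")
    n_res = topology.n_res
    scale = n_res / block_ids.size

    if r_max_a is None:
        r_max_a = max(confine_extent(traj, topology), 2 * bin_width_a)
    edges = np.arange(0.0, r_max_a + bin_width_a, bin_width_a)
    n_bins = edges.size - 1

    per_frame = np.zeros((traj.n_frames, n_bins))
    masses = topology.mass[: n_res]
    chains_per_frame = np.zeros(traj.n_frames)
    for f in range(traj.n_frames):
        ca = assign_clusters(traj.coords[f], topology, traj.box, cluster_cutoff)
        chains = ca.largest()
        chains_per_frame[f] = chains.size
        xyz = _unwrap_cluster(traj.coords[f], topology, chains, traj.box)
        w = np.broadcast_to(masses, xyz.shape[:2])
        com = np.einsum("cr,crk->k", w, xyz) / w.sum()
        r = np.linalg.norm(xyz[:, block_ids, :] - com, axis=-1).ravel()
        per_frame[f] = np.histogram(np.clip(r, 0, edges[-1] - 1e-9), bins=edges)[0]

    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    dens_frames = per_frame / shell_vol * MOLAR_PER_A3 * scale
    mean_chains = max(chains_per_frame.mean(), 1.0)
    sem = dens_frames.std(axis=0, ddof=1) / np.sqrt(traj.n_frames * mean_chains) \
        if traj.n_frames > 1 else np.zeros(n_bins)
    return DensityProfile(
        bin_edges_a=edges,
        density_mol_l=dens_frames.mean(axis=0),
        sem_mol_l=sem,
        mean_counts=per_frame.mean(axis=0),
        block_scale=scale,
        n_frames=traj.n_frames,
    )


def confine_extent(traj: TrajectoryFrames, topology: Topology) -> float:
    """Rough radial extent (A) of the system, used to size density histograms."""
    f0 = traj.coords[0].reshape(topology.n_chains, topology.n_res, 3)
    com = f0.mean(axis=(0, 1))
    return float(np.linalg.norm(f0 - com, axis=-1).max() * 1.5 + 10.0)


@dataclass
class ContactMap:
    """Interchain residue-residue contact probability per chain (symmetric)."""

    probability: np.ndarray
    n_frames: int
    n_chains: int


def contact_map(
    traj: TrajectoryFrames,
    topology: Topology,
    contact_scale: float = CONTACT_SCALE,
) -> ContactMap:
    """Interchain contact probabilities per residue pair.

    Beads on different chains are in contact when closer than
    ``contact_scale`` times the mean bead diameter of the pair.  Counts are
    accumulated symmetrically and divided by (mean number of chains x number
    of frames) to give contacts per chain.
    """
    n_res, n_chains = topology.n_res, topology.n_chains
    if n_chains < 2:
        raise ValueError("interchain contact map requires >= 2 chains")
    sig1 = topology.sigma[:n_res]
    thresh = contact_scale * 0.5 * (sig1[:, None] + sig1[None, :])
    thresh2 = thresh**2

    counts = np.zeros((n_res, n_res))
    for f in range(traj.n_frames):
        pos = traj.coords[f].reshape(n_chains, n_res, 3)
        for a in range(n_chains):
            for b in range(a + 1, n_chains):
                d = _min_image(pos[a][:, None, :] - pos[b][None, :, :], traj.box)
                hit = np.einsum("ijk,ijk->ij", d, d) < thresh2
                counts += hit
                counts += hit.T
    prob = counts / (n_chains * traj.n_frames)
    return ContactMap(probability=prob, n_frames=traj.n_frames, n_chains=n_chains)
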