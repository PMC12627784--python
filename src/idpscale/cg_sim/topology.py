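"""Bead topology construction, sequence property profiles and block charges."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from idpscale.cg_sim import forcefield as ff

__all__ = [
    "Topology",
    "build_topology",
    "sequence_profile",
    "block_net_charge",
]

BOND_R0_A = 3.8
BOND_K_KJ_A2 = 10.0
ELASTIC_CUTOFF_A = 12.0


@dataclass
class Topology:
    """One-bead-per-residue topology, possibly replicated over several chains.

    Bonds connect backbone neighbours (rest length 3.8 A); elastic-network
    pairs are harmonic restraints between structured-region beads with rest
    lengths taken from the input coordinates and the same rigidity.  Block
    labels (e.g. the disordered FG block vs the folded DNA-binding block)
    partition each chain by residue index.
    """

    sequence: str
    n_chains: int
    lam: np.ndarray
    sigma: np.ndarray
    charge: np.ndarray
    mass: np.ndarray
    bonds: np.ndarray          # (M, 2) int bead indices
    bond_r0: np.ndarray        # (M,) A
    elastic: np.ndarray        # (P, 2) int bead indices
    elastic_r0: np.ndarray     # (P,) A
    bond_k: float = BOND_K_KJ_A2
    blocks: dict = field(default_factory=dict)   # name -> per-chain residue indices

    @property
    def n_res(self) -> int:
        return len(self.sequence)

    @property
    def n_beads(self) -> int:
        return self.n_res * self.n_chains

    def chain_of(self, bead: int) -> int:
        return bead // self.n_res

    def chain_slice(self, chain: int) -> slice:
        return slice(chain * self.n_res, (chain + 1) * self.n_res)

    def block_indices(self, block: str, chain: int = 0) -> np.ndarray:
        if block not in self.blocks:
            raise KeyError(f"unknown block {block!r}")
        return np.asarray(self.blocks[block], dtype=int) + chain * self.n_res

    def bead_volume_a3(self) -> float:
        """Total van der Waals bead volume (A^3), used to size simulation boxes."""
        return float(np.sum(np.pi / 6.0 * self.sigma**3))


def build_topology(
    sequence: str,
    structured_coords: dict | None = None,
    blocks: dict | None = None,
    n_chains: int = 1,
    his_charge: float = 0.0,
    elastic_cutoff: float = ELASTIC_CUTOFF_A,
    bond_k: float = BOND_K_KJ_A2,
) -> Topology:
    """Build a bead topology from a sequence and optional folded-domain coordinates.

    Parameters
    ----------
    sequence : str
        One-letter amino-acid sequence of a single chain.
    structured_coords : dict, optional
        Mapping residue index (0-based) -> (x, y, z) A for every residue in a
        structured region.  All pairs of structured residues closer than
        ``elastic_cutoff`` get an elastic-network bond whose rest length is
        their input-coordinate distance.
    blocks : dict, optional
        Mapping block name -> iterable of residue indices (or (start, stop)
        half-open tuple) labelling chain segments for block-wise analyses.
    n_chains : int
        Number of identical copies; bonds and elastic pairs are replicated.
    """
    seq = str(sequence).upper()
    n = len(seq)
    lam1, sig1, q1, m1 = ff.residue_params(seq, his_charge=his_charge)

    bonds1 = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    bond_r01 = np.full(n - 1, BOND_R0_A)

    el_pairs, el_r0 = [], []
    if structured_coords:
        idx = np.array(sorted(structured_coords), dtype=int)
        if np.any(idx < 0) or np.any(idx >= n):
            raise ValueError("structured residue index out of sequence range")
        xyz = np.array([structured_coords[i] for i in idx], dtype=float)
        if xyz.shape != (idx.size, 3):
            raise ValueError("structured coordinates must be (x, y, z) per residue")
        d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
        for a in range(idx.size):
            for b in range(a + 1, idx.size):
                if d[a, b] < elastic_cutoff:
                    el_pairs.append((idx[a], idx[b]))
                    el_r0.append(d[a, b])
    elastic1 = np.asarray(el_pairs, dtype=int).reshape(-1, 2)
    el_r01 = np.asarray(el_r0, dtype=float)

    block_map: dict = {}
    if blocks:
        for name, spec in blocks.items():
            if isinstance(spec, tuple) and len(spec) == 2:
                ids = np.arange(spec[0], spec[1])
            else:
                ids = np.asarray(list(spec), dtype=int)
            if ids.size == 0:
                raise ValueError(f"block {name!r} is empty")
            if ids.min() < 0 or ids.max() >= n:
                raise ValueError(f"block {name!r} indices out of range")
            block_map[name] = ids

    def tile(arr):
        return np.tile(arr, n_chains)

    offs = np.arange(n_chains)[:, None, None] * n
    bonds = (bonds1[None, :, :] + offs).reshape(-1, 2)
    elastic = (
        (elastic1[None, :, :] + offs).reshape(-1, 2)
        if elastic1.size
        else np.zeros((0, 2), dtype=int)
    )
    return Topology(
        sequence=seq,
        n_chains=n_chains,
        lam=tile(lam1), sigma=tile(sig1), charge=tile(q1), mass=tile(m1),
        bonds=bonds, bond_r0=np.tile(bond_r01, n_chains),
        elastic=elastic, elastic_r0=np.tile(el_r01, n_chains),
        bond_k=bond_k,
        blocks=block_map,
    )


def sequence_profile(sequence: str, window: int = 25):
    """Sliding-window hydrophobicity, FCR and net-charge profile of a sequence.

    Returns ``(positions, lambda_mean, fcr, net_charge)`` where positions are
    0-based window-centre residue indices; with the default window of 25 the
    profile spans centres 12 .. L-13, so the terminal residues carry no value.
    """
    seq = str(sequence).upper()
    if len(seq) < window:
        raise ValueError(f"sequence shorter than window ({len(seq)} < {window})")
    lam, _, q, _ = ff.residue_params(seq)
    kern = np.ones(window) / window
    lam_w = np.convolve(lam, kern, mode="valid")
    fcr_w = np.convolve((q != 0).astype(float), kern, mode="valid")
    net_w = np.convolve(q, kern, mode="valid")
    positions = np.arange(lam_w.size) + (window - 1) // 2
    return positions, lam_w, fcr_w, net_w


def block_net_charge(topology: Topology, block: str) -> tuple[float, float]:
    """(total charge e, charge per residue e) of a labelled block of one chain."""
    ids = topology.block_indices(block, chain=0)
    total = float(topology.charge[ids].sum())
    return total, total / ids.size
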