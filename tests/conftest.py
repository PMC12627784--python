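"""Shared fixtures, including the session-scoped coarse-grained simulations."""

from __future__ import annotations

import numpy as np
import pytest

from idpscale import cg_sim

# NHA9-like diblock used by the simulation-based tests: an FG-repeat-rich
# hydrophobic block followed by a short, strongly positive hydrophilic block.
# Aromatic-rich hydrophobic block: a desk-scale stand-in for a long FG-repeat
# domain.  At 32 residues a natural FG-motif composition sits at its collapse
# transition and flips state between runs; the W/Y-rich block (mean lambda
# ~0.84) collapses decisively, reproducing at this length the single-chain
# compaction a ~500-residue FG domain shows at its native hydrophobicity.
FG_BLOCK = "YYWYYYYWYY" * 3 + "YW"          # 32 residues
CHARGED_BLOCK = "KRSKEKKRGK"                # 10 residues, +5e
DIBLOCK = FG_BLOCK + CHARGED_BLOCK
DIBLOCK_BLOCKS = {"fg": (0, len(FG_BLOCK)), "dbd": (len(FG_BLOCK), len(DIBLOCK))}
# several offsets per sequence separation within the FG block, for statistics
FRET_PAIRS = [(0, 8), (12, 20), (23, 31),
              (0, 16), (8, 24), (15, 31),
              (0, 24), (7, 31),
              (0, 31)]
# independent pinned copies used to sample the single-chain (dilute) state
N_SINGLE_COPIES = 6


def run_diblock_sim(n_chains: int, production_steps: int | None = None, seed: int = 0):
    """Equilibrate and run one diblock system; returns (topology, trajectory).

    ``n_chains == 1`` is sampled as several pinned, far-apart copies on a
    sparse lattice (one box, no interchain interaction) so the dilute-state
    statistics come from independent chains.  Clusters run longer (4 ns vs
    2.5 ns production) because interchain rearrangement is slower than
    single-chain relaxation.
    """
    single = n_chains == 1
    if production_steps is None:
        production_steps = 250_000 if single else 400_000
    n_copies = N_SINGLE_COPIES if single else n_chains
    topo = cg_sim.build_topology(DIBLOCK, n_chains=n_copies, blocks=DIBLOCK_BLOCKS)
    cfg = cg_sim.SimulationConfig(seed=seed)
    mode = "single" if single else "cluster"
    coords = cg_sim.equilibrate(
        topo, cfg, mode=mode, seed=seed,
        schedule={"soft": 3000, "temp_ramp": 2000, "dt_ramp": 2000, "relax": 12000},
    )
    traj = cg_sim.langevin_run(
        topo, cfg, production_steps, coords, seed=seed + 100,
        frame_interval_steps=500,
        fixed_beads=[c * topo.n_res for c in range(n_copies)] if single else None,
    )
    return topo, traj


@pytest.fixture(scope="session")
def diblock_sims():
    """Production trajectories for 1-, 5- and 10-chain diblock systems."""
    return {n: run_diblock_sim(n, seed=n) for n in (1, 5, 10)}


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (keeps tests order-independent)."""
    return np.random.default_rng(12345)
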