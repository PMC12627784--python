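"""Topology building, pair energetics, Langevin thermostat and sequence profiles."""

import numpy as np
import pytest
from scipy.integrate import quad

from idpscale import cg_sim
from idpscale.cg_sim import engine, forcefield as ff

KT = ff.KB_KJ_MOL_K * 300.0


class TestTopology:
    def test_collinear_structured_elastic_pairs(self):
        coords = {i: (3.8 * i, 0.0, 0.0) for i in range(3)}
        topo = cg_sim.build_topology("AAA", structured_coords=coords)
        pairs = {tuple(p) for p in topo.elastic}
        assert pairs == {(0, 1), (1, 2), (0, 2)}   # 7.6 A < 12 A

    def test_disordered_chain_has_no_elastic_pairs(self):
        topo = cg_sim.build_topology("GSGSGSGS")
        assert topo.elastic.shape == (0, 2)

    def test_elastic_pairs_match_all_pairs_scan(self, rng):
        n = 15
        xyz = rng.uniform(0, 25, size=(n, 3))
        coords = {i: tuple(xyz[i]) for i in range(n)}
        topo = cg_sim.build_topology("A" * n, structured_coords=coords)
        expected = {
            (i, j)
            for i in range(n) for j in range(i + 1, n)
            if np.linalg.norm(xyz[i] - xyz[j]) < 12.0
        }
        assert {tuple(p) for p in topo.elastic} == expected
        for (i, j), r0 in zip(topo.elastic, topo.elastic_r0):
            assert r0 == pytest.approx(np.linalg.norm(xyz[i] - xyz[j]))

    def test_multichain_replication(self):
        topo = cg_sim.build_topology("ACDE", n_chains=3)
        assert topo.n_beads == 12
        assert topo.bonds.shape == (9, 2)
        assert topo.chain_of(5) == 1

    def test_unknown_residue_rejected(self):
        with pytest.raises(KeyError):
            cg_sim.build_topology("ACXE")


class TestSequenceProfile:
    def test_polyglycine_flat(self):
        pos, lam, fcr, net = cg_sim.sequence_profile("G" * 40)
        assert np.allclose(lam, ff.LAMBDA["G"])
        assert np.all(fcr == 0) and np.all(net == 0)
        assert lam.size == 40 - 25 + 1
        assert pos[0] == 12 and pos[-1] == 40 - 13

    def test_ke_repeat_charge_pattern(self):
        seq = "KE" * 20
        _, _, fcr, net = cg_sim.sequence_profile(seq)
        assert np.allclose(fcr, 1.0)
        assert np.allclose(net, [0.04 if i % 2 == 0 else -0.04
                                 for i in range(len(seq) - 24)])

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            cg_sim.sequence_profile("ACDEFG")


class TestBlockCharge:
    def test_decalysine(self):
        topo = cg_sim.build_topology("K" * 10 + "G" * 5, blocks={"k": (0, 10)})
        assert cg_sim.block_net_charge(topo, "k") == (10.0, 1.0)

    def test_balanced_block(self):
        topo = cg_sim.build_topology("KEKE" * 3, blocks={"all": (0, 12)})
        total, per = cg_sim.block_net_charge(topo, "all")
        assert total == 0.0

    def test_dbd_like_block_charge(self):
        # synthetic 57-residue DNA-binding-domain stand-in with the +8e
        # (+0.14 e/residue) net charge of a homeodomain-like block
        dbd = "KRKKRRKR" + "GSTA" * 12 + "N"
        assert len(dbd) == 57
        topo = cg_sim.build_topology(dbd, blocks={"dbd": (0, 57)})
        total, per = cg_sim.block_net_charge(topo, "dbd")
        assert total == pytest.approx(8.0)
        assert per == pytest.approx(8.0 / 57.0)


class TestPairEnergetics:
    def test_contact_energy_matches_lennard_jones(self):
        # lambda = 1 beads: Ashbaugh-Hatch reduces to plain LJ; at r = sigma
        # the LJ term vanishes, at the minimum the energy is -epsilon
        topo = cg_sim.build_topology("WW")  # highest-lambda residue, uncharged
        topo.lam[:] = 1.0
        topo.bonds = np.zeros((0, 2), dtype=int)
        topo.bond_r0 = np.zeros(0)
        cfg = cg_sim.SimulationConfig(box_a=200.0)
        sigma = ff.SIGMA["W"]
        for r, expected in ((sigma, 0.0), (2 ** (1 / 6) * sigma, -ff.EPSILON_KJ_MOL)):
            pos = np.array([[50.0, 50, 50], [50.0 + r, 50, 50]])
            e, _ = cg_sim.pair_energy_forces(pos, topo, cfg)
            assert e == pytest.approx(expected, abs=1e-9)

    def test_beyond_cutoffs_zero(self):
        topo = cg_sim.build_topology("KE")  # oppositely charged pair
        topo.bonds = np.zeros((0, 2), dtype=int)
        topo.bond_r0 = np.zeros(0)
        cfg = cg_sim.SimulationConfig(box_a=200.0)
        pos = np.array([[50.0, 50, 50], [90.0, 50, 50]])  # 40 A > both cutoffs
        e, f = cg_sim.pair_energy_forces(pos, topo, cfg)
        assert e == 0.0 and np.all(f == 0.0)

    def test_forces_are_exact_gradients(self):
        topo = cg_sim.build_topology("ACDEFGHIKLMNPQRSTVWY")
        cfg = cg_sim.SimulationConfig(box_a=200.0)
        pos = engine.initial_coords(topo, cfg, mode="cluster", seed=1)
        _, forces = cg_sim.pair_energy_forces(pos, topo, cfg)
        h = 1e-5
        rng = np.random.default_rng(2)
        for i in rng.choice(topo.n_beads, size=6, replace=False):
            for k in range(3):
                p1, p2 = pos.copy(), pos.copy()
                p1[i, k] += h
                p2[i, k] -= h
                fd = -(cg_sim.pair_energy_forces(p1, topo, cfg)[0]
                       - cg_sim.pair_energy_forces(p2, topo, cfg)[0]) / (2 * h)
                assert abs(fd - forces[i, k]) < 1e-4

    def test_overlap_rejected(self):
        topo = cg_sim.build_topology("GG")
        cfg = cg_sim.SimulationConfig(box_a=200.0)
        pos = np.array([[50.0, 50, 50], [50.0, 50, 50.05]])
        with pytest.raises(engine.SingularConfigurationError):
            cg_sim.pair_energy_forces(pos, topo, cfg)


class TestLangevin:
    def test_reproducible_given_seed(self):
        topo = cg_sim.build_topology("GSGSG")
        cfg = cg_sim.SimulationConfig(box_a=200.0)
        pos = engine.initial_coords(topo, cfg, seed=0)
        t1 = cg_sim.langevin_run(topo, cfg, 500, pos, seed=9, frame_interval_steps=100)
        t2 = cg_sim.langevin_run(topo, cfg, 500, pos, seed=9, frame_interval_steps=100)
        assert np.array_equal(t1.coords, t2.coords)

    def test_zero_temperature_energy_descends(self):
        topo = cg_sim.build_topology("FFFFFFFF")
        cfg = cg_sim.SimulationConfig(box_a=200.0, temperature=0.0)
        # straight chain at bond rest length: smooth downhill relaxation
        pos = np.zeros((8, 3))
        pos[:, 0] = 100.0 + 3.8 * np.arange(8)
        pos[:, 1] = 100.0
        pos[:, 2] = 100.0
        traj = cg_sim.langevin_run(topo, cfg, 4000, pos, seed=1,
                                   frame_interval_steps=100, temperature=0.0)
        etot = traj.e_pot_kj + traj.e_kin_kj
        assert np.all(np.diff(etot) <= 1e-9)

    def test_first_bead_fixed_in_single_mode(self):
        topo = cg_sim.build_topology("GSGSGSGS")
        cfg = cg_sim.SimulationConfig(box_a=300.0)
        pos = engine.initial_coords(topo, cfg, mode="single", seed=3)
        traj = cg_sim.langevin_run(topo, cfg, 2000, pos, seed=4,
                                   frame_interval_steps=200, fixed_beads=[0])
        assert np.all(traj.coords[:, 0, :] == pos[0])

    def test_equilibrate_two_chain_toy(self):
        topo = cg_sim.build_topology("FGFGFGFG", n_chains=2)
        cfg = cg_sim.SimulationConfig(box_a=300.0, seed=5)
        sched = {"soft": 500, "temp_ramp": 400, "dt_ramp": 400, "relax": 1000}
        coords = cg_sim.equilibrate(topo, cfg, mode="cluster", schedule=sched)
        e, _ = cg_sim.pair_energy_forces(coords, topo, cfg)
        assert np.isfinite(e)
        start = engine.initial_coords(topo, cfg, mode="cluster", seed=5)
        e0, _ = cg_sim.pair_energy_forces(start, topo, cfg)
        # relaxed energy is below the clash-ridden initial full-interaction energy
        assert e < e0


class TestThermostatStatistics:
    def test_equipartition_temperature(self):
        # 64 non-interacting beads, velocity OU process sampled over 2 ns
        topo = cg_sim.build_topology("G", n_chains=64)
        cfg = cg_sim.SimulationConfig(box_a=400.0)
        pos = engine.initial_coords(topo, cfg, mode="lattice", seed=2)
        traj = cg_sim.langevin_run(topo, cfg, 200_000, pos, seed=3,
                                   frame_interval_steps=100)
        assert cg_sim.temperature(traj, topo) == pytest.approx(300.0, rel=0.02)

    def test_harmonic_dimer_boltzmann(self):
        topo = cg_sim.build_topology("GG")
        cfg = cg_sim.SimulationConfig(box_a=200.0)
        pos = np.array([[100.0, 100, 100], [103.8, 100, 100]])
        traj = cg_sim.langevin_run(topo, cfg, 2_000_000, pos, seed=7,
                                   frame_interval_steps=200)
        d = np.linalg.norm(traj.coords[:, 1] - traj.coords[:, 0], axis=1)
        k, r0 = 10.0, 3.8
        w = lambda r: r**2 * np.exp(-0.5 * k * (r - r0) ** 2 / KT)
        z = quad(w, 0, 20)[0]
        mean_th = quad(lambda r: r * w(r), 0, 20)[0] / z
        var_th = quad(lambda r: (r - mean_th) ** 2 * w(r), 0, 20)[0] / z
        assert d.mean() == pytest.approx(mean_th, rel=0.03)
        assert d.std() == pytest.approx(np.sqrt(var_th), rel=0.03)


class TestCompactionPhysics:
    def test_hydrophobicity_drives_compaction(self):
        # identical 30-bead homopolymers, lambda = 1 vs lambda = 0
        results = {}
        for lam in (1.0, 0.0):
            topo = cg_sim.build_topology("G" * 30)
            topo.lam[:] = lam
            topo.sigma[:] = 5.0
            cfg = cg_sim.SimulationConfig(box_a=300.0, seed=11)
            pos = np.zeros((30, 3))
            pos[:, 0] = 100.0 + 3.8 * np.arange(30)
            pos[:, 1] = pos[:, 2] = 150.0
            traj = cg_sim.langevin_run(topo, cfg, 120_000, pos, seed=12,
                                       frame_interval_steps=400)
            half = traj.coords[traj.n_frames // 2:]
            re2 = np.mean(np.sum((half[:, -1] - half[:, 0]) ** 2, axis=-1))
            results[lam] = np.sqrt(re2)
        assert results[1.0] < 0.75 * results[0.0]

    def test_noninteracting_chain_is_ideal(self):
        # with nonbonded interactions off, <R^2(N)> grows linearly in N
        topo = cg_sim.build_topology("G" * 40)
        cfg = cg_sim.SimulationConfig(box_a=300.0, seed=13)
        pos = np.zeros((40, 3))
        pos[:, 0] = 80.0 + 3.8 * np.arange(40)
        pos[:, 1] = pos[:, 2] = 150.0
        traj = cg_sim.langevin_run(topo, cfg, 200_000, pos, seed=14,
                                   frame_interval_steps=400, nb_scale=0.0)
        half = traj.coords[traj.n_frames // 2:]
        seps = np.array([5, 10, 20, 39])
        r2 = np.array([
            np.mean(np.sum((half[:, s] - half[:, 0]) ** 2, axis=-1)) for s in seps
        ])
        slope = np.polyfit(np.log(seps), np.log(r2), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.15)
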