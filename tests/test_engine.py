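"""Monte Carlo engine: initialisation, moves, bookkeeping, reproducibility."""

import math

import numpy as np
import pytest

from dielsat import reference
from dielsat.engine import (MCState, MoveSchedule, OverpackedError,
                            build_cluster, cluster_move, displace_move,
                            initialize_configuration, load_checkpoint, run,
                            save_checkpoint)
from dielsat.geometry import BulkBox, SlitBox
from dielsat.model import DielectricRampModel
from dielsat.observables import FrameRecorder, RDFObserver

RAMP = DielectricRampModel()


class TestInitializeConfiguration:
    def test_empty_state(self):
        st = initialize_configuration(0, 0, BulkBox(20.0), seed=1)
        assert st.n_ions == 0 and st.energy == 0.0

    def test_same_seed_reproduces_configuration(self):
        a = initialize_configuration(20, 20, BulkBox(40.0), seed=9)
        b = initialize_configuration(20, 20, BulkBox(40.0), seed=9)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_no_overlaps_at_half_molar(self):
        # 100 + 100 ions at 0.5 M in the matched box
        from dielsat.constants import MOLAR_TO_PER_A3

        L = (100 / (0.5 * MOLAR_TO_PER_A3)) ** (1 / 3)
        st = initialize_configuration(100, 100, BulkBox(L), seed=2)
        d = st.positions[:, None, :] - st.positions[None, :, :]
        d -= L * np.round(d / L)
        r = np.sqrt((d**2).sum(-1))
        np.fill_diagonal(r, np.inf)
        assert r.min() >= RAMP.d

    def test_overpacked_box_raises(self):
        with pytest.raises(OverpackedError):
            initialize_configuration(50, 50, BulkBox(8.0), seed=3,
                                     max_attempts_per_ion=50)

    def test_slit_ions_inside_walls(self):
        slit = SlitBox(L=20.0, H=12.0)
        st = initialize_configuration(10, 10, slit, seed=4)
        assert np.all(np.abs(st.positions[:, 2]) <= (12.0 - 3.0) / 2.0)


class TestParticleEnergy:
    def test_contact_pair(self, unlike_pair_state):
        st = unlike_pair_state
        assert st.particle_energy(0) == pytest.approx(-8.13, abs=0.05)

    def test_isolated_ion_zero(self):
        st = MCState(positions=np.array([[5.0, 5.0, 5.0]]),
                     valences=np.array([1.0]), geometry=BulkBox(30.0),
                     model=RAMP)
        assert st.particle_energy(0) == 0.0

    def test_double_counting_identity(self):
        st = initialize_configuration(15, 15, BulkBox(30.0), seed=11)
        total = sum(st.particle_energy(i) for i in range(st.n_ions))
        assert total == pytest.approx(2.0 * st.total_energy(), rel=1e-10)

    def test_total_matches_bruteforce_reference(self):
        st = initialize_configuration(12, 12, BulkBox(25.0), seed=13)
        e_ref = reference.total_energy_bulk(st.positions, st.valences,
                                            st.geometry, st.model)
        assert st.total_energy() == pytest.approx(e_ref, rel=1e-10)

    def test_invalid_index(self):
        st = initialize_configuration(2, 2, BulkBox(20.0), seed=14)
        with pytest.raises(IndexError):
            st.particle_energy(99)


@pytest.fixture
def unlike_pair_state():
    pos = np.array([[10.0, 10.0, 10.0], [13.0, 10.0, 10.0]])
    st = MCState(positions=pos, valences=np.array([1.0, -1.0]),
                 geometry=BulkBox(60.0), model=RAMP)
    st.energy = st.total_energy()
    return st


class TestSingleMoves:
    def test_zero_energy_change_always_accepted(self):
        # uncharged particles far apart: every in-bounds trial has dU = 0
        st = MCState(positions=np.array([[10.0, 10.0, 10.0]]),
                     valences=np.array([0.0]), geometry=BulkBox(40.0),
                     model=RAMP)
        rng = np.random.default_rng(5)
        assert all(displace_move(st, rng, max_step=1.0) for _ in range(50))

    def test_overlap_trial_rejected(self):
        pos = np.array([[10.0, 10.0, 10.0], [13.1, 10.0, 10.0]])
        st = MCState(positions=pos, valences=np.array([1.0, -1.0]),
                     geometry=BulkBox(40.0), model=RAMP)
        st.energy = st.total_energy()
        rejected = 0
        rng = np.random.default_rng(6)
        for _ in range(200):
            before = st.positions.copy()
            if not displace_move(st, rng, max_step=3.0):
                np.testing.assert_array_equal(st.positions, before)
                rejected += 1
        assert rejected > 0  # some trials must have hit the hard core

    def test_energy_consistent_after_moves(self, unlike_pair_state):
        st = unlike_pair_state
        rng = np.random.default_rng(7)
        for _ in range(300):
            displace_move(st, rng, max_step=2.0)
        assert st.energy == pytest.approx(st.total_energy(), abs=1e-8)


class TestClusterMoves:
    def _two_pair_state(self):
        # two tight +/- pairs far apart
        pos = np.array([[10.0, 10.0, 10.0], [13.2, 10.0, 10.0],
                        [35.0, 35.0, 35.0], [38.2, 35.0, 35.0]])
        st = MCState(positions=pos, valences=np.array([1.0, -1.0, 1.0, -1.0]),
                     geometry=BulkBox(50.0), model=RAMP)
        st.energy = st.total_energy()
        return st

    def test_build_cluster_transitive(self):
        st = self._two_pair_state()
        assert list(build_cluster(st, 0, 3.5)) == [0, 1]
        assert list(build_cluster(st, 3, 3.5)) == [2, 3]

    def test_isolated_pair_translation_accepted(self):
        # far from everything, external dU ~ 0 => acceptance ~ 1
        st = self._two_pair_state()
        rng = np.random.default_rng(8)
        sched = MoveSchedule(cluster_step=2.0, cluster_delta=3.5)
        accepted = sum(cluster_move(st, rng, sched) for _ in range(100))
        assert accepted >= 95
        assert st.energy == pytest.approx(st.total_energy(), abs=1e-8)

    def test_merge_guard_rejects(self):
        # clusters 3.0 apart along x; a +x translation that would bring
        # them within delta must be rejected outright
        pos = np.array([[10.0, 10.0, 10.0], [13.2, 10.0, 10.0],
                        [18.0, 10.0, 10.0], [21.2, 10.0, 10.0]])
        st = MCState(positions=pos, valences=np.array([1.0, -1.0, 1.0, -1.0]),
                     geometry=BulkBox(50.0), model=RAMP)
        st.energy = st.total_energy()

        class ShiftRight:
            def __init__(self):
                self._i = 0

            def integers(self, n):
                return 0  # seed ion 0 -> left pair

            def random(self, size=None):
                if size == 3:
                    # +1.5 A in x: brings the pairs to 3.3 A, inside delta
                    # but outside the hard core, so only the guard can fire
                    return np.array([0.875, 0.5, 0.5])
                return 0.0

        sched = MoveSchedule(cluster_step=2.0, cluster_delta=3.5)
        assert cluster_move(st, ShiftRight(), sched) is False
        np.testing.assert_array_equal(st.positions, pos)

    def test_sampling_agrees_with_and_without_cluster_moves(self):
        """Equilibrium g(r) of a small system is the same whether or not
        cluster moves are mixed in (cross-validation of the samplers)."""
        gs = []
        for frac, seed in ((0.0, 31), (0.3, 33)):
            st = initialize_configuration(10, 10, BulkBox(30.0), seed=seed)
            obs = RDFObserver(st.geometry, bin_width=1.0)
            sched = MoveSchedule(equilibration=2000, production=30_000,
                                 stride=25, cluster_fraction=frac,
                                 max_step=3.0, cluster_step=3.0, tune=False)
            run(st, sched, observers=(obs,))
            gs.append(obs.rdf.g_pm)
        # compare where the RDF is well resolved
        mask = gs[0] + gs[1] > 0.2
        diff = np.abs(gs[0] - gs[1])[mask]
        assert np.mean(diff) < 0.15


class TestRunDriver:
    def test_zero_production_gives_empty_accumulators(self):
        st = initialize_configuration(5, 5, BulkBox(25.0), seed=41)
        rec = FrameRecorder()
        sched = MoveSchedule(equilibration=100, production=0, stride=10)
        run(st, sched, observers=(rec,))
        assert len(rec) == 0

    def test_energy_drift_below_tolerance_over_1e4_sweeps(self):
        """Running energy vs O(N^2) recomputation after 1e4 sweeps."""
        st = initialize_configuration(20, 20, BulkBox(35.0), seed=43)
        sched = MoveSchedule(equilibration=0, production=10_000, stride=10_000,
                             tune=False, reconcile_every=10**9)
        run(st, sched)
        drift = abs(st.energy - st.total_energy())
        assert drift < 1e-6 * st.n_ions

    def test_no_overlaps_or_wall_violations_in_sampled_frames(self):
        slit = SlitBox(L=25.0, H=20.0, sigma=-8 / (2 * 25.0**2))
        st = initialize_configuration(18, 10, slit, seed=45)
        rec = FrameRecorder()
        sched = MoveSchedule(equilibration=500, production=2000, stride=100)
        run(st, sched, observers=(rec,))
        zmax = (20.0 - 3.0) / 2.0
        for pos in rec.positions:
            assert np.all(np.abs(pos[:, 2]) <= zmax + 1e-12)
            d = pos[:, None, :] - pos[None, :, :]
            d[..., 0] -= 25.0 * np.round(d[..., 0] / 25.0)
            d[..., 1] -= 25.0 * np.round(d[..., 1] / 25.0)
            r = np.sqrt((d**2).sum(-1))
            np.fill_diagonal(r, np.inf)
            assert r.min() >= 3.0

    def test_same_seed_reproduces_run(self):
        outs = []
        for _ in range(2):
            st = initialize_configuration(8, 8, BulkBox(28.0), seed=47)
            sched = MoveSchedule(equilibration=200, production=500, stride=100)
            run(st, sched)
            outs.append((st.positions.copy(), st.energy))
        np.testing.assert_array_equal(outs[0][0], outs[1][0])
        assert outs[0][1] == outs[1][1]

    def test_checkpoint_resume_bitwise_identical(self, tmp_path):
        """Interrupting at a checkpoint and resuming reproduces the
        uninterrupted observable stream exactly."""
        ck = tmp_path / "ck.json"

        def fresh():
            st = initialize_configuration(8, 8, BulkBox(28.0), seed=51)
            return st

        # uninterrupted
        st_a = fresh()
        rec_a = FrameRecorder()
        sched = MoveSchedule(equilibration=200, production=1000, stride=100,
                             tune=False)
        run(st_a, sched, observers=(rec_a,))

        # interrupted: run half, checkpoint, reload, continue
        st_b = fresh()
        rec_b = FrameRecorder()
        half = MoveSchedule(equilibration=200, production=500, stride=100,
                            tune=False)
        run(st_b, half, observers=(rec_b,))
        save_checkpoint(st_b, half, ck)
        st_c, _ = load_checkpoint(ck)
        full = MoveSchedule(equilibration=200, production=1000, stride=100,
                            tune=False)
        run(st_c, full, observers=(rec_b,))

        assert len(rec_a) == len(rec_b)
        for pa, pb in zip(rec_a.positions, rec_b.positions):
            np.testing.assert_array_equal(pa, pb)

    def test_uncharged_hard_spheres_have_flat_rdf(self):
        """50+50 uncharged hard spheres at low density: g(r) ~ 1 beyond d."""
        box = BulkBox(60.0)
        # switch the coupling off via temperature: l_B ~ 1/T, so at 1e9 K
        # only the hard cores remain while the +/- labels stay intact
        st = initialize_configuration(50, 50, box, seed=53, T=1.0e9)
        obs = RDFObserver(box, bin_width=1.0)
        sched = MoveSchedule(equilibration=500, production=5000, stride=25,
                             max_step=6.0, cluster_fraction=0.0, tune=False)
        run(st, sched, observers=(obs,))
        rdf = obs.rdf
        sel = (rdf.r > 5.0) & (rdf.r < 25.0)
        g_all = (rdf.g_pp[sel] + rdf.g_pm[sel]) / 2.0
        assert np.all(np.abs(g_all - 1.0) < 0.15)
        assert abs(g_all.mean() - 1.0) < 0.03


class TestTwoIonBoltzmann:
    def test_pair_distance_distribution_matches_quadrature(self, two_ion_distances):
        """Long-run sampled +/- pair separation density vs the numerically
        integrated Boltzmann form r^2 exp(-beta u(r))."""
        r = two_ion_distances
        edges = np.linspace(3.0, 10.0, 11)
        inside = r[(r >= edges[0]) & (r <= edges[-1])]
        counts, _ = np.histogram(inside, bins=edges)
        p_obs = counts / counts.sum()
        grid = np.linspace(3.0, 10.0, 2000)
        pdf = reference.two_ion_distance_pdf(grid, RAMP)
        p_exp = np.array([
            np.trapezoid(pdf[(grid >= lo) & (grid <= hi)],
                         grid[(grid >= lo) & (grid <= hi)])
            for lo, hi in zip(edges[:-1], edges[1:])
        ])
        p_exp /= p_exp.sum()
        tv = 0.5 * np.abs(p_obs - p_exp).sum()
        assert tv < 0.01  # total-variation agreement at the 1% level
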