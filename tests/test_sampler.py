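"""Sampler: ladder, Metropolis, movers, replica exchange, REMC driver."""

from types import SimpleNamespace

import numpy as np
import pytest

from cgdock import System, build_temperature_ladder, metropolis_accept, project_to_lattice
from cgdock.fixtures import ideal_helix, random_sequence
from cgdock.sampler import (
    AnnealingSchedule,
    MoveSet,
    RemcConfig,
    SimState,
    propose_move,
    replica_exchange_sweep,
    run_remc,
)


class TestTemperatureLadder:
    def test_unit_ratio_reduces_to_uniform_spacing(self):
        lad = build_temperature_ladder(1.0, 3.0, 5, 1.0)
        assert np.allclose(np.diff(lad.temps), 0.5)

    def test_geometric_closed_form(self):
        lad = build_temperature_ladder(1.0, 2.0, 3, 2.0)
        assert np.allclose(lad.temps, [1.0, 4.0 / 3.0, 2.0])

    def test_twenty_rungs_strictly_increasing_with_geometric_increments(self):
        lad = build_temperature_ladder(1.0, 2.5, 20, 1.15)
        assert len(lad) == 20
        inc = np.diff(lad.temps)
        assert (inc > 0).all()
        assert np.allclose(inc[1:] / inc[:-1], 1.15)
        assert lad.temps[0] == 1.0 and lad.temps[-1] == 2.5

    def test_degenerate_ladder_rejected(self):
        with pytest.raises(ValueError):
            build_temperature_ladder(1.0, 1.0, 4, 1.1)


class TestMetropolis:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(-d, 1.0, rng) for d in (0.0, 0.5, 100.0))

    def test_acceptance_rate_at_ln2(self):
        rng = np.random.default_rng(42)
        temp = 1.7
        hits = sum(metropolis_accept(temp * np.log(2.0), temp, rng)
                   for _ in range(10_000))
        assert hits / 10_000 == pytest.approx(0.5, abs=0.02)

    def test_two_state_boltzmann_occupancy(self):
        # E=0 vs E=1 at T=1: occupancy ratio should be e within 3 sigma
        rng = np.random.default_rng(7)
        state, counts = 0, [0, 0]
        n = 100_000
        for _ in range(n):
            target = 1 - state
            if metropolis_accept(float(target - state), 1.0, rng):
                state = target
            counts[state] += 1
        p1 = 1.0 / (1.0 + np.e)
        sigma = np.sqrt(p1 * (1 - p1) * n)  # iid bound; correlated chain is wider
        assert abs(counts[1] - n * p1) < 5 * sigma


@pytest.fixture()
def single_chain_state():
    seq = random_sequence(10, np.random.default_rng(0))
    chain = project_to_lattice(ideal_helix(10), seq, role="receptor")
    return SimState(System(chain))


class TestMovers:
    def test_single_bead_footprint(self, single_chain_state):
        rng = np.random.default_rng(1)
        ms = MoveSet([("single", 1.0)])
        prop = None
        while prop is None:
            prop = propose_move(single_chain_state, ms, rng)
        assert prop.moved.tolist() in [[i] for i in range(1, 9)]
        assert prop.new_lat.shape == (1, 3)

    def test_chain_end_footprint(self, single_chain_state):
        rng = np.random.default_rng(1)
        ms = MoveSet([("end", 1.0)])
        prop = propose_move(single_chain_state, ms, rng)
        assert prop.moved.tolist() in ([0], [9])

    def test_two_bead_footprint(self, single_chain_state):
        rng = np.random.default_rng(1)
        ms = MoveSet([("two", 1.0)])
        prop = propose_move(single_chain_state, ms, rng)
        i, j = prop.moved
        assert j == i + 1

    def test_proposals_preserve_lattice_bonds(self, single_chain_state):
        state = single_chain_state
        rng = np.random.default_rng(3)
        ms = MoveSet()
        for _ in range(500):
            state.attempt_move(ms, 2.0, rng)
        state.to_system().receptor.validate()

    def test_single_bead_proposal_symmetric(self, single_chain_state):
        # forward and reverse proposal counts for a fixed bead must agree:
        # both states share the same geometric candidate set
        state = single_chain_state
        rng = np.random.default_rng(5)
        ms = MoveSet([("single", 1.0)])
        i = 4
        lat = state.ca_lat[0]
        old = lat[i].copy()
        e = tuple(int(x) for x in (lat[i + 1] - lat[i - 1]))
        cand = state._middle_vectors(e)
        new = None
        for v in cand:
            if not np.array_equal(lat[i - 1] + v, old):
                new = lat[i - 1] + v
                break
        n_fwd = n_rev = 0
        trials = 20_000
        for _ in range(trials):
            prop = propose_move(state, ms, rng)
            if prop is not None and prop.moved[0] == i and np.array_equal(prop.new_lat[0], new):
                n_fwd += 1
        lat[i] = new  # jump to the other state (geometry only; no energies used)
        for _ in range(trials):
            prop = propose_move(state, ms, rng)
            if prop is not None and prop.moved[0] == i and np.array_equal(prop.new_lat[0], old):
                n_rev += 1
        lat[i] = old
        rate = 1.0 / (8 * len(cand))  # bead choice x candidate choice
        sigma = np.sqrt(trials * rate)
        assert abs(n_fwd - n_rev) < 6 * sigma


class TestReplicaExchange:
    @staticmethod
    def _stub(energies):
        return [SimpleNamespace(energy=e, temp_index=k) for k, e in enumerate(energies)]

    def test_equal_energies_always_swap(self):
        reps = self._stub([5.0, 5.0])
        ladder = build_temperature_ladder(1.0, 2.0, 2, 1.0)
        n = replica_exchange_sweep(reps, ladder, np.random.default_rng(0))
        assert n == 1
        assert [r.temp_index for r in reps] == [1, 0]

    def test_strongly_ordered_energies_never_swap(self):
        # cold replica much lower in energy: swap argument extremely negative
        reps = self._stub([-100.0, 100.0])
        ladder = build_temperature_ladder(1.0, 2.0, 2, 1.0)
        rng = np.random.default_rng(0)
        assert sum(replica_exchange_sweep(reps, ladder, rng) for _ in range(100)) == 0

    def test_temperature_assignment_stays_permutation(self):
        rng = np.random.default_rng(3)
        reps = self._stub(list(rng.normal(size=6)))
        ladder = build_temperature_ladder(1.0, 2.0, 6, 1.2)
        for _ in range(50):
            replica_exchange_sweep(reps, ladder, rng)
            assert sorted(r.temp_index for r in reps) == list(range(6))


@pytest.fixture(scope="module")
def small_traj():
    seq = random_sequence(10, np.random.default_rng(0))
    chain = project_to_lattice(ideal_helix(10), seq, role="receptor")
    cfg = RemcConfig(n_replicas=4, snapshots_per_replica=20,
                     annealing=AnnealingSchedule(4, 0.9), seed=9,
                     exchange_every=50)
    return run_remc(System(chain), cfg), cfg


class TestRunRemc:
    def test_snapshot_count_and_fraction(self, small_traj):
        traj, cfg = small_traj
        assert len(traj) == 4 * 20
        for r in range(4):
            frames = traj.replica_frames(r)
            assert len(frames) == cfg.snapshots_per_replica
            assert len(frames) / cfg.attempts_per_replica == cfg.save_fraction

    def test_bit_identical_replay(self, small_traj):
        traj, cfg = small_traj
        seq = random_sequence(10, np.random.default_rng(0))
        chain = project_to_lattice(ideal_helix(10), seq, role="receptor")
        traj2 = run_remc(System(chain), cfg)
        for a, b in zip(traj.frames, traj2.frames):
            assert np.array_equal(a.ca_lat[0], b.ca_lat[0])
            assert a.energy == b.energy and a.rung == b.rung

    def test_annealing_cools_whole_ladder(self, small_traj):
        traj, _ = small_traj
        first = {f.rung: f.temperature for f in traj.frames if f.stage == 0}
        last = {f.rung: f.temperature for f in traj.frames if f.stage == 3}
        for rung in first:
            assert last[rung] < first[rung]

    def test_no_snapshot_violates_excluded_volume(self, small_traj):
        traj, _ = small_traj
        for f in traj.frames:
            nodes = [tuple(p) for lat in f.ca_lat for p in lat]
            assert len(nodes) == len(set(nodes))

    def test_rung_mean_energy_increases_with_temperature(self, small_traj):
        traj, _ = small_traj
        by_rung = {}
        for f in traj.frames:
            by_rung.setdefault(f.rung, []).append(f.energy["total"])
        means = [np.mean(by_rung[r]) for r in sorted(by_rung)]
        assert means[0] <= means[-1] + 1e-9
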