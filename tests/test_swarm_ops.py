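"""Unit tests for the 2D swarm model operations: elastic energy, initial
conditions, direction weighting, reversals, contact detection and
signaling/sporulation accounting."""

from __future__ import annotations

import math

import numpy as np
import pytest

from conftest import state_from_bodies
from myxofruit.swarm import (
    SwarmConfig,
    apply_signaling_and_sporulation,
    compute_direction,
    detect_end_contacts,
    draw_reversal_interval,
    elastic_energy,
    init_swarm,
    maybe_reverse,
    relax_trailing_nodes,
)

OPEN = SwarmConfig(domain_size=100.0, discs=(), n_cells=1, w_noise=0.0, seed=0)


class TestElasticEnergy:
    def test_straight_rest_body_has_zero_energy(self):
        nodes = [(0, 0), (2.5, 0), (5, 0)]
        assert elastic_energy(nodes, kb=10.0, ks=5.0, l0=2.5) == pytest.approx(0.0)

    def test_pure_bend_energy(self):
        # segments at rest length, bent by theta = 0.2 rad: H = 0.5*10*0.04
        th = 0.2
        nodes = [(0, 0), (2.5, 0), (2.5 + 2.5 * math.cos(th), 2.5 * math.sin(th))]
        assert elastic_energy(nodes, kb=10.0, ks=5.0, l0=2.5) == pytest.approx(0.2)

    def test_stretch_energy_additive_and_angle_independent(self):
        delta = 0.3
        straight = [(0, 0), (2.5, 0), (5 + delta, 0)]
        h = elastic_energy(straight, kb=7.0, ks=4.0, l0=2.5)
        assert h == pytest.approx(0.5 * 4.0 * delta**2)
        th = 0.2
        bent = [(0, 0), (2.5, 0),
                (2.5 + (2.5 + delta) * math.cos(th), (2.5 + delta) * math.sin(th))]
        hb = elastic_energy(bent, kb=7.0, ks=4.0, l0=2.5)
        assert hb == pytest.approx(0.5 * 7.0 * th**2 + 0.5 * 4.0 * delta**2)

    def test_degenerate_segment_rejected(self):
        with pytest.raises(ValueError):
            elastic_energy([(0, 0), (0, 0), (5, 0)], 1.0, 1.0, 2.5)


class TestInitSwarm:
    def test_tangential_orientation_in_disc(self):
        # a cell east of the disc center must point along ±y; with the
        # counter-clockwise convention, along +y
        cfg = SwarmConfig(domain_size=200.0, discs=(((100.0, 100.0), 50.0),),
                          n_cells=10_000, seed=5)
        state = init_swarm(cfg)
        mids = state.midpoints()
        ori = state.orientations()
        east = (np.abs(mids[:, 1] - 100.0) < 3.0) & (mids[:, 0] > 110.0) & (mids[:, 0] < 145.0)
        assert east.sum() > 10
        assert (ori[east, 1] > 0.95).all()  # tangent tilts with the y-offset

    def test_disc_occupancy_fraction(self):
        # 4 discs of r=50 in a 500x500 domain cover pi*50^2*4/500^2 = 12.6%
        cfg = SwarmConfig(n_cells=10_000, seed=8)
        state = init_swarm(cfg)
        mids = state.midpoints()
        inside = np.zeros(len(mids), dtype=bool)
        for (cx, cy), r in cfg.discs:
            inside |= (mids[:, 0] - cx) ** 2 + (mids[:, 1] - cy) ** 2 <= r**2
        p = 4 * math.pi * 50**2 / 500**2
        sigma = math.sqrt(p * (1 - p) / 10_000)
        assert abs(inside.mean() - p) < 3 * sigma

    def test_deterministic_under_seed(self):
        cfg = SwarmConfig(n_cells=100, seed=3)
        a, b = init_swarm(cfg), init_swarm(cfg)
        assert (a.pos == b.pos).all()
        assert (a.next_rev == b.next_rev).all()

    def test_rest_length_bodies(self):
        state = init_swarm(SwarmConfig(n_cells=50, seed=1))
        seg1 = np.linalg.norm(state.pos[:, 1] - state.pos[:, 0], axis=1)
        seg2 = np.linalg.norm(state.pos[:, 2] - state.pos[:, 1], axis=1)
        assert np.allclose(seg1, 2.5) and np.allclose(seg2, 2.5)

    def test_overlapping_discs_rejected(self):
        with pytest.raises(ValueError):
            SwarmConfig(discs=(((100.0, 100.0), 50.0), ((140.0, 100.0), 50.0)))

    def test_disc_outside_domain_rejected(self):
        with pytest.raises(ValueError):
            SwarmConfig(domain_size=80.0, discs=(((40.0, 40.0), 50.0),))


class TestComputeDirection:
    def test_isolated_cell_follows_long_axis(self):
        state = state_from_bodies(OPEN, [((50.0, 50.0), 30.0)])
        d = compute_direction(state, OPEN, 0, with_noise=False)
        assert d @ [math.cos(math.radians(30)), math.sin(math.radians(30))] > 0.999999

    def test_symmetric_forward_neighbors_average_out(self):
        cfg = SwarmConfig(domain_size=100.0, discs=(), n_cells=3,
                          w_axis=0.0, w_trail=0.0, w_noise=0.0, seed=0)
        state = state_from_bodies(
            cfg, [((50.0, 50.0), 0.0), ((55.0, 51.0), 10.0), ((55.0, 49.0), -10.0)]
        )
        d = compute_direction(state, cfg, 0, with_noise=False)
        assert d[0] == pytest.approx(1.0, abs=1e-9)
        assert d[1] == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_with_fixed_substream(self):
        cfg = SwarmConfig(domain_size=100.0, discs=(), n_cells=1, seed=0)
        state = state_from_bodies(cfg, [((50.0, 50.0), 75.0)])
        d1 = compute_direction(state, cfg, 0, seed=99)
        d2 = compute_direction(state, cfg, 0, seed=99)
        assert (d1 == d2).all()

    def test_spore_direction_undefined(self):
        state = state_from_bodies(OPEN, [((50.0, 50.0), 0.0)], spores=[0])
        with pytest.raises(ValueError):
            compute_direction(state, OPEN, 0)


class TestReversals:
    def test_swap_is_involution_and_counter_untouched(self, rng):
        state = state_from_bodies(OPEN, [((50.0, 50.0), 20.0)])
        state.next_rev[0] = 5.0
        state.counter[0] = 17
        pos0 = state.pos.copy()
        assert maybe_reverse(state, OPEN, 0, now=5.0, rng=rng)
        assert state.headend[0] == 2
        assert (state.pos == pos0).all()
        assert state.counter[0] == 17
        state.next_rev[0] = 6.0
        assert maybe_reverse(state, OPEN, 0, now=6.0, rng=rng)
        assert state.headend[0] == 0

    def test_no_reversal_before_due_time(self, rng):
        state = state_from_bodies(OPEN, [((50.0, 50.0), 20.0)])
        state.next_rev[0] = 10.0
        assert not maybe_reverse(state, OPEN, 0, now=9.99, rng=rng)
        assert state.headend[0] == 0

    def test_interval_distribution_mean(self, rng):
        draws = [draw_reversal_interval(rng, 8.0, 1.0) for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(8.0, abs=0.03)
        assert np.std(draws) == pytest.approx(1.0, abs=0.1)
        assert min(draws) > 0


class TestEndContacts:
    cfg = SwarmConfig(domain_size=100.0, discs=(), n_cells=2, seed=0)

    @staticmethod
    def _pair_at_angle(cfg, angle_deg, gap=0.3):
        """Cell A along +x; cell B starting ``gap`` beyond A's head, tilted."""
        a_mid = (40.0, 50.0)
        head = (42.5, 50.0)
        u = np.array([math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))])
        b_mid = np.array(head) + np.array([gap, 0.0]) + u * cfg.l0
        return state_from_bodies(cfg, [(a_mid, 0.0), (tuple(b_mid), angle_deg)])

    def test_aligned_end_contact_detected(self):
        state = self._pair_at_angle(self.cfg, 29.0)
        assert detect_end_contacts(state, self.cfg) == {(0, 1)}

    def test_misaligned_contact_rejected(self):
        state = self._pair_at_angle(self.cfg, 31.0)
        assert detect_end_contacts(state, self.cfg) == set()

    def test_polarity_ignored(self):
        state = self._pair_at_angle(self.cfg, 29.0)
        state.headend[1] = 2  # flip polarity of B; acute angle unchanged
        assert detect_end_contacts(state, self.cfg) == {(0, 1)}

    def test_side_by_side_excluded(self):
        state = state_from_bodies(self.cfg, [((50.0, 50.0), 0.0), ((50.0, 50.6), 0.0)])
        assert detect_end_contacts(state, self.cfg) == set()

    def test_distant_cells_excluded(self):
        state = state_from_bodies(self.cfg, [((20.0, 20.0), 0.0), ((80.0, 80.0), 0.0)])
        assert detect_end_contacts(state, self.cfg) == set()

    def test_spores_never_signal(self):
        state = self._pair_at_angle(self.cfg, 10.0)
        state.state[1] = 1
        assert detect_end_contacts(state, self.cfg) == set()


class TestSignalingAndSporulation:
    def test_pinned_pair_converts_after_exactly_500_events(self):
        cfg = SwarmConfig(domain_size=100.0, discs=(), n_cells=2, seed=0)
        state = TestEndContacts._pair_at_angle(cfg, 5.0)
        for step in range(499):
            pairs = detect_end_contacts(state, cfg)
            assert pairs == {(0, 1)}
            apply_signaling_and_sporulation(state, pairs, cfg)
        assert (state.state == 0).all()
        apply_signaling_and_sporulation(state, detect_end_contacts(state, cfg), cfg)
        assert (state.state == 1).all()
        assert (state.counter == 500).all()

    def test_empty_pair_set_is_identity(self):
        cfg = SwarmConfig(domain_size=100.0, discs=(), n_cells=1, seed=0)
        state = state_from_bodies(cfg, [((50.0, 50.0), 0.0)])
        before = state.counter.copy()
        assert apply_signaling_and_sporulation(state, set(), cfg) == 0
        assert (state.counter == before).all()

    def test_multi_pair_cell_gains_per_pair(self):
        cfg = SwarmConfig(domain_size=100.0, discs=(), n_cells=3, seed=0)
        state = state_from_bodies(cfg, [((50.0, 50.0), 0.0)] * 3)
        apply_signaling_and_sporulation(state, {(0, 1), (0, 2)}, cfg)
        assert state.counter.tolist() == [2, 1, 1]

    def test_spore_body_collapses_to_midpoint(self):
        cfg = SwarmConfig(domain_size=100.0, discs=(), n_cells=1,
                          signal_threshold=1, seed=0)
        state = state_from_bodies(cfg, [((50.0, 50.0), 30.0)])
        apply_signaling_and_sporulation(state, {(0, 0)}, cfg)
        assert state.state[0] == 1
        assert np.allclose(state.pos[0], state.pos[0, 1])
        assert np.allclose(state.pos[0, 1], (50.0, 50.0))


class TestRelax:
    def test_free_straight_advance_always_accepted(self):
        cfg = SwarmConfig(domain_size=100.0, discs=(), n_cells=1, w_noise=0.0, seed=0)
        state = state_from_bodies(cfg, [((50.0, 50.0), 0.0)])
        step_len = cfg.speed * cfg.dt
        for k in range(1000):
            head = state.pos[0, 0] + [step_len, 0.0]
            assert relax_trailing_nodes(state, cfg, 0, head, seed=k)
        # rigid translation: body advanced by 1000 steps exactly
        assert state.pos[0, 1, 0] == pytest.approx(50.0 + 1000 * step_len - 100.0 * 2)

    def test_blocked_by_spore_wall_stalls(self):
        cfg = SwarmConfig(domain_size=100.0, discs=(), n_cells=4, w_noise=0.0, seed=0)
        bodies = [((50.0, 50.0), 0.0)] + [((53.3, 49.0 + dy), 0.0) for dy in (0.0, 1.0, 2.0)]
        state = state_from_bodies(cfg, bodies, spores=[1, 2, 3])
        before = state.pos[0].copy()
        head = state.pos[0, 0] + [0.5, 0.0]  # drives the head into the wall
        assert not relax_trailing_nodes(state, cfg, 0, head, seed=1)
        assert (state.pos[0] == before).all()
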