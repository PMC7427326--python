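"""Simulator contracts: elementary terms, exclusion, reproducibility."""

import math

import numpy as np
import pytest

import polconvoy as pc
from polconvoy.simulate import (
    Convoy,
    EnergyLandscape,
    initiation_allowed,
    ler_engagement,
    rna_element_term,
    run_replicates,
    sample_velocity,
    torsion_term,
)


class TestSampleVelocity:
    def test_degenerate_mixture_is_constant(self):
        p = pc.ModelParams(p_pause=0.0, sigma_rel=1e-12)
        rng = np.random.default_rng(0)
        draws = sample_velocity(p, rng, size=100)
        np.testing.assert_allclose(draws, 50.0, atol=1e-6)

    def test_paused_component_fraction(self):
        p = pc.ModelParams()
        rng = np.random.default_rng(11)
        draws = sample_velocity(p, rng, size=1_000_000)
        # paused draws cluster near 0.9 +/- 1.5; active near 50 +/- 20:
        # below ~10 nt/s the active component contributes ~2.3%
        paused_est = np.mean(draws < 10) - 0.0228 * np.mean(draws >= 10)
        sd = math.sqrt(0.078 * 0.922 / 1e6)
        assert abs(np.mean(draws < 10) - (0.078 + 0.0228 * 0.922)) < 5 * sd + 1e-3

    def test_sample_mean_matches_mixture_mean(self):
        p = pc.ModelParams()
        rng = np.random.default_rng(5)
        draws = sample_velocity(p, rng, size=1_000_000)
        expected = 0.078 * 0.9 + 0.922 * 50.0
        se = draws.std() / 1000.0
        assert abs(draws.mean() - expected) < 3 * se


class TestTorsionTerm:
    def test_relaxed_state_is_exactly_zero(self):
        assert torsion_term(100.0, 120.0, 100.0, 120.0, 500.0, 11.0) == 0.0

    def test_approaching_downstream_neighbour_slows(self):
        t = torsion_term(90.0, None, 100.0, None, 500.0, 11.0)
        assert t == pytest.approx(500.0 * (1 - 89.0 / 79.0))
        assert t < 0

    def test_separating_downstream_neighbour_pulls_forward(self):
        t = torsion_term(110.0, None, 100.0, None, 500.0, 11.0)
        assert t == pytest.approx(500.0 * (1 - 89.0 / 99.0))
        assert t > 0

    def test_upstream_term_has_opposite_sign(self):
        # falling behind the upstream neighbour (dxm shrinks) pushes forward
        t = torsion_term(None, 90.0, None, 100.0, 500.0, 11.0)
        assert t == pytest.approx(-500.0 * (1 - 89.0 / 79.0))
        assert t > 0

    def test_gap_at_bubble_capped(self):
        cap = 250.0
        t = torsion_term(11.0, None, 100.0, None, 500.0, 11.0, cap=cap)
        assert t == -cap

    def test_absent_neighbours_contribute_nothing(self):
        assert torsion_term(None, None, None, None, 500.0, 11.0) == 0.0


class TestLerEngagement:
    @pytest.mark.parametrize(
        "pos,expected", [(0, 0.0), (1000, 0.5), (2000, 1.0), (5000, 1.0)]
    )
    def test_linear_engagement(self, pos, expected):
        assert ler_engagement(pos, 2000) == expected


class TestRnaElementTerm:
    def test_structure_above_threshold_excluded(self):
        assert rna_element_term(-10.0, 0.0, 1.25, 0.6, -11.0) == 0.0

    def test_structure_below_threshold_promotes(self):
        assert rna_element_term(-15.0, 0.0, 1.25, 0.6, -11.0) == pytest.approx(18.75)

    def test_hybrid_always_opposes(self):
        assert rna_element_term(0.0, -10.0, 1.25, 0.6, -11.0) == pytest.approx(-6.0)

    def test_flat_tracks_and_nan_are_neutral(self):
        assert rna_element_term(0.0, 0.0, 1.25, 0.6, -11.0) == 0.0
        assert rna_element_term(math.nan, math.nan, 1.25, 0.6, -11.0) == 0.0


class TestInitiation:
    def test_promoter_proximal_polymerase_blocks(self, small_flat_landscape):
        p = pc.ModelParams(unit_length=2000, add_prob=125.0, dt=0.008)
        conv = Convoy(small_flat_landscape, p, np.random.default_rng(0))
        conv.place([20])
        for _ in range(100):
            assert not conv.attempt_initiation()
        assert not initiation_allowed([20], p.init_region)

    def test_zero_add_prob_never_initiates(self, small_flat_landscape):
        p = pc.ModelParams(unit_length=2000, add_prob=0.0)
        conv = Convoy(small_flat_landscape, p, np.random.default_rng(0))
        conv.run(5.0)
        assert conv.n == 0

    def test_engagement_rate_matches_binomial(self, small_flat_landscape):
        # empty unit, removal immediately after engagement: count attempts
        p = pc.ModelParams(unit_length=2000, add_prob=0.8, dt=0.008)
        conv = Convoy(small_flat_landscape, p, np.random.default_rng(42))
        n_steps = 100_000
        engaged = 0
        for _ in range(n_steps):
            if conv.attempt_initiation():
                engaged += 1
                conv._remove([0])
        expect = n_steps * 0.8 * 0.008
        sd = math.sqrt(n_steps * 0.0064 * (1 - 0.0064))
        assert abs(engaged - expect) < 3 * sd

    def test_anchors_recorded_at_engagement(self, small_flat_landscape):
        p = pc.ModelParams(unit_length=2000, add_prob=125.0, dt=0.008)
        conv = Convoy(small_flat_landscape, p, np.random.default_rng(1))
        conv.place([150])
        while not conv.attempt_initiation():
            pass
        assert conv.pos[0] == 0
        assert conv.xp_init[0] == 150.0
        assert conv.xm_init[1] == 150.0


class TestConvoyStep:
    def test_hard_core_exclusion_against_frozen_leader(self):
        land = EnergyLandscape.flat(2000)
        p = pc.ModelParams.variant(
            "stochastic", unit_length=2000, add_prob=0.0, seed=0
        )
        conv = Convoy(land, p, np.random.default_rng(3))
        conv.place([100, 100 + p.footprint])
        conv.frozen = {100 + p.footprint}
        blocked_before = conv.events["blocked_collisions"]
        conv.run(20.0)
        assert conv.pos[1] == 100 + p.footprint
        assert conv.pos[0] <= 100  # can only hold or backtrack
        assert conv.events["blocked_collisions"] > blocked_before

    def test_single_polymerase_mean_velocity(self):
        land = EnergyLandscape.flat(20000)
        p = pc.ModelParams.variant(
            "stochastic", unit_length=20000, add_prob=0.0
        )
        conv = Convoy(land, p, np.random.default_rng(7))
        conv.place([0])
        conv.run(300.0)
        v = conv.pos[0] / 300.0
        assert v == pytest.approx(0.078 * 0.9 + 0.922 * 50.0, rel=0.05)

    def test_backtrack_steps_logged_and_max_pos_kept(self):
        land = EnergyLandscape(np.zeros(2000), np.full(2000, -60.0))
        p = pc.ModelParams.variant(
            "rna_only", unit_length=2000, add_prob=0.0, s_struct=1.25
        )
        # hybrid drag of 36 nt/s makes net velocity ~ +10: backtracking common
        conv = Convoy(land, p, np.random.default_rng(9))
        conv.place([1000])
        conv.run(30.0)
        assert conv.events["backtrack_steps"] > 0
        assert conv.max_pos[0] >= conv.pos[0]

    def test_top1_shifts_anchor_by_full_turns(self):
        land = EnergyLandscape.flat(2000)
        p = pc.ModelParams(
            unit_length=2000, add_prob=0.0, p_top1=125.0, dt=0.008,
            torsion_on=True, ler_on=False, rna_elements_on=False,
        )
        conv = Convoy(land, p, np.random.default_rng(4))
        conv.place([100, 200])
        conv.xp_init[0] = 60.0  # overwound anchor vs 100-nt gap
        for _ in range(10):
            conv._top1(0)
        # 60 -> 70.5 -> 81 -> 91.5, then within one turn of the gap: stop
        assert conv.xp_init[0] == pytest.approx(91.5)
        # no action once the anchor already matches the gap
        conv.place([100, 100 + p.footprint])
        before = conv.xp_init[0]
        for _ in range(10):
            conv._top1(0)
        assert conv.xp_init[0] == before


class TestRunReplicates:
    def test_reproducible_and_seed_sensitive(self, small_flat_landscape):
        p = pc.ModelParams.variant(
            "stochastic", unit_length=2000, total_time=50, n_snapshots=10,
            burn_in=10,
        )
        a = run_replicates(small_flat_landscape, p, 2, base_seed=5)
        b = run_replicates(small_flat_landscape, p, 2, base_seed=5)
        for r in range(2):
            np.testing.assert_array_equal(a.snap_pos[r], b.snap_pos[r])
        assert not np.array_equal(a.snap_pos[0], a.snap_pos[1])
        c = run_replicates(small_flat_landscape, p, 2, base_seed=6)
        assert not np.array_equal(a.snap_pos[0], c.snap_pos[0])

    def test_snapshot_spacing(self, small_flat_landscape):
        p = pc.ModelParams.variant(
            "stochastic", unit_length=2000, total_time=2000, n_snapshots=200,
        )
        ens = run_replicates(small_flat_landscape, p, 1, base_seed=0)
        assert len(ens.snapshot_times) == 200
        np.testing.assert_allclose(np.diff(ens.snapshot_times), 10.0)

    def test_snapshots_ordered_with_footprint_gaps(self, small_flat_landscape):
        p = pc.ModelParams.variant(
            "full", unit_length=2000, ler_end=1000, total_time=120,
            n_snapshots=24, burn_in=20,
        )
        ens = run_replicates(small_flat_landscape, p, 2, base_seed=8)
        checked = 0
        for positions, max_positions in ens.iter_snapshots():
            assert np.all(positions <= max_positions)
            if positions.size > 1:
                assert np.all(np.diff(positions) >= p.footprint)
                checked += 1
        assert checked > 0

    def test_premature_termination_depletes_unit(self, small_flat_landscape):
        base = dict(unit_length=2000, ler_end=1000, total_time=150,
                    n_snapshots=30, burn_in=50)
        p_off = pc.ModelParams.variant("stochastic", **base)
        p_on = pc.ModelParams.variant("stochastic", p_term=0.5, **base)
        off = run_replicates(small_flat_landscape, p_off, 2, base_seed=2)
        on = run_replicates(small_flat_landscape, p_on, 2, base_seed=2)
        assert on.events["premature_terminations"] > 0
        assert off.events["premature_terminations"] == 0
        assert on.mean_polymerase_count() < off.mean_polymerase_count()

    def test_landscape_length_must_match(self, small_flat_landscape):
        p = pc.ModelParams(unit_length=7000)
        with pytest.raises(ValueError):
            run_replicates(small_flat_landscape, p, 1)
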