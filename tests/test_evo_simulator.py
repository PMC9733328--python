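"""Repeat-locus evolution: determinism, replay, slippage, and frame survival."""

import numpy as np
import pytest

from polyframe.evo_simulator import (
    SimParams,
    evolve,
    frame_survival,
    polyq_survival_closed_form,
    replay_events,
    stop_gain_hazard,
)

LOCUS = "CAG" * 20


class TestMechanics:
    def test_all_rates_zero_sequence_unchanged(self):
        traj = evolve(LOCUS, SimParams(mu=0.0, generations=25, n_replicates=3, seed=7))
        assert all(rep.final_seq == LOCUS for rep in traj.replicates)
        assert all(rep.events == [] for rep in traj.replicates)

    def test_same_seed_same_trajectory(self):
        p = SimParams(mu=0.001, sigma=0.01, delta=0.005, generations=100,
                      n_replicates=5, seed=42)
        a, b = evolve(LOCUS, p), evolve(LOCUS, p)
        for ra, rb in zip(a.replicates, b.replicates):
            assert ra.final_seq == rb.final_seq and ra.events == rb.events

    def test_forced_slippage_changes_length_by_one_unit_keeping_purity(self):
        traj = evolve("CAG" * 10, SimParams(mu=0.0, sigma=1.0, generations=1,
                                            n_replicates=20, seed=3))
        lengths = {len(r.final_seq) for r in traj.replicates}
        assert lengths <= {27, 33}
        assert 33 in lengths and 27 in lengths  # both directions occur in 20 draws
        for r in traj.replicates:
            n = len(r.final_seq) // 3
            assert r.final_seq == "CAG" * n  # pure repeat stays pure

    def test_event_log_replays_to_final_sequence(self):
        p = SimParams(mu=0.005, sigma=0.05, delta=0.02, generations=60,
                      n_replicates=10, seed=11)
        traj = evolve(LOCUS, p)
        assert any(r.events for r in traj.replicates)
        for r in traj.replicates:
            assert replay_events(LOCUS, r.events) == r.final_seq

    def test_snapshots_consistent_with_replay(self):
        p = SimParams(mu=0.01, generations=30, n_replicates=2, seed=5,
                      snapshot_every=10)
        traj = evolve(LOCUS, p)
        for r in traj.replicates:
            for gen, snap in r.snapshots.items():
                partial = [e for e in r.events if e[0] <= gen]
                assert replay_events(LOCUS, partial) == snap

    def test_length_constant_without_indel_processes(self):
        traj = evolve(LOCUS, SimParams(mu=0.02, generations=50, n_replicates=5, seed=2))
        assert all(len(r.final_seq) == len(LOCUS) for r in traj.replicates)

    def test_symmetric_slippage_preserves_expected_length(self):
        """+/-1-unit symmetric slippage is a martingale: mean final length
        equals the initial length within 3 SE."""
        n_rep, gens, sigma = 150, 40, 0.3
        traj = evolve("CAG" * 30, SimParams(mu=0.0, sigma=sigma, generations=gens,
                                            n_replicates=n_rep, seed=123))
        finals = np.array([len(r.final_seq) for r in traj.replicates], dtype=float)
        se = finals.std(ddof=1) / np.sqrt(n_rep)
        assert abs(finals.mean() - 90) <= 3 * max(se, 1e-9)

    def test_invalid_params_rejected_before_simulation(self):
        with pytest.raises(ValueError):
            SimParams(mu=1.5)
        with pytest.raises(ValueError):
            SimParams(mu=0.1, generations=0)
        with pytest.raises(ValueError):
            SimParams(mu=0.1, dup_len=(2, 10))


class TestFrameSurvival:
    def test_mu_zero_survival_one_everywhere(self):
        traj = evolve(LOCUS, SimParams(mu=0.0, generations=20, n_replicates=10, seed=1))
        for frame in ("polyQ", "polyS", "polyA"):
            assert np.all(frame_survival(traj, frame).survival == 1.0)

    def test_unknown_frame_rejected(self):
        traj = evolve(LOCUS, SimParams(mu=0.0, generations=2, n_replicates=1, seed=1))
        with pytest.raises(ValueError):
            frame_survival(traj, "polyW")

    def test_survival_monotone_non_increasing(self):
        traj = evolve("CAG" * 40, SimParams(mu=0.002, generations=80,
                                            n_replicates=200, seed=9))
        for frame in ("polyQ", "polyS", "polyA"):
            s = frame_survival(traj, frame).survival
            assert np.all(np.diff(s) <= 1e-12)

    def test_polyq_decays_while_syn_frames_dominate(self):
        traj = evolve("CAG" * 40, SimParams(mu=0.002, generations=80,
                                            n_replicates=200, seed=9))
        q = frame_survival(traj, "polyQ").survival
        s = frame_survival(traj, "polyS").survival
        a = frame_survival(traj, "polyA").survival
        assert np.all(s >= q) and np.all(a >= q)
        assert q[-1] < 0.7  # substantial polyQ loss under these rates

    def test_polyq_survival_tracks_single_hit_closed_form(self):
        n_units, mu = 60, 0.001
        traj = evolve("CAG" * n_units, SimParams(mu=mu, generations=60,
                                                 n_replicates=400, seed=77))
        curve = frame_survival(traj, "polyQ")
        for t in range(0, 61, 10):
            expected = polyq_survival_closed_form(n_units, mu, t)
            tol = 3 * max(curve.se[t], 1e-6)
            assert abs(curve.survival[t] - expected) <= tol


class TestHazard:
    def test_cag_polyq_hazard_is_mu_over_three_unbiased(self):
        mu = 0.004
        assert stop_gain_hazard("CAG", "polyQ", mu) == pytest.approx(mu / 3)

    @pytest.mark.parametrize("frame", ["polyS", "polyA"])
    def test_cag_synonymous_frames_cannot_gain_a_stop_in_one_hit(self, frame):
        assert stop_gain_hazard("CAG", frame, 0.01) == 0.0

    def test_transition_bias_concentrates_hazard_on_c_to_t(self):
        mu = 0.003
        # C->T is a transition: kappa > 1 raises the polyQ hazard above mu/3
        assert stop_gain_hazard("CAG", "polyQ", mu, kappa=4.0) > mu / 3
        assert stop_gain_hazard("CAG", "polyQ", mu, kappa=4.0) == pytest.approx(
            mu * 4 / 6
        )

    def test_unknown_frame_rejected(self):
        with pytest.raises(ValueError):
            stop_gain_hazard("CAG", "polyX", 0.01)

    def test_register_indexing_matches_labels(self):
        assert stop_gain_hazard("CAG", 0, 0.01) == stop_gain_hazard("CAG", "polyQ", 0.01)
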