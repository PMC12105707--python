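"""Stability statistics: break rates, spacing, events, length summaries."""

import numpy as np
import pytest

from cptube.geometry import build_nanotube
from cptube.hbonds import CountSeries, hbond_timeseries
from cptube.stability import (InsufficientDataError, broken_bonds_per_ns,
                              detect_dissociation_events,
                              length_to_unimer_count,
                              mean_interunimer_distance, summarize_lengths)
from cptube.synthetic import (BondStateSeries, jitter_trajectory,
                              script_cap_unbinding, simulate_bond_states,
                              stationary_formed_fraction)


def _series(presence, labels=None, frame_dt=0.1):
    presence = np.asarray(presence, dtype=bool)
    if labels is None:
        labels = np.array(["core"] * presence.shape[0])
    return BondStateSeries(presence=presence, labels=np.asarray(labels),
                           frame_dt=frame_dt)


class TestBrokenBondsPerNs:
    def test_all_present_zero_rate(self):
        rep = broken_bonds_per_ns(_series(np.ones((5, 100))))
        assert rep.bhb_total == 0.0
        assert rep.mean_count_total == 5.0

    def test_alternating_bond_rate(self):
        # One bond alternating present/absent over 101 frames at 0.1 ns:
        # 50 present->absent transitions in 10 ns -> 5.0 events/ns.
        presence = np.zeros((1, 101), dtype=bool)
        presence[0, ::2] = True
        rep = broken_bonds_per_ns(_series(presence))
        assert rep.bhb_total == pytest.approx(5.0)

    def test_additivity_exact(self):
        rng = np.random.default_rng(0)
        presence = rng.random((56, 500)) < 0.8
        labels = np.array(["cap"] * 16 + ["core"] * 40)
        rep = broken_bonds_per_ns(_series(presence, labels))
        assert rep.bhb_total == rep.bhb_cap + rep.bhb_core

    def test_single_frame_insufficient(self):
        with pytest.raises(InsufficientDataError):
            broken_bonds_per_ns(_series(np.ones((3, 1))))

    def test_flicker_window_monotone(self):
        rng = np.random.default_rng(1)
        presence = rng.random((20, 2000)) < 0.7
        series = _series(presence)
        rates = [broken_bonds_per_ns(series, flicker_window=w).bhb_total
                 for w in (0, 1, 2, 5, 10, 50)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_flicker_window_suppresses_single_frame_blips(self):
        presence = np.ones((1, 100), dtype=bool)
        presence[0, 50] = False              # 1-frame blip
        presence[0, 80:90] = False           # sustained break
        series = _series(presence)
        assert broken_bonds_per_ns(series, 0).bhb_total == \
            pytest.approx(2 / 9.9)
        assert broken_bonds_per_ns(series, 5).bhb_total == \
            pytest.approx(1 / 9.9)

    @pytest.mark.parametrize("k_break", [0.005, 0.05, 0.5])
    def test_markov_recovery_unbiased(self, k_break):
        # Pooled over replicates, the raw break-event rate estimates
        # n_bonds * k_break * pi_formed within 3 standard errors.  Frame
        # spacing is fine relative to 1/k so discretization bias is
        # negligible against the statistical error.
        k_reform, dt, frames, reps = 10 * k_break, 0.01, 5_000, 7
        pi = stationary_formed_fraction(k_break, k_reform)
        expected = 56 * k_break * pi
        estimates = []
        for rep in range(reps):
            bs = simulate_bond_states(16, 40, k_break, k_break, k_reform,
                                      frame_dt=dt, n_frames=frames,
                                      seed=100 + rep)
            estimates.append(broken_bonds_per_ns(bs).bhb_total)
        p = 1.0 - np.exp(-k_break * dt)
        n_formed = 56 * (frames - 1) * pi * reps
        se = np.sqrt(n_formed * p * (1 - p)) / (reps * (frames - 1) * dt)
        assert abs(np.mean(estimates) - expected) < 3 * se

    def test_cap_core_rates_ordered_when_simulated_ordered(self):
        # Capping bonds simulated less stable than core bonds: the
        # estimated decomposition must preserve the ordering, raw and
        # per-bond (bond populations differ 16 vs 40).
        bs = simulate_bond_states(16, 40, k_break_cap=0.2,
                                  k_break_core=0.02, k_reform=2.0,
                                  frame_dt=0.01, n_frames=10_000, seed=21)
        rep = broken_bonds_per_ns(bs)
        assert rep.bhb_cap > rep.bhb_core
        assert rep.bhb_cap_per_bond > rep.bhb_core_per_bond


class TestMeanInterunimerDistance:
    def test_ideal_octamer_spacing(self, ideal_octamer):
        traj = jitter_trajectory(ideal_octamer, 5, 0.0, seed=0)
        assert mean_interunimer_distance(traj) == pytest.approx(4.85)

    def test_rotation_invariant(self, ideal_octamer):
        from scipy.spatial.transform import Rotation
        from cptube.synthetic import Trajectory
        traj = jitter_trajectory(ideal_octamer, 5, 0.1, seed=4)
        rot = Rotation.from_euler("yx", [72, 15], degrees=True).as_matrix()
        moved = Trajectory(frames=traj.frames @ rot.T + 5.0,
                           frame_dt=traj.frame_dt,
                           n_unimers=traj.n_unimers,
                           n_residues=traj.n_residues)
        assert mean_interunimer_distance(moved) == \
            pytest.approx(mean_interunimer_distance(traj), abs=1e-9)

    def test_jittered_spacing_near_ideal(self, ideal_octamer):
        # Centroid averaging over 32 sites suppresses 0.2 A atomic jitter;
        # noise inflation of the distance is O(sigma^2 / d).
        traj = jitter_trajectory(ideal_octamer, 1000, 0.2, seed=11)
        assert mean_interunimer_distance(traj) == pytest.approx(4.85,
                                                                abs=0.02)

    def test_single_ring_rejected(self):
        model = build_nanotube(n_unimers=1)
        traj = jitter_trajectory(model, 3, 0.0, seed=0)
        with pytest.raises(ValueError):
            mean_interunimer_distance(traj)


class TestDissociationDetector:
    def _count_series(self, totals, frame_dt=0.1):
        totals = np.asarray(totals)
        return CountSeries(total=totals, cap=np.zeros_like(totals),
                           core=totals, frame_dt=frame_dt)

    def test_constant_series_no_events(self):
        assert detect_dissociation_events(
            self._count_series(np.full(500, 56))) == []

    def test_step_drop_detected_with_magnitude_eight(self):
        totals = np.concatenate([np.full(500, 56), np.full(500, 48)])
        events = detect_dissociation_events(self._count_series(totals))
        assert len(events) == 1
        frame, magnitude = events[0]
        assert frame == 500
        assert magnitude == pytest.approx(8.0)

    def test_single_frame_dip_ignored(self):
        totals = np.full(500, 56)
        totals[250] = 47
        events = detect_dissociation_events(self._count_series(totals),
                                            persistence=50)
        assert events == []

    def test_short_series_insufficient(self):
        with pytest.raises(InsufficientDataError):
            detect_dissociation_events(self._count_series(np.full(20, 56)),
                                       persistence=50)

    def test_end_to_end_scripted_unbinding(self, ideal_octamer):
        traj = jitter_trajectory(ideal_octamer, 300, 0.0, seed=0)
        traj = script_cap_unbinding(traj, 150, 10.0)
        series, _ = hbond_timeseries(traj)
        events = detect_dissociation_events(series)
        assert len(events) == 1
        assert events[0][0] == 150
        assert events[0][1] == pytest.approx(8.0)


class TestLengths:
    def test_degenerate_mean(self):
        summary = summarize_lengths([157.0, 157.0, 157.0])
        assert summary.mean_nm == pytest.approx(157.0)
        assert summary.sd_nm == pytest.approx(0.0)
        assert summary.n_tubes == 3

    def test_mean_within_range(self):
        rng = np.random.default_rng(5)
        lengths = rng.normal(105.0, 20.0, size=200).clip(min=10.0)
        summary = summarize_lengths(lengths)
        assert lengths.min() <= summary.mean_nm <= lengths.max()
        assert summary.hist_counts.sum() == 200

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            summarize_lengths([])

    def test_tem_length_to_unimer_count(self):
        # A 157 nm tube at the 0.485 nm stacking period holds
        # round(157 / 0.485) = 324 unimers.
        assert length_to_unimer_count(157.0, 0.485) == 324

    def test_one_period_is_one_unimer(self):
        assert length_to_unimer_count(0.485, 0.485) == 1
        assert length_to_unimer_count(0.1, 0.485) == 1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            length_to_unimer_count(-5.0)
        with pytest.raises(ValueError):
            length_to_unimer_count(100.0, 0.0)
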