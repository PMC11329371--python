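"""Synthetic photon-stream generator: microtimes, streams, trap dynamics."""

import numpy as np
import pytest

from fretfluor.photon_sim import (
    SimConfig,
    TrapParams,
    attach_trajectories,
    sample_nanotime,
    simulate_level,
    simulate_stream,
    simulate_trap_trajectory,
    stokes_einstein_diffusion,
)
from fretfluor.stream import GREEN_CHANNELS, AcquisitionMeta


class TestSampleNanotime:
    def test_values_on_quantized_grid_within_period(self, meta, rng):
        t = sample_nanotime(1.5, meta.irf, meta.pulse_period, rng,
                            meta.microtime_bin, size=5000)
        assert np.all(t >= 0)
        assert np.all(t < meta.pulse_period)
        steps = t / meta.microtime_bin
        assert np.allclose(steps, np.round(steps), atol=1e-6)

    def test_zero_lifetime_collapses_to_irf(self, meta, rng):
        t = sample_nanotime(0.0, meta.irf, meta.pulse_period, rng,
                            meta.microtime_bin, size=20000)
        assert np.mean(t) == pytest.approx(meta.irf.center, abs=0.02)
        assert np.std(t) == pytest.approx(meta.irf.width_sigma, abs=0.02)

    def test_mean_shift_equals_lifetime(self, meta, rng):
        tau = 1.2  # short enough that period wrap-around is negligible
        t = sample_nanotime(tau, meta.irf, meta.pulse_period, rng,
                            meta.microtime_bin, size=50000)
        assert np.mean(t) == pytest.approx(meta.irf.center + tau, abs=0.03)

    def test_negative_lifetime_rejected(self, meta, rng):
        with pytest.raises(ValueError):
            sample_nanotime(-1.0, meta.irf, meta.pulse_period, rng)


class TestSimulateLevel:
    def test_exact_photon_count(self, registry, meta, rng):
        s = simulate_level(registry["AB12"], 2500, meta, rng)
        assert len(s) == 2500

    def test_channel_branching_matches_construct(self, registry, meta, rng):
        c = registry["AB12"]
        s = simulate_level(c, 40000, meta, rng)
        green_frac = np.mean(s.channel_mask(GREEN_CHANNELS))
        e, sc = c.fret_E, c.acceptor_brightness_scale
        expected = (1 - e) / ((1 - e) + e * sc)
        assert green_frac == pytest.approx(expected, abs=0.01)

    def test_arrival_rate_matches_brightness(self, registry, meta, rng):
        c = registry["AB12"]
        n = 20000
        s = simulate_level(c, n, meta, rng)
        rate_ms = (c.green_brightness + c.red_brightness) * meta.excitation_power
        expected_span = n / rate_ms
        assert s.macrotime_ms[-1] == pytest.approx(expected_span, rel=0.05)


class TestSimulateStream:
    def _config(self, **kw):
        base = dict(mixture=[("AB10", 0.5), ("AB14", 0.5)], total_duration=10.0,
                    seed=7, event_rate=0.5, dwell_mean=0.8)
        base.update(kw)
        return SimConfig(**base)

    def test_same_seed_reproduces_stream(self, registry):
        a = simulate_stream(registry, self._config())
        b = simulate_stream(registry, self._config())
        np.testing.assert_array_equal(a.macrotime_ms, b.macrotime_ms)
        np.testing.assert_array_equal(a.microtime_ns, b.microtime_ns)
        np.testing.assert_array_equal(a.channel, b.channel)

    def test_different_seed_differs(self, registry):
        a = simulate_stream(registry, self._config())
        b = simulate_stream(registry, self._config(seed=8))
        assert len(a) != len(b) or not np.array_equal(a.macrotime_ms, b.macrotime_ms)

    def test_stream_sorted_with_full_truth_cover(self, registry):
        s = simulate_stream(registry, self._config())
        assert np.all(np.diff(s.macrotime_ms) >= 0)
        assert s.truth is not None
        assert len(s.truth.event_id) == len(s)
        labels = set(s.truth.event_label)
        assert labels <= {"AB10", "AB14"}

    def test_background_only_rate(self, registry):
        cfg = SimConfig(mixture=(), total_duration=20.0, seed=3,
                        background_rates=(400.0, 400.0, 400.0, 400.0))
        s = simulate_stream(registry, cfg)
        # 4 channels x 400 / s over 20 s
        assert len(s) == pytest.approx(32000, rel=0.05)
        assert np.all(s.truth.event_id == -1)

    def test_in_trap_rate_above_background(self, registry):
        cfg = self._config(total_duration=30.0, event_rate=1.0)
        s = simulate_stream(registry, cfg)
        in_trap = s.truth.event_id >= 0
        assert in_trap.sum() > 0
        trap_time = np.sum(s.truth.event_stop_ms - s.truth.event_start_ms)
        trap_rate = in_trap.sum() / trap_time  # counts / ms
        bg_rate = sum(cfg.background_rates) / 1e3
        assert trap_rate > 3 * bg_rate

    def test_mixture_fractions_must_normalize(self):
        with pytest.raises(ValueError):
            SimConfig(mixture=[("AB10", 0.5), ("AB14", 0.2)], seed=0)


class TestTrapDynamics:
    def test_stationary_variance_matches_closed_form(self, rng):
        d, g, dt = 50.0, 0.5, 0.1
        traj = simulate_trap_trajectory(d, g, dt, 200000, 0.0, rng)
        expected = 2 * d * 1e3 * dt / (1 - (1 - g) ** 2)
        var = traj.true_position.var(axis=0)
        assert np.allclose(var, expected, rtol=0.05)
        assert traj.stationary_variance_nm2 == pytest.approx(expected)

    def test_zero_diffusion_stays_at_origin(self, rng):
        traj = simulate_trap_trajectory(0.0, 0.5, 0.1, 1000, 0.0, rng)
        assert np.all(traj.true_position == 0)

    def test_localization_noise_inflates_estimates_only(self, rng):
        traj = simulate_trap_trajectory(50.0, 0.5, 0.1, 50000, 30.0, rng)
        true_var = traj.true_position.var(axis=0).mean()
        est_var = traj.estimated_position.var(axis=0).mean()
        assert est_var > true_var

    def test_invalid_gain_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_trap_trajectory(50.0, 0.0, 0.1, 100, 0.0, rng)

    def test_index_at_maps_times(self, rng):
        traj = simulate_trap_trajectory(50.0, 0.5, 0.1, 100, 0.0, rng, start_ms=5.0)
        assert traj.index_at(5.0) == 0
        assert traj.index_at(5.25) == 2


class TestStokesEinstein:
    def test_representative_value(self):
        # a ~2 nm construct in water at 20 C diffuses at ~1e2 um^2/s
        d = stokes_einstein_diffusion(2.0)
        assert d == pytest.approx(107.0, rel=0.02)

    def test_inverse_radius_scaling(self):
        assert stokes_einstein_diffusion(1.0) == pytest.approx(
            2 * stokes_einstein_diffusion(2.0)
        )


class TestAttachTrajectories:
    def test_one_trajectory_per_event(self, registry):
        cfg = SimConfig(mixture=[("AB10", 1.0)], total_duration=20.0, seed=11,
                        event_rate=0.5, dwell_mean=0.5)
        s = simulate_stream(registry, cfg)
        s = attach_trajectories(s, registry, TrapParams(seed=1))
        assert set(s.trajectories) == set(range(s.truth.n_events))
        for eid, traj in s.trajectories.items():
            span = s.truth.event_stop_ms[eid] - s.truth.event_start_ms[eid]
            assert traj.times_ms[0] == pytest.approx(s.truth.event_start_ms[eid])
            assert traj.times_ms[-1] >= s.truth.event_start_ms[eid] + span - 0.2

    def test_bound_events_diffuse_slower(self, registry):
        cfg = SimConfig(mixture=[("AB10", 1.0)], total_duration=60.0, seed=5,
                        event_rate=1.0, dwell_mean=0.5, bound_fraction=0.5)
        s = simulate_stream(registry, cfg)
        s = attach_trajectories(s, registry, TrapParams(seed=2))
        bound_d = [s.trajectories[e].diffusion_D
                   for e in range(s.truth.n_events) if s.truth.event_bound[e]]
        free_d = [s.trajectories[e].diffusion_D
                  for e in range(s.truth.n_events) if not s.truth.event_bound[e]]
        assert bound_d and free_d
        assert max(bound_d) < min(free_d)

    def test_requires_ground_truth(self, registry, meta, rng):
        from fretfluor.stream import PhotonStream

        bare = PhotonStream(np.array([0.1, 0.2]), np.array([1.0, 1.0]),
                            np.array([0, 0], dtype=np.uint8), meta=meta)
        with pytest.raises(ValueError):
            attach_trajectories(bare, registry)
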