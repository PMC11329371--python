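"""Per-level observables: brightness, FRET efficiency, lifetime, confinement."""

import numpy as np
import pytest

from fretfluor.level_stats import (
    FretCorrections,
    LevelStatsOptions,
    fit_lifetime_mle,
    fret_efficiency,
    group_photons,
    level_brightness,
    position_sigma,
    signatures_to_frame,
    summarize_levels,
)
from fretfluor.photon_sim import sample_nanotime, simulate_level, simulate_trap_trajectory
from fretfluor.segmentation import BackgroundEstimate, Level
from fretfluor.level_stats import PhotonGroup


def _level(counts, duration_ms=1000.0, start=0.0):
    counts = np.asarray(counts)
    return Level(level_id=0, start_ms=start, stop_ms=start + duration_ms,
                 counts=counts, index_range=(0, int(counts.sum())))


def _background(rates_per_s):
    return BackgroundEstimate(rates=np.asarray(rates_per_s, dtype=float), chosen_K=1)


class TestLevelBrightness:
    def test_background_subtraction_arithmetic(self):
        # 1000 ms level; 3000 G_par counts with 500/s background:
        # net green = (3000+3000-500-500)/1000ms/100uW
        lv = _level([3000, 3000, 1000, 1000])
        bg = _background([500.0] * 4)
        _, green, red, clamped = level_brightness(lv, bg, power=100.0)
        assert green == pytest.approx((6000 - 1000) / 1000.0 / 100.0)
        assert red == pytest.approx((2000 - 1000) / 1000.0 / 100.0)
        assert not clamped

    def test_negative_net_counts_clamp_and_flag(self):
        lv = _level([100, 100, 400, 400])
        bg = _background([500.0] * 4)
        _, green, red, clamped = level_brightness(lv, bg, power=100.0)
        assert green == 0.0
        assert clamped

    def test_rejects_nonpositive_power(self):
        with pytest.raises(ValueError):
            level_brightness(_level([1, 1, 1, 1]), _background([0.0] * 4), power=0.0)


class TestFretEfficiency:
    def test_neutral_corrections_give_proximity_ratio(self):
        assert fret_efficiency(0.3, 0.1) == pytest.approx(0.25)

    def test_both_zero_is_undefined(self):
        assert np.isnan(fret_efficiency(0.0, 0.0))

    def test_gamma_rescales_donor_term(self):
        corr = FretCorrections(gamma=2.0)
        assert fret_efficiency(0.3, 0.1, corr) == pytest.approx(0.1 / (0.1 + 0.6))

    def test_crosstalk_subtraction(self):
        corr = FretCorrections(crosstalk_alpha=0.1)
        a = 0.1 - 0.1 * 0.3
        assert fret_efficiency(0.3, 0.1, corr) == pytest.approx(a / (a + 0.3))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            fret_efficiency(-0.1, 0.1)


class TestLifetimeMLE:
    def test_recovers_simulated_lifetime(self, meta):
        rng = np.random.default_rng(42)
        tau = 0.8
        t = sample_nanotime(tau, meta.irf, meta.pulse_period, rng,
                            meta.microtime_bin, size=10000)
        fit = fit_lifetime_mle(t, meta.irf, meta.pulse_period, meta.microtime_bin)
        assert fit.converged
        assert fit.tau_ns == pytest.approx(tau, abs=0.03)
        assert fit.ci_ns[0] < tau < fit.ci_ns[1]

    def test_refuses_underpowered_fits(self, meta):
        fit = fit_lifetime_mle(np.ones(10), meta.irf, meta.pulse_period,
                               meta.microtime_bin)
        assert not fit.converged
        assert np.isnan(fit.tau_ns)
        assert fit.flag == "too_few_photons"

    def test_flat_background_handled_when_declared(self, meta):
        rng = np.random.default_rng(7)
        tau = 1.2
        sig = sample_nanotime(tau, meta.irf, meta.pulse_period, rng,
                              meta.microtime_bin, size=6000)
        bg = rng.uniform(0, meta.pulse_period, 4000)
        bg = np.floor(bg / meta.microtime_bin) * meta.microtime_bin
        t = np.concatenate([sig, bg])
        fit = fit_lifetime_mle(t, meta.irf, meta.pulse_period, meta.microtime_bin,
                               background_fraction=0.4)
        assert fit.tau_ns == pytest.approx(tau, abs=0.05)

    def test_undeclared_background_biases_upward(self, meta):
        # documents why the analysis mixes a flat floor into the model
        rng = np.random.default_rng(7)
        tau = 1.2
        sig = sample_nanotime(tau, meta.irf, meta.pulse_period, rng,
                              meta.microtime_bin, size=6000)
        bg = rng.uniform(0, meta.pulse_period, 4000)
        t = np.concatenate([sig, np.floor(bg / meta.microtime_bin) * meta.microtime_bin])
        naive = fit_lifetime_mle(t, meta.irf, meta.pulse_period, meta.microtime_bin)
        assert naive.tau_ns > tau + 0.2


class TestGroupPhotons:
    def test_floor_division_into_exact_groups(self):
        lv = Level(0, 0.0, 100.0, np.array([2500, 0, 0, 0]), (100, 2600))
        groups = group_photons(lv, M=1000)
        assert len(groups) == 2
        assert groups[0].index_range == (100, 1100)
        assert groups[1].index_range == (1100, 2100)
        assert all(g.n_photons == 1000 for g in groups)

    def test_rejects_invalid_group_size(self):
        lv = Level(0, 0.0, 100.0, np.array([10, 0, 0, 0]), (0, 10))
        with pytest.raises(ValueError):
            group_photons(lv, M=0)


class TestPositionSigma:
    def test_sigma_over_group_span(self, rng, meta):
        traj = simulate_trap_trajectory(100.0, 0.5, 0.1, 5000, 30.0, rng)
        from fretfluor.stream import PhotonStream

        mac = np.sort(rng.uniform(0, 490.0, 2000))
        stream = PhotonStream(mac, np.zeros(2000), np.zeros(2000, dtype=np.uint8),
                              meta=meta)
        group = PhotonGroup(0, 0, (0, 2000))
        pt = position_sigma(traj, group, stream, event_id=3)
        expected = np.sqrt(traj.stationary_variance_nm2 + 30.0**2)
        assert pt.sigma_x == pytest.approx(expected, rel=0.15)
        assert pt.sigma_y == pytest.approx(expected, rel=0.15)
        assert pt.event_id == 3

    def test_too_short_span_rejected(self, rng, meta):
        traj = simulate_trap_trajectory(100.0, 0.5, 0.1, 5000, 30.0, rng)
        from fretfluor.stream import PhotonStream

        mac = np.array([10.0, 10.01])
        stream = PhotonStream(mac, np.zeros(2), np.zeros(2, dtype=np.uint8), meta=meta)
        with pytest.raises(ValueError):
            position_sigma(traj, PhotonGroup(0, 0, (0, 2)), stream)


class TestSummarizeLevels:
    def test_signature_matches_construct_truth(self, registry, meta, rng):
        c = registry["AB12"]
        stream = simulate_level(c, 20000, meta, rng)
        lv = Level(0, float(stream.macrotime_ms[0]), float(stream.macrotime_ms[-1]),
                   np.bincount(stream.channel, minlength=4), (0, len(stream)))
        bg = _background([0.0] * 4)
        sigs = summarize_levels([lv], stream, bg)
        assert len(sigs) == 1
        sig = sigs[0]
        assert sig.green_brightness == pytest.approx(c.green_brightness, rel=0.05)
        assert sig.red_brightness == pytest.approx(c.red_brightness, rel=0.05)
        assert sig.donor_lifetime == pytest.approx(c.donor_lifetime, abs=0.05)
        e_expected = c.red_brightness / (c.red_brightness + c.green_brightness)
        assert sig.fret_E == pytest.approx(e_expected, abs=0.02)

    def test_frame_has_exportable_schema(self, registry, meta, rng):
        stream = simulate_level(registry["AB12"], 5000, meta, rng)
        lv = Level(0, float(stream.macrotime_ms[0]), float(stream.macrotime_ms[-1]),
                   np.bincount(stream.channel, minlength=4), (0, len(stream)))
        frame = signatures_to_frame(summarize_levels([lv], stream, _background([0.0] * 4)))
        for col in ("level_id", "green_b", "red_b", "E", "tau_ns", "n_photons",
                    "duration_ms", "flags"):
            assert col in frame.columns
        assert len(frame) == 1

    def test_underpowered_lifetime_flagged_not_fatal(self, registry, meta, rng):
        stream = simulate_level(registry["AB12"], 120, meta, rng)
        lv = Level(0, float(stream.macrotime_ms[0]), float(stream.macrotime_ms[-1]),
                   np.bincount(stream.channel, minlength=4), (0, len(stream)))
        opts = LevelStatsOptions(min_fit_photons=1000)
        sigs = summarize_levels([lv], stream, _background([0.0] * 4), opts)
        assert np.isnan(sigs[0].donor_lifetime)
        assert "lifetime_too_few_photons" in sigs[0].flags
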