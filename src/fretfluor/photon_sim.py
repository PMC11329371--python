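"""Synthetic photon-stream and feedback-trap simulator.

Generates data with the statistical structure the analysis assumes:

* trapping events arrive as a Poisson process (one molecule at a time);
* within an event, green/red photon rates follow the construct's donor
  brightness and FRET efficiency ``E``, with Poisson arrival statistics;
* TCSPC microtimes are exponential decays convolved with the IRF and
  wrapped on the pulse period, with the donor lifetime shortened to
  ``tau_D0 * (1 - E)`` under FRET;
* the acceptor can photobleach (exponential waiting time) or blink,
  reverting the construct to donor-only emission;
* trapped molecules undergo discrete feedback-damped Brownian motion whose
  diffusion constant follows Stokes-Einstein scaling with the construct's
  hydrodynamic radius, so larger (target-bound) complexes are more tightly
  confined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import lfilter

from .registry import ConstructSpec, Registry
from .stream import (
    AcquisitionMeta,
    IRFModel,
    PhotonStream,
    StreamTruth,
)

__all__ = [
    "SimConfig",
    "TrapParams",
    "TrapTrajectory",
    "sample_nanotime",
    "simulate_stream",
    "simulate_level",
    "simulate_trap_trajectory",
    "attach_trajectories",
    "stokes_einstein_diffusion",
]

_KB = 1.380649e-23  # J/K
_WATER_VISCOSITY = 1.002e-3  # Pa s at 293 K


def stokes_einstein_diffusion(radius_nm: float, temperature_K: float = 293.15) -> float:
    """Diffusion constant (um^2 s^-1) of a sphere of given radius in water."""
    if radius_nm <= 0:
        raise ValueError("radius must be > 0")
    d_m2_s = _KB * temperature_K / (6.0 * np.pi * _WATER_VISCOSITY * radius_nm * 1e-9)
    return d_m2_s * 1e12  # m^2/s -> um^2/s


def _quantize(t_ns: np.ndarray, bin_width: float) -> np.ndarray:
    # left bin edge; small epsilon guards exact-multiple float representations
    return np.floor(t_ns / bin_width + 1e-9) * bin_width


def sample_nanotime(
    lifetime_tau: float,
    irf: IRFModel,
    pulse_period: float,
    rng: np.random.Generator,
    microtime_bin: float = 0.016,
    size: Optional[int] = None,
    extra_delay: Optional[np.ndarray] = None,
) -> np.ndarray | float:
    """Draw TCSPC microtimes: exponential(tau) + IRF, wrapped mod the period.

    For ``tau = 0`` the output distribution collapses to the IRF itself.
    ``extra_delay`` adds per-photon delays (used for acceptor emission,
    which inherits the donor transfer delay).
    """
    if lifetime_tau < 0:
        raise ValueError("lifetime_tau must be >= 0")
    scalar = size is None
    n = 1 if scalar else int(size)
    decay = rng.exponential(lifetime_tau, n) if lifetime_tau > 0 else np.zeros(n)
    t = decay + irf.sample(n, rng, pulse_period)
    if extra_delay is not None:
        t = t + extra_delay
    t = np.mod(t, pulse_period)
    t = _quantize(t, microtime_bin)
    # guard against float round-up at the period boundary
    t = np.minimum(t, pulse_period - microtime_bin)
    return float(t[0]) if scalar else t


@dataclass
class SimConfig:
    """Study conditions for a simulated acquisition.

    Defaults emulate the experimental regime of trap measurements on
    FRET-barcode mixtures: ~25-30 kHz in-trap photon rates (set by the
    construct brightness and the 100 uW default excitation power), seconds-
    scale trap residence, and a kHz-scale background per channel.
    """

    mixture: Sequence[tuple] = ()  # (label, molar fraction)
    event_rate: float = 0.5  # trapping events s^-1
    dwell_mean: float = 1.0  # s, exponential trap residence
    background_rates: Sequence[float] = (500.0, 500.0, 500.0, 500.0)  # counts s^-1
    bleach_rate: float = 0.0  # s^-1, acceptor photobleaching
    blink_on_rate: float = 0.0  # s^-1, dark -> emissive
    blink_off_rate: float = 0.0  # s^-1, emissive -> dark
    total_duration: float = 30.0  # s
    seed: int = 0
    bound_fraction: float = 0.0  # probability an event is target-bound
    acceptor_tau: float = 1.0  # ns, acceptor emission decay

    def __post_init__(self) -> None:
        if self.mixture:
            total = sum(f for _, f in self.mixture)
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ValueError(f"mixture fractions must sum to 1 (got {total})")
        for name in ("event_rate", "bleach_rate", "blink_on_rate", "blink_off_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(r < 0 for r in self.background_rates):
            raise ValueError("background rates must be >= 0")
        if self.dwell_mean <= 0:
            raise ValueError("dwell_mean must be > 0")
        if not 0 <= self.bound_fraction <= 1:
            raise ValueError("bound_fraction must be in [0, 1]")


def _emission_segments(
    start: float, stop: float, bleach: float, sim: SimConfig, rng: np.random.Generator
) -> list[tuple[float, float, bool]]:
    """Split an event into (t0, t1, acceptor_active) segments.

    Acceptor activity ends at the bleach time; before it, an optional
    two-state blinking telegraph (emissive/dark) modulates activity.
    """
    pre_stop = min(stop, bleach)
    segments: list[tuple[float, float, bool]] = []
    if sim.blink_on_rate > 0 and sim.blink_off_rate > 0:
        t, on = start, True
        while t < pre_stop:
            rate = sim.blink_off_rate if on else sim.blink_on_rate
            dur = rng.exponential(1000.0 / rate)
            seg_end = min(t + dur, pre_stop)
            segments.append((t, seg_end, on))
            t, on = seg_end, not on
    elif pre_stop > start:
        segments.append((start, pre_stop, True))
    if stop > pre_stop:
        segments.append((pre_stop, stop, False))
    return segments


def simulate_stream(
    registry: Registry,
    sim: SimConfig,
    meta: Optional[AcquisitionMeta] = None,
) -> PhotonStream:
    """Simulate a full acquisition of trapping events over a background.

    Events arrive sequentially (at most one molecule trapped at a time),
    each drawn from the configured mixture; photons carry truth labels.
    """
    meta = meta or AcquisitionMeta()
    rng = np.random.default_rng(sim.seed)
    for label, _ in sim.mixture:
        if label not in registry:
            raise ValueError(f"mixture label {label!r} not in registry")

    total_ms = sim.total_duration * 1e3
    mac: list[np.ndarray] = []
    mic: list[np.ndarray] = []
    chan: list[np.ndarray] = []
    evid: list[np.ndarray] = []

    event_label: list[str] = []
    event_bound: list[bool] = []
    event_start: list[float] = []
    event_stop: list[float] = []
    event_bleach: list[float] = []

    labels = [l for l, _ in sim.mixture]
    fracs = np.array([f for _, f in sim.mixture], dtype=float)

    t = 0.0
    if total_ms > 0 and sim.event_rate > 0 and labels:
        while True:
            start = t + rng.exponential(1e3 / sim.event_rate)
            if start >= total_ms:
                break
            stop = min(start + rng.exponential(sim.dwell_mean * 1e3), total_ms)
            label = labels[rng.choice(len(labels), p=fracs / fracs.sum())]
            construct = registry[label]
            bound = bool(rng.random() < sim.bound_fraction)
            bleach = (
                start + rng.exponential(1e3 / sim.bleach_rate)
                if sim.bleach_rate > 0
                else np.inf
            )
            eid = len(event_label)
            event_label.append(label)
            event_bound.append(bound)
            event_start.append(start)
            event_stop.append(stop)
            event_bleach.append(bleach)

            for t0, t1, acceptor_on in _emission_segments(start, stop, bleach, sim, rng):
                e = construct.fret_E if acceptor_on else 0.0
                _emit_segment(construct, e, t0, t1, meta, sim, rng, eid, mac, mic, chan, evid)
            t = stop

    # background photons: Poisson, uniform in time, flat microtime
    for c, rate in enumerate(sim.background_rates):
        n_bg = rng.poisson(rate / 1e3 * total_ms) if rate > 0 and total_ms > 0 else 0
        if n_bg:
            mac.append(rng.uniform(0, total_ms, n_bg))
            mic.append(_quantize(rng.uniform(0, meta.pulse_period, n_bg), meta.microtime_bin))
            chan.append(np.full(n_bg, c, dtype=np.uint8))
            evid.append(np.full(n_bg, -1, dtype=np.int32))

    if mac:
        macrotime = np.concatenate(mac)
        order = np.argsort(macrotime, kind="stable")
        macrotime = macrotime[order]
        microtime = np.concatenate(mic)[order]
        channel = np.concatenate(chan)[order]
        event_id = np.concatenate(evid)[order]
    else:
        macrotime = np.empty(0)
        microtime = np.empty(0)
        channel = np.empty(0, dtype=np.uint8)
        event_id = np.empty(0, dtype=np.int32)

    truth = StreamTruth(
        event_id=event_id,
        event_label=event_label,
        event_bound=np.asarray(event_bound, dtype=bool),
        event_start_ms=np.asarray(event_start, dtype=float),
        event_stop_ms=np.asarray(event_stop, dtype=float),
        event_bleach_ms=np.asarray(event_bleach, dtype=float),
    )
    return PhotonStream(macrotime, microtime, channel, meta=meta, truth=truth,
                        duration_ms=total_ms)


def _emit_segment(construct, e, t0, t1, meta, sim, rng, eid, mac, mic, chan, evid):
    """Append the photons of one constant-E emission segment."""
    dur = t1 - t0
    if dur <= 0:
        return
    b0 = construct.family.donor_brightness_0
    power = meta.excitation_power
    tau_eff = construct.family.donor_lifetime_0 * (1.0 - e)
    g_rate = b0 * (1.0 - e) * power  # counts/ms
    r_rate = b0 * e * construct.acceptor_brightness_scale * power

    n_g = rng.poisson(g_rate * dur)
    if n_g:
        mac.append(rng.uniform(t0, t1, n_g))
        mic.append(
            sample_nanotime(tau_eff, meta.irf, meta.pulse_period, rng,
                            meta.microtime_bin, size=n_g)
        )
        chan.append(rng.integers(0, 2, n_g).astype(np.uint8))
        evid.append(np.full(n_g, eid, dtype=np.int32))

    n_r = rng.poisson(r_rate * dur)
    if n_r:
        mac.append(rng.uniform(t0, t1, n_r))
        # acceptor emission inherits the donor transfer delay
        transfer = rng.exponential(tau_eff, n_r) if tau_eff > 0 else np.zeros(n_r)
        mic.append(
            sample_nanotime(sim.acceptor_tau, meta.irf, meta.pulse_period, rng,
                            meta.microtime_bin, size=n_r, extra_delay=transfer)
        )
        chan.append((2 + rng.integers(0, 2, n_r)).astype(np.uint8))
        evid.append(np.full(n_r, eid, dtype=np.int32))


def simulate_level(
    construct: ConstructSpec,
    n_photons: int,
    meta: Optional[AcquisitionMeta] = None,
    rng: Optional[np.random.Generator] = None,
    acceptor_tau: float = 1.0,
) -> PhotonStream:
    """Draw one background-free trapping level with exactly ``n_photons``.

    A cheap single-event generator for classification studies: channel
    assignment is multinomial over the construct's branching probabilities
    and arrival times follow the total emission rate.
    """
    meta = meta or AcquisitionMeta()
    rng = rng if rng is not None else np.random.default_rng(0)
    e = construct.fret_E
    s = construct.acceptor_brightness_scale
    weights = np.array([(1 - e) / 2, (1 - e) / 2, e * s / 2, e * s / 2])
    if weights.sum() <= 0:
        raise ValueError("construct emits no photons (E=1 with zero acceptor scale)")
    probs = weights / weights.sum()
    channel = rng.choice(4, size=n_photons, p=probs).astype(np.uint8)

    total_rate = construct.family.donor_brightness_0 * weights.sum() * meta.excitation_power
    macrotime = np.cumsum(rng.exponential(1.0 / total_rate, n_photons))

    tau_eff = construct.family.donor_lifetime_0 * (1.0 - e)
    microtime = np.empty(n_photons)
    green = channel < 2
    n_g = int(green.sum())
    n_r = n_photons - n_g
    if n_g:
        microtime[green] = sample_nanotime(
            tau_eff, meta.irf, meta.pulse_period, rng, meta.microtime_bin, size=n_g
        )
    if n_r:
        transfer = rng.exponential(tau_eff, n_r) if tau_eff > 0 else np.zeros(n_r)
        microtime[~green] = sample_nanotime(
            acceptor_tau, meta.irf, meta.pulse_period, rng, meta.microtime_bin,
            size=n_r, extra_delay=transfer,
        )
    truth = StreamTruth(
        event_id=np.zeros(n_photons, dtype=np.int32),
        event_label=[construct.label],
        event_bound=np.array([False]),
        event_start_ms=np.array([0.0]),
        event_stop_ms=np.array([macrotime[-1] if n_photons else 0.0]),
        event_bleach_ms=np.array([np.inf]),
    )
    return PhotonStream(macrotime, microtime, channel, meta=meta, truth=truth)


@dataclass
class TrapTrajectory:
    """Discrete feedback-trap trajectory of one trapped molecule.

    Per-axis dynamics: ``x(t+dt) = x(t) - gain * xhat(t) + sqrt(2 D dt) xi``
    with ``xhat = x + localization noise``.  Positions in nm, times in ms.
    """

    times_ms: np.ndarray
    true_position: np.ndarray  # (n, 2) nm
    estimated_position: np.ndarray  # (n, 2) nm
    applied_feedback: np.ndarray  # (n, 2) nm (correction commanded per step)
    diffusion_D: float  # um^2 s^-1, ground truth
    feedback_gain: float
    dt_ms: float
    localization_noise: float = 0.0  # nm

    def __post_init__(self) -> None:
        n = len(self.times_ms)
        for arr in (self.true_position, self.estimated_position, self.applied_feedback):
            if len(arr) != n:
                raise ValueError("trajectory arrays must have equal length")
        if not 0 < self.feedback_gain <= 1:
            raise ValueError("feedback_gain must be in (0, 1]")

    def __len__(self) -> int:
        return len(self.times_ms)

    @property
    def stationary_variance_nm2(self) -> float:
        """Closed-form stationary variance of the true position (noise-free)."""
        g = self.feedback_gain
        step_var = 2.0 * self.diffusion_D * 1e3 * self.dt_ms  # nm^2
        return step_var / (1.0 - (1.0 - g) ** 2)

    def index_at(self, t_ms: np.ndarray | float) -> np.ndarray:
        """Trajectory sample index for absolute time(s) ``t_ms``."""
        idx = np.floor((np.asarray(t_ms) - self.times_ms[0]) / self.dt_ms).astype(int)
        return np.clip(idx, 0, len(self) - 1)


def simulate_trap_trajectory(
    diffusion_D: float,
    feedback_gain: float,
    dt: float,
    n_steps: int,
    localization_noise: float,
    rng: np.random.Generator,
    start_ms: float = 0.0,
) -> TrapTrajectory:
    """Simulate feedback-damped Brownian motion (both axes independently).

    ``diffusion_D`` in um^2 s^-1, ``dt`` in ms, positions in nm.  With zero
    localization noise the true-position stationary variance is
    ``2 D dt / (1 - (1-gain)^2)``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not 0 < feedback_gain <= 1:
        raise ValueError("feedback_gain must be in (0, 1]")
    if diffusion_D < 0:
        raise ValueError("diffusion_D must be >= 0")
    n = int(n_steps)
    step_sigma = np.sqrt(2.0 * diffusion_D * 1e3 * dt)  # nm per step
    g = feedback_gain

    true_pos = np.zeros((n, 2))
    eta = (
        rng.normal(0.0, localization_noise, (n, 2))
        if localization_noise > 0
        else np.zeros((n, 2))
    )
    if n > 1:
        w = rng.normal(0.0, step_sigma, (n - 1, 2)) if step_sigma > 0 else np.zeros((n - 1, 2))
        # x[i] = (1-g) x[i-1] + (w[i-1] - g eta[i-1]); linear recursion via IIR filter
        u = w - g * eta[:-1]
        for axis in range(2):
            true_pos[1:, axis] = lfilter([1.0], [1.0, -(1.0 - g)], u[:, axis])
    est = true_pos + eta
    feedback = g * est
    times = start_ms + np.arange(n) * dt
    return TrapTrajectory(
        times_ms=times,
        true_position=true_pos,
        estimated_position=est,
        applied_feedback=feedback,
        diffusion_D=diffusion_D,
        feedback_gain=g,
        dt_ms=dt,
        localization_noise=localization_noise,
    )


@dataclass
class TrapParams:
    """Feedback-trap simulation parameters for :func:`attach_trajectories`."""

    dt_ms: float = 0.1
    feedback_gain: float = 0.5
    localization_noise_nm: float = 30.0
    bound_radius_multiplier: float = 3.0
    temperature_K: float = 293.15
    seed: int = 0


def attach_trajectories(
    stream: PhotonStream,
    registry: Registry,
    trap: Optional[TrapParams] = None,
) -> PhotonStream:
    """Attach one trap trajectory per ground-truth trapping event.

    Each event's diffusion constant follows Stokes-Einstein scaling with
    the construct's hydrodynamic radius, multiplied by the bound-complex
    radius factor when the event is flagged bound.  Photons map to
    trajectory samples by macrotime via :meth:`TrapTrajectory.index_at`.
    """
    trap = trap if trap is not None else TrapParams()
    if stream.truth is None:
        raise ValueError("attach_trajectories requires a stream with ground truth")
    rng = np.random.default_rng(trap.seed)
    trajectories: dict[int, TrapTrajectory] = {}
    truth = stream.truth
    for eid in range(truth.n_events):
        construct = registry[truth.event_label[eid]]
        radius = construct.hydrodynamic_radius
        if truth.event_bound[eid]:
            radius *= trap.bound_radius_multiplier
        d = stokes_einstein_diffusion(radius, trap.temperature_K)
        start = truth.event_start_ms[eid]
        stop = truth.event_stop_ms[eid]
        n_steps = max(2, int(np.ceil((stop - start) / trap.dt_ms)) + 1)
        trajectories[eid] = simulate_trap_trajectory(
            d,
            trap.feedback_gain,
            trap.dt_ms,
            n_steps,
            trap.localization_noise_nm,
            rng,
            start_ms=start,
        )
    stream.trajectories = trajectories
    return stream
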