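"""Photon-stream containers: per-photon records plus acquisition metadata.

The interchange object between the simulator and the analysis pipeline is a
:class:`PhotonStream`: ordered per-photon macrotimes (ms since acquisition
start), TCSPC microtimes (ns since the associated excitation pulse) and a
detection channel among green/red x parallel/perpendicular.  Simulated
streams may carry ground truth (per-photon event id, per-event construct
label and bound flag) for testing; real acquisitions would not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "CHANNELS",
    "G_PAR",
    "G_PERP",
    "R_PAR",
    "R_PERP",
    "GREEN_CHANNELS",
    "RED_CHANNELS",
    "IRFModel",
    "AcquisitionMeta",
    "StreamTruth",
    "PhotonStream",
]

#: Detector channel names in canonical order (codes 0-3).
CHANNELS = ("G_par", "G_perp", "R_par", "R_perp")
G_PAR, G_PERP, R_PAR, R_PERP = 0, 1, 2, 3
GREEN_CHANNELS = (G_PAR, G_PERP)
RED_CHANNELS = (R_PAR, R_PERP)

#: Pulse period for 60 MHz pulsed excitation, ns.
DEFAULT_PULSE_PERIOD_NS = 1e3 / 60.0


@dataclass(frozen=True)
class IRFModel:
    """Instrument response function, either parametric Gaussian or tabulated.

    The Gaussian form is parameterized by ``center`` and ``width_sigma``
    (both ns); the histogram form tabulates a density over one pulse period.
    """

    kind: str = "gaussian"
    center: float = 2.0
    width_sigma: float = 0.25
    histogram: Optional[np.ndarray] = None  # density per bin, any bin count

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "histogram"):
            raise ValueError(f"unknown IRF kind: {self.kind!r}")
        if self.kind == "gaussian" and self.width_sigma < 0:
            raise ValueError("IRF width_sigma must be >= 0")
        if self.kind == "histogram":
            if self.histogram is None or len(self.histogram) == 0:
                raise ValueError("histogram IRF requires a non-empty table")
            h = np.asarray(self.histogram, dtype=float)
            if np.any(h < 0) or h.sum() <= 0:
                raise ValueError("IRF histogram must be nonnegative with positive mass")

    def density_on_grid(self, pulse_period: float, bin_width: float) -> np.ndarray:
        """Per-bin probability mass on the microtime grid, wrapped periodically.

        Returns an array of length ``round(pulse_period / bin_width)`` that
        sums to 1.
        """
        n_bins = int(round(pulse_period / bin_width))
        centers = (np.arange(n_bins) + 0.5) * bin_width
        if self.kind == "histogram":
            h = np.asarray(self.histogram, dtype=float)
            # resample the tabulated density (defined over one period) onto the grid
            src = np.linspace(0, pulse_period, len(h), endpoint=False)
            dens = np.interp(centers, src, h, period=pulse_period)
        else:
            if self.width_sigma == 0:
                dens = np.zeros(n_bins)
                dens[int(self.center / bin_width) % n_bins] = 1.0
                return dens
            # wrap the Gaussian over a few periods; sigma << period in practice
            dens = np.zeros(n_bins)
            for m in (-2, -1, 0, 1, 2):
                z = (centers - self.center + m * pulse_period) / self.width_sigma
                dens += np.exp(-0.5 * z * z)
        total = dens.sum()
        if total <= 0:
            raise ValueError("IRF density vanished on the grid")
        return dens / total

    def sample(self, n: int, rng: np.random.Generator, pulse_period: float) -> np.ndarray:
        """Draw ``n`` IRF delays (ns, unwrapped; caller wraps mod period)."""
        if self.kind == "gaussian":
            return rng.normal(self.center, self.width_sigma, size=n)
        h = np.asarray(self.histogram, dtype=float)
        p = h / h.sum()
        width = pulse_period / len(h)
        idx = rng.choice(len(h), size=n, p=p)
        return (idx + rng.uniform(0, 1, size=n)) * width


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition metadata shared by all photons of a stream."""

    pulse_period: float = DEFAULT_PULSE_PERIOD_NS  # ns
    excitation_power: float = 100.0  # uW
    microtime_bin: float = 0.016  # ns, TCSPC resolution
    irf: IRFModel = field(default_factory=IRFModel)

    def __post_init__(self) -> None:
        if self.pulse_period <= 0:
            raise ValueError("pulse_period must be > 0")
        if not 0 < self.microtime_bin < self.pulse_period:
            raise ValueError("microtime_bin must be in (0, pulse_period)")
        if self.excitation_power <= 0:
            raise ValueError("excitation_power must be > 0")

    @property
    def n_microtime_bins(self) -> int:
        return int(round(self.pulse_period / self.microtime_bin))


@dataclass
class StreamTruth:
    """Simulator ground truth carried alongside a stream, for testing only."""

    event_id: np.ndarray  # per photon, int32; -1 = background
    event_label: list  # per event, construct label
    event_bound: np.ndarray  # per event, bool
    event_start_ms: np.ndarray  # per event
    event_stop_ms: np.ndarray  # per event
    event_bleach_ms: np.ndarray  # per event; inf if acceptor never bleached

    @property
    def n_events(self) -> int:
        return len(self.event_label)


@dataclass
class PhotonStream:
    """Ordered per-photon records plus acquisition metadata."""

    macrotime_ms: np.ndarray
    microtime_ns: np.ndarray
    channel: np.ndarray
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)
    truth: Optional[StreamTruth] = None
    trajectories: Optional[dict] = None  # event id -> TrapTrajectory
    duration_ms: Optional[float] = None  # acquisition span; defaults to last photon

    def __post_init__(self) -> None:
        self.macrotime_ms = np.asarray(self.macrotime_ms, dtype=np.float64)
        self.microtime_ns = np.asarray(self.microtime_ns, dtype=np.float64)
        self.channel = np.asarray(self.channel, dtype=np.uint8)
        n = len(self.macrotime_ms)
        if len(self.microtime_ns) != n or len(self.channel) != n:
            raise ValueError("photon record arrays must have equal length")
        if n:
            if np.any(np.diff(self.macrotime_ms) < 0):
                raise ValueError("macrotimes must be sorted ascending")
            if self.macrotime_ms[0] < 0:
                raise ValueError("macrotimes must be nonnegative")
            if np.any(self.microtime_ns < 0) or np.any(
                self.microtime_ns >= self.meta.pulse_period
            ):
                raise ValueError("microtimes must lie in [0, pulse_period)")
            if np.any(self.channel > 3):
                raise ValueError("channel codes must be 0-3")
        if self.truth is not None and len(self.truth.event_id) != n:
            raise ValueError("truth must cover every photon record")

    def __len__(self) -> int:
        return len(self.macrotime_ms)

    @property
    def span_ms(self) -> float:
        """Acquisition span: explicit duration if known, else the last macrotime."""
        if self.duration_ms is not None:
            return float(self.duration_ms)
        return float(self.macrotime_ms[-1]) if len(self) else 0.0

    def channel_mask(self, channels) -> np.ndarray:
        return np.isin(self.channel, np.asarray(channels, dtype=np.uint8))
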