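"""Photon-stream container I/O.

The canonical container is HDF5 (`/photons/*` datasets, acquisition
metadata as root attributes, optional `/truth/*` datasets); a plain CSV
dialect (columns ``macrotime_ms, microtime_ns, channel``) serves for small
text fixtures.  Write-read round trips preserve records bit-exactly.
"""

from __future__ import annotations

from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .stream import AcquisitionMeta, IRFModel, PhotonStream, StreamTruth

__all__ = ["read_stream", "write_stream", "StreamFormatError"]


class StreamFormatError(ValueError):
    """Raised for malformed stream files."""


def _is_hdf5(path: str) -> bool:
    return path.endswith((".h5", ".hdf5", ".hdf"))


def write_stream(stream: PhotonStream, path: str) -> None:
    """Write a stream; format inferred from the extension (.h5/.hdf5 or .csv)."""
    if _is_hdf5(path):
        _write_hdf5(stream, path)
    elif path.endswith(".csv"):
        pd.DataFrame(
            {
                "macrotime_ms": stream.macrotime_ms,
                "microtime_ns": stream.microtime_ns,
                "channel": stream.channel,
            }
        ).to_csv(path, index=False)
    else:
        raise StreamFormatError(f"unrecognized stream extension: {path}")


def _write_hdf5(stream: PhotonStream, path: str) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("photons")
        g.create_dataset("macrotime_ms", data=stream.macrotime_ms, dtype="f8")
        g.create_dataset("microtime_ns", data=stream.microtime_ns, dtype="f8")
        g.create_dataset("channel", data=stream.channel, dtype="u1")
        meta = stream.meta
        f.attrs["pulse_period_ns"] = meta.pulse_period
        f.attrs["excitation_power_uW"] = meta.excitation_power
        f.attrs["microtime_bin_ns"] = meta.microtime_bin
        f.attrs["irf_kind"] = meta.irf.kind
        if meta.irf.kind == "gaussian":
            f.attrs["irf_center_ns"] = meta.irf.center
            f.attrs["irf_sigma_ns"] = meta.irf.width_sigma
        else:
            f.create_dataset("irf_histogram", data=np.asarray(meta.irf.histogram))
        if stream.duration_ms is not None:
            f.attrs["duration_ms"] = stream.duration_ms
        if stream.truth is not None:
            t = f.create_group("truth")
            t.create_dataset("event_id", data=stream.truth.event_id, dtype="i4")
            t.create_dataset(
                "event_label",
                data=np.array(stream.truth.event_label, dtype=h5py.string_dtype()),
            )
            t.create_dataset("event_bound", data=stream.truth.event_bound)
            t.create_dataset("event_start_ms", data=stream.truth.event_start_ms)
            t.create_dataset("event_stop_ms", data=stream.truth.event_stop_ms)
            t.create_dataset("event_bleach_ms", data=stream.truth.event_bleach_ms)


def read_stream(path: str, meta: Optional[AcquisitionMeta] = None) -> PhotonStream:
    """Read a stream written by :func:`write_stream`.

    For CSV fixtures, which carry no metadata, ``meta`` supplies the
    acquisition parameters (defaults otherwise).
    """
    if _is_hdf5(path):
        return _read_hdf5(path)
    if path.endswith(".csv"):
        df = pd.read_csv(path)
        for col in ("macrotime_ms", "microtime_ns", "channel"):
            if col not in df.columns:
                raise StreamFormatError(f"CSV stream missing column {col!r}")
        meta = meta or AcquisitionMeta()
        return _validated_stream(
            df["macrotime_ms"].to_numpy(float),
            df["microtime_ns"].to_numpy(float),
            df["channel"].to_numpy(),
            meta,
            None,
            None,
            path,
        )
    raise StreamFormatError(f"unrecognized stream extension: {path}")


def _read_hdf5(path: str) -> PhotonStream:
    with h5py.File(path, "r") as f:
        try:
            g = f["photons"]
            mac = g["macrotime_ms"][:]
            mic = g["microtime_ns"][:]
            chan = g["channel"][:]
        except KeyError as exc:
            raise StreamFormatError(f"{path}: missing dataset {exc}") from None
        kind = f.attrs.get("irf_kind", "gaussian")
        if kind == "histogram":
            irf = IRFModel(kind="histogram", histogram=f["irf_histogram"][:])
        else:
            irf = IRFModel(
                kind="gaussian",
                center=float(f.attrs.get("irf_center_ns", 2.0)),
                width_sigma=float(f.attrs.get("irf_sigma_ns", 0.25)),
            )
        meta = AcquisitionMeta(
            pulse_period=float(f.attrs["pulse_period_ns"]),
            excitation_power=float(f.attrs["excitation_power_uW"]),
            microtime_bin=float(f.attrs["microtime_bin_ns"]),
            irf=irf,
        )
        duration = float(f.attrs["duration_ms"]) if "duration_ms" in f.attrs else None
        truth = None
        if "truth" in f:
            t = f["truth"]
            truth = StreamTruth(
                event_id=t["event_id"][:],
                event_label=[s.decode() if isinstance(s, bytes) else str(s)
                             for s in t["event_label"][:]],
                event_bound=t["event_bound"][:].astype(bool),
                event_start_ms=t["event_start_ms"][:],
                event_stop_ms=t["event_stop_ms"][:],
                event_bleach_ms=t["event_bleach_ms"][:],
            )
    return _validated_stream(mac, mic, chan, meta, truth, duration, path)


def _validated_stream(mac, mic, chan, meta, truth, duration, path) -> PhotonStream:
    if len(mac) and np.min(mac) < 0:
        raise StreamFormatError(f"{path}: negative macrotime in macrotime_ms")
    if len(mic) and (np.min(mic) < 0 or np.max(mic) >= meta.pulse_period):
        raise StreamFormatError(
            f"{path}: microtime_ns outside [0, pulse_period)"
        )
    try:
        return PhotonStream(mac, mic, chan, meta=meta, truth=truth, duration_ms=duration)
    except ValueError as exc:
        raise StreamFormatError(f"{path}: {exc}") from None
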