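"""Run orchestration: configuration, fixed stage order, reports, manifest.

Stage order is fixed: background -> change points -> levels -> signatures
-> clustering -> confusion/subset -> classification -> binding.  Runs are
deterministic given the configuration and its seeds, and every run writes
a manifest with per-stage record counts.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binding import binding_efficiency, split_bound_unbound
from .classify import (
    DEFAULT_THRESHOLD,
    classify_level,
    cluster_levels,
    confusion_matrix,
    fit_cluster_gaussian,
    select_compatible_subset,
)
from .io import read_stream
from .level_stats import (
    DEFAULT_GROUP_M,
    FretCorrections,
    LevelStatsOptions,
    group_photons,
    position_sigma,
    signatures_to_frame,
    summarize_levels,
)
from .photon_sim import SimConfig, TrapParams, attach_trajectories, simulate_stream
from .registry import Registry, default_registry, load_registry
from .segmentation import (
    DEFAULT_MIN_LEVEL_MS,
    bin_stream,
    build_levels,
    detect_change_points,
    estimate_background,
    merge_change_points,
)
from .stream import CHANNELS, PhotonStream

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_pipeline", "run_config_from_yaml", "write_outputs"]


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    Exactly one of ``input_path`` (a stream file) or ``sim`` (a simulation
    block) must be given.
    """

    input_path: Optional[str] = None
    sim: Optional[SimConfig] = None
    registry_config: Optional[str] = None  # YAML path; None -> packaged default
    min_level_ms: float = DEFAULT_MIN_LEVEL_MS
    cp_alpha: float = 0.05
    merge_window_ms: float = 10.0
    corrections: FretCorrections = field(default_factory=FretCorrections)
    classify_K: int | str = "auto"
    threshold: float = DEFAULT_THRESHOLD
    n_mc: int = 10**5
    seed: int = 0
    # keep a level only if its total count rate exceeds this multiple of the
    # total background rate (signal-presence filter; 0 disables)
    min_signal_rate_factor: float = 2.0
    group_M: int = DEFAULT_GROUP_M
    simulate_trajectories: bool = True
    trap: TrapParams = field(default_factory=TrapParams)

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.sim is None):
            raise ValueError("exactly one of input_path or sim must be set")


@dataclass
class RunResult:
    """Everything a run produces, plus the manifest."""

    stream: PhotonStream
    background: object
    change_points: object
    levels: list
    signatures: list
    signature_frame: pd.DataFrame
    cluster_assignments: Optional[np.ndarray]
    models: list
    confusion: object
    subset: object
    classifications: list
    binding_calls: list
    binding_report: Optional[pd.DataFrame]
    manifest: dict


def run_config_from_yaml(source) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML path or mapping."""
    if isinstance(source, str):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = dict(source)
    sim = None
    if "simulation" in doc:
        sim_doc = dict(doc["simulation"])
        if "mixture" in sim_doc:
            sim_doc["mixture"] = [tuple(m) for m in sim_doc["mixture"]]
        sim = SimConfig(**sim_doc)
    corr = FretCorrections(**doc.get("corrections", {}))
    trap = TrapParams(**doc.get("trap", {}))
    kwargs = {
        k: doc[k]
        for k in (
            "input_path",
            "registry_config",
            "min_level_ms",
            "cp_alpha",
            "merge_window_ms",
            "classify_K",
            "threshold",
            "n_mc",
            "seed",
            "min_signal_rate_factor",
            "group_M",
            "simulate_trajectories",
        )
        if k in doc
    }
    return RunConfig(sim=sim, corrections=corr, trap=trap, **kwargs)


def _config_hash(config: RunConfig) -> str:
    def default(o):
        return repr(o)

    text = yaml.safe_dump(
        {"repr": repr(config)}, default_flow_style=True
    )
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _load_registry(config: RunConfig) -> Registry:
    if config.registry_config is None:
        return default_registry()
    return load_registry(config.registry_config)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis with the fixed stage order."""
    registry = _load_registry(config)

    # --- input -------------------------------------------------------------
    if config.sim is not None:
        stream = simulate_stream(registry, config.sim)
        if config.simulate_trajectories:
            stream = attach_trajectories(stream, registry, config.trap)
    else:
        stream = read_stream(config.input_path)
    logger.info("stage input: %d photons", len(stream))

    # --- background --------------------------------------------------------
    trace = bin_stream(stream)
    background = estimate_background(trace)
    logger.info("stage background: rates %s counts/s", np.round(background.rates, 1))

    # --- change points -----------------------------------------------------
    per_channel = []
    for c in range(len(CHANNELS)):
        times = stream.macrotime_ms[stream.channel == c]
        per_channel.append(detect_change_points(times, alpha=config.cp_alpha, channel=c))
    merged = merge_change_points(per_channel, merge_window=config.merge_window_ms)
    logger.info("stage change_points: %d merged", len(merged))

    # --- levels ------------------------------------------------------------
    candidates = build_levels(stream, merged, min_duration=0.0)
    levels = [lv for lv in candidates if lv.duration_ms > config.min_level_ms]
    if config.min_signal_rate_factor > 0:
        bg_rate_ms = background.total_rate / 1e3
        levels = [
            lv
            for lv in levels
            if lv.n_photons / lv.duration_ms > config.min_signal_rate_factor * bg_rate_ms
        ]
    logger.info("stage levels: %d candidates, %d retained", len(candidates), len(levels))

    # --- signatures ---------------------------------------------------------
    options = LevelStatsOptions(corrections=config.corrections)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        signatures = summarize_levels(levels, stream, background, options)
    frame = signatures_to_frame(signatures)

    # --- clustering / confusion / subset / classification -------------------
    # a level enters the cluster space only with a trustworthy 3D point:
    # finite axes and an interior (non-degenerate) lifetime fit
    valid = frame[["green_b", "red_b", "tau_ns"]].notna().all(axis=1).to_numpy()
    bad_fit = frame["flags"].str.contains(
        "lifetime_at_bound|lifetime_flat_likelihood|lifetime_too_few_photons"
    ).to_numpy()
    valid &= ~bad_fit
    assignments = None
    models: list = []
    conf = None
    subset = None
    classifications: list = []
    pts = frame.loc[valid]
    min_pts = 10
    if len(pts) >= min_pts:
        try:
            assignments = cluster_levels(pts, K=config.classify_K, seed=config.seed)
            models = fit_cluster_gaussian(pts, assignments, strict=False)
            if len(models) >= 2:
                conf = confusion_matrix(models, n_mc=config.n_mc, seed=config.seed)
                subset = select_compatible_subset(conf, threshold=config.threshold)
            for i, sig in enumerate(signatures):
                if valid[i] and models:
                    classifications.append(classify_level(sig, models))
                else:
                    classifications.append(None)
        except ValueError as exc:
            warnings.warn(f"classification stage degraded: {exc}", stacklevel=2)
            classifications = [None] * len(signatures)
    else:
        warnings.warn("too few valid signatures for clustering; stage skipped",
                      stacklevel=2)
        classifications = [None] * len(signatures)

    # --- binding ------------------------------------------------------------
    binding_calls: list = []
    binding_report = None
    if stream.trajectories:
        points = []
        for i, lv in enumerate(levels):
            if lv.event_id < 0 or lv.event_id not in stream.trajectories:
                continue
            traj = stream.trajectories[lv.event_id]
            lab = classifications[i].label if classifications[i] is not None else ""
            for grp in group_photons(lv, config.group_M):
                try:
                    pt = position_sigma(traj, grp, stream, event_id=lv.event_id)
                except ValueError:
                    continue
                points.append(
                    type(pt)(pt.sigma_x, pt.sigma_y, pt.level_id, pt.group_index,
                             event_id=pt.event_id, label=lab)
                )
        if len(points) >= 10:
            binding_calls, _summary = split_bound_unbound(points, seed=config.seed)
            binding_report = binding_efficiency(binding_calls)
        else:
            warnings.warn("too few confinement points; binding stage skipped",
                          stacklevel=2)
    else:
        logger.info("stage binding: no trajectories available, skipped")

    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "sim_seed": config.sim.seed if config.sim is not None else None,
        "counts": {
            "photons": len(stream),
            "change_points": len(merged),
            "candidate_levels": len(candidates),
            "retained_levels": len(levels),
            "clusters": len(models),
            "confinement_points": len(binding_calls),
        },
    }
    return RunResult(
        stream=stream,
        background=background,
        change_points=merged,
        levels=levels,
        signatures=signatures,
        signature_frame=frame,
        cluster_assignments=assignments,
        models=models,
        confusion=conf,
        subset=subset,
        classifications=classifications,
        binding_calls=binding_calls,
        binding_report=binding_report,
        manifest=manifest,
    )


def write_outputs(result: RunResult, outdir: str) -> None:
    """Write the TSV/YAML report bundle of a run."""
    import os

    os.makedirs(outdir, exist_ok=True)
    levels_df = pd.DataFrame(
        {
            "level_id": [lv.level_id for lv in result.levels],
            "start_ms": [lv.start_ms for lv in result.levels],
            "stop_ms": [lv.stop_ms for lv in result.levels],
            "duration_ms": [lv.duration_ms for lv in result.levels],
            "counts_Gpar": [lv.counts[0] for lv in result.levels],
            "counts_Gperp": [lv.counts[1] for lv in result.levels],
            "counts_Rpar": [lv.counts[2] for lv in result.levels],
            "counts_Rperp": [lv.counts[3] for lv in result.levels],
        }
    )
    levels_df.to_csv(os.path.join(outdir, "levels.tsv"), sep="\t", index=False)
    frame = result.signature_frame.copy()
    frame["assigned_label"] = [
        c.label if c is not None else "" for c in result.classifications
    ]
    frame.to_csv(os.path.join(outdir, "signatures.tsv"), sep="\t", index=False)
    if result.confusion is not None:
        result.confusion.to_frame().to_csv(
            os.path.join(outdir, "confusion_matrix.tsv"), sep="\t"
        )
    if result.subset is not None:
        with open(os.path.join(outdir, "subset.yaml"), "w") as fh:
            yaml.safe_dump(
                {
                    "labels": list(result.subset.labels),
                    "threshold": result.subset.threshold,
                    "certificate": float(result.subset.certificate),
                },
                fh,
            )
    if result.binding_report is not None:
        result.binding_report.to_csv(
            os.path.join(outdir, "binding.tsv"), sep="\t", index=False
        )
    with open(os.path.join(outdir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(result.manifest, fh)
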