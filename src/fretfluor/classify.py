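"""Cluster classification of level signatures and label-palette design.

Level signatures live in a three-dimensional detection space (green
brightness, red brightness, donor lifetime).  Each label's cluster is
summarized as an axis-aligned 3D Gaussian (no covariance) after >3-sigma
outlier rejection; the probability that a molecule of one label is
misread as another is the one-tailed mass of its Gaussian beyond the
equal-density decision surface of the pair.  A misclassification
threshold over all ordered pairs defines a compatibility graph whose
maximum clique is the largest label palette usable in one mixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .level_stats import (
    DEFAULT_MIN_FIT_PHOTONS,
    LevelSignature,
    fit_lifetime_mle,
    fret_efficiency,
)
from .photon_sim import simulate_level
from .registry import Registry
from .stream import G_PAR, GREEN_CHANNELS, AcquisitionMeta, PhotonStream

__all__ = [
    "ClusterModel",
    "ConfusionMatrix",
    "SubsetSelection",
    "PairwiseOverlap",
    "ClassificationResult",
    "cluster_levels",
    "fit_cluster_gaussian",
    "pairwise_misclassification",
    "confusion_matrix",
    "select_compatible_subset",
    "classify_level",
    "accuracy_vs_photons",
]

DEFAULT_THRESHOLD = 0.025
DEFAULT_MIN_CLUSTER_SIZE = 5


@dataclass
class ClusterModel:
    """Axis-aligned 3D Gaussian signature of one label's cluster."""

    label: str
    mean: np.ndarray  # (green_b, red_b, tau)
    sigma: np.ndarray  # per-axis standard deviations
    n_members: int = 0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma <= 0):
            raise ValueError(f"cluster {self.label!r}: sigma components must be > 0")

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        z = (x - self.mean) / self.sigma
        return -0.5 * np.sum(z * z, axis=1) - np.log(self.sigma).sum()

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(self.mean, self.sigma, size=(n, len(self.mean)))


def _as_points(points) -> np.ndarray:
    """Accept an (n, 3) array, a signature list or a signature DataFrame."""
    if isinstance(points, pd.DataFrame):
        return points[["green_b", "red_b", "tau_ns"]].to_numpy(dtype=float)
    if len(points) and isinstance(points[0], LevelSignature):
        return np.array(
            [[s.green_brightness, s.red_brightness, s.donor_lifetime] for s in points]
        )
    return np.asarray(points, dtype=float)


def cluster_levels(
    points,
    K: int | str = "auto",
    seed: int = 0,
    n_restarts: int = 20,
    k_range: Sequence[int] = range(2, 13),
) -> np.ndarray:
    """Initial classification: K-means on per-axis standardized coordinates.

    ``K="auto"`` selects the cluster count by minimum BIC of an
    axis-aligned Gaussian mixture in the standardized space over
    ``k_range``, then partitions at that count.  Returns integer cluster
    labels.
    """
    x = _as_points(points)
    if x.ndim != 2:
        raise ValueError("points must be 2-D")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    n, _ = z.shape

    def fit_k(k: int) -> KMeans:
        if k > n:
            raise ValueError(f"K={k} exceeds the number of points ({n})")
        return KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(z)

    if K != "auto":
        return fit_k(int(K)).labels_
    best_k, best_bic = None, np.inf
    for k in k_range:
        if k > n:
            break
        gm = GaussianMixture(n_components=k, covariance_type="diag",
                             random_state=seed, n_init=3,
                             reg_covar=1e-6).fit(z)
        bic = float(gm.bic(z))
        if bic < best_bic:
            best_bic, best_k = bic, k
    if best_k is None:
        raise ValueError("no feasible K in k_range")
    return fit_k(best_k).labels_


def fit_cluster_gaussian(
    points,
    member_labels: np.ndarray,
    min_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    max_iter: int = 10,
    cluster_names: Optional[dict] = None,
    strict: bool = True,
) -> list[ClusterModel]:
    """Axis-aligned Gaussian per cluster with iterative >3-sigma rejection.

    With ``strict=False``, clusters that are undersized or degenerate are
    skipped with a warning instead of raising, and models are returned for
    the remaining clusters.

    Iterates mean/sigma estimation, dropping points with any-axis |z| > 3,
    until membership stabilizes (at most ``max_iter`` rounds).
    """
    x = _as_points(points)
    member_labels = np.asarray(member_labels)
    models: list[ClusterModel] = []
    for lab in np.unique(member_labels):
        try:
            pts = x[member_labels == lab]
            if len(pts) < min_size:
                raise ValueError(f"cluster {lab} has fewer than {min_size} members")
            keep = np.ones(len(pts), dtype=bool)
            for _ in range(max_iter):
                sub = pts[keep]
                if len(sub) < min_size:
                    raise ValueError(f"cluster {lab} emptied by outlier rejection")
                mean = sub.mean(axis=0)
                sigma = sub.std(axis=0, ddof=1)
                if np.any(sigma == 0):
                    raise ValueError(f"cluster {lab} has zero variance on an axis")
                new_keep = np.all(np.abs(pts - mean) <= 3.0 * sigma, axis=1)
                if np.array_equal(new_keep, keep):
                    break
                keep = new_keep
        except ValueError:
            if strict:
                raise
            warnings.warn(f"skipping unmodelable cluster {lab}", stacklevel=2)
            continue
        name = cluster_names[lab] if cluster_names else str(lab)
        models.append(ClusterModel(name, mean, sigma, n_members=int(keep.sum())))
    if not strict and not models:
        raise ValueError("no cluster could be modelled")
    return models


@dataclass
class PairwiseOverlap:
    """Monte-Carlo estimate of a one-tailed pairwise misclassification."""

    p: float
    se: float


def pairwise_misclassification(
    a: ClusterModel,
    b: ClusterModel,
    n_mc: int = 10**6,
    seed: int = 0,
) -> PairwiseOverlap:
    """Probability that a point truly from ``a`` is assigned to ``b``.

    The decision boundary is the equal-density surface of the two
    axis-aligned Gaussians (equal priors); the probability is the mass of
    ``a``'s distribution on ``b``'s side, estimated by Monte Carlo.  For
    two clusters differing on one axis with common sigma this reduces to
    the classical tail overlap ``Phi(-d / (2 sigma))``.  Exactly identical
    clusters give 0.5 (every draw ties; ties count half).
    """
    rng = np.random.default_rng(seed)
    draws = a.sample(n_mc, rng)
    la = a.logpdf(draws)
    lb = b.logpdf(draws)
    p = float(np.mean(lb > la) + 0.5 * np.mean(lb == la))
    se = float(np.sqrt(max(p * (1 - p), 1e-12) / n_mc))
    return PairwiseOverlap(p, se)


@dataclass
class ConfusionMatrix:
    """Ordered pairwise misclassification probabilities.

    ``p[i, j]`` (i != j) is the probability that a point truly from label
    ``i`` is assigned to label ``j`` under the pairwise decision rule; the
    diagonal carries the remaining self-identification mass (a pairwise
    approximation, not a joint all-cluster integral).
    """

    labels: list
    p: np.ndarray
    se: np.ndarray

    @property
    def n_offdiagonal(self) -> int:
        n = len(self.labels)
        return n * (n - 1)

    def offdiagonal(self) -> np.ndarray:
        mask = ~np.eye(len(self.labels), dtype=bool)
        return self.p[mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p, index=self.labels, columns=self.labels)


def confusion_matrix(
    models: Sequence[ClusterModel],
    n_mc: int = 10**5,
    seed: int = 0,
) -> ConfusionMatrix:
    """All ordered pairwise misclassification probabilities."""
    if len(models) < 2:
        raise ValueError("confusion matrix needs at least 2 cluster models")
    n = len(models)
    p = np.zeros((n, n))
    se = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            res = pairwise_misclassification(
                models[i], models[j], n_mc=n_mc, seed=seed + i * n + j
            )
            p[i, j], se[i, j] = res.p, res.se
    np.fill_diagonal(p, 1.0 - p.sum(axis=1))
    return ConfusionMatrix([m.label for m in models], p, se)


@dataclass
class SubsetSelection:
    """A mutually compatible label palette under a misclassification threshold."""

    labels: list
    threshold: float
    certificate: float  # max pairwise misclassification within the subset

    def __post_init__(self) -> None:
        if self.certificate > self.threshold and len(self.labels) > 1:
            raise ValueError("subset certificate exceeds the threshold")


def select_compatible_subset(
    matrix: ConfusionMatrix,
    threshold: float = DEFAULT_THRESHOLD,
) -> SubsetSelection:
    """Largest label subset with all pairwise misclassifications <= threshold.

    Builds the compatibility graph (edge iff both directed probabilities
    are within threshold) and finds an exact maximum clique; ties break to
    the lexicographically smallest label set.
    """
    if not 0 < threshold < 0.5:
        raise ValueError("threshold must be in (0, 0.5)")
    labels = matrix.labels
    n = len(labels)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if matrix.p[i, j] <= threshold and matrix.p[j, i] <= threshold:
                g.add_edge(i, j)
    best: Optional[tuple] = None
    for clique in nx.find_cliques(g):
        key = (-len(clique), tuple(sorted(labels[i] for i in clique)))
        if best is None or key < best[0]:
            best = (key, clique)
    assert best is not None
    chosen = sorted(best[1], key=lambda i: labels[i])
    cert = 0.0
    for i in chosen:
        for j in chosen:
            if i != j:
                cert = max(cert, float(matrix.p[i, j]))
    return SubsetSelection([labels[i] for i in chosen], threshold, cert)


@dataclass
class ClassificationResult:
    """Maximum-density label assignment with normalized posteriors."""

    label: str
    posteriors: dict
    flags: tuple = ()


def classify_level(
    point,
    models: Sequence[ClusterModel],
    density_floor: Optional[float] = None,
) -> ClassificationResult:
    """Assign a signature point to the highest-density cluster (equal priors).

    Ties break deterministically to the lexicographically first label
    (flagged).  With ``density_floor`` set, points whose best log-density
    falls below it are returned as ``"unassigned"``.
    """
    if not models:
        raise ValueError("need at least one cluster model")
    x = _as_points([point] if isinstance(point, LevelSignature) else [point])
    logd = np.array([float(m.logpdf(x)[0]) for m in models])
    # normalized posteriors (equal priors)
    shifted = np.exp(logd - logd.max())
    post = shifted / shifted.sum()
    posteriors = {m.label: float(p) for m, p in zip(models, post)}
    best = logd.max()
    flags: list[str] = []
    winners = [m.label for m, d in zip(models, logd) if d == best]
    if len(winners) > 1:
        flags.append("tie")
    label = sorted(winners)[0]
    if density_floor is not None and best < density_floor:
        label = "unassigned"
        flags.append("below_density_floor")
    return ClassificationResult(label, posteriors, tuple(flags))


def reference_models(
    registry: Registry,
    labels: Optional[Sequence[str]] = None,
    n_levels: int = 60,
    n_photons: int = 5000,
    meta: Optional[AcquisitionMeta] = None,
    seed: int = 0,
    min_fit_photons: int = DEFAULT_MIN_FIT_PHOTONS,
) -> list[ClusterModel]:
    """Simulated reference cluster per construct at a fixed photon budget.

    Draws ``n_levels`` background-free levels of ``n_photons`` photons for
    each construct and summarizes them as an axis-aligned Gaussian; used
    for palette design when no measured signature table is available.
    """
    meta = meta or AcquisitionMeta()
    rng = np.random.default_rng(seed)
    labels = list(labels) if labels is not None else registry.labels
    per_label = {
        lab: np.array(
            [
                _signature_point(
                    simulate_level(registry[lab], n_photons, meta, rng), min_fit_photons
                )
                for _ in range(n_levels)
            ]
        )
        for lab in labels
    }
    # a construct too dim in the fitted channel at this photon budget has no
    # usable lifetime axis; keep the model space consistent by dropping the
    # axis for every construct
    use_tau = all(
        np.sum(np.isfinite(pts[:, 2])) >= 2 for pts in per_label.values()
    )
    if not use_tau:
        warnings.warn(
            "lifetime axis dropped from reference models: too few fittable "
            "photons for at least one construct at this photon budget",
            stacklevel=2,
        )
    models = []
    for lab in labels:
        pts = per_label[lab] if use_tau else per_label[lab][:, :2]
        mean = np.nanmean(pts, axis=0)
        sigma = np.nanstd(pts, axis=0, ddof=1)
        sigma[sigma <= 0] = 1e-9
        models.append(ClusterModel(lab, mean, sigma, n_members=n_levels))
    return models


# ---------------------------------------------------------------------------
# Photon-budget accuracy curves
# ---------------------------------------------------------------------------


def _signature_point(stream: PhotonStream, min_fit_photons: int) -> np.ndarray:
    """(green_b, red_b, tau) of a background-free single-level stream."""
    meta = stream.meta
    dur = float(stream.macrotime_ms[-1] - stream.macrotime_ms[0]) if len(stream) else 0.0
    if dur <= 0:
        return np.array([np.nan, np.nan, np.nan])
    green = int(np.sum(stream.channel_mask(GREEN_CHANNELS)))
    red = len(stream) - green
    power = meta.excitation_power
    gpar = stream.microtime_ns[stream.channel == G_PAR]
    fit = fit_lifetime_mle(
        gpar, meta.irf, meta.pulse_period, microtime_bin=meta.microtime_bin,
        min_fit_photons=min_fit_photons,
    )
    return np.array([green / dur / power, red / dur / power, fit.tau_ns])


def accuracy_vs_photons(
    registry: Registry,
    target_label: str,
    competitor_sets: dict,
    M_grid: Sequence[int],
    n_reps: int = 200,
    n_ref: int = 150,
    seed: int = 0,
    meta: Optional[AcquisitionMeta] = None,
    min_fit_photons: int = DEFAULT_MIN_FIT_PHOTONS,
) -> pd.DataFrame:
    """Correct/incorrect identification rates versus photons per point.

    For each photon budget M, reference clusters are rebuilt from M-photon
    simulated levels of every involved construct (cluster spread grows as
    M shrinks, as in experiment), and fresh M-photon draws of the target
    construct are classified against the target plus each competitor set.
    Below ``min_fit_photons`` the lifetime axis is dropped (flagged in the
    ``axes`` column).
    """
    if list(M_grid) != sorted(M_grid):
        raise ValueError("M_grid must be ascending")
    meta = meta or AcquisitionMeta()
    rng = np.random.default_rng(seed)
    involved = {target_label}
    for labels in competitor_sets.values():
        involved.update(labels)
    rows = []
    for m_photons in M_grid:
        use_tau = m_photons >= min_fit_photons
        axes = slice(0, 3) if use_tau else slice(0, 2)
        ref_models: dict[str, ClusterModel] = {}
        for lab in sorted(involved):
            pts = np.array(
                [
                    _signature_point(
                        simulate_level(registry[lab], m_photons, meta, rng), min_fit_photons
                    )[axes]
                    for _ in range(n_ref)
                ]
            )
            mean = np.nanmean(pts, axis=0)
            sigma = np.nanstd(pts, axis=0, ddof=1)
            sigma[sigma == 0] = 1e-12
            ref_models[lab] = ClusterModel(lab, mean, sigma, n_members=n_ref)
        target_pts = np.array(
            [
                _signature_point(
                    simulate_level(registry[target_label], m_photons, meta, rng),
                    min_fit_photons,
                )[axes]
                for _ in range(n_reps)
            ]
        )
        for set_name, comp_labels in competitor_sets.items():
            models = [ref_models[target_label]] + [ref_models[l] for l in comp_labels]
            assigned = [classify_level(p, models).label for p in target_pts]
            correct = float(np.mean([a == target_label for a in assigned]))
            rows.append(
                {
                    "M": m_photons,
                    "competitor_set": set_name,
                    "correct_rate": correct,
                    "incorrect_rate": 1.0 - correct,
                    "n_reps": n_reps,
                    "axes": "3d" if use_tau else "2d_no_lifetime",
                }
            )
    return pd.DataFrame(rows)
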