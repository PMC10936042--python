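"""K-means++ clustering of latent representations and model selection.

Clustering uses K-means with k-means++ seeding and multiple restarts;
the number of profiles is chosen by combining the elbow of the inertia
curve (maximum distance to the chord between its endpoints), mean
silhouette, and a cluster-balance constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .cae import ConfigurationError


@dataclass
class ClusterSolution:
    k: int
    assignments: np.ndarray
    centroids: np.ndarray
    inertia: float
    mean_silhouette: float | None = None


@dataclass
class KSelectionReport:
    k_values: list[int]
    inertia: list[float]
    silhouette: list[float | None]
    cluster_sizes: list[list[int]]
    chosen_k: int = 0
    elbow_k: int | None = None
    balance_fraction: float = 0.1
    notes: list[str] = field(default_factory=list)


def kmeans_pp(
    latents: np.ndarray, k: int, n_restarts: int = 10, seed: int = 0
) -> ClusterSolution:
    """Best-of-restarts K-means with k-means++ initialization."""
    latents = np.asarray(latents, dtype=np.float64)
    n = len(latents)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of points n={n}")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=n_restarts, tol=1e-4, random_state=seed
    ).fit(latents)
    sol = ClusterSolution(
        k=k,
        assignments=km.labels_.astype(np.int64),
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
    )
    if 2 <= len(np.unique(sol.assignments)) <= n - 1:
        sol.mean_silhouette = float(np.mean(silhouette_samples(latents, sol.assignments)))
    return sol


def silhouette_report(latents: np.ndarray, solution: ClusterSolution) -> tuple[np.ndarray, float]:
    """Per-point silhouette values and their mean (k >= 2 required)."""
    if solution.k < 2:
        raise ValueError("silhouette undefined for k < 2")
    vals = silhouette_samples(np.asarray(latents, dtype=np.float64), solution.assignments)
    return vals, float(vals.mean())


def evaluate_k_range(
    latents: np.ndarray, k_values: range | list[int], n_restarts: int = 10, seed: int = 0
) -> tuple[dict[int, ClusterSolution], KSelectionReport]:
    """Fit K-means over a range of k and assemble the selection report."""
    solutions: dict[int, ClusterSolution] = {}
    report = KSelectionReport(k_values=list(k_values), inertia=[], silhouette=[], cluster_sizes=[])
    for k in report.k_values:
        sol = kmeans_pp(latents, k, n_restarts=n_restarts, seed=seed)
        solutions[k] = sol
        report.inertia.append(sol.inertia)
        report.silhouette.append(sol.mean_silhouette)
        report.cluster_sizes.append(np.bincount(sol.assignments, minlength=k).tolist())
    return solutions, report


def _elbow_by_chord(k_values: list[int], inertia: list[float]) -> int | None:
    """k with maximum perpendicular distance to the chord joining the
    first and last points of the (k, inertia) curve; None when the curve
    is (numerically) linear."""
    ks = np.asarray(k_values, dtype=float)
    ys = np.asarray(inertia, dtype=float)
    if len(ks) < 3:
        return None
    span = ys[0] - ys[-1]
    if span <= 0:
        return None
    ysn = (ys - ys[-1]) / span
    ksn = (ks - ks[0]) / (ks[-1] - ks[0])
    # chord from (0, ysn[0]=1) to (1, 0): distance ∝ |ysn + ksn - 1|
    d = 1.0 - ksn - ysn  # positive below the chord (convex drop)
    if np.max(d) < 1e-6:
        return None
    return int(ks[int(np.argmax(d))])


def select_k(
    report: KSelectionReport,
    candidates: list[int] | None = None,
    balance_fraction: float = 0.1,
) -> KSelectionReport:
    """Choose the number of profiles.

    Elbow candidates come from the maximum distance-to-chord point of the
    inertia curve; among candidate k within +-1 of the elbow (or an
    explicit shortlist), prefer the one maximizing mean silhouette subject
    to the smallest cluster holding at least ``balance_fraction`` of
    participants. Falls back to the best-silhouette k when no elbow exists.
    """
    if not report.k_values:
        raise ValueError("empty k range")
    n_total = [sum(s) for s in report.cluster_sizes]
    report.balance_fraction = balance_fraction
    elbow = _elbow_by_chord(report.k_values, report.inertia)
    report.elbow_k = elbow
    sil = {k: s for k, s in zip(report.k_values, report.silhouette) if s is not None}
    if candidates is None:
        if elbow is None:
            report.notes.append("no elbow detected; falling back to max silhouette")
            warnings.warn("inertia curve has no elbow; using max-silhouette k")
            candidates = list(sil)
        else:
            candidates = [k for k in report.k_values if abs(k - elbow) <= 1]
    candidates = [k for k in candidates if k in set(report.k_values)]
    if not candidates:
        raise ValueError("no feasible candidate k")

    def balanced(k: int) -> bool:
        i = report.k_values.index(k)
        sizes = report.cluster_sizes[i]
        return min(sizes) >= balance_fraction * n_total[i]

    pool = [k for k in candidates if k in sil and balanced(k)]
    if not pool:
        report.notes.append("no balanced candidate; relaxing balance constraint")
        pool = [k for k in candidates if k in sil] or candidates
    chosen = max(pool, key=lambda k: sil.get(k, -np.inf))
    report.chosen_k = int(chosen)
    return report
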