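"""Ensemble statistics: k-means clustering, cluster average structures,
bending tables and 2D population distributions.

Models are superposed (all heavy atoms, least squares) before any
featurization, so every statistic is invariant under rigid-body motion of
the whole ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .geometry import kabsch
from .io import Conformation, Ensemble, StructureError

__all__ = [
    "ClusterResult",
    "BendingTable",
    "Histogram2D",
    "kmeans_cluster",
    "select_k",
    "average_structure",
    "bending_table",
    "hist2d",
    "pool_loops",
    "BENDING_BINS",
]

#: Bending-table bin edges (degrees): 0-20, 20-30, 30-40, 40-50, 50-60, >60.
BENDING_BINS = (0.0, 20.0, 30.0, 40.0, 50.0, 60.0, float("inf"))
_BIN_LABELS = ("0-20", "20-30", "30-40", "40-50", "50-60", ">60")


@dataclass(frozen=True)
class ClusterResult:
    k: int
    labels: np.ndarray
    populations: np.ndarray  # percent per cluster, sums to 100
    seed: int


@dataclass(frozen=True)
class BendingTable:
    bins: tuple[str, ...]
    percent: np.ndarray
    average_angle: float


@dataclass(frozen=True)
class Histogram2D:
    x_label: str
    y_label: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray  # probability mass per bin, sums to 1


def _superposed_coords(e: Ensemble, reference: np.ndarray | None = None) -> np.ndarray:
    """(n_models, n_atoms, 3) after rigid superposition to the reference."""
    stack = e.coords()
    ref = stack[0] if reference is None else reference
    out = np.empty_like(stack)
    for i, x in enumerate(stack):
        R, t, _ = kabsch(x, ref)
        out[i] = x @ R.T + t
    return out


def kmeans_cluster(e: Ensemble, k: int, seed: int = 0) -> ClusterResult:
    """k-means on flattened heavy-atom coordinates (superposed to model 1)."""
    n = len(e)
    if k < 1 or k > n:
        raise ValueError(f"k must lie in [1, {n}]")
    X = _superposed_coords(e).reshape(n, -1)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(X)
    pops = np.array([100.0 * np.sum(labels == c) / n for c in range(k)])
    return ClusterResult(k=k, labels=labels, populations=pops, seed=seed)


def select_k(
    e: Ensemble, k_range: tuple[int, int] = (8, 20), seed: int = 0
) -> int:
    """Silhouette sweep over the cluster-count range (clipped to n-1)."""
    n = len(e)
    lo = max(2, min(k_range[0], n - 1))
    hi = max(lo, min(k_range[1], n - 1))
    X = _superposed_coords(e).reshape(n, -1)
    best_k, best_score = lo, -np.inf
    for k in range(lo, hi + 1):
        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(X, labels)
        if score > best_score:
            best_k, best_score = k, score
    return best_k


def average_structure(
    e: Ensemble, labels: np.ndarray, cluster_id: int
) -> Conformation:
    """Coordinate-wise mean of a cluster after superposition to its medoid."""
    members = np.flatnonzero(np.asarray(labels) == cluster_id)
    if members.size == 0:
        raise ValueError(f"cluster {cluster_id} is empty")
    sub = Ensemble([e[int(i)] for i in members])
    X = _superposed_coords(sub)
    # medoid in the common frame, then re-superpose everyone onto it
    flat = X.reshape(len(sub), -1)
    d = np.linalg.norm(flat[:, None, :] - flat[None, :, :], axis=2)
    medoid = int(np.argmin(d.sum(axis=1)))
    X = _superposed_coords(sub, reference=sub[medoid].coords)
    return sub[medoid].with_coords(X.mean(axis=0))


def bending_table(cluster_angles, populations) -> BendingTable:
    """Binned bending statistics over cluster average structures."""
    angles = np.asarray(cluster_angles, dtype=float)
    pops = np.asarray(populations, dtype=float)
    if angles.shape != pops.shape:
        raise ValueError("angles and populations must have equal length")
    if np.any((angles < 0) | (angles > 180)):
        raise ValueError("bending angles must lie in [0, 180] degrees")
    if abs(pops.sum() - 100.0) > 1e-6:
        raise ValueError("populations must sum to 100 percent")
    edges = np.asarray(BENDING_BINS)
    percent = np.zeros(len(edges) - 1)
    for a, p in zip(angles, pops):
        b = int(np.searchsorted(edges, a, side="right")) - 1  # left-closed bins
        b = min(b, len(percent) - 1)
        percent[b] += p
    avg = float(np.sum(angles * pops) / 100.0)
    return BendingTable(bins=_BIN_LABELS, percent=percent, average_angle=avg)


def hist2d(
    x, y, bins=40, x_label: str = "x", y_label: str = "y",
    range_=None,
) -> Histogram2D:
    """Normalized 2D population distribution of paired per-step series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y series must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    counts, xe, ye = np.histogram2d(x[ok], y[ok], bins=bins, range=range_)
    total = counts.sum()
    if total == 0:
        raise ValueError("no finite data points")
    return Histogram2D(
        x_label=x_label, y_label=y_label, x_edges=xe, y_edges=ye,
        density=counts / total,
    )


def pool_loops(e: Ensemble, pm) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Pooled internal-loop coordinates for loop-conformation clustering.

    Retains all internal loops except the first and last (both kept when
    exactly two), includes one closing pair on each side, and augments each
    loop with its strand-swapped symmetric copy.  Returns the flattened
    coordinate matrix and (model, loop) provenance (symmetric copies get
    negative loop ids).
    """
    loops = pm.internal_loops()
    if len(loops) > 2:
        loops = loops[1:-1]
    if not loops:
        raise StructureError("construct has no internal loops")
    n = pm.n_pairs
    rows, prov = [], []
    for im, c in enumerate(e, start=1):
        arr = c.atoms
        coords = c.coords
        for il, loop in enumerate(loops, start=1):
            pairs = (loop[0] - 1,) + tuple(loop) + (loop[-1] + 1,)
            fwd, rev = [], []
            for i in pairs:
                j = n + 1 - i
                mi = (arr.chain_id == pm.chain_i) & (arr.res_id == i)
                mj = (arr.chain_id == pm.chain_ii) & (arr.res_id == j)
                fwd.append(np.vstack([coords[mi], coords[mj]]))
                rev.append(np.vstack([coords[mj], coords[mi]]))
            X = np.vstack(fwd)
            rows.append((X - X.mean(axis=0)).ravel())
            prov.append((im, il))
            Xr = np.vstack(rev[::-1])
            rows.append((Xr - Xr.mean(axis=0)).ravel())
            prov.append((im, -il))
    return np.array(rows), prov
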