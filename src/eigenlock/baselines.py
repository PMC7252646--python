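"""Comparison clustering methods for time-varying phase-locking networks.

Baselines against which the prime-eigenvector dynamics are judged:

* single-linkage hierarchical clustering of the per-window distance matrix
  cut at a branch-depth threshold (equivalently, connected components of
  the d < threshold graph, which matches how the eigenvector pipeline
  defines edges);
* greedy (Newman agglomerative) modularity maximization, fed either the
  weighted matrix (distances converted to similarities) or the thresholded
  binary adjacency;
* overlap-based temporal tracking that stitches per-window partitions into
  a labelled cluster timeline by greedy maximal Jaccard matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "ClusterTimeline",
    "hierarchical_partition",
    "modularity_partition",
    "track_clusters",
]

#: Regularizer of the distance -> similarity map used in weighted modularity.
SIMILARITY_EPS = 1e-6


def _check_square(matrix: np.ndarray) -> np.ndarray:
    m = np.array(matrix, dtype=float)  # copy: callers mutate the diagonal
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(m, m.T):
        raise ValueError("matrix must be symmetric")
    return m


def hierarchical_partition(distances: np.ndarray,
                           depth_threshold: float) -> np.ndarray:
    """Single-linkage dendrogram cut at a branch-depth threshold.

    Oscillators end up in one cluster iff they are connected by a chain of
    pairwise distances strictly below ``depth_threshold``.  Returns
    positive integer labels, one per oscillator.
    """
    d = _check_square(distances)
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="single")
    # fcluster merges at distance <= t; shave the threshold so that ties at
    # exactly the threshold stay separate, matching the strict edge rule.
    t = np.nextafter(depth_threshold, -np.inf)
    return fcluster(z, t=t, criterion="distance")


def modularity_partition(matrix: np.ndarray, mode: str = "thresholded") -> np.ndarray:
    """Greedy modularity community labels of a weighted or binary matrix.

    ``mode="thresholded"`` expects a binary adjacency.  ``mode="weighted"``
    expects a *distance* matrix and converts it to edge similarities
    ``s = 1 / (eps + d)`` so that tightly locked pairs carry large weight.
    Uses the deterministic Newman agglomerative scheme (Clauset-Newman-
    Moore greedy modularity).  Returns positive integer labels.
    """
    m = _check_square(matrix)
    n = m.shape[0]
    if mode == "weighted":
        np.fill_diagonal(m, np.inf)
        if np.any(m < 0):
            raise ValueError("distances must be nonnegative")
        weights = 1.0 / (SIMILARITY_EPS + m)
    elif mode == "thresholded":
        if np.any((m != 0) & (m != 1)):
            raise ValueError("thresholded mode expects a 0/1 adjacency")
        weights = m.copy()
        np.fill_diagonal(weights, 0.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if np.any(weights < 0):
        raise ValueError("negative weights are not allowed")

    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu = np.triu_indices(n, k=1)
    for i, j, w in zip(iu[0], iu[1], weights[iu]):
        if w > 0:
            g.add_edge(int(i), int(j), weight=float(w))
    labels = np.zeros(n, dtype=int)
    if g.number_of_edges() == 0:
        return np.arange(1, n + 1)
    communities = nx.community.greedy_modularity_communities(g, weight="weight")
    for cid, nodes in enumerate(communities, start=1):
        labels[list(nodes)] = cid
    return labels


@dataclass
class ClusterTimeline:
    """Per-window oscillator labels with continuity across windows."""

    labels: np.ndarray  # (n_windows, n_oscillators) positive ints

    @property
    def n_windows(self) -> int:
        return self.labels.shape[0]

    @property
    def n_oscillators(self) -> int:
        return self.labels.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-form (window, oscillator, label) table."""
        w, o = np.meshgrid(np.arange(self.n_windows),
                           np.arange(self.n_oscillators), indexing="ij")
        return pd.DataFrame({
            "window": w.ravel(), "oscillator": o.ravel(),
            "label": self.labels.ravel(),
        })


def _jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b)


def track_clusters(partitions: list[np.ndarray]) -> ClusterTimeline:
    """Stitch per-window partitions into a continuous cluster timeline.

    Labels propagate window to window by greedy maximal Jaccard overlap
    (largest overlap matched first; ties resolved toward the lower
    previous label); clusters with no overlapping predecessor get fresh
    labels.  Zero-overlap matches never propagate a label.
    """
    if not partitions:
        raise ValueError("need at least one partition")
    n = len(partitions[0])
    parts = []
    for p in partitions:
        p = np.asarray(p, dtype=int)
        if p.shape != (n,):
            raise ValueError("all partitions must cover the same oscillator set")
        parts.append(p)

    out = np.zeros((len(parts), n), dtype=int)
    next_label = 1

    def clusters_of(p: np.ndarray) -> list[frozenset]:
        return [frozenset(np.flatnonzero(p == v).tolist()) for v in np.unique(p)]

    prev_assign: dict[frozenset, int] = {}
    for w, p in enumerate(parts):
        cur = clusters_of(p)
        assign: dict[frozenset, int] = {}
        if w == 0:
            for c in sorted(cur, key=lambda c: min(c)):
                assign[c] = next_label
                next_label += 1
        else:
            # greedy maximal-overlap matching, largest Jaccard first
            cands = sorted(
                ((_jaccard(c, q), lbl, c)
                 for c in cur for q, lbl in prev_assign.items()
                 if c & q),
                key=lambda t: (-t[0], t[1]),
            )
            used_cur: set[frozenset] = set()
            used_lbl: set[int] = set()
            for j, lbl, c in cands:
                if c in used_cur or lbl in used_lbl:
                    continue
                assign[c] = lbl
                used_cur.add(c)
                used_lbl.add(lbl)
            for c in sorted(set(cur) - used_cur, key=min):
                assign[c] = next_label
                next_label += 1
        for c, lbl in assign.items():
            out[w, list(c)] = lbl
        prev_assign = assign
    return ClusterTimeline(labels=out)
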