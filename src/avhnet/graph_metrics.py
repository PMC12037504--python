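"""Segregation and integration metrics on binarized graphs.

Definitions (standard binary-graph formulations):

* clustering coefficient Cp — mean over nodes of 2*triangles/(deg*(deg-1)),
  nodes of degree < 2 contributing 0;
* characteristic path length Lp — mean BFS shortest-path length over
  connected pairs; disconnected pairs are excluded from the mean by default
  (``lp_mode="exclude"``) or the mean is restricted to the largest component
  (``lp_mode="largest-component"``), with the component count recorded either
  way, since thresholded networks can fragment at low sparsity;
* global efficiency Eglob — mean over all pairs of 1/d with 1/inf = 0;
* local efficiency Eloc — mean over nodes of the global efficiency of each
  node's neighborhood subgraph (Latora-Marchiori), degree < 2 contributing 0.

Degree-0/1 nodes stay in every average so the denominator is N for all
subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .connectivity import BinaryGraph
from .errors import UndefinedMetricError

LP_MODES = ("exclude", "largest-component")


@dataclass
class GraphMetrics:
    """The four per-graph metrics plus the component count."""

    cp: float
    lp: float
    eloc: float
    eglob: float
    n_components: int


def _adj(g: BinaryGraph) -> np.ndarray:
    return np.ascontiguousarray(g.adjacency, dtype=np.uint8)


def n_components(g: BinaryGraph) -> int:
    labels = _kernels.component_labels(_adj(g))
    return int(labels.max()) + 1


def clustering_coefficient(g: BinaryGraph) -> float:
    if g.n < 3:
        raise UndefinedMetricError("clustering needs at least 3 nodes")
    return float(_kernels.clustering_mean(_adj(g)))


def characteristic_path_length(g: BinaryGraph,
                               lp_mode: str = "exclude") -> float:
    """Mean shortest-path length; see module docstring for fragmentation
    handling."""
    if g.edge_count == 0:
        raise UndefinedMetricError("path length undefined on edgeless graph")
    if lp_mode not in LP_MODES:
        raise ValueError(f"lp_mode must be one of {LP_MODES}")
    adj = _adj(g)
    if lp_mode == "largest-component":
        labels = _kernels.component_labels(adj)
        sizes = np.bincount(labels)
        keep = np.flatnonzero(labels == int(np.argmax(sizes)))
        adj = np.ascontiguousarray(adj[np.ix_(keep, keep)])
    dist = _kernels.bfs_distances(adj)
    lp, _ = _kernels.lp_eglob_from_dist(dist)
    return float(lp)


def global_efficiency(g: BinaryGraph) -> float:
    if g.n < 2:
        raise UndefinedMetricError("efficiency needs at least 2 nodes")
    dist = _kernels.bfs_distances(_adj(g))
    _, eg = _kernels.lp_eglob_from_dist(dist)
    return float(eg)


def local_efficiency(g: BinaryGraph) -> float:
    if g.n < 2:
        raise UndefinedMetricError("efficiency needs at least 2 nodes")
    return float(_kernels.local_efficiency_mean(_adj(g)))


def compute_metrics(g: BinaryGraph, lp_mode: str = "exclude") -> GraphMetrics:
    """All four metrics in one pass (shares the BFS distance matrix)."""
    adj = _adj(g)
    dist = _kernels.bfs_distances(adj)
    _, eglob = _kernels.lp_eglob_from_dist(dist)
    labels = _kernels.component_labels(adj)
    ncomp = int(labels.max()) + 1
    if g.edge_count == 0:
        raise UndefinedMetricError("path length undefined on edgeless graph")
    if lp_mode == "largest-component":
        lp = characteristic_path_length(g, lp_mode=lp_mode)
    else:
        lp, _ = _kernels.lp_eglob_from_dist(dist)
    return GraphMetrics(
        cp=float(_kernels.clustering_mean(adj)),
        lp=float(lp),
        eloc=float(_kernels.local_efficiency_mean(adj)),
        eglob=float(eglob),
        n_components=ncomp,
    )
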