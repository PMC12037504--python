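"""Degree-preserving null models, small-world normalization, and AUC summary.

Each empirical graph is compared against an ensemble of Maslov-Sneppen
rewired graphs (double edge swaps, preserving the degree sequence exactly).
gamma = Cp / <Cp_null>, lambda = Lp / <Lp_null>, and small-worldness
sigma = gamma / lambda; sigma > 1 (with gamma > 1, lambda >~ 1) is the usual
small-world signature. Metric curves across the sparsity grid are summarized
by their trapezoidal area under the curve (AUC), one scalar per metric per
subject.

Defaults: 100 null graphs per empirical graph and 10 successful swaps per
edge, the usual mixing heuristic; both are configurable and the larger
simulation studies in the test suite scale the ensemble down. Nulls are not forced to
be connected: their Lp uses the same disconnected-pair rule as the empirical
graph, which keeps the lambda ratio unbiased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .connectivity import BinaryGraph, SparsityGrid, CorrMatrix, sparsity_sweep
from .errors import DegenerateNullError, InsufficientDataError
from .graph_metrics import (characteristic_path_length, clustering_coefficient,
                            compute_metrics)

DEFAULT_N_NULL = 100
DEFAULT_SWAP_FACTOR = 10.0

#: Metrics emitted per subject by :func:`metric_curves`.
METRIC_NAMES = ("cp", "lp", "eloc", "eglob", "gamma", "lambda", "sigma")

_MAX_ATTEMPT_FACTOR = 100  # attempts allowed per requested swap


@dataclass
class SmallWorldMetrics:
    gamma: float
    lambda_: float
    sigma: float
    n_null: int
    null_cp_mean: float
    null_lp_mean: float


@dataclass
class MetricCurve:
    """A metric's value at each sparsity level of the sweep."""

    metric_name: str
    sparsities: list[float]
    values: list[float]

    def __post_init__(self):
        if len(self.sparsities) != len(self.values):
            raise ValueError("sparsities and values must have equal length")
        if any(b <= a for a, b in zip(self.sparsities, self.sparsities[1:])):
            raise ValueError("sparsities must be strictly increasing")


@dataclass
class MetricAUC:
    metric_name: str
    auc: float


def rewire_preserving_degree(g: BinaryGraph, swap_factor: float = DEFAULT_SWAP_FACTOR,
                             rng_seed: int = 0) -> BinaryGraph:
    """Randomize a graph by double edge swaps, preserving every degree.

    Performs ``swap_factor * edge_count`` successful swaps (attempts are
    capped; a graph admitting no legal swap, e.g. a complete graph, comes
    back as an isomorphic copy with a warning).
    """
    if g.edge_count < 2:
        raise InsufficientDataError("rewiring needs at least 2 edges")
    n_target = int(round(swap_factor * g.edge_count))
    adj, successes = _kernels.rewire_degree_preserving(
        np.ascontiguousarray(g.adjacency, dtype=np.uint8),
        n_target, _MAX_ATTEMPT_FACTOR * max(n_target, 1), int(rng_seed))
    if n_target > 0 and successes == 0:
        warnings.warn(
            "no legal double edge swap exists; returning the graph unchanged",
            stacklevel=2)
    return BinaryGraph(adjacency=adj, sparsity=g.sparsity)


def normalized_small_world(g: BinaryGraph, n_null: int = DEFAULT_N_NULL,
                           swap_factor: float = DEFAULT_SWAP_FACTOR,
                           rng_seed: int = 0) -> SmallWorldMetrics:
    """gamma, lambda, sigma of a graph against its rewired null ensemble.

    ``swap_factor=0`` is the self-normalization test hook: every null is the
    graph itself, so gamma = lambda = sigma = 1.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    cp = clustering_coefficient(g)
    lp = characteristic_path_length(g)
    # one swap chain per ensemble: burn-in of swap_factor * E successful
    # swaps, then a snapshot every E swaps
    n_burn = int(round(swap_factor * g.edge_count))
    n_thin = g.edge_count if swap_factor > 0 else 0
    null_cp, null_lp, _ = _kernels.null_cp_lp_ensemble(
        np.ascontiguousarray(g.adjacency, dtype=np.uint8),
        n_null, n_burn, n_thin, _MAX_ATTEMPT_FACTOR * max(n_burn, 1),
        int(rng_seed))
    cp_mean = float(np.mean(null_cp))
    lp_mean = float(np.nanmean(null_lp))
    if cp_mean == 0 or lp_mean == 0 or not np.isfinite(lp_mean):
        raise DegenerateNullError(
            f"null reference mean degenerate (cp={cp_mean}, lp={lp_mean})")
    gamma = cp / cp_mean
    lam = lp / lp_mean
    return SmallWorldMetrics(gamma=gamma, lambda_=lam, sigma=gamma / lam,
                             n_null=n_null, null_cp_mean=cp_mean,
                             null_lp_mean=lp_mean)


def auc(curve: MetricCurve) -> MetricAUC:
    """Trapezoidal area under the metric curve over the sparsity grid."""
    if len(curve.sparsities) < 2:
        raise InsufficientDataError("AUC needs at least 2 grid points")
    val = float(np.trapezoid(curve.values, curve.sparsities))
    return MetricAUC(metric_name=curve.metric_name, auc=val)


def metric_curves(corr: CorrMatrix, grid: SparsityGrid,
                  n_null: int = DEFAULT_N_NULL,
                  swap_factor: float = DEFAULT_SWAP_FACTOR,
                  rng_seed: int = 0, ranking: str = "signed",
                  lp_mode: str = "exclude") -> dict[str, MetricCurve]:
    """All seven metric curves (cp, lp, eloc, eglob, gamma, lambda, sigma)
    for one subject across the sparsity sweep.

    Null ensembles at each level consume seeds derived from ``rng_seed`` so
    the whole sweep is reproducible.
    """
    graphs = sparsity_sweep(corr, grid, ranking=ranking)
    values: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    for lvl, g in enumerate(graphs):
        m = compute_metrics(g, lp_mode=lp_mode)
        sw = normalized_small_world(
            g, n_null=n_null, swap_factor=swap_factor,
            rng_seed=(int(rng_seed) + 7919 * lvl) % 2**31)
        values["cp"].append(m.cp)
        values["lp"].append(m.lp)
        values["eloc"].append(m.eloc)
        values["eglob"].append(m.eglob)
        values["gamma"].append(sw.gamma)
        values["lambda"].append(sw.lambda_)
        values["sigma"].append(sw.sigma)
    return {name: MetricCurve(name, list(grid.levels), vals)
            for name, vals in values.items()}


def curve_aucs(curves: dict[str, MetricCurve]) -> dict[str, float]:
    return {name: auc(c).auc for name, c in curves.items()}
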