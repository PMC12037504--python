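"""Per-subject correlation matrices and sparsity-threshold binarization.

Pearson correlations between all region pairs give an N x N matrix per
subject-session; each matrix is binarized at a sweep of sparsity levels
(fraction of possible edges retained), which fixes the edge count at every
level and thereby equates network density across subjects. By default edges
are ranked by signed correlation (strongest positive first); ``absolute``
ranking is available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateSparsityError, InsufficientDataError

RANKING_MODES = ("signed", "absolute")


def _round_half_away(x: float) -> int:
    """round() with halves away from zero (not banker's rounding)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass
class CorrMatrix:
    """Symmetric correlation matrix with unit diagonal."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("correlation matrix contains non-finite entries")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("correlation matrix is not symmetric")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 1.0)
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryGraph:
    """Undirected, unweighted adjacency at one sparsity level."""

    adjacency: np.ndarray
    sparsity: float
    edge_count: int = field(init=False)

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        self.adjacency = a.astype(np.uint8)
        self.edge_count = int(self.adjacency.sum()) // 2

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    def edges(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return list(zip(i.tolist(), j.tolist()))


@dataclass
class SparsityGrid:
    """Uniform sparsity sweep; default 0.08-0.48 in steps of 0.01."""

    s_min: float = 0.08
    s_max: float = 0.48
    step: float = 0.01
    levels: list[float] = field(init=False)

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("step must be positive")
        if not 0 < self.s_min <= self.s_max < 1:
            raise ValueError("need 0 < s_min <= s_max < 1")
        n_steps = int(round((self.s_max - self.s_min) / self.step))
        levels = [round(self.s_min + k * self.step, 10)
                  for k in range(n_steps + 1)]
        self.levels = [s for s in levels if s <= self.s_max + 1e-12]

    def __len__(self) -> int:
        return len(self.levels)


def correlation_matrix(timeseries: np.ndarray) -> CorrMatrix:
    """Pearson correlations between all column pairs of a T x N matrix.

    Zero-variance columns get correlation 0 to every other node (with a
    warning) rather than NaN; fewer than 3 timepoints is an error.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be 2-D (T x N)")
    if ts.shape[0] < 3:
        raise InsufficientDataError(
            f"need at least 3 timepoints, got {ts.shape[0]}")
    constant = np.flatnonzero(np.ptp(ts, axis=0) == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ts, rowvar=False)
    if constant.size:
        warnings.warn(
            f"zero-variance column(s) {constant.tolist()}: correlations "
            "set to 0", stacklevel=2)
        r[constant, :] = 0.0
        r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return CorrMatrix(values=r)


def threshold_by_sparsity(corr: CorrMatrix, s: float,
                          ranking: str = "signed") -> BinaryGraph:
    """Binarize at sparsity ``s``: keep the round(s*N(N-1)/2) strongest edges.

    ``signed`` ranking keeps the largest correlations (strongest positive
    first, conventionally excluding negative edges at usual sparsities);
    ``absolute`` ranks by |r|. Ties break by lexicographic (i, j) order.
    """
    if not 0 < s < 1:
        raise ValueError(f"sparsity must be in (0,1), got {s}")
    if ranking not in RANKING_MODES:
        raise ValueError(f"ranking must be one of {RANKING_MODES}")
    n = corr.n
    n_pairs = n * (n - 1) // 2
    k = _round_half_away(s * n_pairs)
    if k < 1:
        raise DegenerateSparsityError(
            f"sparsity {s} retains 0 of {n_pairs} edges")
    iu, ju = np.triu_indices(n, 1)
    vals = corr.values[iu, ju]
    key = np.abs(vals) if ranking == "absolute" else vals
    # stable sort on descending key; np.argsort is stable with 'stable' kind,
    # and (iu, ju) are already in lexicographic order
    order = np.argsort(-key, kind="stable")[:k]
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[iu[order], ju[order]] = 1
    adj |= adj.T
    return BinaryGraph(adjacency=adj, sparsity=s)


def sparsity_sweep(corr: CorrMatrix, grid: SparsityGrid,
                   ranking: str = "signed") -> list[BinaryGraph]:
    """One BinaryGraph per grid level; edge sets are nested across levels."""
    return [threshold_by_sparsity(corr, s, ranking=ranking)
            for s in grid.levels]
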