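"""Network-based statistic (NBS) on edgewise connectivity differences.

Edgewise tests run on Fisher z-transformed correlations (variance
stabilization): a two-sample t per edge for unpaired designs (HC vs SZ,
responders vs non-responders) or a one-sample t on within-pair differences
for the paired pre/post design. Edges exceeding the primary threshold are
collected into connected components (nodes linked by shared endpoints) and
each observed component's extent (edge count) is referred to the
permutation distribution of the maximum component size — group-label
exchange for unpaired designs, per-pair sign flips for paired ones — with
the add-one rule p = (1 + #{max >= observed}) / (1 + n_perm), so p is never
exactly zero.

The primary threshold defaults to the t-value of a two-sided p < 0.01 at
the design's degrees of freedom; component extent can optionally be
replaced by the summed supra-threshold t-mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .connectivity import CorrMatrix
from .errors import InsufficientDataError, PairingError

DEFAULT_P_PRIMARY = 0.01
DEFAULT_N_PERM = 5000
DESIGNS = ("unpaired", "paired")
DIRECTIONS = ("greater", "less")
_Z_CLIP = 0.999999


@dataclass
class EdgeStatMatrix:
    t_values: np.ndarray  # N x N symmetric, zero diagonal
    design: str
    df: int

    @property
    def n(self) -> int:
        return self.t_values.shape[0]


@dataclass
class Component:
    edges: list[tuple[int, int]]  # 0-based (i, j), i < j
    size: int                     # edge count (the NBS extent statistic)
    p_perm: float = np.nan
    mass: float = np.nan          # summed |t| over the component's edges


@dataclass
class NBSResult:
    components: list[Component]
    threshold_t: float
    n_perm: int
    alpha: float
    direction: str
    null_max_sizes: np.ndarray = field(default_factory=lambda: np.empty(0))

    def significant(self) -> list[Component]:
        return [c for c in self.components if c.p_perm < self.alpha]


def fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -_Z_CLIP, _Z_CLIP))


def _stack_z(matrices: list[CorrMatrix]) -> tuple[np.ndarray, int]:
    """(subjects x edges) Fisher-z upper-triangle stack."""
    n = matrices[0].n
    iu, ju = np.triu_indices(n, 1)
    z = np.stack([fisher_z(m.values[iu, ju]) for m in matrices])
    return z, n


def _t_two_sample(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per column: (mean_a - mean_b)/se."""
    na, nb = xa.shape[0], xb.shape[0]
    ma, mb = xa.mean(axis=0), xb.mean(axis=0)
    va = xa.var(axis=0, ddof=1)
    vb = xb.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def _t_one_sample(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    m = d.mean(axis=0)
    v = d.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(v / n)
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def edgewise_stats(matrices_a: list[CorrMatrix], matrices_b: list[CorrMatrix],
                   design: str = "unpaired") -> EdgeStatMatrix:
    """Per-edge t statistics on Fisher-z correlations.

    Unpaired: two-sample t (positive t means group a > group b). Paired:
    one-sample t on the per-pair differences a - b (lists aligned by
    position; positive t means a > b).
    """
    if design not in DESIGNS:
        raise ValueError(f"design must be one of {DESIGNS}")
    if len(matrices_a) < 2 or len(matrices_b) < 2:
        raise InsufficientDataError("need at least 2 subjects per group")
    za, n = _stack_z(matrices_a)
    zb, n2 = _stack_z(matrices_b)
    if n != n2:
        raise PairingError("groups have different node counts")
    if design == "paired":
        if za.shape[0] != zb.shape[0]:
            raise PairingError(
                f"paired design needs aligned lists, got "
                f"{za.shape[0]} vs {zb.shape[0]}")
        t_flat = _t_one_sample(za - zb)
        df = za.shape[0] - 1
    else:
        t_flat = _t_two_sample(za, zb)
        df = za.shape[0] + zb.shape[0] - 2
    iu, ju = np.triu_indices(n, 1)
    t = np.zeros((n, n))
    t[iu, ju] = t_flat
    t += t.T
    return EdgeStatMatrix(t_values=t, design=design, df=df)


def primary_threshold(df: int, p_thr: float = DEFAULT_P_PRIMARY) -> float:
    """t-value of a two-sided p < ``p_thr`` at ``df`` degrees of freedom."""
    return float(stats.t.ppf(1.0 - p_thr / 2.0, df))


def _components_from_mask(mask: np.ndarray) -> list[Component]:
    iu, ju = np.triu_indices(mask.shape[0], 1)
    sup = mask[iu, ju]
    if not sup.any():
        return []
    ei, ej = iu[sup], ju[sup]
    adj = sparse.coo_matrix(
        (np.ones(ei.size), (ei, ej)), shape=mask.shape)
    _, labels = connected_components(adj, directed=False)
    comps: dict[int, list[tuple[int, int]]] = {}
    for a, b in zip(ei.tolist(), ej.tolist()):
        comps.setdefault(int(labels[a]), []).append((a, b))
    out = [Component(edges=e, size=len(e)) for e in comps.values()]
    out.sort(key=lambda c: c.size, reverse=True)
    return out


def supra_threshold_components(stats_mat: EdgeStatMatrix, t_thr: float,
                               direction: str = "greater") -> list[Component]:
    """Connected components of edges with t beyond the primary threshold."""
    if t_thr <= 0:
        raise ValueError("t_thr must be positive")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    t = stats_mat.t_values
    mask = (t > t_thr) if direction == "greater" else (t < -t_thr)
    comps = _components_from_mask(mask)
    for c in comps:
        c.mass = float(sum(abs(t[i, j]) for i, j in c.edges))
    return comps


def _max_component_size(t_flat: np.ndarray, iu, ju, n: int, t_thr: float,
                        direction: str, statistic: str) -> float:
    sup = (t_flat > t_thr) if direction == "greater" else (t_flat < -t_thr)
    if not sup.any():
        return 0.0
    ei, ej = iu[sup], ju[sup]
    adj = sparse.coo_matrix((np.ones(ei.size), (ei, ej)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    comp_of_edge = labels[ei]
    if statistic == "extent":
        return float(np.bincount(comp_of_edge).max())
    mass = np.zeros(labels.max() + 1)
    np.add.at(mass, comp_of_edge, np.abs(t_flat[sup]))
    return float(mass.max())


def nbs_from_stacks(za: np.ndarray, zb: np.ndarray, n: int,
                    design: str = "unpaired", t_thr: float | None = None,
                    p_thr: float = DEFAULT_P_PRIMARY,
                    n_perm: int = DEFAULT_N_PERM, rng_seed: int = 0,
                    direction: str = "greater", alpha: float = 0.05,
                    statistic: str = "extent") -> NBSResult:
    """NBS core on pre-stacked (subjects x edges) data (upper-triangle order).

    Used directly for quantities that are already on a test-ready scale
    (e.g. per-patient edge-change matrices); :func:`nbs_permutation` is the
    correlation-matrix front end.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if statistic not in ("extent", "mass"):
        raise ValueError("statistic must be 'extent' or 'mass'")
    if design not in DESIGNS:
        raise ValueError(f"design must be one of {DESIGNS}")
    iu, ju = np.triu_indices(n, 1)
    if design == "paired":
        if za.shape[0] != zb.shape[0]:
            raise PairingError("paired design needs aligned stacks")
        t_flat_obs = _t_one_sample(za - zb)
        df = za.shape[0] - 1
    else:
        t_flat_obs = _t_two_sample(za, zb)
        df = za.shape[0] + zb.shape[0] - 2
    t_mat = np.zeros((n, n))
    t_mat[iu, ju] = t_flat_obs
    t_mat += t_mat.T
    obs = EdgeStatMatrix(t_values=t_mat, design=design, df=df)
    if t_thr is None:
        t_thr = primary_threshold(obs.df, p_thr)
    comps = supra_threshold_components(obs, t_thr, direction=direction)
    rng = np.random.default_rng(int(rng_seed))
    max_sizes = np.empty(n_perm)
    if design == "paired":
        d = za - zb
        n_pairs = d.shape[0]
        for p in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=n_pairs)
            t_flat = _t_one_sample(d * signs[:, None])
            max_sizes[p] = _max_component_size(
                t_flat, iu, ju, n, t_thr, direction, statistic)
    else:
        pooled = np.vstack([za, zb])
        na = za.shape[0]
        s = pooled.shape[0]
        for p in range(n_perm):
            idx = rng.permutation(s)
            t_flat = _t_two_sample(pooled[idx[:na]], pooled[idx[na:]])
            max_sizes[p] = _max_component_size(
                t_flat, iu, ju, n, t_thr, direction, statistic)

    for c in comps:
        obs_stat = c.size if statistic == "extent" else c.mass
        c.p_perm = float((1 + np.sum(max_sizes >= obs_stat)) / (1 + n_perm))
    return NBSResult(components=comps, threshold_t=float(t_thr),
                     n_perm=n_perm, alpha=alpha, direction=direction,
                     null_max_sizes=max_sizes)


def nbs_permutation(matrices_a: list[CorrMatrix], matrices_b: list[CorrMatrix],
                    design: str = "unpaired", t_thr: float | None = None,
                    p_thr: float = DEFAULT_P_PRIMARY,
                    n_perm: int = DEFAULT_N_PERM, rng_seed: int = 0,
                    direction: str = "greater", alpha: float = 0.05,
                    statistic: str = "extent") -> NBSResult:
    """Full NBS on correlation matrices: Fisher-z edgewise stats,
    supra-threshold components, max-component-size permutation p-values."""
    # run edgewise_stats for its validation (subject counts, alignment)
    edgewise_stats(matrices_a, matrices_b, design=design)
    za, n = _stack_z(matrices_a)
    zb, _ = _stack_z(matrices_b)
    return nbs_from_stacks(za, zb, n, design=design, t_thr=t_thr,
                           p_thr=p_thr, n_perm=n_perm, rng_seed=rng_seed,
                           direction=direction, alpha=alpha,
                           statistic=statistic)
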