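"""Responder stratification by AHRS change and subgroup connectivity tests.

A patient is a responder when the fractional AHRS reduction from baseline
to post-treatment, (pre - post) / pre, is at least 0.5 (boundary
inclusive). The rule is scale-free: rescaling all scores by a positive
constant leaves the labels unchanged. Patients lacking either session are
excluded listwise before classification (the caller logs the count).

Connectivity change between the subgroups is compared edgewise on the
per-patient pre-to-post Fisher-z change matrices with an unpaired NBS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, DegenerateVarianceError, ParameterError
from .nbs import EdgeStatMatrix, NBSResult, nbs_from_stacks, _t_two_sample

RESPONSE_THRESHOLD = 0.5

RESPONDER = "responder"
NON_RESPONDER = "non_responder"


@dataclass
class ResponderLabeling:
    labels: list[str]
    pct_reduction: np.ndarray
    n_resp: int
    n_nonresp: int

    @property
    def rate(self) -> float:
        """Responder percentage, 100 * n_resp / total."""
        return 100.0 * self.n_resp / (self.n_resp + self.n_nonresp)

    @property
    def mask(self) -> np.ndarray:
        return np.array([lab == RESPONDER for lab in self.labels])


def classify_responders(ahrs_pre, ahrs_post,
                        threshold: float = RESPONSE_THRESHOLD) -> ResponderLabeling:
    """Label each patient by the >= 50% AHRS-reduction rule (inclusive)."""
    pre = np.asarray(ahrs_pre, dtype=float)
    post = np.asarray(ahrs_post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre/post score vectors must be paired")
    if np.any(pre <= 0):
        bad = np.flatnonzero(pre <= 0).tolist()
        raise ParameterError(
            f"baseline AHRS must be positive to define a fractional "
            f"reduction; offending patient position(s): {bad}")
    reduction = (pre - post) / pre
    labels = [RESPONDER if r >= threshold else NON_RESPONDER
              for r in reduction]
    n_resp = sum(lab == RESPONDER for lab in labels)
    return ResponderLabeling(labels=labels, pct_reduction=100.0 * reduction,
                             n_resp=n_resp, n_nonresp=len(labels) - n_resp)


def compare_responder_connectivity(
    deltas: list[np.ndarray], labeling: ResponderLabeling,
    t_thr: float | None = None, p_thr: float = 0.01,
    n_perm: int = 5000, rng_seed: int = 0, direction: str = "less",
    alpha: float = 0.05,
) -> tuple[EdgeStatMatrix, NBSResult]:
    """Unpaired edgewise comparison of per-patient edge-change matrices
    (responders vs non-responders), NBS-corrected.

    ``deltas`` are N x N symmetric change matrices (post - pre, Fisher-z
    scale), one per patient, aligned with ``labeling``. The default
    direction ``less`` asks where responders' connectivity decreased more.
    """
    if len(deltas) != len(labeling.labels):
        raise ValueError("one delta matrix per labeled patient required")
    mask = labeling.mask
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise InsufficientDataError(
            f"need >= 2 patients per subgroup, got "
            f"{int(mask.sum())}/{int((~mask).sum())}")
    n = deltas[0].shape[0]
    iu, ju = np.triu_indices(n, 1)
    stack = np.stack([np.asarray(d, dtype=float)[iu, ju] for d in deltas])
    if np.all(stack.var(axis=0) == 0):
        raise DegenerateVarianceError(
            "all edge changes identical across patients")
    za = stack[mask]
    zb = stack[~mask]
    t_flat = _t_two_sample(za, zb)
    t_mat = np.zeros((n, n))
    t_mat[iu, ju] = t_flat
    t_mat += t_mat.T
    stats = EdgeStatMatrix(t_values=t_mat, design="unpaired",
                           df=len(deltas) - 2)
    result = nbs_from_stacks(za, zb, n, design="unpaired", t_thr=t_thr,
                             p_thr=p_thr, n_perm=n_perm, rng_seed=rng_seed,
                             direction=direction, alpha=alpha)
    return stats, result
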