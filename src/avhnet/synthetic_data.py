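"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a two-group resting-state study on the packaged
35-region AVH network: healthy controls (HC, baseline only) and patients
(SZ, paired baseline/post sessions), each subject-session a T x 35 Gaussian
time series drawn from a modular population correlation matrix plus white
observation noise.

Population structure
--------------------
Nodes are partitioned into four modules (temporal/auditory, prefrontal,
subcortical, parietal/visual). The population correlation matrix is built
as an explicit factor model — guaranteeing positive semi-definiteness —
whose Gram matrix realizes a set of correlation tiers:

* ``r_within`` between ordinary peers of the same module, ``r_within_hub``
  between each module's connector hubs and their peers (so thresholded
  modules assemble around their hub rather than fragmenting);
* ``r_club`` between hubs of different modules (a rich-club backbone that
  keeps the thresholded graph connected at 8% density, as small-world
  cortical networks are), ``r_bridge`` between hubs and other modules'
  periphery, and a low ``r_between`` background elsewhere.

Patient baseline pathology is planted as three effects, mirroring the
segregation/integration deficits and focal hyperconnectivity reported for
schizophrenia with hallucinations:

* ``sz_segregation_deficit`` — subtractive shrink of within-module
  correlations (lowers clustering, local efficiency, gamma and sigma of
  the binarized graphs);
* ``sz_integration_deficit`` — proportional shrink of the hub-mediated
  bridge and club ties that integrate modules;
* ``sz_node_attenuation`` — attenuation of all ties of a designated set of
  decoupled (sensory/visual) nodes, which isolates them at threshold and
  drags down clustering and global/local efficiency.

A hyperconnectivity web — two focal edges (defaults TPJ.L-LPFC.L and
MTG.R-DPUT.R) plus a connected set of neighbors over the temporal /
prefrontal / striatal / parietal hallucination circuit — is elevated by
``delta_hyper`` at patient baseline via per-edge factors drawn from the
endpoints' idiosyncratic variance (so the matrix stays a valid
correlation matrix). After treatment, responders have
``restoration_fraction`` of the deficits reversed (clustering and
decoupling more than the bridge deficit; see the ``restore_*_share``
fields), and every patient's web-edge Fisher-z change is tied linearly to
their fractional AHRS reduction with slope ``coupling_slope`` plus noise,
so symptom improvement and connectivity reduction correlate.

Exactly ``round(responder_fraction * n_sz)`` patients are made responders
(fractional AHRS reductions drawn in [0.50, 0.75]; non-responders in
[0.05, 0.45], leaving the 50% boundary unambiguous). Demographics are
drawn near the study's marginals (age ~ 24.5 +/- 5.8 y, FD ~ 0.28 +/- 0.05
mm, AHRS ~ 25.2 +/- 5.1 at baseline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .connectivity import CorrMatrix, correlation_matrix
from .data_io import Cohort, NodeTable, SubjectRecord, load_packaged_node_table
from .errors import ParameterError

logger = logging.getLogger(__name__)

#: Default node-to-module assignment over the packaged 35-node atlas
#: (1-based node indices; editable).
DEFAULT_MODULES: dict[str, list[int]] = {
    "temporal_auditory": [1, 4, 9, 13, 27, 28, 29],
    "prefrontal": [5, 6, 7, 14, 15, 16, 19, 22, 23, 30, 32],
    "subcortical": [8, 11, 12, 34],
    "parietal_visual": [2, 3, 10, 17, 18, 20, 21, 24, 25, 26, 31, 33, 35],
}

#: Connector hubs carrying the elevated between-module ties (1-based).
#: Disjoint from the hyperconnectivity web below so the planted treatment
#: effects ride on ordinary (non-backbone) edges.
DEFAULT_HUBS: list[int] = [11, 14, 19, 20, 23, 24, 27, 30]

#: Sensory/visual nodes decoupled in patients (1-based).
DEFAULT_DECOUPLED: list[int] = [2, 3, 4, 10, 17, 21, 25, 35]

#: Hyperconnected edges at patient baseline, by (1-based) node index:
#: TPJ.L-LPFC.L and MTG.R-DPUT.R, the two symptom-coupled pathways.
DEFAULT_HYPER_EDGES: list[tuple[int, int]] = [(26, 16), (28, 12)]

#: The wider hyperconnectivity web around the focal edges (temporal /
#: prefrontal / striatal / parietal regions implicated in hallucination
#: circuits); elevated at baseline and reduced after treatment like the
#: focal edges, so pre-to-post reductions form one connected component
#: rather than isolated edges (singleton components can never reach
#: significance under the extent-based network statistic).
DEFAULT_HYPER_NETWORK: list[tuple[int, int]] = [
    (16, 28),  # LPFC.L - MTG.R (joins the two focal edges)
    (26, 22),  # TPJ.L - SPFC.L
    (26, 7),   # TPJ.L - MPFC
    (28, 8),   # MTG.R - IPUT.R
    (16, 6),   # LPFC.L - IFG.L
    (12, 8),   # DPUT.R - IPUT.R
    (22, 31),  # SPFC.L - IPL.L
    (7, 31),   # MPFC - IPL.L
    (6, 29),   # IFG.L - ITG.L
    (29, 31),  # ITG.L - IPL.L
    (12, 22),  # DPUT.R - SPFC.L
]


@dataclass
class CohortSpec:
    """Parameters of the synthetic study; defaults are the study conditions."""

    n_hc: int = 47
    n_sz: int = 40
    t_len: int = 180
    modules: dict[str, list[int]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_MODULES.items()})
    hubs: list[int] = field(default_factory=lambda: list(DEFAULT_HUBS))
    decoupled_nodes: list[int] = field(
        default_factory=lambda: list(DEFAULT_DECOUPLED))
    r_within: float = 0.50
    r_within_hub: float = 0.55
    r_between: float = 0.10
    r_bridge: float = 0.22
    r_club: float = 0.60
    sz_segregation_deficit: float = 0.14
    sz_integration_deficit: float = 0.04
    sz_node_attenuation: float = 0.60
    restoration_fraction: float = 0.8
    # share of each deficit reversed in responders (x restoration_fraction):
    # clustering recovers, sensory decoupling recovers most, and the bridge
    # deficit only partly, mirroring the partial-normalization pattern
    restore_seg_share: float = 0.85
    restore_att_share: float = 0.75
    restore_int_share: float = 0.5
    hyper_edges: list[tuple[int, int]] = field(
        default_factory=lambda: list(DEFAULT_HYPER_EDGES))
    hyper_network_edges: list[tuple[int, int]] = field(
        default_factory=lambda: list(DEFAULT_HYPER_NETWORK))
    delta_hyper: float = 0.15
    coupling_slope: float = 0.5
    coupling_noise_sd: float = 0.25
    noise_sd: float = 0.3
    subject_jitter_sd: float = 0.02
    responder_fraction: float = 0.675
    ahrs_pre_mean: float = 25.2
    ahrs_pre_sd: float = 5.1
    rng_seed: int = 0

    def __post_init__(self):
        assigned = sorted(i for nodes in self.modules.values() for i in nodes)
        n = len(assigned)
        if assigned != list(range(1, n + 1)):
            raise ParameterError(
                "modules must partition nodes 1..N without gaps or overlap")
        if not 0 < self.responder_fraction < 1:
            raise ParameterError("responder_fraction must be in (0, 1)")
        if not 0 <= self.restoration_fraction <= 1:
            raise ParameterError("restoration_fraction must be in [0, 1]")
        if self.t_len < 3:
            raise ParameterError("t_len must be at least 3")
        for lvl in (self.r_within, self.r_between, self.r_bridge):
            if not -1 < lvl < 1:
                raise ParameterError("correlation levels must lie in (-1, 1)")

    @property
    def n_nodes(self) -> int:
        return sum(len(v) for v in self.modules.values())

    @property
    def n_responders(self) -> int:
        return int(round(self.responder_fraction * self.n_sz))


@dataclass
class SubjectEffects:
    """Per-subject modifiers applied on top of the group-level structure."""

    jitter_within: float = 0.0
    jitter_bridge: float = 0.0
    restoration: float = 0.0           # fraction of deficits reversed (post)
    hyper_z: dict[tuple[int, int], float] = field(default_factory=dict)


def _module_masks(spec: CohortSpec) -> np.ndarray:
    """n x n boolean mask of within-module pairs (diagonal False)."""
    n = spec.n_nodes
    block = np.zeros(n, dtype=int)
    for b, (_, nodes) in enumerate(spec.modules.items()):
        for i in nodes:
            block[i - 1] = b
    within = block[:, None] == block[None, :]
    np.fill_diagonal(within, False)
    return within


def build_population_covariance(
    spec: CohortSpec, group: str, session: str = "baseline",
    subject_effects: SubjectEffects | None = None,
    psd_repair: bool = True,
) -> np.ndarray:
    """Population correlation matrix (unit diagonal, PSD by construction).

    The matrix is the Gram matrix of an explicit factor model — one latent
    factor per module (hub nodes loading more strongly than peers), a
    hub-loaded integration factor producing the ``r_bridge`` /
    ``r_between`` / ``r_club`` between-module tiers, a club-only factor,
    and one factor per planted hyperconnectivity edge — plus idiosyncratic
    variance bringing every node to unit variance. HC matrices carry the
    base structure (peer-peer within-module entries equal ``r_within``
    exactly); SZ baseline scales the module factors down (segregation
    deficit), the hub integration loadings down (integration deficit), the
    decoupled nodes' loadings down (sensory decoupling), and elevates the
    hyperconnectivity web; SZ post reverses the deficits according to the
    subject's restoration and sets the hyper edges from the subject's
    coupled Fisher-z values (capped by the nodes' idiosyncratic-variance
    budget so the result stays a valid correlation matrix).
    """
    eff = subject_effects or SubjectEffects()
    n = spec.n_nodes
    hub_mask = np.zeros(n, dtype=bool)
    hub_mask[[h - 1 for h in spec.hubs]] = True

    # effective correlation tiers for this subject-session
    r_b = spec.r_between
    r_w = spec.r_within + eff.jitter_within
    r_wh = spec.r_within_hub + eff.jitter_within
    r_brg = spec.r_bridge + eff.jitter_bridge
    r_clb = spec.r_club + eff.jitter_bridge
    att = 0.0
    if group == "SZ":
        restore = eff.restoration if session == "post" else 0.0
        # treatment response restores clustering and sensory decoupling
        # more than the bridge deficit -- efficiency and clustering
        # normalize partially while integration stays somewhat reduced
        seg = spec.sz_segregation_deficit * (1 - spec.restore_seg_share * restore)
        integ = spec.sz_integration_deficit * (1 - spec.restore_int_share * restore)
        att = spec.sz_node_attenuation * (1 - spec.restore_att_share * restore)
        r_w -= seg
        r_wh -= seg
        if spec.r_bridge > 0:
            u = max((spec.r_bridge - integ) / spec.r_bridge, 0.0)
            r_brg *= u
            r_clb *= u

    # factor geometry from the effective tiers
    p_p = np.sqrt(r_b) if r_b > 0 else 0.0
    if r_brg > 0 and p_p == 0:
        raise ParameterError("r_bridge > 0 requires r_between > 0")
    p_h = r_brg / p_p if p_p > 0 else 0.0
    if p_p > 0 and spec.r_club < (spec.r_bridge / p_p) ** 2 - 1e-9:
        raise ParameterError(
            f"infeasible tiers: need r_club >= r_bridge^2 / r_between "
            f"({(spec.r_bridge / p_p) ** 2:.3f}), got {spec.r_club}")
    # a jitter-induced shortfall realizes the club tier at p_h^2 instead of
    # the requested value
    g = np.sqrt(max(r_clb - p_h ** 2, 0.0))
    a_p2 = r_w - r_b
    if a_p2 < 0:
        raise ParameterError("r_within must exceed r_between")
    a_p = np.sqrt(a_p2)
    a_h = (r_wh - r_brg) / a_p if a_p > 0 else 0.0

    n_mod = len(spec.modules)
    load = np.zeros((n, n_mod + 2))
    for m, (_, nodes) in enumerate(spec.modules.items()):
        for node in nodes:
            i = node - 1
            load[i, m] = a_h if hub_mask[i] else a_p
    load[:, n_mod] = np.where(hub_mask, p_h, p_p)
    load[:, n_mod + 1] = np.where(hub_mask, g, 0.0)

    if att > 0:
        dec = np.zeros(n, dtype=bool)
        dec[[d - 1 for d in spec.decoupled_nodes]] = True
        load[dec] *= 1.0 - att

    cov = load @ load.T
    committed = np.sum(load ** 2, axis=1)
    if committed.max() > 0.985:
        raise ParameterError(
            f"node variance over-committed ({committed.max():.3f} > 0.985); "
            "lower the correlation tiers")
    np.fill_diagonal(cov, 1.0)  # idiosyncratic variance fills to 1

    if group == "SZ":
        # planted hyperconnectivity: per-edge factors drawn from the
        # endpoints' idiosyncratic budget, so PSD is preserved
        budget = 1.0 - committed - 0.02
        for (a, b) in list(spec.hyper_edges) + list(spec.hyper_network_edges):
            i, j = a - 1, b - 1
            if session == "post" and (a, b) in eff.hyper_z:
                target = float(np.tanh(eff.hyper_z[(a, b)]))
            else:
                target = cov[i, j] + spec.delta_hyper
            delta = target - cov[i, j]
            cap = max(min(budget[i], budget[j]), 0.0)
            delta = float(np.clip(delta, -cap, cap))
            cov[i, j] += delta
            cov[j, i] = cov[i, j]
            budget[i] -= abs(delta)
            budget[j] -= abs(delta)

    if psd_repair:
        w = np.linalg.eigvalsh(cov)
        if w[0] < -1e-10:  # safety net; unreachable for valid specs
            logger.warning("covariance not PSD (min eig %.3g); repairing",
                           w[0])
            cov = _nearest_psd(cov)
    return cov


def _nearest_psd(mat: np.ndarray) -> np.ndarray:
    """Eigenvalue-clipped PSD repair, renormalized to unit diagonal."""
    w, v = np.linalg.eigh(mat)
    w = np.clip(w, 1e-8, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2


def _draw_jitter(rng: np.random.Generator, sd: float) -> float:
    """Subject-level tier jitter, truncated at 2.5 sd so extreme draws
    cannot over-commit a node's variance budget."""
    return float(np.clip(rng.normal(0, sd), -2.5 * sd, 2.5 * sd))


def simulate_timeseries(cov: np.ndarray, t_len: int, noise_sd: float,
                        rng: np.random.Generator) -> np.ndarray:
    """T x N draw: correlated Gaussian signal plus white observation noise."""
    n = cov.shape[0]
    lchol = np.linalg.cholesky(cov + 1e-10 * np.eye(n))
    z = rng.standard_normal((t_len, n))
    ts = z @ lchol.T
    if noise_sd > 0:
        ts = ts + noise_sd * rng.standard_normal((t_len, n))
    return ts


def simulate_cohort(spec: CohortSpec,
                    node_table: NodeTable | None = None) -> Cohort:
    """Generate the full cohort: records with time series, demographics,
    AHRS/PANSS scores, and paired baseline/post sessions for patients."""
    node_table = node_table or load_packaged_node_table()
    if node_table.n != spec.n_nodes:
        raise ParameterError(
            f"module partition covers {spec.n_nodes} nodes but node table "
            f"has {node_table.n}")
    rng = np.random.default_rng(int(spec.rng_seed))
    records: list[SubjectRecord] = []

    # --- healthy controls: single baseline session -----------------------
    for i in range(spec.n_hc):
        eff = SubjectEffects(
            jitter_within=_draw_jitter(rng, spec.subject_jitter_sd),
            jitter_bridge=_draw_jitter(rng, spec.subject_jitter_sd))
        cov = build_population_covariance(spec, "HC", "baseline", eff)
        ts = simulate_timeseries(cov, spec.t_len, spec.noise_sd, rng)
        records.append(SubjectRecord(
            subject_id=f"HC{i + 1:03d}", group="HC", session="baseline",
            age=float(np.clip(rng.normal(24.9, 5.0), 18, 45)),
            sex="male" if rng.random() < 29 / 48 else "female",
            fd=float(np.clip(rng.normal(0.27, 0.03), 0.05, None)),
            timeseries=ts))

    # --- patients: responder assignment and AHRS trajectories ------------
    resp_flags = np.zeros(spec.n_sz, dtype=bool)
    resp_flags[rng.choice(spec.n_sz, size=spec.n_responders,
                          replace=False)] = True
    frac_red = np.where(resp_flags,
                        rng.uniform(0.50, 0.75, spec.n_sz),
                        rng.uniform(0.05, 0.45, spec.n_sz))
    ahrs_pre = np.clip(rng.normal(spec.ahrs_pre_mean, spec.ahrs_pre_sd,
                                  spec.n_sz), 8.0, None)
    ahrs_post = ahrs_pre * (1.0 - frac_red)

    panss_pre = {"panss_pos": (21.5, 4.1), "panss_neg": (19.2, 4.7),
                 "panss_gen": (43.0, 8.6), "panss_total": (89.7, 11.6)}
    panss_post = {"panss_pos": (18.3, 3.0), "panss_neg": (19.6, 5.7),
                  "panss_gen": (44.3, 8.1), "panss_total": (79.3, 11.6)}

    for i in range(spec.n_sz):
        sid = f"SZ{i + 1:03d}"
        age = float(np.clip(rng.normal(24.5, 5.8), 18, 45))
        sex = "male" if rng.random() < 27 / 47 else "female"
        fd = float(np.clip(rng.normal(0.28, 0.05), 0.05, None))
        jit_w = _draw_jitter(rng, spec.subject_jitter_sd)
        jit_b = _draw_jitter(rng, spec.subject_jitter_sd)

        eff_pre = SubjectEffects(jitter_within=jit_w, jitter_bridge=jit_b)
        cov_pre = build_population_covariance(spec, "SZ", "baseline", eff_pre)
        hyper_z_post = {}
        for (a, b) in list(spec.hyper_edges) + list(spec.hyper_network_edges):
            z_pre = float(np.arctanh(cov_pre[a - 1, b - 1]))
            dz = spec.coupling_slope * frac_red[i] + rng.normal(
                0, spec.coupling_noise_sd)
            hyper_z_post[(a, b)] = z_pre - dz
        eff_post = SubjectEffects(
            jitter_within=jit_w, jitter_bridge=jit_b,
            restoration=spec.restoration_fraction if resp_flags[i] else 0.0,
            hyper_z=hyper_z_post)
        cov_post = build_population_covariance(spec, "SZ", "post", eff_post)

        clin = dict(subject_id=sid, group="SZ", age=age, sex=sex, fd=fd)
        records.append(SubjectRecord(
            session="baseline", ahrs=float(ahrs_pre[i]),
            **{k: float(np.clip(rng.normal(*v), 1, None))
               for k, v in panss_pre.items()},
            timeseries=simulate_timeseries(cov_pre, spec.t_len,
                                           spec.noise_sd, rng),
            **clin))
        records.append(SubjectRecord(
            session="post", ahrs=float(ahrs_post[i]),
            **{k: float(np.clip(rng.normal(*v), 1, None))
               for k, v in panss_post.items()},
            timeseries=simulate_timeseries(cov_post, spec.t_len,
                                           spec.noise_sd, rng),
            **clin))

    return Cohort(node_table=node_table, records=records)


def write_cohort(cohort: Cohort, directory, node_table_name="node_table.tsv",
                 clinical_name="clinical.csv") -> None:
    """Emit the cohort in the exact formats the loaders read."""
    from pathlib import Path

    import pandas as pd

    from . import data_io

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data_io.write_node_table(cohort.node_table, directory / node_table_name)
    rows = []
    for rec in cohort.records:
        rows.append({c: getattr(rec, c) for c in data_io.CLINICAL_COLUMNS})
        if rec.timeseries is not None:
            np.savetxt(directory / f"{rec.subject_id}_{rec.session}.tsv",
                       rec.timeseries, delimiter="\t", fmt="%.10g")
    pd.DataFrame(rows).to_csv(directory / clinical_name, index=False)


def recovery_report(spec: CohortSpec, n_reps: int = 10, rng_seed: int = 0,
                    **analysis_kwargs) -> dict:
    """Run the full pipeline on ``n_reps`` regenerated cohorts and report
    detection rates for every planted effect.

    Returns a dict with, per replicate-averaged quantity: the rate of
    detecting HC > SZ-baseline deficits in cp/eloc/eglob/sigma AUCs, of
    detecting post > pre recovery in eloc/eglob/sigma, of NBS-detecting
    each planted hyper-edge reduction, and the median recovered
    edge-change/AHRS-change correlation (with its positive-sign rate).
    """
    from .pipeline import AnalysisConfig, analyze_cohort

    if n_reps < 2:
        raise ParameterError("n_reps must be at least 2")
    config = AnalysisConfig(**analysis_kwargs)
    deficit_metrics = ("cp", "eloc", "eglob", "sigma")
    recovery_metrics = ("eloc", "eglob", "sigma")
    hits_deficit = {m: 0 for m in deficit_metrics}
    hits_recovery = {m: 0 for m in recovery_metrics}
    hits_hyper = {e: 0 for e in spec.hyper_edges}
    rs = []
    for rep in range(n_reps):
        rep_spec = replace(spec, rng_seed=(int(rng_seed) + 104729 * rep)
                           % 2**31)
        cohort = simulate_cohort(rep_spec)
        res = analyze_cohort(cohort, replace(
            config, rng_seed=(config.rng_seed + 15485863 * rep) % 2**31))
        for comp in res["comparisons"]:
            if (comp.contrast == "HC_vs_pre"
                    and comp.metric_name in deficit_metrics
                    and comp.p_fdr < config.fdr_alpha
                    and comp.direction > 0):
                hits_deficit[comp.metric_name] += 1
            if (comp.contrast == "pre_vs_post"
                    and comp.metric_name in recovery_metrics
                    and comp.p_fdr < config.fdr_alpha
                    and comp.direction > 0):  # post - pre increase
                hits_recovery[comp.metric_name] += 1
        sig_edges = {e for c in res["nbs_pre_post"].significant()
                     for e in c.edges}
        for (a, b) in spec.hyper_edges:
            key = (min(a, b) - 1, max(a, b) - 1)
            if key in sig_edges:
                hits_hyper[(a, b)] += 1
        # coupling recovery: correlate each planted edge's z-reduction with
        # the AHRS reduction, independently of NBS significance
        pairs = cohort.paired_patients()
        d_ahrs = np.array([p.ahrs - q.ahrs for p, q in pairs])
        edge_rs = []
        for (a, b) in spec.hyper_edges:
            i, j = a - 1, b - 1
            red = []
            for p, q in pairs:
                zp = np.arctanh(np.clip(np.corrcoef(
                    p.timeseries[:, i], p.timeseries[:, j])[0, 1],
                    -0.999999, 0.999999))
                zq = np.arctanh(np.clip(np.corrcoef(
                    q.timeseries[:, i], q.timeseries[:, j])[0, 1],
                    -0.999999, 0.999999))
                red.append(zp - zq)
            edge_rs.append(float(np.corrcoef(red, d_ahrs)[0, 1]))
        rs.append(float(np.mean(edge_rs)))
    return {
        "n_reps": n_reps,
        "deficit_detection": {m: hits_deficit[m] / n_reps
                              for m in deficit_metrics},
        "recovery_detection": {m: hits_recovery[m] / n_reps
                               for m in recovery_metrics},
        "hyper_edge_detection": {f"{a}-{b}": hits_hyper[(a, b)] / n_reps
                                 for (a, b) in spec.hyper_edges},
        "median_coupling_r": float(np.median(rs)) if rs else np.nan,
        "coupling_r_positive_rate": (float(np.mean([r > 0 for r in rs]))
                                     if rs else np.nan),
    }
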