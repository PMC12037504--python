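"""End-to-end orchestration: connectivity -> metrics -> null normalization
-> AUC -> group inference -> NBS -> responder analysis -> correlations.

``analyze_cohort`` runs the whole analysis on an in-memory :class:`Cohort`
and returns a result dict; ``run_pipeline`` wraps it with file loading and
plain-text report writing driven by a :class:`RunConfig` (YAML-loadable).

Reproducibility: the master seed is fanned out to the stochastic stages
(per-subject null ensembles, pre/post NBS, responder NBS) through
``numpy.random.SeedSequence`` spawning in a fixed order, so a rerun with
the same config and seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import (CorrMatrix, RANKING_MODES, SparsityGrid,
                           correlation_matrix)
from .data_io import (Cohort, attach_timeseries, load_clinical,
                      load_node_table)
from .errors import ConfigError
from .graph_metrics import LP_MODES
from .group_inference import (ComparisonResult, CorrelationResult,
                              compare_auc_tables, correlate_with_symptoms)
from .nbs import fisher_z, nbs_permutation
from .null_models import METRIC_NAMES, curve_aucs, metric_curves
from .responder_analysis import (classify_responders,
                                 compare_responder_connectivity)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Tunable parameters of one analysis run (defaults = study conditions)."""

    s_min: float = 0.08
    s_max: float = 0.48
    step: float = 0.01
    ranking: str = "signed"
    lp_mode: str = "exclude"
    n_null: int = 100
    swap_factor: float = 10.0
    nbs_p_thr: float = 0.01
    nbs_t_thr: float | None = None
    nbs_n_perm: int = 5000
    nbs_statistic: str = "extent"
    fdr_alpha: float = 0.05
    responder_threshold: float = 0.5
    rng_seed: int = 0

    def violations(self) -> list[str]:
        out = []
        if self.step <= 0:
            out.append(f"step must be positive, got {self.step}")
        elif not 0 < self.s_min <= self.s_max < 1:
            out.append(f"need 0 < s_min <= s_max < 1, got "
                       f"[{self.s_min}, {self.s_max}]")
        if self.ranking not in RANKING_MODES:
            out.append(f"unknown ranking {self.ranking!r}")
        if self.lp_mode not in LP_MODES:
            out.append(f"unknown lp_mode {self.lp_mode!r}")
        if self.n_null < 1:
            out.append(f"n_null must be >= 1, got {self.n_null}")
        if self.swap_factor < 0:
            out.append(f"swap_factor must be >= 0, got {self.swap_factor}")
        if self.nbs_n_perm < 100:
            out.append(f"nbs_n_perm must be >= 100, got {self.nbs_n_perm}")
        if not 0 < self.nbs_p_thr < 1:
            out.append(f"nbs_p_thr must be in (0,1), got {self.nbs_p_thr}")
        if not 0 < self.fdr_alpha < 1:
            out.append(f"fdr_alpha must be in (0,1), got {self.fdr_alpha}")
        if not 0 < self.responder_threshold < 1:
            out.append("responder_threshold must be in (0,1)")
        return out

    @property
    def grid(self) -> SparsityGrid:
        return SparsityGrid(self.s_min, self.s_max, self.step)


@dataclass
class RunConfig:
    """AnalysisConfig plus the on-disk locations of inputs and outputs."""

    node_table: str = ""
    timeseries_dir: str = ""
    clinical: str = ""
    output_dir: str = "avhnet_out"
    dedupe_nodes: bool = False
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        ana = AnalysisConfig(**raw.pop("analysis", {}))
        return cls(analysis=ana, **raw)

    def violations(self) -> list[str]:
        out = self.analysis.violations()
        for name in ("node_table", "clinical"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                out.append(f"{name} path does not exist: {p}")
        if self.timeseries_dir and not Path(self.timeseries_dir).is_dir():
            out.append(f"timeseries_dir is not a directory: "
                       f"{self.timeseries_dir}")
        return out


def validate_config(config: RunConfig | AnalysisConfig) -> list[str]:
    """List configuration violations without running anything."""
    return config.violations()


def _stage_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % 2**31)


def analyze_cohort(cohort: Cohort, config: AnalysisConfig | None = None) -> dict:
    """Run every analysis stage on an in-memory cohort.

    Returns a dict with the per-subject AUC table, metric curves, the
    FDR-corrected comparison list, the paired pre/post NBS (direction
    ``less``: connectivity reductions after treatment), responder labels
    and their subgroup NBS, and edge-change vs AHRS-change correlations
    for NBS-significant edges.
    """
    config = config or AnalysisConfig()
    bad = config.violations()
    if bad:
        raise ConfigError("; ".join(bad))
    grid = config.grid
    ss = np.random.SeedSequence(int(config.rng_seed))
    ss_metrics, ss_nbs, ss_resp = ss.spawn(3)

    # stage 1-3: correlation, thresholding sweep, metrics + normalization
    corr: dict[tuple[str, str], CorrMatrix] = {}
    curves: dict[tuple[str, str], dict] = {}
    aucs_by_key: dict[tuple[str, str], dict[str, float]] = {}
    auc_rows = []
    record_seeds = ss_metrics.spawn(len(cohort.records))
    for rec, seed in zip(cohort.records, record_seeds):
        key = (rec.subject_id, rec.session)
        cm = (CorrMatrix(values=rec.corr) if rec.corr is not None
              else correlation_matrix(rec.timeseries))
        corr[key] = cm
        cv = metric_curves(cm, grid, n_null=config.n_null,
                           swap_factor=config.swap_factor,
                           rng_seed=_stage_seed(seed),
                           ranking=config.ranking, lp_mode=config.lp_mode)
        curves[key] = cv
        aucs_by_key[key] = curve_aucs(cv)
        for metric, a in aucs_by_key[key].items():
            auc_rows.append(dict(subject_id=rec.subject_id, group=rec.group,
                                 session=rec.session, metric=metric, auc=a))
    auc_table = pd.DataFrame(auc_rows)

    # stage 4: covariate-adjusted group comparisons with family-wide FDR
    group_keys = {"HC": ("HC", "baseline"), "pre": ("SZ", "baseline"),
                  "post": ("SZ", "post")}
    auc_by_group: dict[str, dict[str, np.ndarray]] = {}
    cov_by_group: dict[str, np.ndarray] = {}
    for gkey, (grp, ses) in group_keys.items():
        recs = cohort.select(grp, ses)
        if not recs:
            continue
        auc_by_group[gkey] = {
            m: np.array([aucs_by_key[(r.subject_id, ses)][m] for r in recs])
            for m in METRIC_NAMES}
        cov_by_group[gkey] = np.array(
            [[r.age, r.sex_code, r.fd] for r in recs])
    comparisons: list[ComparisonResult] = []
    if len(auc_by_group) >= 2:
        comparisons = compare_auc_tables(auc_by_group, cov_by_group)

    # stage 5: paired pre/post NBS on edgewise connectivity (reductions)
    pairs = cohort.paired_patients()
    nbs_pre_post = None
    if len(pairs) >= 2:
        pre_mats = [corr[(p.subject_id, "baseline")] for p, _ in pairs]
        post_mats = [corr[(p.subject_id, "post")] for p, _ in pairs]
        nbs_pre_post = nbs_permutation(
            post_mats, pre_mats, design="paired", t_thr=config.nbs_t_thr,
            p_thr=config.nbs_p_thr, n_perm=config.nbs_n_perm,
            rng_seed=_stage_seed(ss_nbs), direction="less",
            alpha=config.fdr_alpha, statistic=config.nbs_statistic)

    # stage 6: responder classification and subgroup connectivity change
    responders = None
    nbs_responders = None
    deltas = []
    if pairs:
        pre_scores = np.array([p.ahrs for p, _ in pairs])
        post_scores = np.array([q.ahrs for _, q in pairs])
        responders = classify_responders(pre_scores, post_scores,
                                         threshold=config.responder_threshold)
        n = cohort.node_table.n
        for p, q in pairs:
            deltas.append(fisher_z(corr[(q.subject_id, "post")].values)
                          - fisher_z(corr[(p.subject_id, "baseline")].values))
        for d in deltas:
            np.fill_diagonal(d, 0.0)
        if (responders.n_resp >= 2 and responders.n_nonresp >= 2):
            _, nbs_responders = compare_responder_connectivity(
                deltas, responders, t_thr=config.nbs_t_thr,
                p_thr=config.nbs_p_thr, n_perm=config.nbs_n_perm,
                rng_seed=_stage_seed(ss_resp), alpha=config.fdr_alpha)

    # stage 7: edge-change vs symptom-change correlations on significant edges
    correlations: list[CorrelationResult] = []
    if nbs_pre_post is not None and responders is not None:
        d_ahrs = np.array([p.ahrs - q.ahrs for p, q in pairs])  # reduction
        seen = set()
        for comp in nbs_pre_post.significant():
            for (i, j) in comp.edges:
                if (i, j) in seen:
                    continue
                seen.add((i, j))
                edge_red = np.array([-d[i, j] for d in deltas])  # z decrease
                correlations.append(correlate_with_symptoms(
                    edge_red, d_ahrs,
                    x_name=f"edge_{i + 1}_{j + 1}",
                    y_name="delta_ahrs"))

    provenance = dict(config=dataclasses.asdict(config),
                      seed=int(config.rng_seed),
                      n_records=len(cohort.records),
                      n_nodes=cohort.node_table.n,
                      software_version=__version__)
    return dict(auc_table=auc_table, curves=curves, comparisons=comparisons,
                nbs_pre_post=nbs_pre_post, responders=responders,
                nbs_responders=nbs_responders, correlations=correlations,
                pairs=[(p.subject_id) for p, _ in pairs],
                provenance=provenance)


def _comparisons_frame(comparisons) -> pd.DataFrame:
    return pd.DataFrame([dict(metric=c.metric_name, contrast=c.contrast,
                              t=c.statistic, df=c.df, p_raw=c.p_raw,
                              p_fdr=c.p_fdr, direction=c.direction)
                         for c in comparisons])


def _nbs_frame(result, node_table) -> pd.DataFrame:
    rows = []
    if result is not None:
        for cid, comp in enumerate(result.components):
            for (i, j) in comp.edges:
                rows.append(dict(
                    node_i_abbrev=node_table.abbrevs[i],
                    node_j_abbrev=node_table.abbrevs[j],
                    node_i=i + 1, node_j=j + 1,
                    component_id=cid, component_size=comp.size,
                    p_perm=comp.p_perm))
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Load inputs, run :func:`analyze_cohort`, write all plain-text outputs.

    Writes per-subject metric curves (long TSV), AUC table, comparison and
    correlation tables, NBS reports, responder labels, and a deterministic
    machine-readable ``summary.json``.
    """
    bad = validate_config(config)
    if bad:
        raise ConfigError("; ".join(bad))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("loading inputs")
    node_table = load_node_table(config.node_table, dedupe=config.dedupe_nodes)
    records = load_clinical(config.clinical)
    attach_timeseries(records, config.timeseries_dir, node_table)
    cohort = Cohort(node_table=node_table, records=records)

    res = analyze_cohort(cohort, config.analysis)

    curve_rows = []
    for (sid, ses), cv in res["curves"].items():
        for metric, curve in cv.items():
            for s, v in zip(curve.sparsities, curve.values):
                curve_rows.append(dict(subject_id=sid, session=ses,
                                       sparsity=s, metric=metric, value=v))
    pd.DataFrame(curve_rows).to_csv(out_dir / "metric_curves.tsv", sep="\t",
                                    index=False)
    res["auc_table"].to_csv(out_dir / "metric_aucs.tsv", sep="\t", index=False)
    _comparisons_frame(res["comparisons"]).to_csv(
        out_dir / "group_comparisons.tsv", sep="\t", index=False)
    _nbs_frame(res["nbs_pre_post"], node_table).to_csv(
        out_dir / "nbs_pre_post.tsv", sep="\t", index=False)
    _nbs_frame(res["nbs_responders"], node_table).to_csv(
        out_dir / "nbs_responders.tsv", sep="\t", index=False)
    if res["responders"] is not None:
        lab = res["responders"]
        pd.DataFrame(dict(subject_id=res["pairs"],
                          pct_reduction=lab.pct_reduction,
                          label=lab.labels)).to_csv(
            out_dir / "responder_labels.csv", index=False)
    pd.DataFrame([dict(x=c.x_name, y=c.y_name, n=c.n, r=c.r, p=c.p)
                  for c in res["correlations"]]).to_csv(
        out_dir / "correlations.tsv", sep="\t", index=False)

    summary = dict(
        provenance=dict(res["provenance"],
                        run_config={k: v for k, v in
                                    dataclasses.asdict(config).items()}),
        n_significant_comparisons=int(sum(
            c.p_fdr < config.analysis.fdr_alpha for c in res["comparisons"])),
        nbs_pre_post_components=[
            dict(size=c.size, p_perm=c.p_perm)
            for c in (res["nbs_pre_post"].components
                      if res["nbs_pre_post"] else [])],
        responder_rate=(res["responders"].rate
                        if res["responders"] else None),
        correlations=[dict(x=c.x_name, r=round(c.r, 10), p=round(c.p, 10))
                      for c in res["correlations"]],
    )
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("wrote outputs to %s", out_dir)
    res["summary"] = summary
    return res
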