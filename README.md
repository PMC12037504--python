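# avhnet

Graph-theoretic analysis of an auditory-verbal-hallucination (AVH) related
resting-state brain network. The package reimplements, as a tested and
reusable pipeline, the small-world analysis used to study how low-frequency
rTMS over the left temporoparietal junction reorganizes a 35-region
hallucination network in schizophrenia: per-subject functional
connectivity graphs, small-world and efficiency metrics normalized against
degree-preserving random graphs, covariate-adjusted group inference with
FDR, network-based-statistic (NBS) permutation tests on edges, responder
stratification, and connectivity–symptom correlations.

It is written for researchers who have preprocessed resting-state fMRI
down to regional time series (or correlation matrices) and want an
auditable, scriptable alternative to GUI toolboxes for this family of
analyses — together with a synthetic cohort generator that makes every
stage testable end to end without patient data.

## The analysis

For each subject, Pearson correlations between the time series of all 35
region pairs give a 35 × 35 matrix, binarized by **sparsity thresholding**:
at sparsity *s*, the round(*s*·N(N−1)/2) strongest edges are kept, so every
subject's graph has identical density. Over the sweep *s* = 0.08…0.48
(step 0.01) the pipeline computes:

- segregation: clustering coefficient **Cp**, local efficiency **Eloc**;
- integration: characteristic path length **Lp**, global efficiency
  **Eglob**;
- normalized metrics **γ** = Cp/⟨Cp_null⟩ and **λ** = Lp/⟨Lp_null⟩ against
  ensembles of Maslov–Sneppen degree-preserving rewired graphs, and
  small-worldness **σ = γ/λ** (σ > 1, γ > 1, λ ≳ 1 is the small-world
  signature).

Each metric curve is summarized by its trapezoidal area under the curve
(AUC), one scalar per metric per subject-session. Group inference runs on
AUCs residualized for age, sex and mean frame-wise displacement, with
Benjamini–Hochberg FDR across the metric × contrast family (controls vs
patients at baseline, controls vs post-treatment, paired pre vs post).
Edge-level inference uses the NBS: per-edge t statistics on Fisher-z
correlations, supra-threshold connected components, and family-wise error
control by permuting group labels (or flipping pair signs) and recording
the maximal component size. Patients are classified as responders by a
≥ 50% reduction of the Auditory Hallucination Rating Scale (AHRS) score,
and per-edge connectivity changes are correlated with symptom change.

## Worked example

```python
from avhnet import CohortSpec, simulate_cohort, AnalysisConfig, analyze_cohort

spec = CohortSpec(n_hc=16, n_sz=24, rng_seed=42)   # synthetic study
cohort = simulate_cohort(spec)
config = AnalysisConfig(n_null=20, nbs_n_perm=500, rng_seed=42)
res = analyze_cohort(cohort, config)
```

Printing the headline results of that run:

```text
metric   contrast      t      p_fdr
cp       HC_vs_pre    +19.40  0.0000
cp       HC_vs_post    +4.40  0.0001
cp       pre_vs_post   +6.94  0.0000
eglob    HC_vs_pre     +8.95  0.0000
eglob    HC_vs_post    +3.78  0.0005
eglob    pre_vs_post   +4.02  0.0005
sigma    HC_vs_pre    +12.20  0.0000
sigma    HC_vs_post    +3.90  0.0004
sigma    pre_vs_post   +4.78  0.0001

NBS (pre vs post, reductions): 1 significant component(s)
  13 edges, p_perm = 0.0240

responders: 16/24 (66.7%)
edge_7_26: r = +0.42, p = 0.039 (n = 24)
```

Reading this: patients at baseline have lower clustering, global
efficiency and small-worldness than controls (positive t, HC minus
patients), all three recover partially after treatment (positive paired
t, post minus pre), the paired NBS finds one 13-edge component of reduced
connectivity spanning the planted temporo-prefrontal-striatal web, and
the reduction of the TPJ.L–MPFC edge correlates with AHRS improvement
(r = 0.42). Two thirds of patients cross the 50% responder boundary —
the fraction the generator plants.

The same analysis runs from the shell on on-disk cohorts
(`avhnet simulate`, `avhnet validate`, `avhnet run --config run.yaml`);
`avhnet simulate --out dir` emits a cohort in exactly the formats the
pipeline reads (node table TSV, per-session time-series TSVs, clinical
CSV).

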