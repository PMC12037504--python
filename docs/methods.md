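# Methods

## Network construction

Per subject-session the pipeline computes Pearson correlations between all
pairs of regional time series (zero-variance regions are flagged and their
correlations set to 0) and binarizes the matrix at each level of a sparsity
sweep, default 0.08–0.48 in steps of 0.01 (41 levels; the wider 0.08–0.50
range is available through the grid configuration). At sparsity *s* exactly
round(*s*·N(N−1)/2) edges are retained — rounding half away from zero —
ranked by signed correlation in descending order, so negative edges are
effectively excluded at usual sparsities; `ranking="absolute"` ranks by
|r| instead. Ties break by lexicographic node order, making thresholding
fully deterministic. Because ranking decides retention, any monotone
transform of the correlations (e.g. Fisher's z) leaves the binary graphs
unchanged; the z-transform is therefore applied only where values are
compared on a metric scale (edgewise NBS statistics).

## Graph metrics

All metrics use the standard binary-graph formulations:

- **Cp**: mean over nodes of 2·triangles/(deg·(deg−1)); degree < 2
  contributes 0.
- **Lp**: mean BFS shortest-path length over connected ordered pairs.
  Thresholded graphs can fragment at low sparsity; by default disconnected
  pairs are excluded from the mean and the component count is recorded
  (`lp_mode="largest-component"` restricts the mean to the giant component
  instead). Both conventions are implemented because the choice is a real
  degree of freedom in this family of analyses.
- **Eglob**: mean over all pairs of 1/d with 1/∞ = 0.
- **Eloc**: mean over nodes of the global efficiency of the neighborhood
  subgraph (Latora–Marchiori); degree < 2 contributes 0.

Degree-0/1 nodes stay in every average so the denominator is N for all
subjects. The implementations are numba kernels on dense adjacency
matrices; the test suite checks all four metrics against networkx to 1e-9
on random graphs, including disconnected ones.

## Null models and small-worldness

γ = Cp/⟨Cp_null⟩, λ = Lp/⟨Lp_null⟩ and σ = γ/λ are computed against
ensembles of degree-preserving random graphs (default 100 per empirical
graph) generated by Maslov–Sneppen double edge swaps. The ensemble is one
Markov chain per graph: a burn-in of `swap_factor`·E successful swaps
(default 10 per edge, the usual mixing heuristic) followed by a snapshot
every E swaps — statistically standard thinning that is about an order of
magnitude cheaper than independent restarts. The public rewiring operation
(`rewire_preserving_degree`) performs independent full-length runs.
Nulls are not forced to be connected; their Lp uses the same
disconnected-pair rule as the empirical graph, keeping λ unbiased. Graphs
admitting no legal swap (e.g. complete graphs) are returned unchanged with
a warning; a `swap_factor` of 0 is the self-normalization test hook
(γ = λ = σ = 1 identically).

Metric curves are summarized by the trapezoidal AUC over the sweep (for a
constant curve c over [0.08, 0.48] this is 0.40·c exactly; the O(step)
difference from rectangle sums is immaterial at step 0.01).

## Group inference

Covariates (age in years, sex coded male = 1 / female = 0, mean
frame-wise displacement in mm) are handled by residualization: AUCs are
regressed on intercept + covariates over the pooled sample and the
two-sample t runs on residuals. This equals the ANCOVA group term up to
degree-of-freedom bookkeeping (the reported df is n−2, slightly
anticonservative by the number of covariates; the equivalence and the df
choice are deliberate, documented simplifications). The paired pre/post
contrast tests within-subject AUC differences directly — subject-level
covariates cancel. All tests are two-sided. The three pairwise contrasts
(HC vs pre, HC vs post, pre vs post) times the seven metrics form one
Benjamini–Hochberg FDR family per analysis run; `fdr_bh` delegates to
statsmodels and is property-tested against a brute-force step-up
implementation.

## Network-based statistic

Edgewise tests run on Fisher-z transformed correlations (variance
stabilization): two-sample t for unpaired designs, one-sample t on
within-pair differences for the paired design. Edges beyond the primary
threshold — by default the t of a two-sided p < 0.01 at the design's df,
always configurable because this choice is a known sensitivity of the
method — form connected components whose extent (edge count; summed
|t| mass optional) is referred to the permutation distribution of the
maximum component size: group-label exchange for unpaired designs,
per-pair sign flips for paired ones, 5000 permutations by default. The
add-one rule p = (1 + #{max ≥ obs})/(1 + n_perm) keeps p strictly
positive. The pipeline's pre/post NBS tests the `less` direction of
post − pre, i.e. connectivity reductions after treatment.

## Responder analysis

A patient is a responder when (AHRS_pre − AHRS_post)/AHRS_pre ≥ 0.5,
boundary inclusive; the rule is invariant to positive rescaling of the
scale. Patients without both sessions are excluded listwise with a logged
count. Subgroup comparisons run an unpaired NBS on the per-patient
pre-to-post Fisher-z change matrices.

## Synthetic cohorts

The generator provides the statistical structure the analysis assumes so
that every stage — loaders, thresholding, null normalization, inference —
can be exercised end to end. It emulates: two groups (47 controls with one
session, 40 patients with paired baseline/post sessions, the analyzed
sample sizes of the motivating study design), T = 180 timepoints per
session, demographic marginals (age ≈ 24.5 ± 5.8 y, FD ≈ 0.28 ± 0.05 mm,
AHRS ≈ 25.2 ± 5.1 at baseline), and a modular 35-node covariance.

**Population model.** An explicit factor model (one factor per module,
hub-loaded integration and rich-club factors, per-edge factors for the
hyperconnectivity web) whose Gram matrix realizes correlation tiers:
peer–peer within-module 0.50, hub–peer within 0.55, hub–hub rich club
0.60, hub–periphery bridges 0.22, background 0.10. The construction is
positive semi-definite by design, with unit diagonal; per-edge planted
values draw on the endpoints' idiosyncratic variance and are capped by it.
The rich-club backbone plus hub-centered modules keeps thresholded graphs
connected at 8% density — without it, flat block-constant structure
fragments into module-sized components at low sparsity and, under the
disconnected-pair exclusion rule, drives λ below 1, which real cortical
networks (and the small-world regime this cohort must occupy) do not show.
Subject-level tier jitter (sd 0.02, truncated at 2.5 sd) adds
between-subject heterogeneity; white observation noise (sd 0.3) attenuates
sample correlations uniformly by 1/(1+sd²), which is rank-preserving and
therefore invisible to the binarized graphs.

**Planted pathology.** Patient baselines subtract 0.14 from within-module
ties (segregation deficit → Cp, Eloc, γ, σ down), shrink hub bridge/club
ties proportionally by 0.04/0.22 (integration deficit), and attenuate all
ties of eight sensory/visual "decoupled" nodes by 0.60 — node-level
decoupling is what produces the Eglob deficit, because at fixed edge count
a pure shift of correlation levels only reshuffles ranks and cannot lower
efficiency. A 13-edge hyperconnectivity web around TPJ.L–LPFC.L and
MTG.R–DPUT.R is elevated by 0.15 at baseline. Post-treatment, responders
(exactly round(0.675·n) patients; fractional AHRS reductions uniform in
[0.50, 0.75] vs [0.05, 0.45], so the 50% boundary is never ambiguous)
reverse 85%/75%/50% of the segregation/decoupling/bridge deficits scaled
by `restoration_fraction` = 0.8, and every patient's web-edge z-value
drops by 0.5 × (fractional AHRS reduction) + N(0, 0.25) — so efficiency
recovers, clustering recovers partially, and edge change correlates
positively (r ≈ 0.3–0.5) with symptom change. Effect magnitudes are
fixture parameters chosen so the planted directions are reliably
detectable at the study's sample sizes; the web spans several edges
because a single-edge extent component cannot, by construction of the
max-extent statistic, reach significance.

**What the generator does not emulate.** Hemodynamics and autocorrelated
BOLD noise (samples are temporally white, so correlation sampling
variance is slightly optimistic for a given T), scanner/site effects,
non-Gaussian tails, and any structure–symptom coupling beyond the planted
linear web coupling. Passing recovery tests therefore demonstrates that
the pipeline detects the planted second-order structure at realistic
sample sizes — not that real fMRI effects have these magnitudes.

## Numerical and design choices

- Edge retention: signed ranking by default; both GRETNA-style options
  exposed. round() at the edge-count boundary is half-away-from-zero.
- Correlations are clipped to |r| ≤ 1−10⁻⁶ before the z-transform.
- Reproducibility: a single master seed fans out to the stochastic stages
  via `numpy.random.SeedSequence` spawning in fixed order; reruns with the
  same config are bit-identical (`summary.json` contains no timestamps).
- Degenerate inputs raise typed errors: < 3 timepoints, zero-edge
  sparsity levels, edgeless graphs for Lp, zero variances in t-tests and
  correlations, rank-deficient covariate designs (naming the collinear
  column), zero baseline AHRS.
- Scaled problem sizes in the test suite (smaller null ensembles and
  permutation counts, e.g. 5 nulls and 250 permutations in the 50-cohort
  recovery study) were chosen as the smallest sizes at which the checked
  statistics are stable; study-condition defaults (100 nulls, 5000
  permutations) are unchanged.

## Known limitations

- λ → 1 as density approaches 50%, so subject-level λ > 1 at the top of
  the sweep holds only on average; group-mean curves (the level at which
  small-world criteria are asserted) stay above 1 at every level.
- The residualization df is not reduced by the number of covariates
  (documented above).
- NBS on cohorts with broad genuine effects has a heavy permutation null
  tail (co-moving edges reappear under imbalanced relabelings/sign
  flips); component p-values near α should be read with that in mind.
- The spherical-ROI extractor averages voxels within a radius (default
  6 mm) of each coordinate with no brain mask beyond the volume bounds;
  atlas-mask extraction is out of scope.
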