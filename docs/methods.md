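# Methods notes

This note records the model, the defaults and the numerical choices behind
`metabnet`, and what the synthetic-data tests do and do not establish.

## The analysis model

A group's covariance network treats subjects as repeated observations of a
90-dimensional regional metabolism profile.  After dividing each subject's
profile by its whole-brain mean and removing age, sex and fasting-glucose
effects per region (OLS with intercept), the across-subject Pearson matrix
is binarized by connection density: for density *d* the
`round(d·N(N−1)/2)` pairs with largest |r| become edges.  Density — not a
fixed |r| cutoff — is the controlled variable so that two groups are always
compared at equal edge count, and a sweep (default 10–40%, 1% steps, both
endpoints included) replaces any single arbitrary choice.  Anticorrelations
count through |r| by default because global-mean division is known to
induce negative correlations in PET; `positive_only=True` is available as a
sensitivity mode.

Assumptions worth stating: subjects within a group are i.i.d.; covariate
effects are linear and identical across subjects; one network per group
means there is no subject-level network and hence no parametric standard
error — all inference is by relabeling.

### Residualization is per group

Each group's network is built from its own subjects, so covariate
coefficients are fitted within group (and refitted within each
pseudo-group inside the permutation loop, treating covariate adjustment as
part of network construction).  Pooled fitting would let a group-mean
difference leak into both networks.

## Graph metrics

* Clustering: `C_i = 2e_i/(k_i(k_i−1))`, computed as `diag(A³)/(k(k−1))`;
  `C_i = 0` for degree < 2 and those nodes stay in the mean, which keeps C
  defined at sparse densities.
* Path length: mean BFS distance over ordered pairs (scipy csgraph).  A
  disconnected graph is an error by default; the `connected_pairs` mode
  averages reachable pairs only and is the default inside the
  random-reference ensemble and the permutation loop, because *discarding*
  disconnected references would select for short-path realizations and
  bias λ downward at 10% density.
* Betweenness: Freeman's unordered-pairs, endpoints-excluded convention
  (networkx Brandes).  The test suite checks all three metrics against
  brute-force oracles (triangle enumeration, Floyd–Warshall, shortest-path
  counting by layer recursion) on every connected graph of the networkx
  atlas (2–7 nodes) plus seeded 8- and 10–12-node random graphs.
* Random references: degree-preserving double edge swap, 10 attempted
  swaps per edge, preserving node count, degree sequence and hence mean
  degree and degree distribution.  γ, λ use the mean of `n_random = 100`
  references for observed networks and 10 inside permutations — the
  percentile of the null absorbs the extra Monte-Carlo noise, and 100
  references per permutation would multiply runtime tenfold for no change
  in the decision.
* Hubs: `b_i = B(i)/mean(B) > 1.5`, descending order, exact ties broken by
  canonical region index.  `mean(B) = 0` (e.g. a complete graph) is an
  explicit error, not a silent NaN.

σ of a *single* sparse graph is a noisy quantity: for 90 nodes at 10%
density the clustering of one degree-preserving randomization fluctuates
~15% around the ensemble mean, so the self-calibration check (σ ≈ 1 when
the input is itself a randomization) is asserted on the mean over eight
randomized inputs rather than one.

## Permutation inference

Subjects are reassigned without replacement to pseudo-groups of the
original sizes; one relabeling sequence is reused across all densities,
metrics and regions, preserving their joint dependence.  Empirical
p-values use the `(b+1)/(n_perm+1)` convention.  Per statistic the result
stores both one-sided p-values and the 95th-percentile critical value of
each tail — the decision rule when a direction is prespecified — plus a
primary two-sided flag from the doubled minimum tail p.  The doubled rule
is the default because choosing the test direction *after* seeing the
observed sign while keeping per-tail 95% critical values would double the
type-I error to ~10%; the doubled rule holds the nominal 5% (measured
0.035–0.045 over 200-replicate null experiments).  Benjamini–Hochberg
adjusted p-values are reported alongside the uncorrected flags, which
remain primary.

Nodal comparisons run at a fixed density (default 10%, chosen as the
sparsest level at which the sweep's largest component typically spans all
90 regions; `min_full_connection_density` reports this per dataset), and
the increase and decrease decisions are reported separately.

## The synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes,
not PET physics.  A connected ring-rewired (Watts–Strogatz) graph —
default 90 nodes, even degree 8 (latent density 8/89 ≈ 9%, matching the
10% analysis density), rewiring probability 0.1 — induces a correlation
matrix `r_ij = edge_corr · corr_decay^(d_ij−1)` (defaults 0.6 and 0.5)
with shortest-path distance d.  Distance-decay matrices need not be
positive definite; eigenvalues are clipped at 1e−6 and the matrix
renormalized to unit diagonal, iterating until PD, and the repair's
maximum absolute deviation is returned (≈ 0.07 for the default graph).

Subjects are drawn as latent MVN signals plus linear effects of
standardized covariates plus N(0, noise_sd²) noise, then mapped to
positive uptake-like values as `global_i · 5 · exp(0.15·y)` with a
per-subject lognormal global factor (sd 0.2).  The exponential keeps
values positive and the global factor reproduces exactly what
whole-brain-mean division must remove.  Covariate distributions follow a
typical two-cohort design: group A age 57 ± 10, 74% male, fasting glucose
8.4 ± 0.9 mmol/L; group B 56 ± 8, 73% male, 5.1 ± 0.4 mmol/L; cohort
sizes default to 73 and 91.  Default per-region covariate effects are
small gradients with zero mean across regions — global normalization
removes the region-average component of any covariate effect, so only
relative (region-differential) effects are recoverable, and the
coefficient-recovery test accounts for the 0.15 log-slope and the
covariate standardization.

Group B can differ by degree-preserving rewiring of a stated fraction of
latent edges (optionally restricted to edges incident to chosen nodes), so
planted group differences are topological rather than degree-driven.  The
magnitude of a detectable perturbation at the study's sample sizes is a
calibration property of the design, not an external claim; the planted-hub
recovery test uses an extreme case (all six inter-module bridges moved off
one node).

What the generator does **not** model: voxel data, scanner effects,
partial volume, spatial autocorrelation, non-Gaussian metabolism
distributions, or subject-level network variability.  Passing tests
therefore show the estimators and tests behave correctly under the model's
assumptions — not that those assumptions hold for any particular scanner
or population.

Two quantitative facts about the generator that tests rely on:

* The observable log-value correlation is the planted latent correlation
  attenuated by the shared global factor, `(s²R + g²)/(s² + g²)` with
  s = 0.15, g = 0.2; Monte-Carlo consistency is asserted against that
  expression.
* Whole-brain-mean division also subtracts the *average regional signal*,
  which measurably distorts pairwise correlations when the region count is
  small and mean correlation high (the node with the highest average
  correlation is suppressed most).  At 90 regions the distortion is small;
  recovery tests that need a clean mapping from latent graph to estimated
  network therefore run at 90 regions or at low mean correlation.

## Problem sizes used in checks

The type-I-error experiment uses 200 replicates of 30-region, 30+30
cohorts with 200 permutations (mean clustering at 20% density) — small
enough to replicate hundreds of times while exercising the full
relabel → residualize → correlate → threshold → metric loop.  The
small-world check uses the full default cohort (90 regions, 73+91) with
100 references.  The pipeline's bundled demo configuration scales
everything down (25–30 regions, ~20 subjects per group, 25 permutations,
3–5 references) to keep the smoke and determinism tests fast.

## Known limitations

* Binary undirected networks only; no weighted, partial-correlation or
  sparse-inverse-covariance variants.
* The atlas ships a complete functional classification, but only 35 of
  the 90 region entries carry the `reported` provenance; the mirrored and
  assigned classes are a maintained editorial choice, flagged in the data
  file so analyses can restrict to reported entries.
* Group-level design: no per-subject networks, so no subject-level
  bootstrap or covariate-by-network interactions.
* `extract_roi_means` assumes the image and label volumes are already on
  a common grid; spatial normalization and smoothing are upstream of this
  package.
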