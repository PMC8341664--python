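# Methods

## The procedure

Given an n × p numeric table with optional class labels, a target sample
size s < n, a base seed and a trial budget T, the sampler:

1. computes per-class quotas by largest-remainder apportionment of s over
   the class frequencies (quotas sum to s exactly; a very small class may
   receive 0);
2. for each trial t = 1..T draws, with generator seed `base_seed + t`, a
   uniform without-replacement sample of the quota from each class;
3. scores the trial by the maximum over assessed variables of a two-sample
   dissimilarity between the sample's values and the *full* column;
4. returns the trial with the smallest maximum, ties broken toward the
   lowest trial seed.

Trials are evaluated in chunks of `job_size` (default 10 000); chunk
results merge by global argmin, which is associative, so the outcome is
bit-identical for any worker count. The seed schedule makes runs with
disjoint base seeds combinable into one larger search.

Because quotas are deterministic and the within-class draw is uniform,
every instance of class c is included with probability quota_c / n_c — the
selection step never distorts inclusion probabilities; it only chooses
among draws that plain stratified uniform sampling produces.

## Distribution dissimilarities

Six statistics act on raw values through ECDFs. Conventions: ECDFs are
right-continuous; suprema are evaluated at pooled jump points; ties use
midranks (Cramér–von Mises) or distinct-value blocks weighted by
multiplicity (Anderson–Darling, which reduces to the textbook k-sum on
tie-free data). Ties are the normal case here, since a sample's values are
copies of full-data values. The Anderson–Darling form is the raw

    A² = (1/nm) Σ_{k=1}^{N−1} (M_k N − n k)² / (k (N − k)),

not the standardized k-sample version, because only the argmin matters.
Kolmogorov–Smirnov, Cramér–von Mises (rank form) and the 1-Wasserstein
distance are delegated to scipy; Kuiper, the raw two-sample
Anderson–Darling and the variance-weighted ECDF distance
∫|F1−F2|/√(Fp(1−Fp)) dt (pooled-ECDF weight, intervals with Fp ∈ {0,1}
excluded) have no scipy counterpart and are implemented here. All nine
return raw dissimilarities rather than p-values: p-values would require
null calibration and cannot change an argmin.

Three distances compare kernel-density estimates. The density of a
variable is a smoothed data histogram on 200 equally spaced centers
spanning the **full** column's range (samples are subsets, hence in
range — both densities always share one grid). Each observation votes for
its s nearest centers with linear rank weights s, s−1, …, 1; weights are
normalized to a unit Riemann sum. The smoothing default is s = 20 (10% of
the grid), fixed after checking that it gives stable densities at the
subsample sizes used in the experiments while keeping the sup-norm error
against an analytic normal density below 0.05 at n = 10⁵. Rank ties break
toward the lower-index center. The symmetrized Kullback–Leibler divergence
floors kernel masses at 1e-12 and renormalizes; the mean relative
difference treats a kernel with both densities zero as contributing 0. A
constant full column yields distance 0 under every metric: any subset
preserves a point mass exactly.

## PCA reconstruction of the removed rows

The representativeness measure fits PCA on the retained sample only —
centered, unscaled covariance eigendecomposition — and reconstructs the
removed rows by projecting onto the retained components and back,

    X_reco = (X − x̄) L Lᵀ + x̄,   MSE = ‖X_reco − X_removed‖²_F / (n p).

Component retention is eigenvalue-gated, with two documented rules:

- `kaiser` (default): eigenvalue > 1. The classical criterion; sensible
  when variables are on correlation-like scales (for iris, whose leading
  covariance eigenvalues are 4.23, 0.24, 0.08, 0.02, it retains one
  component).
- `mean`: eigenvalue > mean eigenvalue. The scale-relative form, needed on
  data whose variances are far above 1; there the absolute gate retains
  every component, the projector becomes the identity, and the MSE
  degenerates to machine noise, which measures nothing.

If no eigenvalue passes the gate, the first component is kept (logged), so
a projection always exists. The `pca_importance` option of the sampler
reuses the same machinery on the *full* data to restrict the assessed
variables to those whose squared loading on some retained component
exceeds the uniform contribution 100/p; if that leaves nothing, all
variables are assessed and a warning is logged.

## Experiment grids

`evaluate_downsampling` crosses sampled fractions with trial budgets over
R replicates. A fraction maps to size round(f·n) (ties to even).
Replicate r uses base seed `base_seed + r · max(trial budgets)`, so the
trial-seed blocks of different replicates never overlap. Each cell runs
the full sampler, fits PCA on the winning sample, and records the
reconstruction MSE of the removed rows plus the retained component count;
results are exported as a tidy table (fraction, n_trials, replicate,
metric, k_components, mse) for downstream analysis of variance or
plotting by standard tools.

Problem sizes used in the shipped experiments: the 150 × 4 iris table with
fractions {1%, 10%}, budgets {1, 1000} and 20 replicates; the synthetic
10-variable mixture at n = 3000 with fractions {1%, 10%}, budgets
{1, 100} and 20 replicates; the outlier scenario with 10⁴ trials and 10
repetitions. These sizes keep a full evaluation on one CPU in the
low-minute range while leaving the replicate counts large enough for
paired one-sided tests.

## Synthetic fixtures

- 1-D three-class Gaussian mixture: priors [0.6, 0.1, 0.3], means
  [0, 4, 6], SDs [2, 0.001, 0.2]. The 10% class is a near-point "needle"
  hidden inside the broad class's right flank — the hard case for
  unlabeled downsampling. Class sizes can be drawn from the priors
  (default, n = 3000) or fixed per class, since both designs are common.
- 10-variable three-modal mixture: shared class memberships with priors
  [0.5, 0.4, 0.1]; per variable, three component means uniform in
  [1, 100] and SDs uniform in [1, 30], components relabeled in ascending
  mean order. Variances are therefore two to three orders of magnitude
  above 1, which is exactly the regime where the absolute Kaiser gate
  saturates (see limitations).
- Outlier scenario: appends consecutive integers 15…24 (count
  configurable) to a 1-D base whose own maximum is ≈ 7.2, either merged
  into a single unlabeled class or tagged as their own class.

What these fixtures do *not* emulate: heavy-tailed or strongly skewed
marginals, correlated within-class noise, measurement artifacts
(spillover, saturation) of real cytometry, and sequential dependence —
passing tests on them shows the selection machinery works as specified,
not that any particular instrument's data will reconstruct equally well.

## Numerical and design choices

- Random generator: numpy's default PCG64 throughout, seeded per trial;
  bit-equality with any other ecosystem's generator streams is explicitly
  not a goal — reproducibility is within this package.
- Largest-remainder apportionment (ties toward lower class index) makes
  quotas sum exactly to the requested size; the counting utilities use
  round-half-even per class instead, since they count hypothetical spaces
  rather than allocate a fixed budget. Both conventions are documented
  because neither is forced by the problem.
- Winner ties break by lowest trial seed: deterministic and independent of
  chunking/scheduling.
- Degenerate inputs: constant columns score 0 under all metrics; a
  constant reference collapses the density grid to a single unit-mass
  center; all-constant data makes the PCA importance filter fall back to
  all variables.
- Missing values are rejected at load rather than imputed: imputation
  would alter the very distributions the method is meant to preserve.
- Output CSVs print 17 significant digits and are parsed with round-trip
  float precision, so write→read is the identity on doubles.

## Known limitations

- The min–max criterion optimizes marginal distributions only; joint
  structure is preserved only insofar as stratification and the marginals
  imply it.
- Eigenvalue-gated reconstruction couples the retained component count k
  to the sample: at small sample sizes the eigenvalue spectrum is noisy
  and k tends to run *higher* than on large samples, which lowers the MSE
  of small samples for reasons unrelated to representativeness. On
  covariance-scale data this can mask or even invert the expected
  improvement of MSE with the sampled fraction; the trial-count effect is
  more robust but also seed-dependent at n = 3000. The tidy export
  includes k_components precisely so users can spot this confound.
- Sampling assumes exchangeable rows; sequential data (e.g. Markov chains)
  lose information under any row subsampling and are out of scope.
- Very small fractions of very small classes can round to zero retained
  instances; that is a property of proportional apportionment, and
  subgroup enrichment is deliberately not offered.
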