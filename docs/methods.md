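# Methods

## Connectivity features

A subject's resting-state scan is reduced to a T×R matrix of regional time
courses (R = 90 AAL regions by default; any R ≥ 3 is supported). The
feature vector is the upper triangle of the R×R sample Pearson correlation
matrix, flattened row-major over pairs (i, j) with 0-based i < j:
(0,1), (0,2), …, (0,R−1), (1,2), … This ordering is frozen package-wide —
feature index 0 always means the PreCG.L–PreCG.R connection in the AAL-90
atlas — because the feature-selection ranking, the persisted cluster
manifests and the region-weight computation all exchange bare feature
indices. Correlations are used raw: no Fisher z-transform, thresholding or
standardisation is applied, so every feature lives in [−1, 1].

Preprocessing of the raw images (realignment, normalisation, filtering,
nuisance regression) is upstream of this package and out of scope; the
package begins at extracted regional time series. The only
quality-control step retained is the head-motion rule: a subject is
excluded when maximum absolute translation strictly exceeds 2 mm or
rotation strictly exceeds 2°; values exactly at the limit are kept.

## The random SVM cluster

With N ≈ 60 subjects and P = 4005 features, a single SVM overfits and is
unstable. The ensemble trades the single fit for k weak, diverse members:

- the dataset is split once into train (N1 = 40), test (N2 = 2) and
  validation (N3 = 18) subsets, uniformly at random (re-drawn, bounded,
  until train and validation contain both classes);
- member t draws n = 40 training subjects and d = 62 features and fits an
  RBF SVM on that n×d slice;
- prediction is the majority vote of the k members, and reported accuracy
  is Nc/N3 on the validation subset.

d follows the √P rule, pinned to 62 for P = 4005 to match the replicated
configuration as printed (the exact root is ≈ 63.3; the difference is
immaterial).

**Bootstrap sampling.** Member samples are drawn *with* replacement by
default. With n equal to the full training-set size, sampling without
replacement would hand every member the same 40 subjects and member
diversity would come from the feature subspace alone; the bootstrap keeps
sample-level diversity at n = N1. A without-replacement mode is available
(`sample_with_replacement=False`), in which case n may not exceed N1.

**Kernel parameters.** The replication configuration fixes the RBF width
γ = 3 and a hard margin (cost = Inf). Two conventions for γ exist in the
wild: the libsvm form K(u,v) = exp(−γ‖u−v‖²) and the classical MATLAB
toolbox form K(u,v) = exp(−‖u−v‖²/(2γ²)) in which γ is the kernel *width*.
This package defaults to the width convention
(`SvmParams(gamma_convention="width")`, solver coefficient 1/(2γ²)): on 62
raw correlation features the libsvm reading of γ = 3 makes the Gram matrix
essentially diagonal, every member degenerates to a majority-class
predictor and the vote can only echo the class imbalance, whereas the
width reading reproduces the expected regime of weak (~0.65) members and a
strong ensemble. The libsvm convention remains available as
`gamma_convention="libsvm"`. The infinite cost is realised as a large
finite penalty (1e6, configurable) because the underlying solver requires
a finite value.

**Ties and determinism.** For even k a vote can tie; ties are resolved by
the sign of the summed member decision values, and an exactly zero sum
predicts the control class — deterministic and auditable. All randomness
descends from integer seeds; member t's RNG stream is derived
counter-style from (master seed, t), so a member's subsets do not depend
on how many members were built before it, and sweeps derive one child seed
per grid point up front. Persisted models are manifests of subsets +
parameters + seeds, from which every member is retrained bit-identically;
no solver internals are serialised.

**Parameter tuning.** `tune_params` grid-searches (γ, cost) by cluster
accuracy on the test subset, breaking ties toward smaller γ then smaller
cost. With the replication split the test subset has only two subjects, so
its accuracy takes values {0, ½, 1}; the tuning operation is provided for
completeness, but the replication defaults are the fixed parameters above.

## Feature selection

Members are scored individually on the *validation* subset (N3 = 18): the
test subset's two samples give accuracy granularity ½, which cannot
separate members. An out-of-bag alternative was considered and rejected as
the default because member accuracies then mix evaluation sets of varying
size; the consequence of the validation choice — the same subset scores
members and the final ensemble, a mild selection bias — is accepted and
noted here. Members with accuracy strictly above 0.75 are kept (a member
at exactly 0.75 is excluded). Feature occurrence counts across the kept
members' subsets are exact: they sum to (#kept members)·d by construction,
and this identity is asserted at runtime. Ranking ties are broken by
ascending feature index, making the ranking a deterministic total order
whose top-j is always a prefix of top-(j+1).

The pool sweep rebuilds a full cluster per pool size m ∈ {70, 80, …, 400}
(step 10 by default; the acceptance runs use step 20), drawing each
member's d features only from the first m ranked features, and scores it
on the validation subset. Ties go to the smallest m, favouring the smaller
feature set. The original split is reused across the sweep rather than
re-drawn, matching a single-split experimental design.

## Region weights

A selected connection set (typically the optimal feature set) is read as a
graph on the R regions; a region's weight is its degree — the number of
selected connections incident to it. The phrase "number of regions
associated with" a region's connections could alternatively be read as the
count of *unique* partner regions; degree is used because duplicate
partners cannot arise from distinct connectivity features, making the two
readings equivalent for any selected set of distinct features. The
handshake identity Σ weights = 2·|selected| is enforced in the result
type.

## Demographic tests

Gender balance: Pearson chi-square on the 2×2 male/female table, 1 df,
*without* Yates continuity correction. Age: two-sample Student t from
summary statistics with pooled variance, df = n1 + n2 − 2, two-sided.
These variants reproduce the printed table values (p = 0.693 and
p = 0.168) where the Yates-corrected (p ≈ 0.895) and Welch (p ≈ 0.172)
variants do not. Both are thin wrappers over scipy; the test suite checks
them against a longhand expected-counts computation and numerical
integration of the t density.

## Synthetic cohorts

The generator emulates the study's data shape: two groups (25 patients, 35
controls), R = 90 regions, T = 120 time points. Each group has a target
correlation matrix — uniform background correlation (default 0.1, a
typical resting-state background level) except on a planted set of region
pairs whose correlation differs between groups (default 20 region-disjoint
pairs at 0.6 in patients vs −0.2 in controls). Subject series are drawn as
Z·F' where Z is i.i.d. standard normal and F is the eigen square root of
the group target matrix, plus additive white noise (default SD 0.1, a ~1%
variance perturbation of the unit-variance latent signal). Region-disjoint
planted pairs keep the target matrix trivially well-conditioned; arbitrary
planted sets are accepted, with negative eigenvalues clipped at 1e−8 and
the matrix renormalised to unit diagonal. The repair is flagged on the
output, and if it moves any planted correlation by more than 0.05 the
generator refuses, naming the offending pairs.

What the generator does *not* model: hemodynamics, autocorrelated BOLD
noise, head motion, spatial smoothness, site effects, or diffuse
(non-sparse) group differences. Passing the planted-recovery tests
therefore shows that the pipeline detects sparse covariance differences at
the study's sample size — not that it would attain any particular accuracy
on clinical data, where the group difference is weaker and distributed.

## Problem sizes and numerical choices

The test suite exercises miniature cohorts (12–18 subjects, 12 regions)
for unit behaviour and 20 study-scale cohorts (60 subjects, 4005 features,
k = 500) for the ensemble properties; the end-to-end replication check and
the acceptance script run the full k = 500 pipeline with sweep steps of 25
(k) and 20 (m), which completes in well under a minute. Correlations are
clipped to [−1, 1] against floating-point overshoot; matrix symmetry is
required within 1e−10 on vectorisation; single-class bootstrap draws are
redrawn at most 20 times before erroring; split re-draws for class
coverage are bounded at 100.

## Known limitations

- The validation subset both scores members for feature selection and
  reports the final accuracy; with 18 subjects the optimism this induces
  is visible (pool-sweep accuracies saturate at 1.0 on strong synthetic
  signal).
- Accuracy on an 18-subject validation set has granularity 1/18 ≈ 0.056;
  single-split results should be read with that quantisation in mind, and
  per-seed distributions are preferred throughout.
- Binary classification only; no probability calibration; RBF kernel only.
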