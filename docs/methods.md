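# Methods

## The question the pipeline answers

Stream-resident brook trout populations in the upper-Midwest Driftless
Area are strongly differentiated from one another and from the hatchery
strains historically stocked on top of them. Two readings are possible:
the populations are remnant natives, or they were founded from a common
(hatchery) source and have since drifted apart. `popdrift` implements the
second reading as a quantitative null model: if a set of isolated
populations with the *empirically estimated* effective sizes were founded
from one gene pool, how quickly would standard population-genomic tools
(F_ST, model-based clustering) make them look like distinct, unrelated
populations — and how quickly would detectable ancestry from the founding
source disappear?

## Simulation model

Thirteen isolated Wright–Fisher populations (twelve wild analogs plus one
hatchery-strain analog) drift from a common founding state:

* **Population sizes.** Constant diploid sizes equal to the LD-based
  effective-size point estimates of the corresponding empirical
  populations: 26, 31, 65, 114, 128, 48, 535, 79, 54, 45, 294, 89 (wild)
  and 137 (hatchery analog). Census size equals effective size by
  construction — Ne is the quantity the study controls. The analog of one
  empirical population (the unnamed tributary) is excluded because its
  empirical Ne estimate is biased low by recent admixture.
* **Loci.** 500 independent biallelic loci, founding frequency 0.5. Each
  population's founding state draws each of its 2N gene copies
  independently (Bernoulli 0.5), so realized founding frequencies vary by
  binomial sampling error, and generation-0 samples are *not* exactly
  identical across populations.
* **Dynamics.** Per generation and locus, the next allele count is
  Binomial(2N, p): pure drift — no mutation, migration, or selection.
  Fixation is absorbing. Diploid genotypes are materialized only at
  checkpoint generations (0, 5, 10, 20, 30, 40, 50) by Hardy–Weinberg
  sampling; between checkpoints only frequencies are tracked. With free
  recombination and independent loci this frequency-level scheme is exact
  for every statistic the study pipeline consumes, and it is fast enough
  to run a dense every-generation grid for the F_ST trajectory.
* **Reproducibility.** One `numpy` generator per replicate, spawned from
  the master seed by replicate index; per-stage seeds derive from
  (replicate, stage, generation) via CRC32, so any cell of the study grid
  can be recomputed in isolation.

The frequency-level scheme deliberately produces **no linkage
disequilibrium** between loci. Drift in a real (or individual-based)
population couples loci through the shared, finite parent pool; that LD is
the signal used by single-sample Ne estimation. `simulate_individuals`
therefore provides an individual-based gamete-sampling mode (two parents
per offspring, one allele per locus per parent, free recombination) used
to validate the LD-Ne estimator; the study pipeline itself does not need
LD and keeps the frequency-level scheme.

## Statistics

* **Diversity.** Ho is the heterozygote fraction; He uses Nei's unbiased
  small-sample correction 2n/(2n−1)·2p(1−p); allelic richness is
  hypergeometric rarefaction to a common gene count (default: the
  smallest per-population count); F_IS = 1 − Ho/He on per-population
  means. Missing genotypes are excluded, never treated as homozygotes.
* **F_ST.** Weir & Cockerham (1984) variance components (a, b, c) per
  locus, θ = Σa/Σ(a+b+c) over loci; loci monomorphic across the included
  populations contribute nothing. The estimator is applied to
  equal-sized samples (25 diploids per population, matching the study's
  subsampling design) rather than whole populations, because θ's sample
  weights would otherwise let the two large-Ne populations dominate the
  global value.
* **Distances and trees.** Nei et al. (1983) D_A from per-population
  frequencies; neighbor-joining via scikit-bio; clade support by
  resampling loci with replacement and counting bipartitions.
* **Isolation by distance.** One-tailed Mantel test of F_ST/(1−F_ST)
  against a waterway distance matrix; p = (#{r_perm ≥ r_obs}+1)/(n_perm+1).
* **LD-Ne.** Burrows' composite Δ̂ (half the dosage covariance with the
  n/(n−1) correction) standardized by p_A(1−p_A)p_B(1−p_B); the mean r²
  over retained pairs (MAF ≥ 0.02; same-linkage-group pairs excluded when
  group labels exist) is reduced by the Waples (2006) sample-size
  expectation (1/S + 3.19/S² for S ≥ 30, the small-S variant otherwise)
  and inverted for Ne; non-positive adjusted r² reports Ne = ∞.
  Confidence intervals use a delete-one jackknife over individuals on the
  adjusted r̄². The denominator choice matters: the Waples corrections
  are calibrated for the allele-frequency-standardized statistic, and
  substituting the dosage correlation biases Ne upward by ~15–20% at
  S = 50.

## Ancestry model

The admixture likelihood for unlinked biallelic loci: dosage g_ij ~
Binomial(2, Σ_k q_ik f_kj), with Q row-stochastic and F in [ε, 1−ε]
(ε = 1e−6). Fitting is EM (FRAPPE-style multiplicative updates) from a
seeded Dirichlet/uniform start; the log-likelihood is non-decreasing by
construction and the tests assert it on every fit. Convergence: relative
log-likelihood change below 1e−6 (default cap 1000 iterations); K = 1 has
the closed-form solution. EM rather than quasi-Newton block relaxation
keeps a clean monotonicity test surface at the cost of a slower tail;
multiple restarts are supported (the study uses one per fit — label
switching across replicates is resolved by alignment, and the K = 13
likelihood on structured data is benign).

* **Choosing K.** Masked-entry five-fold cross-validation: observed
  entries are partitioned at random, each fold masked and the model refit
  from scratch; held-out entries are scored by mean binomial deviance
  between observed dosage and 2·Σ_k q_ik f_kj.
* **Alignment.** Cluster labels are arbitrary per run. Every fit is
  aligned to a single final-generation reference fit by maximizing summed
  column-wise Pearson correlation of Q over the position-matched
  individuals (populations occupy fixed row blocks), solved exactly as an
  assignment problem; exact ties resolve to the identity permutation.
* **Averaging and responses.** Q is averaged within populations and
  across replicates per generation. Populations are matched one-to-one to
  "their" clusters on the final-generation mean-Q table (optimal
  assignment, never greedy). The distinct-cluster response reads each
  wild population's own-cluster mean-Q at every generation; the
  hatchery-cluster response reads its mean-Q on the hatchery analog's
  cluster.
* **Output precision.** Q matrices are quantized to 6 decimals before
  averaging (`StudyConfig.q_decimals`), emulating the fixed-precision Q
  files the field's clustering programs write. This is not cosmetic: by
  late generations the smallest ancestry fractions decay to ~1e−20 in
  exact arithmetic, and whether they are carried exactly or become zeros
  decides whether the beta-regression boundary transform (below)
  engages. The published workflows operate on written Q files, so the
  quantized path is the faithful one.

## Drift regressions

One row per wild population × checkpoint generation (12 × 7 = 84; the
hatchery analog's own rows are excluded by default and available via
`include_hatchery_rows`). Response: mean assignment in (0,1); covariates:
generations, Ne, and their product. Five nested beta regressions (logit
mean link, constant precision φ) are fitted by maximum likelihood
(statsmodels `BetaModel`) and ranked by AICc = −2LL + 2k + 2k(k+1)/(n−k−1)
with k = mean coefficients + 1; Akaike weights normalize the relative
likelihoods. Pseudo-R² is the squared Pearson correlation between the
linear predictor and logit(y), zero for the null model. Responses touching
the boundary are nudged by the standard (y(n−1)+0.5)/n transform — with
the quantized-Q pipeline this engages for the hatchery response (whose
smallest cells are exact zeros) and floors it near 0.5/84 ≈ 0.006, which
is what keeps that regression's scale interpretable at all: without the
floor, cells at 1e−20 dominate the logit scale and the fit degenerates.

## Problem sizes and what the tests show

The package's own runs use reduced replication chosen to keep a
desk-scale run practical: 50–60 frequency-level replicates for the F_ST
trajectory, 30 replicates × 7 generations of K = 13 fits for the
regressions, and 1–5 replicates for the cross-validated K scans (the
cross-replicate spread of CV curves is functionally zero, so the
replicate mode is stable at small counts). Observed endpoints at these
sizes: mean global θ first reaches 0.118 at generation 16 (interpolated
~15.7); generation-0 hatchery-cluster assignment ≈ 0.074–0.077; best K
rises from 1 at founding to the 12/13 boundary at generation 50 (the
Ne = 535 analog accrues only ~0.05 of F_ST from the founder in 50
generations and is marginally separable, so the CV curves at K = 12 and
13 differ by ~1e−4); the Gen × Ne interaction model wins
both regressions with Akaike weight ≈ 1, distinct-response slope
β1 ≈ 0.10 and pseudo-R² ≈ 0.83. The pseudo-R² estimates rise with
replication (replicate noise in the response means enters the residual),
so scaled-down runs modestly understate the asymptotic fit quality.

Known limitations:

* The hatchery-response pseudo-R² lands around 0.85, above the published
  0.70, while every other feature of that table (model order, weight,
  coefficient signs) reproduces. The response's fine structure depends on
  numerical details of the upstream clustering program that the written
  record does not pin down (its exact zero handling and the alignment
  protocol across 100 replicates); we document rather than tune this.
* The monoecious WF model treats census = effective size exactly; two-sex
  demography, overlapping generations, and linked loci are out of scope.
* The generator emulates idealized drift with free recombination and no
  genotyping error or missingness; passing tests demonstrate method
  behavior under the drift null, not robustness to real-data artifacts.
* LD-Ne point estimates inherit the method's known mild upward bias at
  S = N and its sensitivity to unmodeled admixture (pooled samples bias
  low, as the tests demonstrate).
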