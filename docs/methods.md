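# Methods

`evoltraj` analyzes Pool-seq time series from reciprocal selection-shift
experiments: two sets of long-established *Drosophila*-style populations
(early-reproducing "A-types" on a short generation cycle, late-reproducing
"C-types" on a long one) are each switched to the opposite regime, and
replicate populations from both trajectories (A→C and C→A) plus their
founders are pooled and sequenced at several generations.  The package
implements the statistical machinery for asking whether the genomic
response is antiparallel, repeatable across replicates, and fueled by
balanced standing variation hidden below standard sequencing depth — and
a ground-truthed simulator for validating every stage.

## Data model

A `SnpTable` holds minor-allele read counts and total coverages for loci ×
samples, with 1-based sync-convention coordinates.  The minor allele at a
site is the globally less common of the two segregating nucleotides,
summed over all samples; exact ties break toward the lexicographically
smaller nucleotide so results are deterministic.  Only biallelic sites
are retained when reading sync files; sites with three or more segregating
nucleotides are dropped (counted, not fatal).  The default filters mirror
standard Pool-seq practice: coverage ≥ 20× in every sample, and pooled
minor-allele frequency (summed minor counts over summed coverage across
all samples) ≥ 0.02, both bounds inclusive.  The pooled interpretation of
the MAF filter matches the global minor-allele definition; sites that are
monomorphic in a *subset* of samples are deliberately retained, because
the pseudo-fixed analysis depends on them.

## Beta-binomial GLMM scan

At each locus the minor count Y with coverage n is modelled as

    Y_ijk ~ BetaBinomial(n_ijk, p_ijk, ρ)
    logit(p_ijk) = β0 + β1·T_j + β2·G_k + β3·(T_j·G_k) + u_j,
    u_j ~ N(0, σ_u²)

with T the trajectory indicator (0 = A→C, 1 = C→A), G generations under
the current regime, and u_j a random intercept per replicate population.
β3 — the trajectory × generation interaction — is the antiparallel-change
parameter: loci whose frequencies move in opposite directions in the two
regimes load on it.  The overdispersion parameter is parameterized as the
intraclass correlation ρ ∈ [0, 1) (shapes a = p(1−ρ)/ρ, b = (1−p)(1−ρ)/ρ),
which is bounded and numerically stable; ρ → 0 recovers the binomial, and
below ρ = 1e−8 the exact binomial limit expression is used because gamma
functions at shape ~1/ρ lose more precision than the limit itself.

Estimation maximizes the marginal likelihood with the random intercept
integrated out by a Laplace approximation; the per-replicate posterior
modes are found by Newton iterations using the analytic beta-binomial
score and observed information in the linear predictor (digamma/trigamma
forms — finite differences there are too noisy for the downstream
curvature computations).  The outer optimization is bounded L-BFGS-B on
(β, logit ρ, log σ_u), warm-started from a quasibinomial GLM fit and a
Pearson moment estimate of ρ, with two fixed fallback starts.  The
generation covariate is standardized internally and estimates are mapped
back to the original scale.  Adaptive Gauss–Hermite quadrature is
available as a validation mode and agrees with the Laplace fits to ~1e−2
on test loci.

Inference uses Wald z-tests with standard errors from the coefficient
block of a finite-difference observed information, holding (ρ, σ_u) at
their estimates: those nuisance directions are nearly orthogonal to the
coefficients but numerically fragile at the σ_u = 0 boundary.  When
σ̂_u reaches the boundary the model degrades gracefully to a fixed-effects
beta-binomial.  Likelihood-ratio p-values are available as a validation
mode.  One caveat, verified by simulation: with a true replicate variance
component and only ~20 replicate populations, Wald z is mildly
anticonservative for the interaction (rejection rate ≈ 0.08 at nominal
0.05); this is a generic property of Wald tests that ignore
variance-component uncertainty, not an implementation artifact.  Without
a replicate effect the test is calibrated (≈ 0.05).  Genome-wide scans
Bonferroni-adjust each term across tested loci (α = 0.05 by default;
failed fits count in the multiplicity denominator) and tally exclusive
significance classes.  Loci with extreme true effects that saturate the
frequency scale (all reads minor in some design cells) can produce
inflated estimates with near-1 p-values; they are never false positives,
but very long experiments with strong selection should be interpreted
with the quasibinomial scan alongside.

## PCA of frequency matrices

Frequencies receive a pseudocount of 1 (so no cell is 0 or 1), each locus
is scaled to unit variance but **not** centered, and the samples × loci
matrix is decomposed by SVD; variance explained comes from squared
singular values and zero-variance loci are dropped with a log message.
Component signs are fixed so the founder-A mean score never exceeds the
founder-C mean.  Each leading PC is modelled as
`score ~ T * G + (1 | population)` by REML (statsmodels MixedLM, Wald z
p-values, recorded as `wald-z-mixedlm-reml`), Bonferroni-adjusted across
PCs × terms at α = 0.005.  An endpoint mode drops generation and fits
ordinary linear models of score on group identity (model F-test per PC).

## Heterozygosity

Site heterozygosity is H = 2f(1−f) with f the raw minor-allele frequency
— no pseudocount, so a site sampled invariant contributes exactly 0, and
H is invariant to allele relabeling.  Per-sample genome-wide means are
compared between the first and last sampled generations of each
trajectory with Welch two-sample t-tests on replicate means (replicates
are the independent units).  A zero mean difference with zero variance is
reported as t = 0, p = 1 rather than NaN.

## Hidden variation at pseudo-fixed sites

Pseudo-fixed sites are scan-significant loci whose minor count is 0 or
equal to coverage in a focal founder sample at standard depth (~90×).
They are intersected with a deep re-read (~800×) of the same pool
(matched by chromosome and position; a deep coverage floor is a
parameter, default 100×), and their folded deep MAFs (min(f, 1−f), so
sites fixed for the globally-minor nucleotide contribute their locally
rare allele) are compared to the full deep background by permutation:
10,000 equal-sized subsets drawn without replacement, a z-score against
the permutation null, and a +1-smoothed one-sided empirical p-value
(1 + #{null ≤ observed}) / (1 + n_perm), which is never exactly zero; the
raw count is also reported.

## Convergence and parallelism scans

The convergence scan asks whether evolved endpoint populations differ
from the founders of their target regime.  Counts are modelled per locus
as overdispersed binomial with a population-type effect; the default test
is a quasi-likelihood F-test (deviance drop over the Pearson dispersion
of the full model, F(1, df)), with replicate-to-replicate variation
absorbed into the dispersion.  Pairing a quasibinomial error with a
likelihood-ratio test is formally incoherent (quasi-likelihoods have no
likelihood), so the F-test is the default and a beta-binomial LRT with an
explicit replicate random intercept is provided for sensitivity analysis.
Chromosome 4 and globally monomorphic sites are excluded; Bonferroni at
α = 0.05.

The baseline parallelism scan regresses each locus's counts on numeric
generation with replicate fixed-effect intercepts under a quasibinomial
GLM (Pearson dispersion, t-tests, Benjamini–Hochberg across estimable
loci).  Because the design matrix is shared by every locus, IRLS is
vectorized across loci as batched weighted least squares — this is what
makes leave-one-out re-scans cheap.  The LOO framework holds out each
replicate in turn, defines target SNPs from the training replicates
(BH-adjusted p < 0.05 and pooled training |Δp| ≥ 0.02 by default, both
exposed), samples an equal number of control SNPs uniformly without
replacement from estimable non-target loci (per-iteration seeds derived
from the global seed), and computes the held-out replicate's own Δp —
pooled counts, last minus first sampled generation — at both sets.
Genome-wide medians pool loci across arms; arm medians are reported
separately.  Replicate-level target and control medians are compared by
two-sample two-tailed t-tests.  Iterations with no targets are recorded
empty and excluded from the t-test with a warning.  Loci inestimable in a
training set are ineligible as targets and as controls for that
iteration.

## The synthetic-data generator

The simulator is a per-locus diploid Wright–Fisher model with viability
selection, discrete non-overlapping generations, constant census N
(default 1000), and free recombination (loci independent).  Three locus
classes define the reciprocal-shift scenario:

* **neutral** — drift only; founders share the ancestral frequency,
  drawn U(0.05, 0.95).
* **directional** — additive selection (favored homozygote 1 + s,
  s = 0.05) with the favored allele reversed between regimes; founder-A
  populations start near the A-optimum (favored-allele frequency
  U(0.85, 0.95)) and founder-C populations mirror them.
* **balanced** — heterozygote advantage with a regime-dependent internal
  equilibrium: under C-type selection the equilibrium is 0.30
  (common-homozygote penalty 0.05), while under A-type selection an
  additional strong cost on the rare homozygote (penalty 0.5) pins the
  equilibrium at a per-locus value drawn U(0.005, 0.02).  This is the
  "hidden reservoir": at ~90× depth such alleles frequently sample zero
  reads and look fixed, but they rebound when the regime flips — the
  generative mechanism behind the heterozygosity-rebound and
  pseudo-fixed analyses, in the spirit of antagonistic pleiotropy
  producing net balancing selection.

Founder replicates are produced by 20 generations of burn-in drift from
the regime base frequencies; trajectory replicate r descends from founder
replicate r and evolves under the opposite regime.  Default sampled
generations are anchored to the phenotype assay schedule of such
experiments: A→C at (12, 33, 65) and C→A at (33, 143, 182) generations,
founders at 0.  Observation is two-stage Pool-seq noise: a pool of 200
diploid individuals drawn binomially from the population frequency, then
reads binomial at the pool frequency with Poisson depth truncated at 1.
Per-sample mean depths are drawn U(62, 113); the deep mode re-reads the
founder-A replicate-1 pool at 800× from the *same* pool frequencies, so
standard and deep samples differ only in read sampling.  All randomness
derives from one seed via named sub-streams; runs are byte-reproducible.

What the generator does **not** emulate: linkage and hitchhiking (the
real data's significant-SNP counts are inflated by LD; per-locus counts
here are not comparable to the study scale), mutation, migration, age
structure, sex-specific selection, reference-bias or mapping artifacts,
and base-calling error.  Passing tests therefore demonstrate that the
statistics recover the signals their models describe under honest
sampling noise — not that they are robust to LD or technical artifacts.

A boundary note on the balanced class: for equilibria within a few
multiples of the drift scale (the stationary sd around a weak
overdominant equilibrium is ≈ sqrt(q(1−q)/(4N·r)) with restoring rate r),
occasional loss of the rare allele is expected and realistic.  The
no-fixation property is asserted in tests at equilibria several
stationary-sd above zero; the hidden scenario (0.005–0.02) tolerates
sporadic losses, which do not affect any downstream analysis.

## Numerical and design choices

* Optimizer finite-difference step for the outer marginal-likelihood
  gradient is 1e−5 — far above the Laplace objective's noise floor.
* Batched IRLS clips fitted probabilities to [1e−8, 1−1e−8] and adds a
  1e−10 ridge to the normal equations; loci with no variation are flagged
  inestimable rather than fitted.
* Permutation ties are counted with a 1e−12 absolute tolerance so a set
  identical to its background yields p = 1 exactly.
* Δp pools counts across replicates within a generation (not a mean of
  ratios), matching the pooled-frequency convention used everywhere.
* Problem sizes in the test suite and acceptance script (e.g. 2,000-locus
  scenarios, 500-locus recovery studies, 10,000-locus LOO power runs) are
  chosen to finish comfortably on one CPU while leaving Monte-Carlo error
  well inside the asserted tolerances; they are desk-scale stand-ins, not
  reproductions of a ~1.4M-SNP dataset.

## Known limitations

* Wald inference on the GLMM interaction is mildly anticonservative when
  a true replicate variance component is present (see above); use the
  LRT mode when replicate heterogeneity is large.
* The Laplace approximation is poor for replicates with very few
  observations at extreme frequencies; quadrature mode is available.
* The convergence quasi-F default absorbs replicate structure into the
  dispersion; with very unbalanced replicate sets prefer the
  beta-binomial LRT mode.
* The PCA mixed models use Wald z p-values (no Satterthwaite degrees of
  freedom); with only 20 populations the PC-level p-values are
  approximate, which the Bonferroni α = 0.005 partially offsets.
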