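# Methods

This note documents the models, estimators and numerical choices behind
`aimpanel`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where more than one reasonable convention exists.

## Generative model (`aimpanel.simulate`)

Breed allele frequencies follow the Balding–Nichols F-model: for each locus
an ancestral minor-allele frequency `p` is drawn uniformly from
`ancestral_maf_range` (default (0.05, 0.5]) and attached to either allele
with probability ½; breed *i*'s frequency is then a draw from
`Beta(p(1−F_i)/F_i, (1−p)(1−F_i)/F_i)`, whose mean is `p` and whose variance
is `F_i·p(1−p)`.  The parameter `F_i` is therefore exactly the quantity the
downstream F_ST estimators target, which is what makes parameter-recovery
tests meaningful.  Genotypes are `Binomial(2, p_ij)` per diploid individual
(Hardy–Weinberg within breeds, no inbreeding, no linkage).

**Recently-split pairs.** A related breed pair is generated through a
two-level hierarchy: a pair-ancestor frequency is drawn from the ancestral
frequency with F equal to the mean of the two members' `F_i`, then each
member diverges from the pair-ancestor with a small within-pair F (default
0.01).  The two members end up as far from the other breeds as their `F_i`
says, but nearly indistinguishable from each other — the situation that
makes assignment genuinely hard in real breed panels.

**Ascertainment.** Chips are designed toward common variants, so candidate
loci whose *pooled* sample MAF falls below `min_maf_filter` (default 0.05)
are discarded and redrawn until the requested number of loci passes; an
attempt budget (200 per locus + 1000, configurable) turns an unattainable
filter into an explicit error rather than a hang.

**Reproducibility.** Every candidate locus has its own random stream seeded
by `(seed, locus_counter)`; enlarging a simulation appends loci without
perturbing earlier draws, and identical configs are bitwise-reproducible.

**Consistency.** The emitted frequency panel is computed from the emitted
genotypes (`sample_frequencies`), so panel and genotypes are exactly
mutually consistent and every individual is, by default, part of the
reference that will later be asked to classify it (resubstitution).  The
cross-validation machinery removes that optimism explicitly.

**The `study_like` preset** emulates the structure of a real 17-breed
survey: unequal diploid sample sizes between 10 and 28 (384 individuals in
total), per-breed divergence spread evenly over 0.02–0.30, and one
recently-split pair.  Heterogeneous divergence matters: several qualitative
phenomena (the global-F_ST pathology, the weaker correlation of global
Wright's with the pairwise rankings) only exist when some breeds are much
more distinct than others, and disappear in an exchangeable equal-F world.

**What the generator does not emulate:** linkage disequilibrium between
loci, mutation or selection, pedigree/half-sib family structure within
breeds, genotyping error, and informative (non-MCAR) missingness.  Passing
tests therefore demonstrate the statistical machinery under idealized
locus-independent sampling, not robustness to LD-induced pseudo-replication
or relatedness, both of which inflate apparent panel power on real data.

## Informativeness estimators (`aimpanel.informativeness`)

* **delta** — mean of `|p_i − p_j|` over all K(K−1)/2 unordered pairs;
  bounded in [0, 1].
* **Wright's F_ST** — `var(p)/(p̄(1−p̄))` with the population (divide-by-K)
  variance and unweighted mean, so two populations fixed for opposite
  alleles score exactly 1.  A locus monomorphic across all populations is
  scored 0 (0/0 case) with a logged warning.  Pairwise mode averages the
  two-population statistic over all pairs with equal weights.
* **Weir & Cockerham's F_ST** — variance-components form
  `MSP = Σ n_i(p̃_i − p̄_w)²/(r−1)`, `MSG = Σ n_i p̃_i(1−p̃_i)/Σ(n_i−1)`,
  `n_c = (N − Σn_i²/N)/(r−1)`, `θ̂ = (MSP − MSG)/(MSP + (n_c−1)MSG)`, with
  `n_i` the sample size in **alleles** (2 × diploid individuals): the ANOVA
  is on gametes, and Monte-Carlo checks show the estimator is unbiased in
  the undifferentiated limit with allele counts and visibly negatively
  biased with individual counts.  Negative estimates are retained; two
  equal-sized samples with identical frequencies score `−1/(n−1)` in allele
  units.  Loci with a zero denominator score 0.  The genotypic form with
  observed-heterozygote correction terms is deliberately not used — the
  estimator works from allele frequencies alone.
* **PCA loading score** — PCA of the K × L frequency matrix with each locus
  column centered by its across-population mean, no variance scaling
  (scaling would inflate low-MAF loci).  Loadings are unit right-singular
  vectors; eigenvalues are `s²/(K−1)`.  Component significance is decided
  per rank against `n_random_matrices` (default 100) randomized panels,
  each built by resampling the K frequency values of every locus with
  replacement across populations; rank k is significant when the observed
  eigenvalue exceeds the 0.95 quantile (configurable; a strict maximum
  corresponds to quantile 1.0) of the randomized rank-k eigenvalues.  The
  score is the sum of squared loadings over the significant components —
  which need not form a leading block.  Each locus's randomization stream
  is seeded from a hash of its identifier, making scores exactly invariant
  to locus column order and population row order.  If no component is
  significant, all scores are 0 with a warning.

Rankings sort by decreasing score with ties broken lexicographically by
locus identifier, so the order is a reproducible total order.  Ranking
comparisons report the Spearman correlation of the score vectors
(average-rank tie handling, i.e. computed on scores, not on pre-ranked
integers) and the cardinality of the top-n intersection.

## Assignment (`aimpanel.assignment`)

Base-10 logarithms throughout, so the stringency thresholds 0/1/2/3 read
directly as 1/10/100/1000-fold likelihood superiority.  Conventions:

* frequencies ≤ 0 are replaced by `1e−5` and ≥ 1 by `0.99999` immediately
  before likelihood computation (the stored panel keeps raw values, and
  pooling/re-estimation happens before clamping);
* missing genotypes contribute a likelihood factor of 1 — likelihoods are
  comparable across populations within an individual, but not across
  individuals with different call patterns;
* the LLR denominator is the best **non-origin** population, matching the
  fallback rule's argmax;
* thresholds are strict: an LLR exactly equal to the threshold is not a
  confident assignment, and the individual falls back to the
  maximum-likelihood population (which can coincide with the origin when
  0 < LLR ≤ t without counting as correct at that stringency);
* exact argmax ties are resolved by population-identifier order and logged.

Pooling undifferentiated populations re-estimates the merged breed's
frequencies from the union of member genotypes (allele-count weighting,
missing-aware) and leaves all other rows untouched.

## Evaluation (`aimpanel.evaluation`)

**Cumulative curves** add markers in ranked blocks (default step 20 up to
400, both configurable) and record overall and per-breed success percent at
every threshold.

**Asymptotic regression** fits `y = a + b·exp(c·x)` by unweighted least
squares (no weighting scheme is imposed on the grid points), initialized at
`a₀ = max y`, `c₀ = −0.01`, `b₀ = y(first) − a₀`, tolerance 1e−8.  Constant
curves are rejected as degenerate and non-convergence raises with the best
iterate; curves that jump to their asymptote within the first grid step are
a known ill-conditioned case (the deficit/rate pair is then unidentified).
Inversion is closed-form, `x* = ln((y*−a)/b)/c`, and a target at or above
the asymptote raises the documented "asymptote below target" error — panel
sizes for a target success level are estimated by inversion of the fit, not
by first grid crossing, which is why they are fractional.

**Random-panel control** draws `n_sets` (default 20) uniform
without-replacement panels of `set_size` (default 400) loci on an RNG
stream independent of the simulator's, evaluates each cumulatively, and
averages per grid point; the LLR > 3 row is the conventional negative
control.

**Cross-validation** holds out, per breed, all designated query individuals
(breeds larger than `size_cutoff` = 50) or `holdout_small` = 5 random
members (smaller breeds), re-estimates training frequencies without them,
re-ranks markers on the training panel (the only leak-free protocol;
`reuse_ranking` allows reusing a fixed full-data ranking for comparison)
and assigns the holdouts against the training panel.  In the simulator's
resubstitution design every individual is both reference and query, so a
breed above the cutoff would retain no training individuals — such breeds
require an explicit query subset, and at least 2 training individuals per
breed are enforced.

**Error rates** per breed at a threshold: type I = own individuals assigned
elsewhere / own individuals; type II = foreign individuals assigned to the
breed / all individuals assigned to it (0 when none).  Both are computed
from the assigned labels, so overall assigned-label accuracy equals
1 − (size-weighted mean type I) exactly at every threshold.

**Differentiation vs success**: a breed's differentiation is its mean (over
partner breeds) of the across-loci mean pairwise Wright's F_ST computed on
the full locus set, not the selected panel; correlated (Spearman) against
per-breed success of the top-20 panel at LLR > 0.

## Problem sizes

The shipped tests and the acceptance script run entirely on simulated data
at sizes chosen to make the statistical assertions stable while staying
light: 5000 loci × 8 breeds × 30 individuals for estimator recovery, 2000
loci for curve/control comparisons, the 17-breed 4000-locus survey preset
for heterogeneity-dependent patterns, and 10 replicates of 1500 loci for
the cross-validation contrast.  The full suite finishes in well under a
minute of compute on a single CPU.

## Known limitations

* Locus independence is assumed everywhere (scores, likelihoods, curves);
  with chip data in strong LD the effective information of a top-ranked
  panel is lower than the independent-locus arithmetic suggests.
* Marker selection and assignment on the same individuals (resubstitution)
  overstates success; the cross-validation mode quantifies, but does not
  remove, that optimism for small breeds.
* The PCA significance test inherits the usual caveat of eigenvalue
  randomization with few rows (K populations): with very small K the
  randomized spectra are coarse and the significant-component count is
  sensitive to the quantile rule.
* Likelihoods ignore genotyping error; a single wrong call at a
  near-fixed locus shifts an individual's LLR by up to ~10 units.
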