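# Methods

This note documents the models behind each `duckmix` stage, the defaults
that matter, what the synthetic-data generators do and do not emulate, and
the numerical choices a maintainer would want to know about.

## Synthetic parental pools (Balding–Nichols)

Two parental gene pools are generated around shared ancestral allele
frequencies p_anc ~ Uniform(0.05, 0.95) (the bounds avoid
quasi-monomorphic loci dominating the panel). Each pool draws its
frequency per locus independently from Beta(p_anc·(1−F)/F,
(1−p_anc)·(1−F)/F), so a pool pair realizes a Hudson-type fixation index
close to the target F. F = 0 is special-cased to the zero-drift limit
(both pools equal the ancestral draw). The default study condition is
F = 0.11 — the autosomal differentiation between the native and the
introduced taxon — with 1000 loci for simulation experiments and 5000 for
distributional checks. Mean realized FST across seeds is within ±0.01 of
the target at 5000 loci.

Genotypes are two independent Bernoulli(p) allele draws (Hardy–Weinberg
within a pool); missingness, where requested, is uniform at random — the
real data's missingness structure is not characterized, so nothing more
specific is modelled.

## Depth profiles and sex assignment

Birds are ZZ (male) / ZW (female). Expected mean depths relative to
autosomal coverage A: males (Z, W) = (A, 0); females = (A/2, A/2).
Multiplicative noise at coefficient of variation `noise_cv` (default 0.1)
is decomposed into a per-individual library-size factor at the full cv,
shared across locus classes, plus independent per-class jitter at cv/4.
The shared factor is the dominant noise source in real libraries and
cancels in the depth ratios; with fully independent per-class noise at
cv = 0.2, ~4% of female Z/A ratios would cross a midpoint split and no
threshold classifier could recover sex perfectly. The caller labels male
when Z/A > 0.75 and W/A < 0.25, female when Z/A < 0.75 and W/A > 0.25
(both strict; a ratio exactly at a split is `unresolved`), and
`unassignable` at zero autosomal depth.

## SNP filter cascade

Order: allele presence (< 80% of alleles called → drop), minor-allele
frequency (maf < 0.002 → drop; monomorphic always dropped), per-SNP
missingness (≥ 20% missing → drop; inclusive boundary), LD pruning
(2-SNP window, step 1, within chromosome class; for any in-window pair
with genotype r² > 0.5 one member is removed uniformly at random, seeded;
the scan loops to a fixed point so no surviving in-window pair violates
the threshold). r² is the squared Pearson correlation of 0/1/2 genotype
vectors over pairwise-complete individuals (composite LD — phase is
unknown in unphased panels). Each filter emits a per-locus removal report;
removed + retained always equals the input, and the cascade is idempotent.

## Admixture model

The likelihood is the standard unlinked-SNP admixture model: genotype
g_il ~ Binomial(2, f_il), f_il = Σ_k q_ik p_kl, with Q row-stochastic.
Estimation is expectation-maximization on the allele-origin complete-data
model; both Q and P updates use responsibilities from the same (previous)
parameter values, which guarantees a non-decreasing log-likelihood — the
fitter asserts this at every evaluation (likelihood evaluated every 5
iterations for speed). Defaults: tol 1e-4 log-likelihood units, max_iter
2000, Q initialized from a symmetric Dirichlet, P from observed
frequencies with N(0, 0.05) jitter, both clipped to [1e-6, 1−1e-6].
Missing genotypes contribute nothing to the likelihood. Supervised mode
pins labelled individuals' Q rows to their cluster; it is used where known
parental references should anchor the cluster axes (see "Backcross
plateau" below).

Replicate fits are label-aligned by maximizing mean per-individual
dot-product similarity against an incrementally built reference —
exhaustive over the K! permutations for K ≤ 8, optimal assignment
(Hungarian) above. K is selected by masked-entry cross-validation: random
folds of observed genotype entries are masked, the model refitted, and
the masked entries scored by squared error against 2·f̂.

PCA operates on the mean-imputed, centered genotype matrix via SVD, with
component signs fixed (largest-magnitude loading positive) for
determinism.

## Hybrid-generation bins and classification

F1s draw one gamete from each pool; backcrosses draw one Mendelian gamete
from the previous-generation individual (loci unlinked) and one gamete
from the recipient pool's frequency vector — the infinite-pool
approximation that matches drawing "proportional to the allelic frequency
in the gene pool". Haplotype origins are tracked, so each simulated bird
carries both its pedigree-expected donor ancestry (0.5^g for class F_g)
and its realized donor-allele fraction.

The default design is 10 F1s, 5 backcross lineages per side, nine
backcross generations, 10 replicate simulations; each simulation also
includes 50 diploid references sampled per pool. Replicate admixture fits
(25 per simulation at full scale; the test suite and demo configs use 2–3,
which changes only the smoothness of the bin limits) are aligned and
averaged; clusters are mapped to taxa by which reference pool loads on
them, and at K = 3 the two same-taxon clusters are merged before any
interspecific quantity is computed. Interspecific assignment is uniformly
1 − (assignment to the individual's own/recipient taxon), i.e. a value in
[0, 0.5] for F1s and empirical birds.

Bins are per-class mean / min / max over all simulated individuals and
fits. Bin means must decrease strictly with generation while they exceed
a plateau floor (default 0.06, the scale of the pure-vetting threshold);
below the floor, classes sit in the estimator's boundary-noise region —
assignment plateaus near 100% after roughly six backcross generations —
and are only required to stay below it. A genuine inversion (an F2 mean
above F1's) raises a hard error.

Classification: a bird's interspecific assignment is compared against the
bins compatible with its majority taxon. Exactly one containing bin wins
outright; several containing bins resolve to the nearest mean (ties to
the earlier generation) or, configurably, to the hybrid swarm ("strict"
mode); a value inside no bin is a hybrid-swarm backcross whose direction
is the majority taxon. Pure and F1 assignments carry no direction.

Parental vetting uses interspecific assignment ≤ 0.05 by default. At
desk scale (1000 SNPs, F = 0.11) the ancestry estimator's noise is
σ ≈ 0.03, so a minority of genuinely pure individuals exceed that
threshold; vetting is therefore treated as a specificity instrument
(hybrids must not pass) rather than a perfect-recall one, and empirical
pure thresholds are taken from the bins rather than hard-coded.

## Backcross plateau

`backcross_plateau_experiment` runs the full design above on synthetic
pools (1000 SNPs, F = 0.11, 50 references per pool) and reports the mean
recipient-cluster assignment over backcross generations six through nine.
The K = 2 fits include the parental references in supervised mode (their
Q rows pinned): the references are known parentals by construction, and
pinning them anchors the two-cluster axis. Unsupervised fits at this SNP
count leave ~1.2% mean interspecific assignment on deep backcrosses purely
from boundary-truncated estimator noise (the converged MLE, not a
convergence artifact — verified at tolerances to 1e-8); with anchored
references the deep-generation mean recipient assignment is ≈ 99.5%,
matching the plateau behaviour expected of near-pure individuals. EM
tolerance is tightened to 1e-5 (max_iter 4000) for this experiment.

## Φ_ST (distance-based AMOVA)

Φ_ST = σ²_among / (σ²_among + σ²_within) from a two-level AMOVA on
pairwise squared distances, with the standard unequal-group-size
coefficient n′ = (N − Σn_g²/N)/(G−1). For aligned sequences the squared
distance is the number of differing sites, N/gap sites excluded pairwise
(not listwise). For SNP partitions the AMOVA is taken at the allele level:
each diploid contributes two alleles per locus, and since the allele
distance is 0/1, all sums of squares reduce to closed forms in the
per-group alternate-allele counts — no phase assignment is needed, and
per-locus variance components are summed across loci (ratio of sums).
This choice matters: an AMOVA over Euclidean distances between diploid
genotype vectors estimates ≈ 2F/(1+F) rather than F for two pools at
fixation index F (the cross-individual term double-counts the
between-pool mean shift), which would not recover the simulated
differentiation. Negative estimates are reported as computed; display
layers may clamp at 0.

## Haplotypes and median-joining networks

Haplotypes collapse by zero mismatches with ambiguous sites (N/gap)
excluded pairwise; because that relation is not transitive, sequences
join the first matching haplotype in input order (documented greedy
behaviour; exact-string collapsing is available). Haplogroup assignment
is nearest reference by Hamming distance, ties → `ambiguous`.

The median-joining network starts from observed haplotypes and
alternates: (a) minimum-spanning network under Hamming distance — Kruskal
by distance class, keeping every tie that joins two pre-class components,
plus classes within ε of the connecting distance (ε = 0 default, the most
parsimonious network); (b) median proposal — the site-wise majority
consensus of a node triplet is added when it strictly reduces the weight
of the minimum spanning tree over the node set (the best such median per
round). Termination follows because the spanning weight is a strictly
decreasing nonnegative integer. Obsolete medians whose removal leaves the
spanning weight unchanged are pruned. Substitution-model refinements
(transition/transversion weighting) are out of scope.

## Genotype–environment turnover and genomic offset

Site minor-allele frequencies (minor defined globally per locus) are
filtered to loci polymorphic in ≥ 5 sites. Per locus, a random forest
(100 trees, min leaf 2, √p feature subsampling, bootstrap, seeded)
regresses site frequency on the environmental variables; the out-of-bag
R² is the locus's fit quality, and loci with non-positive R² get zero
weight. Every split's impurity reduction is recorded against its variable
and threshold; per retained locus these are normalized to sum to one and
scaled by the locus R², then averaged over retained loci. A variable's
cumulative turnover curve is the running sum of its scaled split
improvements along its range — a non-decreasing step function whose final
value is the variable's R²-weighted importance. This reproduces the
quantities downstream analyses consume (importance ranking, cumulative
curves, transformed grids, offsets); conditional permutation importance
from the original gradient-forest formulation is not reproduced.

The null comparison refits the model on environment tables with site
labels permuted (100 permutations at full scale) and reports the
empirical exceedance of mean retained-locus R². Landscape grids are
transformed by evaluating the top-k (default 5) curves at each cell;
values outside the training range clamp to the curve endpoints. The RGB
map rescales the first three PCs of the transformed grid to [0, 255]
(deterministic sign convention; rank-deficient inputs fill missing
channels with 0). Combining models merges curves by fit-quality-weighted
averaging (weights ∝ total positive R² mass), so combining a model with
itself is the identity. Genomic offset is the per-cell Euclidean distance
between current and future transformed coordinates: nonnegative,
symmetric, zero iff the transformed coordinates coincide, and insensitive
to zero-importance variables.

## What the generators do and do not emulate

The synthetic environment dataset plants adaptive loci whose site
frequencies follow logistic(a_l + slope·env1 + noise) against one smooth
environmental gradient, with other variables as standardized spatial
noise; it emulates the *statistical* shape of a genotype–environment
association (a causal variable among correlated distractors) but not
spatial autocorrelation of allele frequencies, isolation by distance,
polygenic architectures, or collinearity blocks among predictors. The
mtDNA generator produces star-like haplogroups around well-separated
references without recombination or rate heterogeneity. Passing tests
therefore demonstrate that each estimator recovers what it is designed to
recover under its own assumptions — not that those assumptions hold in
any particular field dataset.

## Problem sizes

Simulation experiments default to 1000 SNPs, 50 references per pool, and
the 10-simulation pedigree design; distributional checks use 5000 loci
and 20 seeds; the test suite's session fixtures use 2 simulations × 2
replicate fits and the demo pipeline 400 loci with four backcross
generations. These sizes were chosen as the smallest at which each
statistic's sampling noise is comfortably below the tolerance being
checked.

## Known limitations

* LD pruning is O(windows × passes) with per-pair correlation recomputed;
  fine at ddRAD scale, not for dense WGS panels.
* The EM fitter is slower than quasi-Newton block relaxation for large
  panels; it was chosen for verifiable monotonicity at desk scale.
* Min/max bin limits are order statistics and widen with estimator noise;
  at small SNP counts pure-class limits can overlap deep-backcross bins
  (the nearest-mean rule keeps classification defined).
* Haplotype collapsing with ambiguity is order-dependent (documented).
* The turnover forest treats sites as exchangeable samples; spatial
  pseudo-replication is not corrected.
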