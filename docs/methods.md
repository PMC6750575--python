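# Methods

This note records the statistical models implemented in riverpg, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish.

## Data model

Genotypes are diploid calls at microsatellite loci, stored as unordered
pairs of positive integer allele labels with a single internal missing code
(GenePop `000` and CSV `-` both map to it). Missing data are handled by
per-locus pairwise deletion everywhere: each estimator uses every
individual with a non-missing call at the locus in hand, so per-locus
sample sizes may differ within a site. Allele labels are repeat-number
offsets rather than raw fragment sizes, so synthetic and binned real data
share one label space.

### Allele binning

Raw fragment sizes are binned per locus by single-linkage clustering:
sorted sizes are split wherever consecutive values differ by at least
`gap_fraction × motif_length` (default 0.5). Each cluster becomes one
allele labelled `1 + round((cluster_mean − smallest_mean)/motif_length)`;
a label collision raises an error naming the locus and cluster means.

The split threshold trades off against data density. Within-cluster
consecutive gaps shrink roughly like σ·√(2 ln m)/m with m observations per
allele, while the *observed* gap between adjacent allele clusters shrinks
as their edges fill in: at noise σ ≈ motif/10 and hundreds of copies per
allele, the edge-to-edge gap routinely drops below 0.5 × motif and adjacent
clusters chain together. With the default threshold, exact round-trip
recovery is reliable up to σ ≈ motif/15 at ~50 copies per allele; for
noisier data a lower `gap_fraction` (e.g. 0.3) restores reliable splits
because dense clusters have tiny internal gaps. This is why the knob is
exposed in the config rather than fixed.

## Diversity and inbreeding

Observed heterozygosity is the fraction of heterozygous calls; expected
heterozygosity is Nei's unbiased estimator 2n/(2n−1)(1−Σp²). The
inbreeding coefficient is F_IS = 1 − H_o/H_e (Nei's G_IS form; positive
values mean heterozygote deficit, negative mean excess), with a flag rather
than a value when H_e = 0. The multilocus site value weights loci by their
per-locus N: F_IS = 1 − Σ_l N_l H_o,l / Σ_l N_l H_e,l. Weir–Cockerham's
small-sample f would differ in the third decimal at these sample sizes;
G_IS was chosen because it composes directly with the weighted multilocus
summary and is the quantity the recovery tests target.

## Exact Hardy–Weinberg tests

Conditional on allele counts m_i, the probability of a genotype array
{n_ij} under random mating is P = [n!/Πn_ij!]·[Πm_i!/(2n)!]·2^H. The
p-value sums P over arrays no more probable than the observed one.

Two engines share this definition. The enumeration engine recurses over
all arrays with the observed margins, using exact rational arithmetic, so
ties in "P ≤ P_obs" are decided exactly; it is restricted to ≤ 4 alleles
and n ≤ 25. The Markov-chain engine is the Guo–Thompson switch chain run on
the labelled allele-copy representation: conditional on allele counts every
pairing of the 2n copies is equally likely, so on ordered labelled
configurations the stationary law is uniform and each proposed swap of two
copies between individuals is accepted outright — the same chain as the
classic two-genotype switch, without an explicit Metropolis ratio. The
log-probability of the current array is updated incrementally; a state
counts toward the p-value when its log-probability is within 1e-7 of or
below the observed one (the gap between distinct arrays at these sizes is
orders of magnitude larger, so the tolerance only absorbs float drift).
The Monte Carlo standard error uses 50-batch means. The hot loop is
numba-compiled when numba is importable; a pure-python twin provides the
fallback. Default chain settings are 10^6 steps after 10^5 dememorization
steps; a fixed seed gives bit-identical p-values.

The Šidák family-wise correction is 1−(1−α)^(1/m); over the study design's
9 sites × 8 loci = 72 tests at α = 0.05 the per-test level is 0.00071.
Monomorphic cells are untestable (p = 1) but still counted in m by default;
`n_tests_override` lets the analyst count differently.

## Pairwise F_ST

Weir–Cockerham θ is computed per locus and allele from the among-population
(a), among-individual (b), and within-individual (c) variance components,
then combined as the ratio of sums Σa/Σ(a+b+c) over loci and alleles —
ratio-of-sums rather than averaged per-locus ratios, which is biased.
Loci with data in only one member of a pair are skipped; a pair with no
informative locus is flagged undefined. Significance permutes individuals
between the two sites with sizes fixed; p = (#{θ* ≥ θ}+1)/(n_perm+1). The
permutation loop is vectorized: per-individual allele-dosage matrices are
combined by membership-matrix multiplication so thousands of permutations
cost a few matrix products.

## AMOVA

Four nested levels — gene copy ⊂ individual ⊂ population ⊂ group — with
the allele-identity distance (0/1). With 0/1 distances the within-cluster
sum of squares reduces to SS = (m² − Σ_a m_a²)/(2m) from allele counts,
which both the implementation and the brute-force test oracle use (the
oracle from explicit pairwise distances). Variance components follow the
unbalanced nested expected-mean-square equations with gene copies as units;
the individual-level coefficient is exactly 2 (two copies each). Components
are summed across loci (per-locus pairwise deletion), then

F_CT = σ²_a/σ²_T, F_SC = σ²_b/(σ²_b+σ²_c+σ²_d), F_IS = σ²_c/(σ²_c+σ²_d),
F_IT = (σ²_a+σ²_b+σ²_c)/σ²_T,

which satisfy (1−F_IT) = (1−F_CT)(1−F_SC)(1−F_IS) identically. Negative
components are reported unmodified — truncation would break both the
percentage sum and the identity. A zero denominator (no variance below a
level) yields a ratio of 0 by convention. Permutation schemes: whole
populations among groups (F_CT), individuals among populations within
groups (F_SC), gene copies among individuals within populations (F_IS),
and gene copies among individuals across the whole table (F_IT, the one
scheme the design left open; chosen to match the usual total-inbreeding
null).

## Distance models and PrPI

Coordinates are pre-projected planar km; no geodesy is attempted.
Fluvial-path and shortest-path distances are Dijkstra lengths on the
mode-filtered edge set; unreachable pairs are flagged infinite. The
Propagule Pressure Index PrPI(o,d) = Σ_j γ_j·trips_j(o,d) is linear in trip
counts and monotone in each γ; because Mantel input must be symmetric, the
matrix form sums both directions of travel (whether the original index used
one-way or round-trip counts is not determinable, and the choice only
rescales the index). PrPI is a similarity: its expected association with
F_ST is negative, so its Mantel test is one-tailed "less", while the three
distance models are tested one-tailed "greater" (isolation by distance
predicts positive correlation).

## Mantel tests

r is the Pearson correlation of off-diagonal upper triangles; permutations
relabel rows and columns of the second matrix jointly; p uses +1 smoothing.
The suite runs each model against the collapsed-site F_ST matrix and skips
the test (flag, no p-value) for any model whose defined-pair mask covers
fewer than `min_pairs` pairs — the PrPI case, where trip data exist only
for hub–spoke pairs (5 of 15), too few for a meaningful permutation test.

## Admixture model

The uncorrelated-frequencies admixture model: q_i ~ Dirichlet(α1_K) per
individual, p_kl ~ Dirichlet(λ) per cluster × locus, each allele copy
drawn from cluster k with probability q_ik. Three-block Gibbs updates
(copy origins z → frequencies p → memberships q), all vectorized over the
flat copy array. Missing calls contribute nothing to updates or the
likelihood (ignorable missingness). α is fixed (default 1.0, exposed in
config) rather than sampled, trading a little adaptivity for a simpler,
faster sampler; λ defaults to 1.0. Reported Q and P are posterior means
over thinned post-burn-in sweeps — posterior means rather than a MAP state,
and runs are only ever averaged after label alignment (optimal cluster
permutation maximizing Σ min(Q_ref, Q_run), solved as an assignment
problem). Model log-probability is estimated from the thinned likelihood
trace as mean(ℓ) − var(ℓ)/2 (sample variance), and Evanno
ΔK(K) = |L''(K)|/sd(L(K)) is computed from replicate-run means; ΔK is
undefined at the endpoints and wherever replicate spread is zero (flagged,
not dropped).

Desk-scale defaults are burn-in 2,000 / 10,000 sweeps thinned by 10; the
`paper_protocol` flag restores 100,000 / 200,000 with 10 runs per K over
K = 1..10. On well-separated synthetic data the sampler converges within a
few hundred sweeps, which is why the test suite and acceptance script use
short chains (burn-in 200–500, 600–2,000 sweeps) — sizes chosen as the
package's own desk-scale settings.

Dominant membership: an individual is dominant when max_k q_ik exceeds the
threshold (default 0.8); the modal cluster is the one most often dominant;
per-site and overall fractions count dominance in that modal cluster, so
the overall fraction mirrors "individuals assigned to the single most
common genetic group".

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical* structure the estimators
assume: Balding–Nichols differentiation (site frequencies Dirichlet around
an ancestral vector with concentration (1−F)/F, giving Var(p) = p(1−p)F and
recoverable pairwise F_ST ≈ F), an inbreeding mixture (probability F_IS of
duplicating one allele draw) whose multilocus F_IS is recoverable, the
admixture model itself, and a seven-town hub-and-spoke region: pairwise
Euclidean distances spanning ~15–125 km, a single 95 km terrestrial edge
between the hub and one town, fluvial edges elsewhere, star-shaped trip
tables, and vehicle infestation probabilities 0.71 / 0.35 / 0.125 for
large barges, medium barges, and buses. Default genotype conditions are
9 sites of 20–76 individuals (339 total), 8 loci, 5 alleles per locus,
F = 0.05, F_IS = 0.2 — the scale of the emulated field design.

Not emulated: linkage between loci, null alleles and allele dropout,
within-household relatedness (a family-clustering switch exists but is off
by default), mutation models, spatially explicit dispersal, and temporal
structure. Passing recovery tests therefore shows the estimators are
correct and well calibrated *under the assumed models*, not that real
field data meet those assumptions.

## Numerical conventions

- Permutation p-values use (count+1)/(n_perm+1), never exactly zero.
- Enumeration ties use exact rational comparison; the chain engine uses a
  1e-7 log-scale tolerance.
- Degenerate inputs fail loudly: empty loci, zero total variance,
  inconsistent margins, label mismatches, K = 0, thresholds outside (0,1).
- Every stochastic routine takes an explicit seed and is bit-reproducible;
  the pipeline derives stage seeds from one master seed.
- Undefined statistics (monomorphic F_IS, undefined ΔK, untestable PrPI
  Mantel) are flagged, never silently dropped or zero-filled.

## Known limitations

- F_IS uses the G_IS form, so third-decimal differences from
  Weir–Cockerham-based software are expected.
- The AMOVA F_IT permutation scheme is a convention (see above).
- The admixture sampler fixes α; strongly asymmetric admixture may be
  better served by sampling it.
- Allele binning assumes a common motif per locus and no systematic size
  drift between runs; see the density/threshold trade-off above.
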