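# Methods

This note records the models behind each stage of the pipeline, the
numerical choices made where the literature leaves them open, what the
synthetic-data generator does and does not emulate, and the known
limitations.

## Data model

Genotypes are diploid, unordered pairs of positive integer allele codes per
locus; a call is either complete or wholly missing (a half-typed call such
as `007000` in a GENEPOP file is demoted to missing, because every
downstream estimator needs full diploid calls).  Coordinates are taken as
already-projected planar meters — the methods assume a single projection
zone and perform no geodesy.  Sequence alignments are restricted to
`{A,C,G,T,N,-}`; sites containing `N` or gaps are excluded
pairwise-complete from difference counts.

## Diversity and Hardy–Weinberg testing

H_O is the fraction of genotyped calls that are heterozygous.  H_E uses
Nei's small-sample correction (2n/(2n−1))(1 − Σ p̂²).  Allelic richness is
the expected number of distinct alleles in a random draw of g genes,
computed in closed form from hypergeometric tail ratios; g defaults to
twice the smallest per-(population, locus) count of genotyped individuals.

The Hardy–Weinberg exact test is the probability test: p is the total
conditional (Levene) probability of genotype arrays no more probable than
the observed one, given the allele counts.  Complete enumeration is used
while the depth-first search over genotype arrays stays below a node
budget; beyond it, arrays are sampled by randomly re-pairing the gene
vector, which draws exactly from the Levene distribution — an independence
sampler, so no dememorization phase is needed and the (x+1)/(n+1) add-one
estimator applies.  Global per-population HWE combines per-locus p-values
with Fisher's χ² = −2Σ ln p on 2L degrees of freedom (the combination
method is a documented choice; per-locus p-values of zero are floored at
1/(chain length + 1)).  Exact-test p-values are discrete and therefore
conservative at small sample sizes; the test suite checks validity
(sub-uniformity) rather than exact uniformity.

## F-statistics

θ and f are the Weir–Cockerham variance-component estimators, accumulated
per allele and per locus and combined as ratios of sums (not averages of
ratios).  With a single population the among-population component is
dropped and the remaining two components still define f — this is how
per-population and per-sex F_IS values are obtained.  Confidence intervals
bootstrap loci (percentile, 95%); pairwise θ significance permutes
individuals between the two populations, one-tailed, with the (x+1)/(n+1)
estimator.  Negative estimates are reported as computed, never truncated.

Mitochondrial differentiation uses the Hudson–Slatkin–Maddison form
1 − π_w/π_b.  π within a population is the mean over all ordered sequence
pairs including self-pairs (the plug-in estimator): this convention makes
the statistic exactly zero when two populations carry identical samples and
exactly invariant to duplicating every sequence, at the cost of a small
(−1/n) finite-sample shift relative to the distinct-pairs convention.
Between-population π is conventional (not net divergence) — a documented
choice.  The calibration F_n = F_mt/(4 − 3F_mt) converts a haploid,
maternally inherited marker's F_ST to the nuclear scale; it is monotone
with fixed points at 0 and 1.

AMOVA partitions squared inter-individual distances (allele mismatch
counts for genotypes, nucleotide differences for sequences) over the
three-level hierarchy with the standard unequal-size coefficients.  The
SAMOVA search maximizes Φ_CT over groupings that are contiguous on the
Gabriel graph of population coordinates, by simulated annealing
(geometric schedule, T₀ = 1, α = 0.97 per step, 10⁴ steps, 100 restarts by
default — restarts are the knob that matters; the planted-split tests use
fewer, smaller searches).  Significance permutes whole populations among
groups with group sizes fixed.

## Individual-level genetic distance

Rousset's â treats each diploid individual as a deme of two genes.  For a
pair of individuals, per locus and per allele, the between-deme mean square
is (p_i − p_j)² and the within-deme mean square is half the summed
within-individual sums of squares; â is Σ(MSB − MSW)/Σ(2·MSW) over alleles
and loci.  This is the F/(1−F)-scale quantity whose regression on
ln(distance) has expected slope 1/(4πDσ²) in two dimensions.  Pairs sharing
no genotyped locus, or with zero heterozygosity in both members at every
shared locus, are flagged missing.  Same-trap pairs (zero distance) are
excluded from log-distance regressions.

## Landscape stage

Favorability layers hold q ∈ [0,1] per 500 m cell: pond area fraction,
drainage length, and rank-weighted vegetation cover (ranks 1–5 map to
scores 1.00, 0.75, 0.50, 0.25, 0.00), each rescaled by its maximum cell.
The cost transform is linear, cost(q) = 1 + (C_max − 1)(1 − q); the
functional form is a design choice and C_max is deliberately arbitrary,
which is why the robustness analysis exists.  Least-cost distances run on
the 8-connected cell graph with edge weight = step length (cell size, ×√2
diagonally) × mean of the two cell costs; points snap to their containing
cell center.  On a uniform surface the LCD therefore obeys the octile
bound Euclid ≤ LCD ≤ 1.083·Euclid + 2 cells (the additive term absorbs
endpoint snapping).

The robustness statistic re-computes LCDs over a set of C_max values
(default {2, 5, 10, 50, 100, 1000}), normalizes each LCD matrix by its mean
over pairs so that a pure rescaling of all costs cancels, and reports the
per-pair coefficient of variation and its mean ± sd over pairs.  A uniform
landscape yields CV = 0 under this normalization.  Raw (unnormalized) LCDs
divided by their uniform-cost counterparts are monotone non-decreasing in
C_max, which the property suite asserts separately.

## IBD models and model selection

Mantel tests correlate unordered pairs and permute rows/columns of one
matrix jointly; distance–distance tests are one-tailed for positive
association by default, matching the directional IBD hypothesis.  The
partial Mantel correlation comes from the three pairwise correlations; its
p-value permutes the residuals of the response on the conditioning matrix
(Smouse–Long–Sokal).  Distance regressions are ordinary least squares on
the pair list (AICc is defined through least squares; reduced-major-axis
slopes are out of scope).  AICc uses the number of populations, not the
number of pairs, as the effective sample size — pairwise distances are not
independent — and models within ΔAICc < 2 of the best are declared
indistinguishable.

## Dispersal

The corrected assignment index AIc of an individual is the natural-log
likelihood of its multilocus genotype under its own population's allele
frequencies, computed leave-one-out with a 1/(2n) floor for alleles
unobserved after removal (avoiding −∞ at private alleles), centred to mean
zero within each population.  Per-sex F_ST, mAIC and vAIC are compared by
randomizing sex labels within populations (sex counts preserved),
two-sided on the female − male difference.  The dispersing sex is expected
to show lower F_ST, negative mAIC and larger vAIC.

σ is recovered from an IBD slope b and an effective density D (individuals
per m²) through σ = (4πDb)^{−1/2}; the API also reports the σ interval over
a density range, since field densities are usually known only as a bracket.

## Recent-migration MCMC

The model assigns each sampled individual of population r an ancestry
(s, t): non-migrant (t = 0), first-generation immigrant from s (t = 1), or
offspring of one immigrant parent from s (t = 2).  The prior on each row of
the migration matrix m is uniform total immigration T ∈ [0, 1/3] with a
flat Dirichlet split among sources, so the non-migration diagonal is
marginally uniform on [2/3, 1] — this parameterization reproduces the
analytic no-information values (diagonal mean 5/6, per-source mean
(1/6)/(P−1), diagonal 2.5% quantile 0.675) that the prior-only sampler and
`migration_prior_summary` both expose.  A flat-simplex alternative was
rejected because its diagonal mean would depend on the number of
populations.

The ancestry prior given m is made exactly generative: a non-first-
generation individual draws two parent origins from the row distribution,
and when both parents are immigrants one of them is attributed at random,
giving P(t=1,s) = m_rs, P(t=2,s) = m_rr·m_rs·(1+m_rr), P(t=0) = m_rr³,
which sums to one.  Genotype likelihoods: t ∈ {0,1} uses the source
population's inbreeding-adjusted frequencies (P(aa) = p²(1−F) + pF,
P(ab) = 2pq(1−F)); t = 2 draws one allele from the source and one from the
residence population with no F term — the inbreeding treatment of
mixed-ancestry genotypes is ambiguous in the underlying model class, and
omitting F there is the documented resolution.  F_r is uniform on [0,1]
and allele frequencies are flat Dirichlet, initialized from observed
counts with one pseudo-count.

Sampling is Metropolis-within-Gibbs: ancestries by exact conditional
draws; each m row by a reflected random walk on T plus a mass transfer
between two sources (both moves are uniform in the (T, composition)
coordinates, so prior-only acceptance is 1); F and frequencies by bounded
random walks.  Desk-scale defaults are 2×10⁵ sweeps, 5×10⁴ burn-in,
thinning 50; validation runs in the test-suite use shorter, verified
chains.  Row-stochasticity and the diagonal bound are asserted at every
recorded state.  In prior-only mode the likelihood is disabled and the
sampler draws from the prior exactly — the no-information reference.

## Synthetic metapopulation generator

Forward-time Wright–Fisher demes with non-overlapping generations, sexed
diploids, stepwise-mutating microsatellites (±1 repeat at rate μ_nuc =
5×10⁻⁴ per transmission by default), and maternally inherited mtDNA with
Poisson(μ_mt·L) substitutions per transmission and a 10:1
transition:transversion bias.  The default shape mirrors a patchy-pond
survey: 7 demes, 10 loci, 20 sampled diploids per deme, 1024 bp of control
region for a subsample.  A forward simulator (rather than a coalescent)
was chosen because the validation suite needs per-generation migrant truth
and explicit two-generation migrant ancestries.

Three migration regimes: an explicit backward matrix (the offspring itself
immigrates — both parents from the source deme; realized migrant counts
are recorded, and the matrix can be switched on only after a divergence
phase via `migration_onset`, which is how two-generation planted-migration
datasets are made); a gametic kernel (mother and father demes drawn from
sex-specific Gaussian kernels — the regime for IBD and σ truth, with
realized parent–offspring displacements recorded over the last ten
generations); and an individual kernel (the offspring relocates according
to its own sex's kernel — the regime producing genuine sex-biased
dispersal signatures, since the dispersing sex carries foreign genotypes).

The truth record reports both the census density (deme size over cell
area) and the effective density, N_e = 4·N_f·N_m/N per deme averaged over
generations: random sex ratios make N_e ≈ 0.86·N at deme size 6, and the
IBD relation b = 1/(4πDσ²) holds for the effective density.  Realized σ is
the root half mean squared parent–offspring displacement.

What the generator does not emulate: vole life history (litter sizes,
overlapping generations, seasonal breeding), genuine landscape-dependent
movement (kernels are isotropic in distance, not cost), genotyping error
or null alleles, and the geography of any real study area.  Passing tests
therefore demonstrate correctness of the estimators under the stated
models, not robustness to those real-data complications.

## Validation design choices and problem sizes

* IBD slope/σ recovery uses a 14×14 lattice of 500 m cells, 6 diploids per
  deme, σ = 600 m, 20 loci, 200 generations; only the central 8×8 demes
  are analysed (a 3-cell buffer absorbs lattice edge effects, which
  otherwise inflate the slope) and regression pairs are restricted to
  distances in [σ, 6σ], the local scale where the ln-linear approximation
  holds.  Single lattices give noisy slopes, so recovery is judged on the
  mean over six replicates; σ ratios are checked per replicate.
* Planted-migration coverage uses two demes of 60 with m = 0.2 switched on
  for the final two generations after 120 generations of isolation,
  30 sampled diploids per deme, and ten replicate datasets.  The nominal
  95% interval is expected to cover the planted rate in ≥ 90% of
  replicates; most of the residual misses trace to sampling only half of
  each deme, which makes the realized migrant fraction of a sample drift
  from the nominal rate.
* Type-I error of Mantel and partial Mantel tests is calibrated on 5000
  null replicates of 8-label matrices with 99 permutations each; with the
  (x+1)/(n+1) estimator the rejection rate at α = 0.05 is exactly 0.05 in
  expectation.
* Island-model θ is compared to the infinite-island expectation
  1/(1 + 4Nm) within a factor of two; the finite number of islands (8)
  systematically lowers θ by the (d/(d−1))² correction, which the band
  absorbs.

## Known limitations

* The exact HWE enumeration falls back to Monte Carlo on large allele
  counts; p-values then carry O(n_steps^{−1/2}) noise.
* SAMOVA is a stochastic search; with few restarts it can return a local
  optimum (the suite uses enough restarts for the toy problems it poses).
* The migration sampler updates allele frequencies by random-walk moves;
  very large allele counts per locus would mix slowly at the default step
  size.
* â is undefined for pairs with no heterozygosity at shared loci; such
  pairs are dropped from regressions rather than imputed.
* Least-cost distances depend on the raster resolution through the octile
  metric; distances between points inside the same cell are zero.
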