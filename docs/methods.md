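# Methods

`pinpop` re-implements, as a tested pipeline, a population-genomic analysis
of a two-region conifer system: GBS SNP curation, diversity and
differentiation statistics, construction of the joint site-frequency
spectrum (SFS) between the two regions, and coalescent demographic
inference over four two-deme scenarios with AIC-based model choice and
parametric-bootstrap confidence intervals. A synthetic-data generator with
known truth stands in for the study's raw sequencing data, so every stage
is testable end to end.

## The demographic model

Two demes — SMO (Sierra Madre Oriental) and ChD (Chihuahuan Desert) —
split from one ancestral deme `T_DIV` generations ago. Four scenarios are
compared:

| scenario | free parameters | k |
|----------|-----------------|---|
| DIV      | N_SMO, N_ChD, T_DIV | 3 |
| DIV_M    | + m_SMO→ChD, m_ChD→SMO | 5 |
| CON      | + pre-contraction sizes and times T_CON_* ∈ (0, T_DIV) | 7 |
| CON_M    | contraction + migration | 9 |

Sizes are diploid individuals; times are generations (converted to years
with a 40-year generation time, the long reproductive span typical of
pinyon pines); migration rates are per-lineage per-generation
probabilities stated in the forward direction of gene flow and converted
internally to backward-in-time lineage-movement rates. The mutation rate
defaults to 2.91e-8 per base per generation (7.28e-10/yr), a Pinaceae
estimate. The ancestral size is not separately identifiable in this design
and defaults to N_SMO + N_ChD at the merge (mass conservation); it can be
fixed to any value or estimated (`anc_policy="free"`).

## Expected SFS by structured-coalescent Monte Carlo

The expected joint SFS is computed from the mean branch-length matrix over
replicate structured-coalescent genealogies (numba-compiled kernel):
within-deme pairwise coalescence at rate k(k−1)/(4N), per-lineage
migration, size switches at contraction times, and a merge into the
ancestral deme at `T_DIV`. A branch subtending (i, j) sampled chromosomes
accumulates its length into cell (i, j); under infinite sites,
`mu * E[L(i,j)]` is the per-site probability of a segregating site with
those derived counts. The kernel was validated against an independent
coalescent simulator (branch-mode allele-frequency spectra) on the fitted
divergence-with-migration model — total tree length agrees to 0.05% and
the spectrum to total-variation distance at the oracle's own Monte-Carlo
noise — and on a strongly asymmetric one-way-migration model that
distinguishes the direction convention.

Simulated SNP panels draw each site's genealogy with length-biased
rejection sampling (a site conditioned on being polymorphic comes from a
longer-than-average tree), then place one mutation uniformly on the
branches. The envelope is six times the pilot mean tree length; longer
trees are accepted outright, a truncation with negligible probability.

## Composite likelihood and identifiability

SNPs are treated as independent draws from the expected spectrum
(composite likelihood). Two data modes:

* **conditional** — segregating cells renormalised to 1. The spectrum is
  then invariant under the coalescent rescaling (cN, cT, m/c), so absolute
  sizes are *not* identifiable: the classic SNP-panel caveat.
* **absolute** — the observed spectrum also carries the monomorphic site
  count for an implied callable length L in its (0, 0) corner;
  `L = S / (mu * E[tree length])` is reported by the simulator. Together
  with the fixed mutation rate this pins the absolute scale through theta.
  All recovery experiments use this mode.

Two numerical choices matter for a Monte-Carlo likelihood:

* **Sparse-cell pooling** (`pool_below`, default 3 sites): observed cells
  below the threshold are merged into one aggregate category. Pooling is
  defined by the data, hence identical across candidate models, and it
  removes the large downward bias and noise that near-empty cells inject
  when their probabilities are estimated by simulation. With pooling, the
  log-likelihood at 10^4 genealogy replicates is reproducible to ~1 unit
  and model ranking matches 3×10^5-replicate evaluations; without it,
  rankings at 10^4 replicates can invert. Pooling preserves the
  divergence-time signal (profiles with and without pooling have the same
  curvature at high replicate counts).
* **Zero flooring** (`p_min`, default 1/(10·reps)): any remaining
  zero-probability cell is floored before renormalisation.

## Optimisation

Maximum composite likelihood per scenario uses, in order:

1. **Screening** — `n_screen × n_starts` draws from the search priors
   (log-uniform for migration) scored with a cheap common-random-number
   batch; starting points are the best draws subject to a minimum spread
   along `T_DIV`, because the surface has near-tied basins (low divergence
   with little migration vs deeper divergence with migration).
2. **Cyclic coordinate maximisation** (ECM-style) — each free parameter in
   turn on a grid (full range in the first cycle, then geometrically
   shrinking windows), with common random numbers within a cycle; after
   each cycle a joint rescale move (cN, cT, m/c) walks the coalescent
   scaling ridge that coordinate moves crawl along.
3. **Simplex polish** — Nelder-Mead in box-normalised coordinates on the
   fixed-seed (hence deterministic) surface, crossing diagonal ridges.
4. **Profile walk** — `T_DIV` is the weakly identified direction (its
   profile is flat over a wide range, which is also why the study's own
   interval on the divergence time is much wider than on the sizes). The
   walk grids T_DIV geometrically around the current value and re-optimises
   the other parameters at each grid point by short simplex runs,
   warm-started from the neighbouring point (continuation), keeping the
   best point found.

Start endpoints are compared under one larger common evaluation batch.
`FitResult.k` counts the scenario's free parameters so AIC = 2k − 2lnL is
auditable; Akaike weights are exp(−Δ/2) normalised over the compared fits.

Machinery validation: refitting a 50,000-SNP panel simulated at the
published best-fit point recovers the divergence time within 2% and sizes
within 4%, so the estimator stack is effectively unbiased at large n; at
the study's n = 3100 the remaining scatter is dominated by sampling noise,
widest for T_DIV (as the published intervals also show).

## Synthetic data

`generate_dataset` emulates the study's post-filter data shape: 10
populations in 2 regions (5 + 5), 9 trees per population, ~3100 unlinked
biallelic SNPs, 9% missing genotypes, mean site depth 64×. Populations
within a region are exchangeable samples of one deme (the demographic
model has two demes; the small within-region differentiation of the real
data is not modelled). Genotypes pair simulated chromosomes at random, so
within-region Hardy-Weinberg proportions hold by construction. Depths are
Poisson(64) per genotype with heterozygote allele splits Binomial(depth,
1/2); missingness is uniform at random.

Artifact ("paralog-like") loci, 5% by default, emulate collapsed
duplicates: two loci merge into one apparent locus, the apparent genotype
derives from four chromosomes, depth doubles, and heterozygote read ratios
leave 1:1. Half of the artifacts carry a fixed difference in the duplicate
copy — the strongest and most common real signature, giving near-universal
heterozygosity and alternate-biased reads; the rest merge two segregating
loci, a weaker signal. HDplot (per-site heterozygote proportion H vs
pooled read-ratio deviation D = (A−B)/√(A+B)) therefore removes artifact
loci at a much higher rate than clean loci, which the tests check, but
some weak-signal artifacts survive, as in real data.

What the generator does not emulate: sequencing error, allele dropout,
depth-dependent missingness, within-region structure (available as an
optional note but off by default), linkage (sites are unlinked by
construction, so LD pruning only acts on structure-driven correlation),
and reference/mapping biases. Passing tests therefore demonstrate the
statistical machinery, not robustness to those real-data artifacts.

## Filtering cascade

Order: biallelic → depth/missingness (genotypes below 15 reads masked;
sites >25% missing, then individuals ≥20% missing, dropped) → HDplot
(remove H > 0.6 or D outside [−10, 10]; boundaries retained; sites with no
heterozygote reads are judged on H alone) → LD pruning (windows of 50
variants, step 5, greedy removal of the higher-missingness member of any
pair with r² ≥ 0.5, repeated to a fixpoint so the operation is idempotent;
base-pair windows available via config) → Hardy-Weinberg exact test
(per-population by default, Bonferroni across sites at α = 0.05; pooled
testing would confound the two-region structure with HWE departure). Each
stage appends to a ledger with monotone site/individual counts.

With 9-individual populations and thousands of sites the Bonferroni
per-population HWE filter has essentially no power; it is retained for
interface fidelity and becomes active for larger samples or pooled scope.

## Statistics

H_O is the mean heterozygote fraction; H_S the Nei-Chesser small-sample
gene diversity; F_IS = 1 − H̄_O/H̄_S on site-averaged values; π sums
unbiased per-site heterozygosity and divides by a caller-supplied callable
length (per-SNP if omitted — SNP panels do not carry the monomorphic
length, so the absolute scale of π is only meaningful with an explicit
denominator). Watterson's θ is S/a₁ (per dataset, or per site given a
length); Tajima's D uses the 1989 constants with the site-average called
chromosome count (exact for complete data). F_ST is the Weir-Cockerham
(1984) variance-component estimator, multilocus as ratio of summed
components; negative estimates are reported as computed. Allelic richness
is hypergeometric rarefaction to a fixed chromosome count.

## Joint SFS

Missing data are handled by hypergeometric projection: each site
contributes its expected subsample spectrum at fixed (proj_A, proj_B)
chromosomes; sites with too few called chromosomes are dropped; fractional
mass is kept real-valued. Default projection retains ≥90% of sites.
Folding keeps the pooled-minor orientation; exact-half cells are kept once
at the lexicographically smaller member of the pair. The spectrum is
stored as a flat text matrix with a one-line header.

Polarisation: the reference mapping gives no ancestral-state information,
so the default spectrum is folded; the unfolded, reference-polarised
spectrum is available by flag. The two-deme scenarios used here are
identifiable from the folded joint spectrum (verified by the 50k-SNP
recovery above).

## Desk-scale problem sizes

The original analysis ran 100 optimiser replicates × 30 ECM cycles ×
150,000 simulations per likelihood, and 100 bootstrap replicates. This
package's defaults are chosen for single-CPU desk scale and are stated
wherever they differ: likelihood evaluations use 10^4 genealogy replicates
(the pooled likelihood is reproducible to ~1 unit at that size), fits use
2–4 starts and 4–10 cycles plus polish and profile walk, the recovery
experiments refit spectra projected to 20 + 20 chromosomes, and acceptance
runs summarise 6 replicate seeds by their median. Full-scale settings
(150,000 replicates per evaluation, 100 starts) remain available through
`FitSettings`.

## Known limitations

* T_DIV is weakly identified from ~3100 folded SNPs: its profile
  likelihood is flat within a few log-units across roughly ±40% of the
  value, so single-seed recoveries scatter accordingly (the published
  interval on the divergence time is correspondingly the widest).
* The composite likelihood ignores linkage; standard errors from its
  curvature would be anticonservative, which is why intervals come from
  the parametric bootstrap instead.
* Absolute parameter scale rests entirely on the assumed mutation rate and
  the implied callable length; errors in either rescale N and T directly.
* The HWE exact test uses the plain conditional two-sided convention (no
  mid-p correction).
* `hdplot_D` pools reads across heterozygotes; per-individual z-scores are
  not computed.
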