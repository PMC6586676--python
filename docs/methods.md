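# Methods

## Problem setting

One focal specimen sequenced at very low coverage (~0.05x) is compared
to two conspecific reference panels (species A and B, e.g. beluga and
narwhal), themselves at ~0.18–0.24x. No genotypes are called anywhere:
the unit of information is the allele read count per individual per
biallelic site, and at retained sites the focal specimen contributes
exactly one read. The pipeline answers three questions: which pedigree
class (pure, F1, F2, backcross) the specimen belongs to, which species
its maternal lineage is, and what its karyotypic sex is.

## Site model

Sites are classified from the alleles *observed* in the panels, not
from population truth: a "fixed difference" means each panel exhibits
exactly one allele and the two differ. Such sites need not be true
species-wide fixed differences; they are ancestry-informative markers
whose residual misclassification risk is quantified by the
misassignment bound below.

**Unique read depth (urd).** Defined as the number of distinct panel
individuals with at least one read at the site; an individual with
several reads counts once. This joint measure of read and individual
support is the quantity entering the misassignment bound. The
alternative reading — counting reads — is available via
`urd_mode="reads"` for sensitivity analysis; the individual-counting
definition is the default because it is what makes urd draws
independent allele samples (two reads from one individual are not).

**Filters** (defaults): total read depth across all individuals ≤ 9;
urd ≥ 3 in *each* panel; exactly one focal read (so each retained site
contributes one independently sampled allele — sites with ≥2 focal
reads are dropped rather than collapsed); monomorphic sites excluded.
The urd threshold of 3 trades the number of retained sites against the
worst-case misassignment probability (0.105 at urd 3). Filtering is
idempotent and order-independent; the class breakdown (fixed /
poly-A-only / poly-B-only / poly-both) is reported as counts and
percentages of retained sites.

**Panel purity screen.** Each panel individual is scored at
fixed-difference sites classified with that individual *left out*: the
fraction of its covered fixed sites where it carries the other
species' diagnostic allele. Pure individuals score near the sequencing
error rate; an admixed individual planted in a panel scores near 0.5
(slightly above when sites carry several of its reads). This is a
lightweight observational stand-in for a model-based admixture check on
the panels.

## Misassignment bound

With parental-species allele frequency `f` and panel unique read depth
`urd`, the probability that the panel shows only the major allele while
the focal specimen carries the minor one is `P = f^urd (1 - f)`. Its
maximizer is `f_max = urd/(urd+1)` and the bound
`P_max = (urd/(urd+1))^urd / (urd+1)` decreases strictly in urd
(0.148 / 0.105 / 0.082 at urd 2 / 3 / 4). These are worst-case values,
attained only if every site segregated at exactly f_max; and because
both panels are filtered symmetrically, residual misassignment affects
both species nearly equally and largely cancels in the hybrid tests.
Double precision is used throughout (the quantities are smooth rational
functions; comparisons in tests use 1e-12 absolute tolerance). The
module reports probabilities and never enforces a threshold; the
pipeline's `min_urd_per_panel` config does.

## Scenario tests and ancestry likelihood

Let `n_b` / `n_n` be the focal reads matching the A- / B-diagnostic
allele over k single-read fixed-difference sites. A scenario with
expected A-ancestry `b` predicts counts `(b k, (1-b) k)`;
`T = Σ (O-E)²/E` over the two categories is compared to χ²(1 df) — one
free proportion, the standard choice. Pure scenarios (b = 0 or 1) are
clamped to `[error_floor, 1 - error_floor]` (default 0.001, of the
order of the sequencing error rate) so T stays finite while rejection
of mixed data remains overwhelming; with the clamp disabled an
infinite-T result is returned flagged rather than raised.

The likelihood treats sites as independent Bernoulli draws, collapsing
to `log L(b) = n_b log b + n_n log(1-b)` (+ a data-only binomial
constant reported separately so curve shapes are comparable). The MLE
is the closed form `n_b/k`; the interval is the 2-log-likelihood-unit
drop on a grid of step 0.001. Physical linkage violates independence
but leaves the proportion estimate unbiased; no LD correction is
applied, so the reported interval is, if anything, anti-conservative —
a known limitation shared with the single-read design itself. With one
read per site F1 and F2 are indistinguishable (both b = 0.5); the
default seven-scenario set therefore spans
{pure_A, BC2A, BC1A, F1, BC1B, BC2B, pure_B} with expected b
{1, .875, .75, .5, .25, .125, 0}. The set is configurable.

The two scores always agree on the best-supported scenario for
two-category data; they need not order the rejected tail identically,
because the clamp affects pure-scenario likelihoods and T differently.

**Known discrepancy in the published worked example.** For the read
tally (4,679, 4,499) against the F1 expectation (4,589, 4,589), direct
evaluation gives T = 2·90²/4589 = 3.530 and p = 0.0603, whereas the
source study prints T = 3.58 with the same p = 0.06. The printed T is
not reproducible from the printed counts; the package reports the
directly evaluated statistic and the agreement is asserted on the
p-value at two decimals.

**Chi-square accuracy.** An exact brute-force oracle enumerates all
k+1 binomial outcomes and sums the null probabilities of outcomes with
T at least the observed value. The χ²(1) tail overstates significance
at small k (the gap is ~0.02–0.05 at k = 50, a plain continuity effect)
and agrees to ~10⁻³ only by k ≈ 10⁴ — the regime the pipeline actually
operates in. Tests assert the convergence, not a small-k accuracy the
approximation does not have.

## Sex and maternal lineage

**X:autosome ratio.** Per-site depths are partitioned into X-linked and
autosomal classes (the partition is an input column; scaffold-to-
chromosome assignment is upstream and out of scope, with provenance
recorded). Each of `n_reps` replicates draws `sites_per_rep` sites
*with replacement* from each partition (bootstrap-style; the sampling
scheme upstream literature leaves unspecified) and forms the ratio of
mean depths; the point estimate is the replicate mean and the
"confidence intervals" are empirical 5/95% quantiles (with quartiles),
matching the quantile language of the approach being implemented.
Defaults are desk-scale: 10⁴ sites × 100 replicates rather than
genome-scale 10⁷ × 100; the replicate spread shrinks as sites_per_rep
grows, and at these defaults 100 simulated individuals at 0.05–0.3x are
called with ≥99% accuracy. The call is male if the 5–95% band lies
below the boundary, female if above, ambiguous if it straddles. The
boundary defaults to 0.75 — the midpoint of the ~0.5 and ~1.0 cluster
centers; no numeric boundary is prescribed upstream, so it is exposed
in config. Real data deviate from the ideal 0.5 (e.g. a reported
hybrid ratio of ~0.58) through mapping bias and imperfect X-scaffold
assignment; the Poisson simulator does not model those biases, so
passing tests demonstrate the estimator's statistical behaviour, not
robustness to assembly artefacts.

**Mitochondrial comparison.** Mean coverages of the focal reads mapped
competitively to each species' mitogenome are compared; the higher
reference wins if the fold ratio (max/min) is at least `min_fold`
(default 2, comfortably below the ~3-fold separation seen in practice),
otherwise the call is ambiguous. The call is scale-invariant. Consensus
building and haplotype networks are out of scope.

## Synthetic-data generator

What it emulates: two species whose per-site allele-1 frequency pairs
follow the observed class mix (78.0% fixed for alternate alleles, 13.2%
polymorphic in A only, 6.2% in B only, 2.6% in both, remainder
monomorphic-identical; within-species MAF uniform on [0.05, 0.5] with
random major/minor orientation); Hardy–Weinberg diploid panel
individuals (8 + 8 by default, unrelated); Poisson read depth per
individual per site (means 0.24x / 0.18x panels, 0.05x focal); reads
drawn uniformly from the genotype's two alleles and flipped with a
symmetric error rate (default 0.002, a typical post-filter base error
scale); focal genotypes built by recursive gamete draws from the
pedigree recipe. All generators are bit-reproducible under a fixed
seed.

What it does not emulate: base/mapping quality variation, reference
bias, DNA damage, linkage and recombination, population structure or
relatedness within panels, and depth heterogeneity along the genome.
Consequences: simulated urd draws are exactly independent (matching the
misassignment model's assumption), and simulated likelihood intervals
are honest — both assumptions are only approximately true of real reads,
so passing tests validate the statistics, not the upstream
bioinformatics.

A shortcut generator (`simulate_single_read_matches`) produces the
(n_b, n_n) tally directly for a pedigree at all-fixed sites with exactly
one focal read per site — the configuration the scenario tests consume —
and is used for power, recovery and calibration studies at k = 9,178
sites (the fixed-site count of the motivating study).

## Problem sizes used in the checks

Closed-form checks are instantaneous. Monte-Carlo checks use: 10⁵
trials for the misassignment oracle; 200 replicates × 5 hybrid classes
at k = 9,178 for ancestry recovery (binomial SE ≈ 0.005, so the ±0.02
criterion has large margin); 2,000 F1 replicates for type-I calibration
(SE of the rate ≈ 0.005 against a ±0.02 band); 100 individuals for sex
recovery; and an end-to-end pipeline run on 4×10⁵ simulated sites,
which the default filters reduce to ~500 informative single-read sites
— enough to single out F1 among the seven scenarios.

## Degenerate inputs and tie-breaks

Zero panel reads in both panels → monomorphic with an `undetermined`
flag. Empty post-filter tables are a flagged summary, not an exception;
downstream inference on zero informative reads raises. `b = 0` or `1`
with contradicting data evaluates to a log-likelihood of −∞ (a value,
not an error). Scenario ranking sorts by T with a stable sort, so
ties preserve the configured scenario order. Both mito coverages zero
is an error; one zero gives an infinite fold ratio and a confident
call.
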