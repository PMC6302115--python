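# Methods

`ldpopsize` analyses diploid biallelic SNP genotypes, per population, through
a fixed chain: quality control, cross-population common-marker intersection,
pairwise linkage disequilibrium (LD), LD-decay summaries, historical and
contemporary effective population size (Ne), and PCA population structure.
A forward Wright–Fisher simulator with known truth backs every stage's tests.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Genotype model and containers

Genotypes are allele dosages 0/1/2 (copies of the non-reference allele) with a
missing sentinel, aligned to a physical marker map (1-based bp positions,
strictly increasing within a chromosome). All distances are `|pos_i − pos_j|`
in bp. Marker identity across populations is the triple (chromosome,
position, unordered allele pair); strand flips are deliberately not
auto-resolved — silently "fixing" strand is a classic source of phantom
differentiation, and panels from a single array share one strand convention.
When reading PED (which designates no reference allele) the first-seen allele
per marker becomes the reference; every downstream statistic (MAF, HWE, r²,
PCA, Ne) is invariant to that choice, which the tests verify.

## Quality control

The ladder runs in a fixed order with exclusive attribution, so the report's
counts add up exactly: samples with >5% missing genotypes are dropped first,
then SNPs by call rate <95%, then Hardy–Weinberg exact p <1e-6, then
MAF <5%. All boundaries are strict (a SNP at exactly the threshold is kept).
The HWE test is the exact conditional test on observed allele counts
(Wigginton-style), standard tail rather than mid-p; probabilities come from a
ratio recurrence normalised at the end, and the suite checks them against
full enumeration — exhaustively for every configuration up to 50 diploids.
A practical corollary worth knowing: with 20 or fewer diploids *no* genotype
configuration can reach p < 1e-6 (the most extreme balanced no-heterozygote
pattern bottoms out at ~1.3e-6), so the HWE filter is inert for very small
cohorts.

## Linkage disequilibrium

Two r² estimators are exposed, because field practice is split between them:

* **genotypic** (default): squared Pearson correlation of dosage vectors over
  pairwise-complete individuals — what PLINK 1.9's `--r2` computes;
* **em**: the haplotypic Hill–Robertson form `r² = D²/(pA pa pB pb)` with
  haplotype frequencies recovered from unphased genotypes by EM over the
  double-heterozygote ambiguity (tolerance 1e-10, ≤1000 iterations). The EM
  is started from balanced, cis-heavy and trans-heavy resolutions and the
  highest-likelihood fixed point is kept: the balanced start alone is a
  saddle point whenever the unambiguous counts are symmetric, and a
  single-start EM silently returns D = 0 there.

The two differ slightly under Hardy–Weinberg departures; reports name the
estimator used. Pairs are formed within chromosomes up to 10 Mb (decay work)
and summarised as: adjacent-marker mean ± sd per chromosome; 100-kb binned
decay curves over 0–10 Mb; mean r² of the bin containing each fixed distance
(0.1/0.5/1/5/10 Mb tables); and the threshold distance where the binned curve
first falls through r² = 0.2, linearly interpolated between the bracketing
bins' mean distances and reported as an explicit "no crossing" when the curve
starts below or never crosses. Missing data are handled pairwise-complete,
and each pair's complete-sample count `n_used` is kept because the Ne
machinery needs it.

## Historical Ne

The estimator inverts the drift expectation of LD at recombination fraction c:

    E[r²_adj | c] = 1 / (4 f(c) N_t + α)   ⇒
    N_t = (1 / (4 f(c))) (1 / E[r²_adj | c] − α),   t = 1/(2c)

with α = 2 by default (mutation assumed to occur; α = 1 for none), f the
mapping from physical distance (identity by default, c = bp × cM/Mb × 1e-8;
Haldane and a Sved–Feldman-style `c = d/(1+2d)` offered for compatibility
with other tools), and r²_adj the sample-size-adjusted r². The adjustment is
`r² − 1/n` by default (appropriate for genotypic r² with n diploids;
`1/(2n)` and none are configurable), floored at zero with a flag.

Binning: 30 bins of 50 kb starting at 0, with pairs collected to 5 Mb and the
surplus beyond the binned 1.5 Mb span counted and ignored. Width, count, and
collection range are independent knobs because those three defaults are
internally inconsistent if forced to agree, and exposing them keeps the
arithmetic honest. Bins whose mean adjusted r² is too large for the formula
(1/E ≤ α) are flagged ill-posed, not dropped. The per-bin inversion is exact:
manufactured bins on the model recover N to machine precision, which the
acceptance suite asserts for N ∈ {50, 100, 1000} and α ∈ {1, 2}. Summaries
use the harmonic mean (Ne compounds harmonically over time), optionally
restricted to bins informative about the last t generations; per-chromosome
trajectories report their realised t-range rather than imposing one.

`HistoricalNe(pairs, config).fit()` returns a results object carrying the
trajectory table, per-chromosome harmonic means and a `summary()`.

## Contemporary Ne

The single-point LD method (Hill; Waples 2006; NeEstimator v2 conventions):
mean r̂² over marker pairs after excluding markers with MAF < pcrit (default
0.05), minus Waples' empirically calibrated sampling expectation at the
harmonic-mean per-pair sample size S
(`1/S + 3.19/S²` for S ≥ 30, `0.0018 + 0.907/S + 4.44/S²` below), inverted
through the mating-model quadratic — random: `(1/3 + √(1/9 − 2.76 r²'))/(2r²')`,
monogamy: `(2/3 + √(4/9 − 7.2 r²'))/(2r²')`, with the S < 30 variants using
(0.308, 2.08) and (0.618, 5.24). All constants sit in one table
(`WAPLES_CONSTANTS`) so any dialect difference from other implementations is
auditable in one place. Non-positive corrected r² yields an infinite
estimate, the method's standard "no drift signal" outcome. Missing genotypes
are handled by pairwise deletion, which is what the harmonic-mean S absorbs.

The r̂² itself is the Burrows composite: Δ̂ = (S/(S−1)) (Σxᵢyᵢ/(2S) − 2p̂_A p̂_B)
squared over Weir's denominators (p̂(1−p̂) + D_HW) at each locus. This is the
estimator Waples' expectations were calibrated for; substituting the Pearson
dosage correlation (whose independence expectation is ≈ 1/(S−1), not
1/S + 3.19/S²) makes the published constants overcorrect and drives the
estimate to infinity whenever the drift signal is modest — an effect large
enough to matter at S ≲ 50. The package verified this on independent
genotypes: composite r̂² minus the Waples expectation is centred on zero to
~1e-4 across S from 15 to 100.

Unlike the decay machinery this module includes cross-chromosome pairs —
the method wants effectively unlinked loci. Tightly linked pairs inflate
mean r² and crush the estimate, so for dense maps a minimum same-chromosome
pair distance (or an effectively cross-chromosome-only setting) is the right
configuration; the recovery tests use cross-chromosome pairs over eight
chromosomes and the default pipeline reports the configuration used.

Relatedness: method-of-moments IBD sharing per pair from IBS 0/1/2 counts
(PI_HAT = P(IBD=2) + P(IBD=1)/2). The IBS expectations use minimum-variance
unbiased estimates of the allele-frequency products (factorial moments of
allele counts) — this package's equivalent of PLINK's finite-sample
correction factors; plugging raw frequencies into p²q²-type terms inflates
PI_HAT badly for rare alleles. Estimates are clipped to the probability
simplex, which leaves a small positive floor on noisy panels: with few
effectively independent loci (short genetic maps, strong LD) mean "unrelated"
PI_HAT sits visibly above zero even though the unclipped estimator is
centred on it. Judge panels by map length in Morgans, not marker count.

## PCA

Columns standardized as `(g − 2p)/√(2p(1−p))` (variance standardization),
missing dosages mean-imputed (0 after centering), monomorphic columns
dropped; eigendecomposition of the sample-covariance `X Xᵀ / m`. Variance
fractions divide by the sum of *all* eigenvalues, not the retained k, so
"PC1+PC2 explain x%" is well defined. Sign convention: the largest-magnitude
sample loading in each component is made positive. Eigenvalues are checked
against a power-iteration-with-deflation oracle and trace conservation.

## Wright–Fisher generator

Forward-in-time diploid simulation was chosen over coalescent machinery
because monogamy, pedigrees (for relatedness truth) and arbitrary Ne
change-points are then exact by construction. Discrete non-overlapping
generations; each offspring draws two distinct parents (random mating) or a
random couple (monogamy); gametes get Poisson(map length) crossovers at
uniform positions (Haldane, no interference); symmetric recurrent mutation
flips transmitted alleles at `mutation_rate` per site per gamete
(default 1e-4).

Initial standing variation is seeded at linkage equilibrium with frequencies
from a U-shaped Beta(½, ½) spectrum, then burned in for 4·Ne generations
(configurable) so LD reaches equilibrium. The mutation default matters: with
mutation off, equilibrium conditional LD among surviving polymorphic pairs
follows the mutation-free α = 1 form and overshoots it at small c, whereas
recurrent mutation at θ = 4Nu ≈ 0.04–0.4 reproduces the α = 2 regime
`E[r²] ≈ 1/(4Nc+2) + 1/n` that the Ne estimators assume — the acceptance
suite verifies every 50-kb bin over c ∈ [0.0005, 0.01] to within 25% at
Ne = 100, n = 100, pooled over 40 replicates. Sites are over-seeded by the
expected heterozygosity retention `∏(1 − 1/(2Ne_t))` (a heuristic that only
affects how many sites must be simulated, not their distribution), then
ascertained at MAF ≥ 0.05 in the sample and down-sampled to the target count.

Splits: daughter populations branch off a shared lineage at nested times
(the most recent split time must be shared by two populations — the final
bifurcation); daughters drift at their own Ne; all panels share one marker
set ascertained in the pooled sample, emulating a common-SNP array
intersection. A separate helper ascertains on a designated reference
population, which reproduces the classic directional bias: markers chosen in
one lineage show depressed MAF in a diverged one.

What the generator does *not* emulate: selection, migration after splits,
crossover interference, genotyping error beyond uniform missingness, and
realistic site-frequency spectra shaped by genome-scale mutation–
recombination heterogeneity. Passing recovery tests therefore demonstrate
the estimators' correctness under the neutral equilibrium model they assume,
not robustness to real-data pathologies such as admixture or array
ascertainment done on other populations.

## Problem sizes used by the test and acceptance runs

Chosen so each check is statistically meaningful at desk scale: the
LD-bridge pools 40 replicates of 2 × 2 Mb chromosomes (200 markers, n = 100);
historical-Ne recovery uses 20 replicates of 2 × 50 Mb with 2000 ascertained
SNPs (n = 50), scoring the harmonic mean over bins with t ≤ 50 against ±30%;
contemporary-Ne recovery uses eight 5-Mb chromosomes with cross-chromosome
pairs only; the acceptance script's three-population study uses 2 × 30 Mb,
~3000 shared markers, cohorts of 37/43/43 and a deep (150 generations,
Ne 40) plus shallow (50 generations, Ne 80/100) divergence design.

## Numerical choices

HWE tail inclusion uses a 1e-12 relative cushion so exact rational ties are
included despite float round-off. MAF spectrum binning adds a 1e-9 epsilon so
boundary values (e.g. 0.30 with 0.05-wide bins) land in their own bin.
Pairwise r² over missing data is computed from masked matrix products in
closed form, so results are independent of chunking. The decay threshold
interpolates between bin *mean* distances, not bin edges. Pipeline TSVs are
written with fixed 6-significant-digit formatting; identical configs produce
byte-identical outputs, which the tests assert.

## Known limitations

The historical-Ne inversion inherits every assumption of the Sved-type
formula (closed population, equilibrium, one constant recombination rate per
bp); its trajectory points are correlated across bins and carry no
confidence intervals. The contemporary estimate is sensitive to linked pairs
and to the S < 30 empirical constants outside their calibrated range.
PI_HAT needs many effectively independent markers. The EM r² can in
principle keep a local likelihood optimum in pathological tables, though the
multi-start covers all tables realisable from two-locus data we have found.
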