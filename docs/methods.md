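# Methods

This note records the statistical models, estimators, and numerical
choices behind `mimland`, in the spirit of a methods supplement: what each
component assumes, which knobs matter, and what the synthetic data used by
the test suite can and cannot tell you about real data.

## Window statistics with missing data

All of `pi`, `d_xy`, and `F_ST` are built from a single primitive: the
expected allele mismatch between two diploid genotypes. Writing a
genotype as its alternate-allele dosage `x in {0, 1/2, 1}`, the expected
mismatch of one allele drawn from each individual is `x + y - 2xy`, which
enumerates the four allele pairings (hom-ref vs het = 0.5, het vs het =
0.5, opposite homozygotes = 1). For a pair of individuals the distance in
a window is the mismatch sum divided by the number of sites *jointly
genotyped in that pair* — so each pair carries its own denominator and
missing data shrink denominators instead of biasing numerators. Invariant
sites are explicit records and enter every denominator; values are
therefore per genotyped site, not per variant.

- `pi` (nucleotide diversity): mean of per-pair ratios over unordered
  pairs of distinct individuals within a taxon. Within-individual
  heterozygosity is not itself treated as a pair. Pairs sharing no
  genotyped site are excluded from the mean rather than contributing a
  zero (which would bias diversity downward).
- `d_xy` (divergence): same mean, over pairs with one individual from
  each taxon.
- `F_ST` (differentiation): the K_ST family, `1 - K_S / K_T`. `K_S` is
  the weighted mean within-taxon distance with weights proportional to
  the number of within-taxon pairs `n_j (n_j - 1) / 2` (a sample-size
  weighting is available via `ks_weighting="size"`); `K_T` is the mean
  distance over all pairs of distinct individuals in the pooled sample.
  On complete data from strongly diverged taxa this approaches the Hudson
  form `1 - mean(pi) / d_xy` but they are different estimator families
  and exact agreement is not expected (our tests allow 0.05 absolute for
  d_xy >> pi). When the pooled sample carries no variation, `K_T = 0` and
  the window is reported missing.
- `d_a` (net divergence): `d_xy - (pi_a + pi_b)/2` from genome-wide
  means; it strips ancestral diversity and is the divergence-time proxy.

Per-site filters follow the resequencing design they mirror: a site
enters a comparison only if genotyped in at least 3 individuals of each
taxon involved, relaxed to 2 for the small outgroup panel; filtering is
applied independently per comparison. Half-called genotypes are treated
as fully missing (conservative).

Z-transformation of a landscape uses the population SD (`ddof=0`,
configurable); landscape normalization is a descriptive device here, not
an inference step, so no sample-size correction is applied. A
zero-variance landscape is an error naming the offending series.

## Window grids and covariates

Coordinates are 0-based half-open internally and 1-based inclusive in
every report table — the single convention that avoids off-by-one errors
in window tiling. Full windows start at multiples of the step while
`start + size <= contig length`; a contig shorter than one window yields
one truncated window, and nonoverlapping grids append a truncated
remainder window so they tile the contig.

Gene counts increment every window a gene overlaps by at least 1 bp, so
boundary-spanning genes count in both windows. Recombination rates come
from adjacent genetic-map markers as delta-cM / delta-Mbp; the top 5% of
interval estimates genome-wide are discarded as artifacts (map-error
spikes) before averaging, and a window needs at least 3 surviving
overlapping intervals to receive a value. The 5% filter is applied
genome-wide, not per chromosome: the cut is a single operation on the
pooled interval distribution (a `top_fraction` argument exposes it).

## Window trees and concordance

Per-window trees are built by neighbor joining from the same
missing-data-aware genotype distance matrices that drive `pi`/`d_xy`;
negative NJ branch lengths are clamped to zero. The concordance score
consumes only tip-to-tip distance matrices, so a distance-based tree is
the natural construction; externally inferred newick trees (e.g. ML) can
be supplied instead. Concordance between a window tree and the genome
tree is the Pearson correlation of their patristic (branch-length)
cophenetic matrices over the shared tips — scale-invariant, with higher
values meaning more similar trees. Patristic rather than purely
topological distances are used; the choice is configurable only by
supplying different trees, and a star tree (zero variance) yields a
missing score. Rooting uses the outgroup tips; when a window tree does
not recover the outgroup as a clade, the tree is rooted on the edge whose
bipartition best matches the outgroup split and flagged
(`outgroup_conflict`). Clade recovery is the fraction of (rooted) window
trees in which a clade is monophyletic.

## Landscape PCA, autocorrelation, and the deviation scan

The landscape PCA treats windows as observations and taxa (or taxon
pairs) as variables on the correlation matrix: columns are standardized,
so PC1 is the shared topography, not the amplitude, of the landscapes.
Windows with any missing variable are dropped listwise (the count is
reported); loadings are correlation-scaled (`eigenvector *
sqrt(eigenvalue)`, bounded by 1) and PC1's sign is fixed so the mean
loading is non-negative — "high PC1 = high statistic". The per-window
mean of standardized variables is returned alongside for the PC1-vs-mean
consistency check.

The spatial autocorrelation test computes, per linkage group, the Pearson
correlation of window values k grid steps apart with `k = round(lag /
step)` (lag 2 Mbp on a 500-kb grid gives k = 4). The null permutes the
genome-wide values jointly and reassigns them to positions, so it
preserves the value distribution while destroying spatial arrangement;
the p-value is one-sided for positive autocorrelation with a +1
correction, `(#null >= obs + 1) / (n_perm + 1)`. Linkage groups shorter
than k + 2 windows are reported missing.

The deviation scan is descriptive, as in its intended use: per window,
`Z-F_ST(pair) - Z-F_ST(PC1)` in SD units, with a rank; no multiple
-testing machinery is attached.

## Divergence-time trajectories and the pairwise correction

For each taxon pair the package reports Pearson correlations between its
window landscapes (mean pi of the two taxa, F_ST, d_xy) and the
covariate tracks, attached to the pair's d_a. Pairwise comparisons among
n taxa reuse the same deep branches, so the C(n,2) points are not
independent; the correction reduces them to one value per internal node
of the species tree — the unweighted mean over all pairs whose MRCA is
that node — giving n - 1 independent points (8 for 9 taxa). Weighting
pairs by window count when averaging into a node is possible in
principle; the unweighted mean is used because the window grids are
common across pairs here. Trend lines through contrasts are ordinary
least squares. Divergence times follow `T = d_a / (2 mu)` in generations
(`mu` per bp per generation, default 1.5e-8) times a generation time in
years (default 2); a small negative d_a — possible in very shallow pairs
— is clamped to zero with a warning.

## Introgression statistics

Sites are polarized against the outgroup: biallelic sites where the
outgroup panel (at least 2 genotyped individuals) is fixed; the derived
allele is the non-outgroup allele. With derived frequencies p1, p2, p3,

    ABBA = (1 - p1) p2 p3      BABA = p1 (1 - p2) p3
    D = (sum ABBA - sum BABA) / (sum ABBA + sum BABA)

Significance uses a delete-one block jackknife over contiguous 500-kb
blocks (per contig), Z = D / SE, two-sided normal p. The variance is the
classic unweighted delete-one form. A site-sum-weighted variant (Busing
et al., weights = block ABBA+BABA sums) is available but not the
default: on matched migration-free coalescent replicates the weighted SE
was anticonservative (8.0% vs 5.3% rejections at |Z| >= 1.96, with the
t-distribution expectation at 50 blocks being 5.6%), because in
coalescent data a block's weight covaries with its genealogical variance.
Blocks must number at least 10.

The genome-wide admixture proportion f divides the observed excess
S(P1, P2, P3) = sum(ABBA - BABA) by the excess expected under complete
admixture, S(P1, P3a, P3b), where P3a/P3b is a random half-split of the
P3 individuals drawn once per test with a recorded seed; both sums are
restricted to sites where both halves carry data. Window f_d uses the
dynamic-donor denominator S(P1, PD, PD) with PD the higher-derived-
frequency population of {P2, P3} at each site, which keeps the statistic
in [0, 1] for admixed windows; windows with a negative numerator or
non-positive denominator are reported missing rather than zero (the
statistic is undefined there). When genome-wide D is negative, P1 and P2
are swapped before windowing (flagged), so f_d always targets the taxon
with the derived-allele excess. Quartets are explicit inputs — the
package does not enumerate "appropriate" four-taxon combinations from a
tree. Summaries across tests are per-window mean and max over
non-missing tracks.

## Forward simulator

A discrete-generation Wright-Fisher model: an ancestral diploid
population of size N (default 10,000) evolves 10N generations, splits
into two size-N daughters, and diverges a further 10N generations. Each
individual carries one L = 21 Mbp chromosome (mu = 1e-8, r = 1.5e-8 per
bp per generation); the middle third is always neutral and the two
distal thirds host the scenario's selected mutation class(es) with fixed
selection coefficient s = Ns/N per class, codominance h = 0.5, and
multiplicative fitness across sites. Scenario wiring:

- **neutral** — nothing has fitness effects.
- **bgs** — tail mutations deleterious with probability `prop_neg`
  (defaults Ns_neg = 100, prop_neg = 0.1).
- **bdmi** — background selection in the ancestor (a flag disables it);
  after the split each new selected tail mutation is deleterious in one
  randomly chosen population and neutral in the other, with symmetric
  migration m = Nm/N.
- **positive** — tail mutations beneficial with probability `prop_pos`
  (defaults Ns_pos = 100, prop_pos = 0.001).
- **bgs_positive** — both classes active.
- **local_adaptation** — new tail mutations beneficial in one random
  population only, with migration; additionally, at the split every
  segregating neutral tail variant is recruited with probability
  `prop_pos` to be beneficial in one random population (adaptation from
  standing variation). The recruitment probability is a modeling choice
  recorded in the config.

Migration is whole-individual: each offspring draws both parents from
the other deme with probability m, so realized migrant counts average Nm
per generation (recorded in the output for bookkeeping checks).

Mutation is finite-sites on integer coordinates with collision dropping —
effectively infinite-sites at these mutation rates. Neutral variation is
simulated directly in the forward model rather than overlaid on recorded
genealogies; the contract is on output distributions, and the scaled
model is checked against an msprime coalescent with matched theta, rho,
and split time (two-sample KS on window diversity).

Snapshots: the split itself (timepoint 0) plus 10 evenly spaced
timepoints through the divergence phase — N-generation spacing under the
defaults. The split snapshot exists because the model's sharpest
contracts live there: F_ST ~ 0 and r(d_xy, pi) ~ 1 immediately after a
split. At each snapshot, `n_sample` (default 20) individuals per
population are sampled and window pi_a, pi_b, d_xy, and F_ST are
computed through the window-statistics module, with the window length as
the invariant-site denominator (no missing data in simulation output).

**Rescaling.** `rescale(config, Q)` gives N/Q individuals, times /Q, and
mu, r (hence s and m via fixed Ns, Nm) x Q, preserving theta = 4Nmu,
rho = 4Nr, Ns, and Nm. It refuses N/Q < 100 or rescaled |s| > 0.5 and
warns above 0.1. The desk profile (`desk_scenario`) additionally shrinks
the genome tenfold (L = 2.1 Mbp, 50-kb windows), keeping the 42-window
layout of the full-size design; with Q = 20 this gives N = 500,
mu' = 2e-7, r' = 3e-7 — the configuration used by the test suite and the
acceptance script. At Q = 20 the default selected classes have |s'| =
0.2; directional signatures (which side of the chromosome is suppressed
or differentiated) are robust to this, but absolute magnitudes of
selective effects should not be read off rescaled runs.

Replicate counts in the shipped checks are 5 (neutral equilibrium) and 2
each for background and positive selection: the neutral check is a tight
quantitative bound (10% on mean pi), while the directional contrasts —
an ~8-20% center-vs-tail diversity difference under BGS and the much
larger sweep signatures — are comfortably resolved by two replicates
pooled over 42 windows each.

**Engine.** Each population stores haplotypes as rows of a uint8 matrix
whose columns are segregating mutations, kept position-sorted in a core
block (crossovers become contiguous segment copies) plus a small
unsorted pending tail of recent mutations, merged at periodic
compactions. Mutations fixed within a population are archived out of the
matrix and re-materialized only when sampling (they still contribute to
d_xy/F_ST via the union site set). Identical seed and config give
bit-identical output.

## Synthetic radiation generator

The generator exists so every pipeline stage is testable without any
download: it emulates the *statistical signatures* the analyses consume,
not the mechanisms. Windows are independent coalescent loci (msprime)
under a dated 9-taxon species tree (an outgroup plus a nested ingroup
with one very recent ecotype pair, branch lengths in generations), with
intra-window recombination but no inter-window linkage. Heterogeneous
landscapes come from scaling every population size in window w by

    lambda_w = 1 / (1 + alpha * g_w / (rho_w + eps))

where g_w (gene count) and rho_w (recombination) are positive, spatially
autocorrelated tracks (moving averages of gamma draws; width
`smoothness`, optional negative cross-correlation mirroring real
genomes). This is a phenomenological stand-in for linked selection: low
recombination plus high functional density means low local Ne, which
induces the diversity/divergence/differentiation sign structure the
analyses test for, and the smoothed track injects the spatial
autocorrelation the permutation test must detect. Admixture is a
lineage-reassignment pulse (donor, recipient, time, fraction) restricted
to configurable window sets; an event older than the donor/recipient
divergence is an error. Genotypes are emitted diploid with explicit
invariant sites and i.i.d. missingness; the ground truth (lambda_w,
tracks, admixed windows and fractions, per-window midpoint tree,
expected diversity 4 Ne lambda mu) is exported for parameter-recovery
tests.

Defaults: Ne = 10,000; 4 individuals per taxon and 3 for the outgroup
(mirroring a small resequencing panel); mu = 2.5e-7 and r = 3e-6 per bp
(compressed windows: high per-bp rates substitute for length so a 2-4 kb
window behaves statistically like a much longer low-rate window);
alpha = 1, eps = 0.5 giving lambda roughly in [0.3, 0.9]; smoothness 6;
missingness 5%. With 400 windows of 4 kb the observed per-window pi
correlates with lambda_w at r ~ 0.75.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: linkage between windows (inter-window
autocorrelation is injected through the lambda track, not through
recombination), mechanistic linked selection (that lives in the forward
simulator), sequencing error, genotype-quality structure in the
missingness (it is i.i.d.), indels/multiallelic sites, and any attempt
to match a real dataset's absolute site counts.

A companion quartet generator produces (((P1,P2),P3),O) frequency data
as ~50 independent loci, one per 500-kb jackknife block, for calibrating
the D machinery under a migration-free null and under controlled pulses.
Truly unlinked blocks are used deliberately: within one simulated
chromosome, 50-100 kb blocks retain enough genealogical correlation to
inflate jackknife rejection rates regardless of the variance formula.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run everything at desk scale:
200 random matrices for oracle equivalence; 1,000 (tests) or 600
(script) coalescent quartets for D calibration; 600 x 3-kb and 400 x
2-kb window radiations for f and f_d recovery; 400 x 4-kb windows for
the landscape analyses; and the Q = 20 desk simulator profile above.
These sizes are the package's documented desk-scale operating points;
all were fixed as study conditions before the checks were frozen.

## Known limitations

- The K_ST weighting under site-varying sample sizes is one defensible
  reading of the estimator family; the `ks_weighting` switch documents
  the alternative.
- F_ST is exactly 0 for "identical taxa" only when all pairwise
  distances are equal; duplicated samples otherwise perturb K_T through
  self-pair distances. Two samples from one panmictic population give
  F_ST ~ 0 in expectation with O(1/n) finite-sample deviation.
- The genome-wide f estimator pooled across windows with heterogeneous
  local Ne is mildly biased toward zero (observed ~-20% at strong
  landscape heterogeneity); the recovery check therefore runs on a flat
  landscape, and users comparing f across genomes with very different
  diversity landscapes should expect the same compression.
- The forward simulator supports exactly two demes and fixed-s mutation
  classes; no distributions of fitness effects, no tree-sequence output.
- The deviation scan ranks windows; it attaches no error rates.
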