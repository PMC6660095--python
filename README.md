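# mimland

Window-based population-genomic landscapes for a small radiation of taxa
— diversity, divergence, differentiation, tree concordance, landscape
PCA, introgression scans, and a forward simulator of how such landscapes
evolve.

## The problem

Closely related taxa often show strikingly similar "landscapes" of
genetic variation: the same genomic regions have low diversity (π), low
between-taxon divergence (d_xy), and high differentiation (F_ST) in pair
after pair of taxa. The pattern is usually attributed to linked
selection — selection at functional sites indirectly removing variation
at associated neutral sites, most strongly where gene density is high
and recombination is low — but background selection, positive selection,
genetic incompatibilities, and heterogeneous gene flow all leave related
footprints. `mimland` implements the analysis toolkit for dissecting
this, for speciation-genomics practitioners working with a modest panel
of resequenced genomes from a radiation (think 9 taxa, a handful of
individuals each):

- **Window statistics with missing data.** π, d_xy, and K_ST-family
  F_ST = 1 − K_S/K_T in sliding windows, where every pair of individuals
  divides its mismatch count by its own number of jointly genotyped
  sites (variant + invariant), and per-site genotyping thresholds are
  applied per comparison. Net divergence d_a = d_xy − mean π serves as a
  divergence-time proxy, convertible to years via T = d_a / 2μ.
- **Tree landscapes.** Neighbor-joining window trees from the same
  genotype distances, a concordance score (Pearson correlation of
  cophenetic matrices against the genome tree), and per-clade recovery
  fractions.
- **Landscape PCA.** Windows × taxon-pairs correlation-matrix PCA whose
  PC1 is the shared landscape; a permutation test for spatial
  autocorrelation of any window series; and a Z-F_ST deviation scan for
  lineage-specific outliers above PC1.
- **Divergence trajectories.** Per-pair correlations between landscapes
  and genomic covariates (gene count, cM/Mbp recombination), reduced to
  n−1 phylogenetically independent contrasts by node-mean averaging over
  the species tree.
- **Introgression.** Patterson's D from derived-allele frequencies
  (ABBA = (1−p1)p2p3, BABA = p1(1−p2)p3) with delete-one block-jackknife
  significance, the genome-wide admixture proportion f (P3 half-split
  denominator), and window f_d with a dynamic donor.
- **Forward simulation.** A two-population Wright-Fisher model (ancestor
  splits after 10N generations, 21 Mbp chromosome with neutral middle
  third) under six scenarios — neutral, background selection, BDM
  incompatibilities, positive selection, both, local adaptation — with
  population rescaling to desk scale and per-timepoint window-statistic
  output.
- **Synthetic radiation.** A coalescent generator of a 9-taxon dataset
  (VCF with invariant sites, taxon map, gene BED, genetic map, trees)
  whose per-window Ne follows a gene-density/recombination-driven track,
  with configurable admixture pulses and exported ground truth — so the
  entire pipeline is testable without any sequencing data.

## Worked example

Generate a small synthetic radiation with an admixture pulse from
*aurantiacus* into the red ecotype restricted to a quarter of the
windows, then run the landscape and introgression analyses:

```python
import numpy as np
from mimland.synthetic_radiation import SyntheticConfig, AdmixtureEvent, generate_radiation
from mimland.window_stats import compute_window_stats
from mimland.landscape_pca import landscape_pca
from mimland.introgression import four_taxon_test
from mimland.divergence_trajectory import divergence_time

cfg = SyntheticConfig(
    n_windows=120, n_chrom=6, window_bp=2000, seed=1,
    admixture_events=[AdmixtureEvent("aurantiacus", "red", time=1000,
                                     fraction=0.3, windows=list(range(30)))],
)
data = generate_radiation(cfg)
stats = compute_window_stats(data.matrix, data.windows,
                             min_genotyped=3, outgroup="clevelandii", outgroup_min=2)

pca = landscape_pca(stats["fst"].drop(columns=["chrom", "start", "end"]))
print(f"PC1 explains {100 * pca.variance_explained[0]:.1f}% of F_ST variation "
      f"across {len(pca.variables)} taxon pairs")

res = four_taxon_test(data.matrix, ("yellow", "red", "aurantiacus", "clevelandii"),
                      windows=data.windows, block_bp=8000, seed=1)
print(f"Patterson's D = {res.D:.3f} (Z = {res.z:.1f}), admixture fraction f = {res.f:.3f}")

fd = res.fd_track["fd"].to_numpy()
admixed = data.truth["admixed"].to_numpy()
print(f"mean f_d: admixed windows {np.nanmean(fd[admixed]):.3f}, "
      f"others {np.nanmean(fd[~admixed]):.3f}")
```

Output:

```
PC1 explains 62.9% of F_ST variation across 36 taxon pairs
Patterson's D = 0.209 (Z = 3.4), admixture fraction f = 0.065
mean f_d: admixed windows 0.207, others 0.057
```

Read: the 36 pairwise F_ST landscapes share most of their topography
(PC1), the four-taxon test detects the simulated gene flow (D
significantly positive; f ≈ the genome-average admixed fraction, here
0.3 × 25% of windows), and the window-based f_d localizes it — the
pulsed windows carry roughly the simulated 30% admixture signal per
window (attenuated by drift since the pulse) while the rest sit near
zero. `divergence_time(d_a, mu, generation_time_years)` converts any
pair's net divergence to a split time in generations or years.

There is also a thin CLI for file-based use:

```bash
mimland synth --seed 1 --out synthetic/
mimland stats --vcf synthetic/radiation.vcf --taxon-map synthetic/taxon_map.tsv \
              --lengths lengths.tsv --size 500000 --step 50000 --outgroup clevelandii
mimland dstat --vcf ... --quartets quartets.tsv --lengths ... --block 500000
mimland simulate --scenario bgs --rescale 20 --reps 5 --seed 42
```

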