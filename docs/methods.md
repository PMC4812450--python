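# Methods

## Scope and model

rohpipe implements a bin-based analysis of individual autozygosity and
cohort variant sharing for small resequencing cohorts, as used in
conservation genomics of managed populations.  Its core quantity is the
per-individual density of heterozygous SNPs in 10-kb genomic bins: runs of
bins with very low density mark runs of homozygosity (ROHs, the two
haplotypes coalescing in a recent ancestor), and the mean density outside
ROHs is the individual's nucleotide-diversity proxy π (SNPs per 10-kb
bin).  Long ROHs indicate recent consanguinity; short ROHs older
inbreeding, because recombination and mutation erode runs over time.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| bin size | 10,000 bp | adjacent, non-overlapping tiling windows |
| depth window | 0.5–2.0 × sample mean, inclusive | per-sample genotype masking |
| min covered sites | 1,000 (10 % of bin) | bins below are excluded |
| ROH minimum run | 20 consecutive retained bins | |
| ROH cutoff | scaled count < 0.33 × genomic average (strict) | |
| gap tolerance | 0 bins (configurable) | a failing bin terminates a run |
| sex chromosomes | X, Y excluded | different recombination landscape |
| length categories | 0.2, 0.5, 1, 2, 5 Mb, half-open [lo, hi) | short vs long ROHs |
| minor-allele count | ≥ 2 haplotypes | removes likely spurious singleton calls |
| SIFT threshold | 0.05, strict < | not-tolerated vs tolerated nonsynonymous |

Design choices where the definition was genuinely open:

- **Windows tile, not slide.**  "Sliding window" binning is implemented as
  adjacent non-overlapping windows (step = width): only then does ROH
  length equal `n_bins × 10 kb` and does each SNP count exactly once.
- **Scaling correction.**  `scaled = raw × 10000 / covered_sites`
  extrapolates the SNP count from the covered fraction of a bin to its
  full length, removing the downward bias that partial coverage would
  otherwise impose on both π and the ROH cutoff.
- **Covered site** means a position whose depth lies inside the same
  0.5–2.0× window used for variant filtering — one depth criterion is
  used everywhere.
- **Genomic average includes ROH bins.**  The cutoff's reference average
  is defined before ROHs exist; excluding ROH bins would make the
  definition circular.
- **Depth bounds are inclusive** at both ends (mean 10 keeps depths 5 and
  20), and depth filtering masks the offending sample's genotype rather
  than dropping the record, since each sample has its own window.  The
  sample mean depth is computed over non-missing depths only.
- **Partition rules.**  Fixed differences against the reference species
  are operationalised as sites where every non-missing genotype is
  homozygous-alternate (all-reference sites are equally non-variant and
  removed).  The minor allele is counted over cohort haplotypes (het = 1,
  hom = 2); an exact tie treats the alternate allele as minor.  Missing
  genotypes contribute no haplotypes and cannot make a site private.
- **Distances and trees.**  The between-individual metric is the
  allele-sharing (1 − IBS) distance — a reproducible, conventional choice
  for genotype data.  Neighbour joining breaks Q-matrix ties toward the
  lowest (row, column) pair, making output deterministic; negative branch
  estimates are clamped to zero with the deficit moved to the sibling
  branch, preserving the pair's summed length.  Midpoint rooting is exact
  when the midpoint falls strictly inside an edge; the degenerate case of
  a midpoint landing exactly on a node is measure-zero for real data and
  not special-cased.
- **Pedigrees.**  Founders (both parents "WILD") are assumed unrelated and
  non-inbred — the standard studbook assumption, stated explicitly because
  contrasting pedigree F with genomic ROH evidence is the point of
  computing both.  Kinship uses the tabular method in topological order;
  F(i) = f(sire, dam).  Dates parse as ISO-8601; bare years use July 1.
- **Reported means** round half away from zero, matching how integer
  cohort summaries are conventionally quoted.

## The synthetic-data generator

`simulate_individual` places heterozygous sites as a Poisson process with
rate λ per 10-kb bin (default 12, the heterozygosity scale of a severely
bottlenecked suid population) outside planted autozygous tracts and ε·λ
inside them (default ε = 0).  Read depth is modelled per site as
Poisson(mean depth, default 10); the per-bin covered-site count is drawn
as Binomial(10000, p) with p the Poisson mass inside the depth window —
distributionally identical to thresholding 10,000 independent per-site
depths, computed at bin granularity.  Dropout bins lose all coverage and
zero the depths of variants inside them.  Tract positions are
user-specified rather than drawn from a recombination model: exact truth
makes boundary tests sharp, and genetic-map realism is out of scope, as
are sequencing-error and read-level models.

`simulate_cohort` plants exact counts of shared and island-private
variants.  Each site is constructed to pass the MAC ≥ 2 and
fixed-difference rules (one heterozygote per island for shared sites; two
heterozygotes, or one homozygote for a single-sample island, for private
sites), so the partition stage must recover the planted counts exactly.
Cohort sites carry a constant in-window read depth: the generator's
contract is exact count recovery through the full pipeline, and stochastic
depths would let the depth filter mask carriers and silently reclassify
sites.  `simulate_pedigree` emits studbook CSVs for full-sib, half-sib,
first-cousin and outbred designs with known focal F (0.25, 0.125, 0.0625,
0).

What the generator does **not** emulate — linkage disequilibrium, allele
frequency spectra, recombination-driven tract-length distributions,
genotyping error, reference bias — bounds what passing tests show: they
validate the algorithmic pipeline (counting, scaling, thresholds,
run-calling, accounting, tree topology from planted structure), not
robustness to every artefact of real resequencing data.

## Verification strategy and problem sizes

- ROH calling is checked for exact agreement with a brute-force scan over
  every candidate window on 50 random tracks of ≤ 200 bins.
- Planted tracts (0.3 Mb and 1 Mb on a 30-Mb chromosome) are recovered
  with ≤ 1 bin of boundary error per edge over 20 seeded replicates, at
  ε = 0.  At the top of the low-residual regime (ε = 0.05, i.e. 0.6
  residual SNPs per bin) a 30-bin tract has a ≈ 9 % chance of an interior
  bin exceeding the cutoff, which splits the run below the 20-bin minimum
  — a property of the method itself, not of the implementation — so the
  per-tract boundary guarantee is only tested where it mathematically
  holds.
- π recovery is tested within 5 % of λ ∈ {6, 12, 24} on 30-Mb genomes,
  20 replicates each.  These tests supply the simulator's nominal mean
  depth to the filter: an *estimated* mean of, say, 10.008 makes the
  inclusive window [5.004, 20.016] drop every depth-5 site (3.8 % of the
  Poisson(10) mass), a threshold-discreteness artefact of integer depths
  that would add up to ≈ 4 % bias of either sign.  On real data, where the
  window is quoted from a known average coverage, the pipeline estimates
  the mean from the data.
- Neighbour joining is verified exact (≤ 1e-9) on patristic matrices of
  20 random trees with ≤ 8 leaves, and against an independent NJ
  implementation.  Island-clade recovery is tested on cohorts where
  private variation dominates (200 shared / 600 + 600 private): with the
  generator's minimal one-carrier-per-island construction, abundant shared
  variants make same-island samples mutually distant (each of the two
  Negros samples carries roughly half of all shared minor alleles), so
  clade structure emerges only when island-specific variation outweighs
  that noise.
- Tabular kinship agrees exactly with Wright's path-counting oracle on the
  textbook designs and 50 random pedigrees of ≤ 30 individuals.  F can
  legitimately exceed 0.5 under repeated close inbreeding (three
  successive full-sib generations reach 0.5), so the tested bound is
  0 ≤ F < 1.

The per-genome values of the original seven-individual cohort derive from
full whole-genome data and are not recomputable at this scale; the
cohort-level summaries (mean ROH counts and lengths, mean π, partition
totals and the island-specific fraction) are instead recomputed from the
published per-genome table by the same summary functions the pipeline uses
on its own output.

## Known limitations

- ROH calling is threshold-based per bin; no HMM smoothing, so isolated
  noisy bins split runs unless `max_gap_bins` is raised.
- Fixed-difference removal uses the reference-allele proxy, not an
  explicit outgroup genome.
- Variant-effect annotation (VEP/SIFT) is consumed as a precomputed
  table, never computed.
- No admixture/ancestry estimation, no sequential-coalescent demographic
  inference, no bootstrap support values — all outside this package's
  scope.
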